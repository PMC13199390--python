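# Methods

This note documents the models implemented in `lesionscape`, their
assumptions, the defaults that matter, and what the synthetic phantom does
and does not establish about behaviour on real data.

## The phantom: what it emulates

`lesionscape.phantom` generates 3D cohorts on a small grid. The white-matter
(WM) mask is the inscribed ellipsoid of the grid; `k_true` latent clusters
are the Voronoi cells of farthest-point-sampled seeds, so they are spatially
compact and partition the mask. Per voxel and marker, normal-appearing
white matter (NAWM) follows a smooth cubic polynomial in scaled age plus an
additive sex shift — deliberately inside the span of the cubic-spline basis
the normative model fits, so parameter recovery is well-posed. Lesion (WMH)
masks are drawn voxel-wise from a spatially varying prevalence field
(Gaussian bumps at the cluster seeds, peak 0.6 by default) and made coherent
by morphological closing, because real lesions are contiguous.

Within a lesion voxel of cluster c, the marker value is shifted by the
cluster's event cascade evaluated at the subject's latent stage t ∈ [0, 1]:
the cascade is an ordered list of (marker, |z| threshold) events; each
marker's expected abnormality rises piecewise-linearly through its
thresholds up to the cluster's signature magnitude, and the shift is applied
in units of the marker's residual SD with the marker's sign (negative for
FA, ICVF, OD). Latent stages are uniform on [0, 1] and, by default,
perfectly correlated across regions (`stage_mode="shared"`); the alternative
`"independent"` draws one stage per region. Nothing is known empirically
about the joint distribution of regional stages, so the shared default is
simply the stronger coupling assumption and is configurable.

Site effects are an additive location plus multiplicative residual scale per
marker — exactly the structure ComBat models. Group and PRS effects shift
lesion abnormality per (marker, cluster) in SD units.

What the phantom does **not** emulate: anatomically realistic geometry
(ventricles, periventricular gradients), registration or segmentation error,
spatially correlated noise, non-Gaussian marker distributions, longitudinal
structure, and lesion growth coupled to stage (lesion extent is drawn
independently of t). Passing recovery tests therefore demonstrates
correctness of the estimators under the generative assumptions, not
robustness to real-data violations of them.

## Normative modelling

Per voxel and marker, a Bayesian linear regression (Gaussian conjugate
prior; noise and prior precisions by evidence maximization, via
scikit-learn's `BayesianRidge`) on the basis [cubic B-spline of age with 4
interior knots at the {0.2, 0.4, 0.6, 0.8} age quantiles of the training
sample; sex indicator]. The spline basis is a partition of unity, so the
intercept is implicit. Only NAWM-labelled observations enter the fit; voxels
with fewer than `min_nawm` observations are flagged unfitted (default 50 for
synthetic cohorts; real-data analyses of this kind use 5000, which is also
the NAWM prevalence filter below). Predictions clamp age into the training
range rather than extrapolate. The predictive SD combines residual and
parametric variance; at the sample sizes of interest the residual term
dominates. z-scores are only ever computed for WMH voxels — NAWM z-scores
exist solely as a calibration diagnostic (`nawm_zscores`).

Transfer to a new site estimates, per voxel/marker, the location m and scale
s of adaptation-sample NAWM residual z-scores, shrunk toward (0, 1) with
weight n/(n + 10), and applies z' = (z − m)/s. The shrinkage deliberately
leaves a fraction ≈ 10/(n + 10) of any site shift at poorly-observed voxels;
with adaptation samples of one-to-two hundred unaffected subjects the
residual shift is below 0.1 SD. With small training cohorts the per-voxel
shifts also absorb the training cohort's own finite-sample error
(≈ σ·√(p/n_train)), which is why same-site transfer is only identity *on
average* at phantom scale.

## Spatial clustering

Voxels pass two prevalence filters (defaults 30 WMH and 5000 NAWM labels,
matching large-cohort practice; phantom tests override them downward in
proportion to cohort size). The mean abnormality vectors over markers are
clustered with a self-tuning spectral method: Gaussian affinity
`A_ij = exp(−d_ij²/(σ_i σ_j))` with σ_i the distance to the 7th nearest
neighbour, normalized-Laplacian embedding, row-normalized leading
eigenvectors, and k-means with 10 seeded restarts. Features are *not*
re-standardized before clustering: the z-maps are already commensurate
across markers, which is the point of z-scoring. The eigengap selects k* =
argmax over k ∈ 2..k_max of λ_k − λ_{k−1} (ascending Laplacian eigenvalues);
a winning gap below 0.01 is flagged weak.

Search-area completion assigns each unlabelled WM voxel the most prevalent
core label in its Chebyshev neighbourhood, growing the radius by one voxel
until labels are found; ties break to the smallest label; all lookups use
the original core labels, so the result is order-independent and core labels
never change. Dice overlaps restrict to clustered voxels; cross-solution
comparisons match labels by Hungarian assignment maximizing total Dice
before reporting.

## ROI reduction

Median abnormality per (marker, region) within the subject's lesion voxels;
regions with fewer than 5 lesion voxels are imputed as 0 (no lesion-related
abnormality) and flagged. Regional volume is voxel count × voxel volume,
log(x + 1)-transformed — the +1 mm³ offset keeps lesion-free subjects
defined and is irrelevant at realistic volumes. FA/ICVF/OD medians are
sign-inverted so that larger is always worse; the inversion set is recorded
in the feature matrix. Columns are region-major, measure-minor; the
canonical 7-marker panel over 3 regions gives 24 features (8 measures × 3
regions). The disease-contrast family adds the stage as a 9th measure.

## Event-based staging

Events are (marker, threshold) pairs from the base set
Z = (0.5, 1, 1.5, 2, 3, 4, 5), retaining thresholds at least 1% of subjects
reach; a marker's trajectory endpoint z_max is its largest retained
threshold. The likelihood of a subject x under sequence S is
`(1/(|E|+1)) Σ_k Π_m N(x_m; traj_m(k|S), σ_m²)` with σ_m = 1 by default
(the features are z-scores; configurable). Sequences are constrained so each
marker crosses its thresholds in increasing order — without this the
trajectory would not be monotone in stage; random start permutations are
canonicalized into the constraint set and invalid swap proposals are
rejected (they carry zero prior mass).

Inference: greedy full-sweep pairwise-swap ascent from `n_startpoints`
random starts (default 15), then Metropolis MCMC over swap proposals
(default 10,000 samples) from the best start; the MAP sequence is the best
state visited. Stages are posterior modes under the MAP sequence, ties
breaking to the lower stage (stages are reported as integers). Subjects with
all-zero features get stage and subtype 0 by rule. Positional-variance
matrices are event-by-position frequencies over the MCMC samples.

Subtype mixtures grow by splitting the worst-fit subtype: the new sequence
is fitted on the half of subjects the current model explains worst, then
responsibilities, fractions and sequences iterate by EM (sequence M-steps
are responsibility-weighted greedy refits); subtypes collapsing below 0.1%
mass are re-seeded. Solutions are compared by k-fold cross-validated
held-out log-likelihood. Stage–volume associations use Spearman rank
correlation; volume trajectories are least-squares degree-4 B-splines of
each marker against log volume (the quartic basis contains all quartic
polynomials regardless of knot placement).

## Contrasts, harmonization, classification, connectivity

Standardized-β models z-scale the outcome and all continuous predictors
before ordinary least squares; binary predictors stay 0/1, so a group β is
the group difference in outcome-SD units. FDR is Benjamini–Hochberg applied
jointly over each declared family (e.g. 9 measures × 3 regions × 3
diagnoses = 81 p-values for the diagnosis panel). PRS contrasts take the top
1% (alternatively 3%/5%) of the score as cases against the bottom 50%, with
no covariates. Sex differences use two models: volume ~ sex + age, and
pathophysiology ~ sex + age + region-specific volume. Pattern similarity is
Pearson correlation over the shared (measure, region) grid with
complete-linkage clustering on 1 − r.

Harmonization is ComBat with reference-batch fitting: per-site location and
scale of standardized residuals are estimated on control rows only (age and
sex effects estimated jointly and preserved), shrunk across features by the
standard parametric empirical-Bayes priors (normal / inverse-gamma,
moment-matched), and the correction applied to all rows. Re-fitting on
harmonized data yields a near-identity model, which is the operative
idempotence property; the residual site gap after harmonization scales with
the per-feature sampling noise of the reference sample (≈ 0.06–0.08 SD at
420 reference subjects per site against a 1-SD injected shift).

Classification is L1-penalized logistic regression (C = 1, saga solver,
balanced class weights, max_iter 1000, seeded) in a scaler+classifier
pipeline fitted strictly inside training folds; stratified 5-fold splits are
shared across predictor sets within a repeat (seeded seed + repeat), and
AUROC / balanced accuracy / F1 (positive = minority class, 0.5 threshold)
are computed from pooled out-of-fold predictions. F1's positive class is the
minority (disease) class — a documented choice. Predictor sets are compared
by paired Wilcoxon signed-rank tests across repeats, Bonferroni-corrected
over all pairs.

Connectivity counts a streamline into cluster c if any rounded polyline
point lies in a c-labelled voxel, crediting both endpoint parcels (endpoint
attribution, matching connectome-matrix margins); parcel profiles normalize
counts across clusters, and zero-count parcels are flagged and excluded from
correlations. Fiber atlases take per-bundle tract-density maxima within each
class and winner-take-all across classes, ties in the fixed order
association → projection → commissural. Spin tests rotate parcel centroids
Haar-uniformly (SO(3)), reassign one map by nearest rotated centroid, and
use the two-sided permutation p `(1 + #{|r_null| ≥ |r_obs|})/(1 + n_perm)`;
the null permutes values only, preserving each map's multiset and
autocorrelation.

## Problem sizes and numerical conventions

Test and acceptance runs use phantom scales chosen so each estimator's
sampling noise sits well below the property being checked: 16³ grids with
~1100 WM voxels and 100–120 subjects for clustering recovery (20 seeds);
300-subject training cohorts with ≥ 2000 pooled held-out NAWM observations
per marker for z calibration; n = 500 subjects, σ = 1, and the full
49-event panel for staging recovery (10 seeds); n = 2000 for β recovery and
200 replicates for null calibrations; 1200 subjects (two sites) for
harmonization; 200 replicates × 199 permutations for spin calibration.
Monte-Carlo calibration checks compare empirical proportions against their
nominal level plus a one-sided 95% binomial envelope — with 200 replicates a
procedure with exact 5% family-wise error still produces proportions up to
≈ 0.075 by chance.

Tie-breaks are deterministic throughout: smallest label in search-area
votes, lower stage at posterior ties, first fiber class in the fixed order,
stable sorts in canonicalization. All stochastic steps consume explicit
seeds; identical seeds give bit-identical outputs.

## Known limitations

- Spectral clustering is O(n²) in included voxels (dense affinity and eigen
  decomposition); realistic full-brain maps need landmarking or sparse
  affinities, which are out of scope here.
- The event model fixes marker noise at σ = 1 rather than estimating it;
  this matches z-scored inputs but under- or over-weights markers whose
  residual calibration is imperfect.
- The greedy+MCMC sequence search is a local optimizer with restarts; for
  event counts beyond ~50 the swap MCMC mixes slowly and positional
  variances become optimistic.
- ComBat assumes Gaussian site effects and exchangeable features; the
  reference-controls variant further assumes controls are comparable across
  sites apart from site effects.
- The spin test treats parcels as points (their centroids); parcel area and
  adjacency structure are ignored, which is the standard centroid-rotation
  approximation.
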