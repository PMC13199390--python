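# lesionscape

Spatiotemporal modelling of white-matter-hyperintensity (WMH) microstructural
pathophysiology.

WMHs — bright regions on FLAIR MRI of ageing brains — are treated clinically
as one entity, yet their tissue damage is heterogeneous: different lesions
carry different mixtures of fluid accumulation, demyelination, axonal loss
and iron change. `lesionscape` implements an analysis pipeline that parses
this heterogeneity from multimodal microstructural MRI (DTI: MD, FA; NODDI:
ISOVF, ICVF, OD; susceptibility: T2*, QSM), for researchers studying
cerebrovascular and neurodegenerative disease in large imaging cohorts:

1. **Voxel-wise normative modelling.** For each voxel v and marker m, a
   Bayesian linear regression is fitted to normal-appearing white matter
   (NAWM) values across subjects, `x_{ivm} = f(age_i; cubic B-spline, 4 knots)
   + β_sex · sex_i + ε`, with hyperparameters set by evidence maximization.
   Lesion voxels are then expressed as abnormality z-scores
   `z = (x − μ̂(age, sex)) / σ̂`, removing normal anatomical contrast so that
   only the lesion's deviation from expected-normal tissue remains. Models
   transfer to a second cohort via location/scale recalibration of residuals
   on an adaptation sample of unaffected subjects.
2. **Spatial clustering.** Voxels with low WMH or NAWM label prevalence are
   excluded; between-subject mean abnormality maps per marker feed a
   self-tuning spectral clustering (Gaussian affinity with 7th-nearest-
   neighbour local scales, normalized-Laplacian embedding), with the cluster
   count checked by the Laplacian eigengap. The parcellation is completed
   over the whole white matter by iterative search-area majority voting.
3. **ROI reduction.** Median abnormality per (marker, region) plus
   log-transformed regional lesion volume; regions with < 5 lesion voxels are
   imputed as 0; markers with negative lesion effects (FA, ICVF, OD) are
   sign-inverted so larger always means worse.
4. **Temporal staging.** A piecewise-linear z-score event-based progression
   model: each (marker, z-threshold) pair from Z = (0.5, 1, 1.5, 2, 3, 4, 5)
   that ≥ 1% of subjects reach is an event; a subject at stage k follows
   `x_m ~ N(traj_m(k | S), σ_m²)` with a uniform stage prior, where S is the
   event sequence. Sequences are inferred by greedy pairwise-swap ascent plus
   Metropolis MCMC; subjects get posterior-mode stages; lesion-free subjects
   get stage 0. Subtype mixtures are fitted by split-and-refit EM and
   compared by cross-validated log-likelihood.
5. **Effect patterns and classification.** Standardized-β linear models for
   case-control, PRS-extreme-group, sex and interaction contrasts, with
   Benjamini–Hochberg FDR per declared family; pattern correlation +
   hierarchical clustering; ComBat (reference-controls, parametric empirical
   Bayes) harmonization; L1 logistic classification under repeated stratified
   cross-validation with paired Wilcoxon comparisons of predictor sets.
6. **Connectivity profiles.** Streamline counts through each lesion cluster
   per cortical endpoint parcel, normalized per parcel; winner-take-all
   tract-density fiber-class atlases; Pearson correlations against cortical
   parcel maps (e.g. PET SUVR) with spin-test spatial permutation nulls.

Because the cohorts such analyses run on are access-controlled, the package
ships a first-class synthetic-phantom module (`lesionscape.phantom`) that
generates cohorts with known normative trends, cluster structure, event
cascades, site and group effects — every stage above is validated against
that ground truth.

## Worked example

```python
import numpy as np
from lesionscape import phantom, normative, clusters, roi, staging

cfg = phantom.PhantomConfig(grid_shape=(16, 16, 16), k_true=3, n_subjects=120, seed=1)
truth, volumes, table = phantom.simulate_cohort(cfg)

norm = normative.NormativeModel(volumes, table, min_nawm=30).fit()
zmaps = normative.zscore_cohort(norm, volumes, table)

prev = clusters.compute_prevalence(volumes)
mean_maps = clusters.mean_patho_maps(zmaps, prev, tau_wmh=10, tau_nawm=30)
k_star, gaps, weak = clusters.eigengap_select(
    clusters.self_tuning_affinity(mean_maps.values))
parcel = clusters.spectral_cluster(mean_maps, K=3, seed=0)
extended = clusters.assign_excluded_voxels(parcel, truth.wm_mask)
print(f"eigengap k* = {k_star}")

ref = clusters.ClusterParcellation(truth.true_cluster_map,
                                   (truth.true_cluster_map > 0).astype(int), K=3)
_, dice = clusters.match_clusters(ref, parcel)
print("Dice vs ground truth:", {c: round(d, 3) for c, d in sorted(dice.items())})

features = roi.assemble_feature_matrix(zmaps, volumes, extended)
print(f"ROI features per subject: {features.data.shape[1]}")

region1 = features.region_block(1)
fit = staging.ZScoreEventModel(region1).fit(n_startpoints=5, n_mcmc=2000, seed=1)
stages = fit.stage_subjects(region1)
rho, p = staging.stage_volume_association(stages.stages,
                                          features.data["logvol_region1"])
print(fit.summary().head(5).to_string(index=False))
print(f"stage-volume Spearman rho = {rho:.2f} (p = {p:.1e})")
```

prints

```
eigengap k* = 3
Dice vs ground truth: {1: 1.0, 2: 1.0, 3: 1.0}
ROI features per subject: 24
 position     marker  threshold  position_certainty
        1 FA_region1        0.5              1.0000
        2 FA_region1        1.0              0.7880
        3 FA_region1        1.5              0.5410
        4 MD_region1        0.5              0.3095
        5 FA_region1        2.0              0.4065
stage-volume Spearman rho = 0.15 (p = 1.1e-01)
```

The eigengap agrees with the three generated clusters and spectral clustering
recovers them perfectly (Dice 1.0 after optimal label matching). The 7-marker
panel over 3 regions gives the 24 ROI features (8 measures × 3 regions). The
staging summary lists the inferred event sequence for region 1 with the
posterior certainty of each event's position. The stage–volume correlation is
near zero here because the phantom draws lesion extent independently of the
latent stage; in real cohorts, where lesions grow as disease progresses,
this association is the check that stages track an empirical progression
proxy.

A thin CLI mirrors the main entry points:

```bash
lesionscape simulate --out cohort/ --seed 7      # NIfTI volumes + subject CSV
lesionscape cluster --k 3 --n-subjects 120       # phantom pipeline -> Dice
lesionscape stage --features region1.csv         # event model on a feature CSV
```

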