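"""Spatial clustering of mean lesion pathophysiology maps.

Voxels are filtered by lesion/normal-tissue prevalence (voxels rarely covered
by WMH labels, or with too few NAWM observations to support a normative fit,
are excluded), subject-level abnormality z-maps are averaged into mean
pathophysiology maps per marker, and the per-voxel marker vectors are
clustered with self-tuning spectral clustering. The eigengap of the
normalized graph Laplacian selects the cluster count. Voxels excluded by the
prevalence filters are afterwards completed into a full white-matter
parcellation by iterative search-area majority voting. Overlap and stability
are quantified with Dice similarity coefficients after optimal label matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .phantom import LABEL_NAWM, LABEL_WMH

#: prevalence filters of the large-cohort analysis (overridable everywhere)
DEFAULT_TAU_WMH = 30
DEFAULT_TAU_NAWM = 5000

PROV_NONE, PROV_CORE, PROV_EXTENDED = 0, 1, 2


@dataclass
class PrevalenceMaps:
    n_wmh: np.ndarray  # 3D int: subjects with a WMH label at each voxel
    n_nawm: np.ndarray  # 3D int: subjects with a NAWM label
    n_subjects: int


@dataclass
class MeanPathoMaps:
    """Between-subject mean abnormality per marker on the included voxels."""

    grid_shape: tuple
    markers: tuple
    flat_indices: np.ndarray  # included voxels (prevalence filters applied)
    values: np.ndarray  # (n_included, n_markers)

    @property
    def inclusion_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m.ravel()[self.flat_indices] = True
        return m


@dataclass
class ClusterParcellation:
    labels: np.ndarray  # 3D int, 0 = unassigned
    provenance: np.ndarray  # 3D int: 0 none, 1 core, 2 search-area-extended
    K: int

    def core_mask(self) -> np.ndarray:
        return self.provenance == PROV_CORE


def compute_prevalence(label_volumes) -> PrevalenceMaps:
    """Exact per-voxel counts of WMH and NAWM labels across the cohort."""
    vols = [sv.label_volume if hasattr(sv, "label_volume") else sv for sv in label_volumes]
    n_wmh = np.zeros(vols[0].shape, dtype=int)
    n_nawm = np.zeros_like(n_wmh)
    for lab in vols:
        n_wmh += lab == LABEL_WMH
        n_nawm += lab == LABEL_NAWM
    return PrevalenceMaps(n_wmh=n_wmh, n_nawm=n_nawm, n_subjects=len(vols))


def mean_patho_maps(
    abnormality_maps,
    prevalence: PrevalenceMaps,
    tau_wmh: int = DEFAULT_TAU_WMH,
    tau_nawm: int = DEFAULT_TAU_NAWM,
) -> MeanPathoMaps:
    """Average subject abnormality maps at voxels passing both prevalence filters."""
    if tau_wmh < 1 or tau_nawm < 1:
        raise ValueError("prevalence thresholds must be >= 1")
    include = (prevalence.n_wmh >= tau_wmh) & (prevalence.n_nawm >= tau_nawm)
    flat = np.flatnonzero(include.ravel())
    if flat.size == 0:
        raise ValueError("prevalence filters exclude every voxel")
    markers = abnormality_maps[0].markers
    grid_shape = prevalence.n_wmh.shape
    pos = np.full(int(np.prod(grid_shape)), -1, dtype=int)
    pos[flat] = np.arange(flat.size)
    acc = np.zeros((flat.size, len(markers)))
    cnt = np.zeros(flat.size)
    for am in abnormality_maps:
        rows = pos[am.flat_indices]
        ok = rows >= 0
        np.add.at(acc, rows[ok], am.z[ok])
        np.add.at(cnt, rows[ok], 1.0)
    cnt = np.maximum(cnt, 1.0)
    return MeanPathoMaps(
        grid_shape=grid_shape, markers=markers, flat_indices=flat, values=acc / cnt[:, None]
    )


def sem_curve(abnormality_maps, prevalence: PrevalenceMaps, bins) -> pd.DataFrame:
    """Standard error of the voxel-wise mean abnormality, by WMH-prevalence bin.

    SEM(v) = SD over subjects with WMH at v, divided by sqrt(n_WMH(v)),
    averaged over markers then over the voxels of each prevalence bin. Bins
    with no voxels are omitted.
    """
    grid_n = int(np.prod(prevalence.n_wmh.shape))
    markers = abnormality_maps[0].markers
    n = np.zeros(grid_n)
    s1 = np.zeros((grid_n, len(markers)))
    s2 = np.zeros_like(s1)
    for am in abnormality_maps:
        np.add.at(n, am.flat_indices, 1.0)
        np.add.at(s1, am.flat_indices, am.z)
        np.add.at(s2, am.flat_indices, am.z**2)
    sel = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1[sel] / n[sel, None]
        var = np.maximum(s2[sel] / n[sel, None] - mean**2, 0.0) * (n[sel, None] / (n[sel, None] - 1))
        sem = np.sqrt(var) / np.sqrt(n[sel, None])
    sem_v = sem.mean(axis=1)
    n_v = n[sel]
    edges = np.asarray(bins, float)
    rows = []
    which = np.digitize(n_v, edges)
    for b in range(1, len(edges)):
        m = which == b
        if m.any():
            rows.append(
                dict(bin_low=edges[b - 1], bin_high=edges[b], n_voxels=int(m.sum()),
                     mean_sem=float(sem_v[m].mean()), mean_n=float(n_v[m].mean()))
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# spectral clustering with self-tuning local scales
# --------------------------------------------------------------------------


def self_tuning_affinity(features: np.ndarray, n_neighbor: int = 7) -> np.ndarray:
    """Gaussian similarity with local scales set to the 7th-NN distance.

    A_ij = exp(-d_ij^2 / (sigma_i sigma_j)); zero diagonal. Duplicate feature
    rows can drive a local scale to zero; they are floored with a warning.
    """
    d = np.linalg.norm(features[:, None, :] - features[None, :, :], axis=-1)
    ds = np.sort(d, axis=1)
    k = min(n_neighbor, d.shape[0] - 1)
    sigma = ds[:, k]
    if np.any(sigma <= 0):
        warnings.warn("duplicate feature rows: flooring zero local scales (jitter)")
        floor = max(ds[ds > 0].min() if (ds > 0).any() else 1.0, 1e-12) * 1e-3
        sigma = np.maximum(sigma, floor)
    A = np.exp(-(d**2) / np.outer(sigma, sigma))
    np.fill_diagonal(A, 0.0)
    return A


def _normalized_laplacian(A: np.ndarray) -> np.ndarray:
    deg = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    return np.eye(len(A)) - dinv[:, None] * A * dinv[None, :]


def laplacian_eigenvalues(A: np.ndarray, k_max: int | None = None) -> np.ndarray:
    L = _normalized_laplacian(A)
    vals = eigh(L, eigvals_only=True)
    return vals if k_max is None else vals[: k_max + 1]


def eigengap_select(A: np.ndarray, k_max: int = 10):
    """Pick k* = argmax of successive normalized-Laplacian eigenvalue gaps.

    Searches k in 2..k_max; returns ``(k_star, gaps, weak)`` where ``weak``
    flags a near-zero winning gap (no clear cluster structure).
    """
    vals = laplacian_eigenvalues(A, k_max=k_max)
    gaps = {k: float(vals[k] - vals[k - 1]) for k in range(2, min(k_max, len(vals) - 1) + 1)}
    k_star = max(gaps, key=gaps.get)
    weak = gaps[k_star] < 1e-2
    return k_star, gaps, weak


def spectral_cluster(
    mean_maps: MeanPathoMaps, K: int, seed: int = 0, n_restarts: int = 10, n_neighbor: int = 7
) -> ClusterParcellation:
    """Cluster included voxels on their mean-abnormality marker vectors.

    Normalized-Laplacian embedding of the self-tuning affinity, row-normalized
    eigenvectors, centroid partition (k-means with ``n_restarts`` seeded
    restarts). Labels are 1..K on the inclusion mask, 0 elsewhere.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    X = mean_maps.values
    if X.shape[0] < 10 * K:
        raise ValueError(f"only {X.shape[0]} included voxels for K={K} (need >= {10 * K})")
    A = self_tuning_affinity(X, n_neighbor=n_neighbor)
    L = _normalized_laplacian(A)
    vals, vecs = eigh(L)
    emb = vecs[:, :K]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    lab = km.fit_predict(emb) + 1
    labels = np.zeros(mean_maps.grid_shape, dtype=int)
    labels.ravel()[mean_maps.flat_indices] = lab
    prov = np.zeros_like(labels)
    prov.ravel()[mean_maps.flat_indices] = PROV_CORE
    return ClusterParcellation(labels=labels, provenance=prov, K=K)


# --------------------------------------------------------------------------
# overlap, completion, variance explained, stability
# --------------------------------------------------------------------------


def dice_overlap(parcel_a, parcel_b, restrict: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise Dice similarity between the labels of two parcellations.

    Only voxels in ``restrict`` (default: voxels labelled in either
    parcellation — i.e. clustered voxels only) enter the calculation.
    """
    la = parcel_a.labels if isinstance(parcel_a, ClusterParcellation) else np.asarray(parcel_a)
    lb = parcel_b.labels if isinstance(parcel_b, ClusterParcellation) else np.asarray(parcel_b)
    if restrict is None:
        restrict = (la > 0) | (lb > 0)
    la = np.where(restrict, la, 0)
    lb = np.where(restrict, lb, 0)
    labs_a = [int(v) for v in np.unique(la) if v > 0]
    labs_b = [int(v) for v in np.unique(lb) if v > 0]
    out = np.zeros((len(labs_a), len(labs_b)))
    for i, a in enumerate(labs_a):
        ma = la == a
        for j, b in enumerate(labs_b):
            mb = lb == b
            denom = ma.sum() + mb.sum()
            out[i, j] = 2.0 * np.logical_and(ma, mb).sum() / denom if denom else 0.0
    return pd.DataFrame(out, index=labs_a, columns=labs_b)


def assign_excluded_voxels(core: ClusterParcellation, wm_mask: np.ndarray) -> ClusterParcellation:
    """Complete the parcellation over the WM mask by search-area majority vote.

    For every unassigned WM voxel, the core labels within a Chebyshev
    neighborhood (26-connectivity at radius 1) are tallied; the most prevalent
    label wins, ties go to the smallest label. The search area grows by one
    voxel per step until it contains core-labelled voxels. Core labels never
    change; extended voxels are flagged in the provenance map.
    """
    labels = core.labels.copy()
    prov = core.provenance.copy()
    base = core.labels  # assignments always sample the original core labels
    shape = labels.shape
    todo = np.argwhere(wm_mask & (base == 0))
    if (base > 0).sum() == 0:
        raise ValueError("no labeled voxels to extend from")
    max_r = max(shape)
    for x, y, z in todo:
        for r in range(1, max_r + 1):
            sl = tuple(
                slice(max(c - r, 0), min(c + r + 1, s))
                for c, s in zip((x, y, z), shape)
            )
            window = base[sl]
            found = window[window > 0]
            if found.size:
                counts = np.bincount(found)
                labels[x, y, z] = int(np.argmax(counts))  # argmax -> smallest on ties
                prov[x, y, z] = PROV_EXTENDED
                break
    return ClusterParcellation(labels=labels, provenance=prov, K=core.K)


def cluster_variance_explained(mean_maps: MeanPathoMaps, parcel: ClusterParcellation) -> pd.Series:
    """One-way-ANOVA R^2 of each marker's mean map by cluster label."""
    lab = parcel.labels.ravel()[mean_maps.flat_indices]
    sel = lab > 0
    lab = lab[sel]
    if np.unique(lab).size < 2:
        raise ValueError("need >= 2 clusters")
    out = {}
    for j, m in enumerate(mean_maps.markers):
        y = mean_maps.values[sel, j]
        grand = y.mean()
        ss_tot = np.sum((y - grand) ** 2)
        if ss_tot == 0:
            out[m] = np.nan  # zero total variance: undefined
            continue
        ss_b = sum(
            (lab == c).sum() * (y[lab == c].mean() - grand) ** 2 for c in np.unique(lab)
        )
        out[m] = float(ss_b / ss_tot)
    return pd.Series(out, name="r2")


def match_clusters(reference: ClusterParcellation, other: ClusterParcellation):
    """Optimal (Hungarian) label matching maximizing total Dice.

    Returns ``(mapping, matched_dice)`` where mapping maps other-labels to
    reference-labels, computed on voxels labelled in both parcellations.
    """
    both = (reference.labels > 0) & (other.labels > 0)
    d = dice_overlap(reference, other, restrict=both)
    ri, ci = linear_sum_assignment(-d.to_numpy())
    mapping = {int(d.columns[c]): int(d.index[r]) for r, c in zip(ri, ci)}
    matched = {int(d.index[r]): float(d.to_numpy()[r, c]) for r, c in zip(ri, ci)}
    return mapping, matched


def wmh_volume_mm3(label_volume: np.ndarray, voxel_volume: float = 1.0) -> float:
    return float((label_volume == LABEL_WMH).sum() * voxel_volume)


def volume_bins(vols_mm3, edges=(5000.0, 10000.0)) -> np.ndarray:
    """Assign 'low' (<= edges[0]), 'medium' (<= edges[1]), 'high' (> edges[1])."""
    v = np.asarray(vols_mm3, float)
    out = np.where(v <= edges[0], "low", np.where(v <= edges[1], "medium", "high"))
    return out


def subgroup_stability(
    abnormality_maps,
    label_volumes,
    groups,
    K: int,
    tau_wmh: int = DEFAULT_TAU_WMH,
    tau_nawm: int = DEFAULT_TAU_NAWM,
    reference: ClusterParcellation | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-cluster within subgroups and report matched Dice vs the reference.

    ``groups`` is a per-subject array of subgroup names (e.g. WMH-volume bins
    or sex). Clusters of each subgroup solution are matched to the reference
    by optimal assignment before Dice is reported, using only voxels labelled
    in both solutions. Subgroups too small to cluster are flagged.
    """
    groups = np.asarray(groups)
    if reference is None:
        prev = compute_prevalence(label_volumes)
        mm = mean_patho_maps(abnormality_maps, prev, tau_wmh, tau_nawm)
        reference = spectral_cluster(mm, K, seed=seed)
    rows = []
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub_maps = [abnormality_maps[i] for i in idx]
        sub_labels = [label_volumes[i] for i in idx]
        try:
            prev_g = compute_prevalence(sub_labels)
            mm_g = mean_patho_maps(sub_maps, prev_g, tau_wmh, tau_nawm)
            parcel_g = spectral_cluster(mm_g, K, seed=seed)
        except ValueError as e:
            rows.append(dict(subgroup=str(g), cluster=np.nan, dice=np.nan, flag=str(e)))
            continue
        _, matched = match_clusters(reference, parcel_g)
        for c, dsc in matched.items():
            rows.append(dict(subgroup=str(g), cluster=c, dice=dsc, flag=""))
    return pd.DataFrame(rows)
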