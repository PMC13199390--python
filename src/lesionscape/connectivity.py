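"""Streamline connectivity profiles of lesion clusters and spin-test nulls.

Streamlines (voxel-coordinate polylines with cortical endpoint parcels) are
intersected with the extended lesion-cluster parcellation: a streamline
"passes through" a cluster when any rounded polyline point lands in a voxel
of that cluster, and both endpoint parcels of a passing streamline are
credited. Counts are normalized per parcel across clusters, so each parcel's
profile sums to 1. A three-class fiber atlas (association / commissural /
projection) is built by winner-take-all voting on per-bundle tract density.
Cortical maps (e.g. PET SUVR per parcel) are compared to connectivity
profiles with Pearson correlations whose null distribution preserves spatial
autocorrelation: parcel centroids are rotated uniformly on the sphere and
values reassigned to the nearest rotated centroid (a "spin test").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import special_ortho_group

FIBER_CLASSES = ("association", "projection", "commissural")  # tie-break order


@dataclass
class Tractogram:
    """Polyline streamlines in voxel coordinates with endpoint parcel labels."""

    streamlines: list  # list of (n_points, 3) float arrays, n_points >= 2
    endpoint_labels: list  # list of (parcel_a, parcel_b); None = unlabeled
    bundle_ids: list | None = None  # optional per-streamline bundle id
    bundle_classes: dict | None = None  # bundle id -> fiber class

    def __post_init__(self):
        for line in self.streamlines:
            if len(line) < 2:
                raise ValueError("streamlines need >= 2 points")

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class ConnectivityProfile:
    """Streamline counts and per-parcel normalized weights per cluster."""

    counts: pd.DataFrame  # parcels x clusters, N(r, c)
    weights: pd.DataFrame | None = None  # w(r, c), rows sum to 1 where nonzero
    n_skipped: int = 0  # streamlines with unlabeled endpoints
    zero_parcels: list = field(default_factory=list)


def _passes_through(line: np.ndarray, labels: np.ndarray, cluster: int) -> bool:
    pts = np.rint(line).astype(int)
    ok = np.all((pts >= 0) & (pts < np.array(labels.shape)), axis=1)
    pts = pts[ok]
    if not len(pts):
        return False
    return bool(np.any(labels[pts[:, 0], pts[:, 1], pts[:, 2]] == cluster))


def streamline_cluster_counts(
    tract: Tractogram, parcellation, cluster_ids=None, n_parcels: int | None = None
) -> ConnectivityProfile:
    """Count streamlines touching each cluster, credited to both endpoints.

    N(r, c) increments for each endpoint parcel r of every streamline with at
    least one rounded point inside cluster c. Streamlines without endpoint
    labels are skipped and counted.
    """
    labels = parcellation.labels if hasattr(parcellation, "labels") else np.asarray(parcellation)
    if cluster_ids is None:
        cluster_ids = [int(c) for c in np.unique(labels) if c > 0]
    parcels = range(
        n_parcels
        if n_parcels is not None
        else 1 + max((max(e) for e in tract.endpoint_labels if e is not None), default=0)
    )
    counts = pd.DataFrame(0, index=list(parcels), columns=list(cluster_ids))
    skipped = 0
    for line, ends in zip(tract.streamlines, tract.endpoint_labels):
        if ends is None:
            skipped += 1
            continue
        for c in cluster_ids:
            if _passes_through(line, labels, c):
                counts.loc[ends[0], c] += 1
                counts.loc[ends[1], c] += 1
    return ConnectivityProfile(counts=counts, n_skipped=skipped)


def normalize_connectivity(profile: ConnectivityProfile) -> ConnectivityProfile:
    """w(r, c) = N(r, c) / sum_c' N(r, c'); zero-total parcels stay 0, flagged."""
    N = profile.counts
    totals = N.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    w = N.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return ConnectivityProfile(
        counts=N, weights=w, n_skipped=profile.n_skipped, zero_parcels=zero
    )


def tdi_fiber_atlas(tract: Tractogram, grid_shape: tuple) -> np.ndarray:
    """Winner-take-all fiber-class atlas from per-bundle tract density.

    Per voxel: count unique streamlines of each bundle passing through
    (tract density index), take the max TDI within each fiber class, then the
    argmax class; ties break by the fixed class order
    (association, projection, commissural). Returns an int volume with 0 =
    empty, 1..3 = class index in that order.
    """
    if tract.bundle_ids is None or tract.bundle_classes is None:
        raise ValueError("tractogram has no bundle/class annotations")
    if len(tract) == 0:
        return np.zeros(grid_shape, dtype=int)
    bundles = sorted(set(tract.bundle_ids))
    tdi = {b: np.zeros(grid_shape) for b in bundles}
    for line, b in zip(tract.streamlines, tract.bundle_ids):
        pts = np.rint(line).astype(int)
        ok = np.all((pts >= 0) & (pts < np.array(grid_shape)), axis=1)
        pts = np.unique(pts[ok], axis=0)  # one count per streamline per voxel
        if len(pts):
            tdi[b][pts[:, 0], pts[:, 1], pts[:, 2]] += 1
    class_density = np.zeros((len(FIBER_CLASSES),) + tuple(grid_shape))
    for b in bundles:
        k = FIBER_CLASSES.index(tract.bundle_classes[b])
        class_density[k] = np.maximum(class_density[k], tdi[b])
    atlas = np.argmax(class_density, axis=0) + 1  # argmax -> first class on ties
    atlas[class_density.max(axis=0) == 0] = 0
    return atlas


def spatial_correlation_spin(
    map_a, map_b, centroids: np.ndarray, n_perm: int = 10000, seed: int = 0
):
    """Pearson r between parcel maps with a rotation-based permutation p-value.

    The null rotates the parcel centroids Haar-uniformly on the sphere and
    reassigns ``map_a`` values by nearest rotated centroid, preserving each
    map's value multiset and spatial autocorrelation. Two-sided
    p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_perm).
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    cen = np.asarray(centroids, float)
    if len(a) < 4:
        raise ValueError("need >= 4 parcels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map: correlation undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        R = special_ortho_group.rvs(3, random_state=rng)
        rotated = cen @ R.T
        # nearest original centroid for each rotated centroid
        sim = rotated @ cen.T
        nearest = np.argmax(sim, axis=1)
        r_null = np.corrcoef(a[nearest], b)[0, 1]
        if abs(r_null) >= abs(r_obs):
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return r_obs, float(p)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni correction over a declared comparison family."""
    p = np.asarray(pvals, float)
    m = m if m is not None else p.size
    return np.minimum(p * m, 1.0)
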