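"""Synthetic phantom cohorts with known spatiotemporal lesion structure.

The phantom emulates the statistical structure of a large lesion-microstructure
study on a small 3D grid: a white-matter (WM) mask partitioned into ``k_true``
spatially compact latent clusters, per-voxel normative age/sex trends for each
microstructural marker, a spatially varying WMH prevalence field, and — within
lesions — a per-cluster temporal cascade of threshold-crossing abnormality
events scaled by a cluster-specific signature. Site effects (additive location
+ multiplicative scale per marker) and group effects (per marker x cluster, in
SD units) are injected on top, so that every downstream stage (normative
z-scoring, spatial clustering, event-based staging, case-control contrasts,
harmonization, classification) can be validated against known ground truth.

Markers follow the convention of diffusion/NODDI/susceptibility panels: some
markers increase inside lesions (e.g. mean diffusivity, free-water fraction)
and some decrease (anisotropy, neurite density, dispersion); the signature
matrix carries the sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_MARKERS = ("MD", "FA", "ISOVF", "ICVF", "OD", "T2star", "QSM")
#: markers whose lesion abnormality is negative in raw z units
NEGATIVE_MARKERS = ("FA", "ICVF", "OD")

LABEL_BACKGROUND = 0
LABEL_NAWM = 1
LABEL_WMH = 2


def _marker_sign(name: str) -> int:
    return -1 if name in NEGATIVE_MARKERS else 1


@dataclass
class SiteSpec:
    """Additive location + multiplicative scale shift per marker."""

    name: str
    shift: dict = field(default_factory=dict)  # marker -> additive offset (marker units)
    scale: dict = field(default_factory=dict)  # marker -> residual scale factor
    frac: float = 1.0


@dataclass
class GroupSpec:
    """Disease group with per-(marker, cluster) abnormality shifts in SD units."""

    name: str
    effects: dict = field(default_factory=dict)  # (marker, cluster_id) -> shift in SD
    frac: float = 1.0


@dataclass
class PhantomConfig:
    grid_shape: tuple = (24, 24, 24)
    k_true: int = 3
    markers: tuple = DEFAULT_MARKERS
    #: asymptotic mean abnormality z per (cluster, marker); signed
    signature: np.ndarray | None = None
    #: per cluster, ordered list of (marker, |z| threshold) events
    cascade: list | None = None
    #: parameters of the spatial WMH probability field
    prevalence_peak: float = 0.6
    prevalence_length_scale: float = 5.0
    n_subjects: int = 200
    age_range: tuple = (45.0, 81.0)
    sex_ratio: float = 0.5  # fraction of females (sex coded 1)
    sites: list = field(default_factory=lambda: [SiteSpec("site0")])
    groups: list = field(default_factory=lambda: [GroupSpec("control")])
    #: per-(marker, cluster) slope of abnormality (SD units) per SD of PRS
    prs_effects: dict = field(default_factory=dict)
    noise_sd: dict | float = 1.0
    #: "shared": one latent stage per subject; "independent": one per region
    stage_mode: str = "shared"
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if not (0.0 <= self.prevalence_peak <= 1.0):
            raise ValueError("prevalence probabilities must lie in [0, 1]")
        self.markers = tuple(self.markers)
        if self.signature is None:
            self.signature = default_signature(self.k_true, self.markers)
        self.signature = np.asarray(self.signature, dtype=float)
        if self.signature.shape != (self.k_true, len(self.markers)):
            raise ValueError("signature must be (k_true, n_markers)")
        if self.k_true > 1:
            d = np.linalg.norm(
                self.signature[:, None, :] - self.signature[None, :, :], axis=-1
            )
            if np.any(d[np.triu_indices(self.k_true, 1)] <= 0):
                raise ValueError("signature rows must be pairwise distinct")
        if self.cascade is None:
            self.cascade = default_cascade(self.signature, self.markers)
        if np.isscalar(self.noise_sd):
            self.noise_sd = {m: float(self.noise_sd) for m in self.markers}
        if any(s <= 0 for s in self.noise_sd.values()):
            raise ValueError("noise_sd must be > 0")

    @property
    def noise_vector(self) -> np.ndarray:
        return np.array([self.noise_sd[m] for m in self.markers])


def default_signature(k: int, markers=DEFAULT_MARKERS) -> np.ndarray:
    """Well-separated signed signatures: each cluster emphasizes different markers."""
    rng = np.random.default_rng(12345)
    n_m = len(markers)
    base = np.abs(rng.normal(2.5, 0.5, size=(k, n_m)))
    # rotate emphasis so rows are far apart
    for c in range(k):
        boost = np.zeros(n_m)
        boost[(np.arange(n_m) + c) % n_m < max(1, n_m // k)] = 2.0
        base[c] += boost
    signs = np.array([_marker_sign(m) for m in markers], dtype=float)
    return base * signs


def default_cascade(signature: np.ndarray, markers) -> list:
    """One event per marker per cluster, ordered by decreasing |signature|."""
    cascades = []
    for c in range(signature.shape[0]):
        mags = np.abs(signature[c])
        order = np.argsort(-mags, kind="stable")
        cascades.append([(markers[j], float(mags[j]) / 2.0) for j in order])
    return cascades


@dataclass
class PhantomTruth:
    """Ground truth shared by all subjects of a phantom cohort."""

    config: PhantomConfig
    wm_mask: np.ndarray  # bool 3D
    true_cluster_map: np.ndarray  # int 3D, 0 = non-WM
    prevalence_map: np.ndarray  # float 3D in [0, 1]
    #: generative normative coefficients, shape (4, nx, ny, nz, n_markers):
    #: cubic polynomial in centred/scaled age (c0..c3)
    age_coefs: np.ndarray
    #: additive female shift per (voxel, marker)
    sex_shift: np.ndarray
    true_sequences: list  # per cluster, ordered (marker, threshold) events
    subject_truth: pd.DataFrame | None = None  # latent stage per region, filled by simulate_cohort

    def normative_mean(self, age: float, sex: int) -> np.ndarray:
        """Expected NAWM marker values at (age, sex); shape grid + (n_markers,)."""
        lo, hi = self.config.age_range
        t = (np.clip(age, lo, hi) - lo) / (hi - lo) - 0.5
        mean = (
            self.age_coefs[0]
            + self.age_coefs[1] * t
            + self.age_coefs[2] * t**2
            + self.age_coefs[3] * t**3
        )
        if sex:
            mean = mean + self.sex_shift
        return mean


def _trajectory_value(events: list, marker: str, z_max: float, u: float) -> float:
    """Piecewise-linear |z| trajectory of one marker at continuous pseudo-stage u.

    Knots at (event position, threshold) for this marker's events within the
    region cascade, anchored at (0, 0) and (n_events, z_max).
    """
    n_e = len(events)
    xs = [0.0]
    ys = [0.0]
    for pos, (m, thr) in enumerate(events, start=1):
        if m == marker:
            xs.append(float(pos))
            ys.append(float(thr))
    xs.append(float(n_e))
    ys.append(float(z_max))
    return float(np.interp(u, xs, ys))


def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Build the shared ground truth: WM mask, cluster map, normative fields.

    Deterministic for a fixed ``config.seed``. The WM mask is the inscribed
    ellipsoid of the grid; clusters are the nearest-seed (Voronoi) cells of
    ``k_true`` well-spread seed voxels, hence spatially compact.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.grid_shape)
    idx = np.indices(shape, dtype=float)
    center = (np.array(shape, dtype=float) - 1.0) / 2.0
    radii = np.maximum(center - 1.0, 1.0)
    ellip = sum(((idx[d] - center[d]) / radii[d]) ** 2 for d in range(3))
    wm_mask = ellip <= 1.0
    coords = np.argwhere(wm_mask).astype(float)
    if coords.shape[0] < 10 * config.k_true:
        raise ValueError(
            f"grid {shape} too small to host {config.k_true} clusters "
            f"({coords.shape[0]} WM voxels)"
        )

    # farthest-point seeding for compact, well-separated Voronoi cells
    seeds = [coords[rng.integers(len(coords))]]
    for _ in range(1, config.k_true):
        d = np.min(
            np.linalg.norm(coords[:, None, :] - np.array(seeds)[None, :, :], axis=-1),
            axis=1,
        )
        seeds.append(coords[int(np.argmax(d))])
    seeds = np.array(seeds)
    d_all = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=-1)
    labels = np.argmin(d_all, axis=1) + 1
    cluster_map = np.zeros(shape, dtype=int)
    cluster_map[wm_mask] = labels

    # prevalence: superposition of Gaussian bumps at the cluster seeds
    prev = np.zeros(shape)
    vox = idx.reshape(3, -1).T
    for s in seeds:
        d2 = np.sum((vox - s) ** 2, axis=1).reshape(shape)
        prev = np.maximum(
            prev, config.prevalence_peak * np.exp(-d2 / (2 * config.prevalence_length_scale**2))
        )
    prev *= wm_mask

    # smooth generative normative fields (cubic polynomial in scaled age + sex)
    n_m = len(config.markers)
    def smooth_field(scale):
        f = rng.normal(size=shape + (n_m,))
        for j in range(n_m):
            f[..., j] = ndimage.gaussian_filter(f[..., j], sigma=2.0)
        f /= np.maximum(f.std(axis=(0, 1, 2), keepdims=True), 1e-12)
        return f * scale

    age_coefs = np.stack(
        [
            smooth_field(1.0) + 10.0,  # baseline level
            smooth_field(0.5) + 1.0,   # linear age trend
            smooth_field(0.3),         # quadratic
            smooth_field(0.2),         # cubic
        ]
    )
    sex_shift = smooth_field(0.2) + 0.3

    return PhantomTruth(
        config=config,
        wm_mask=wm_mask,
        true_cluster_map=cluster_map,
        prevalence_map=prev,
        age_coefs=age_coefs,
        sex_shift=sex_shift,
        true_sequences=[list(ev) for ev in config.cascade],
    )


@dataclass
class SubjectVolumes:
    subject_id: str
    label_volume: np.ndarray  # int 3D: 0 bg, 1 NAWM, 2 WMH
    marker_volumes: dict  # marker -> float 3D


def expected_abnormality(
    truth: PhantomTruth, cluster: int, latent_stage: float
) -> np.ndarray:
    """Signed expected abnormality z per marker for one region at a latent stage.

    The latent stage in [0, 1] is mapped onto the region's event cascade as a
    continuous pseudo-stage; each marker follows its piecewise-linear
    threshold-crossing trajectory up to the signature magnitude.
    """
    cfg = truth.config
    events = truth.true_sequences[cluster - 1]
    u = float(latent_stage) * len(events)
    out = np.empty(len(cfg.markers))
    for j, m in enumerate(cfg.markers):
        z_max = abs(cfg.signature[cluster - 1, j])
        out[j] = np.sign(cfg.signature[cluster - 1, j]) * _trajectory_value(
            events, m, z_max, u
        )
    return out


def simulate_subject(
    truth: PhantomTruth,
    age: float,
    sex: int,
    site: SiteSpec | None = None,
    group: GroupSpec | None = None,
    latent_stage=0.0,
    prs: float = 0.0,
    seed: int = 0,
    subject_id: str = "sub-0",
) -> SubjectVolumes:
    """Draw one subject's label volume and marker volumes.

    NAWM voxels: normative mean(age, sex) + site shift + site scale x N(0, sd).
    WMH voxels additionally carry the cluster cascade abnormality at the
    subject's latent stage, plus any group and PRS-linked shifts (SD units).
    ``latent_stage`` may be a scalar (shared across regions) or a length-k
    array (per region).
    """
    cfg = truth.config
    lo, hi = cfg.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside configured range {cfg.age_range}")
    rng = np.random.default_rng(seed)
    shape = truth.wm_mask.shape

    wmh = (rng.random(shape) < truth.prevalence_map) & truth.wm_mask
    if wmh.any():
        wmh = ndimage.binary_closing(wmh, structure=np.ones((3, 3, 3))) & truth.wm_mask
    label = np.zeros(shape, dtype=int)
    label[truth.wm_mask] = LABEL_NAWM
    label[wmh] = LABEL_WMH

    stages = np.broadcast_to(np.atleast_1d(np.asarray(latent_stage, float)), (cfg.k_true,))
    mean = truth.normative_mean(age, sex)  # grid + (n_m,)
    site = site or cfg.sites[0]
    group = group or cfg.groups[0]
    sds = cfg.noise_vector

    marker_volumes = {}
    for j, m in enumerate(cfg.markers):
        vol = np.zeros(shape)
        eps = rng.normal(0.0, sds[j], size=shape)
        add = float(site.shift.get(m, 0.0))
        scale = float(site.scale.get(m, 1.0))
        vals = mean[..., j] + add + scale * eps
        # lesion abnormality per cluster, scaled back to marker units
        for c in range(1, cfg.k_true + 1):
            sel = wmh & (truth.true_cluster_map == c)
            if not sel.any():
                continue
            z = expected_abnormality(truth, c, stages[c - 1])[j]
            z += float(group.effects.get((m, c), 0.0)) * _marker_sign(m)
            z += prs * float(cfg.prs_effects.get((m, c), 0.0)) * _marker_sign(m)
            vals[sel] += z * sds[j]
        vol[truth.wm_mask] = vals[truth.wm_mask]
        marker_volumes[m] = vol

    return SubjectVolumes(subject_id=subject_id, label_volume=label, marker_volumes=marker_volumes)


def simulate_cohort(config: PhantomConfig):
    """Generate truth, per-subject volumes and the subject table.

    Returns ``(truth, volumes, table)`` where the table has columns
    id, age, sex, site, group, prs_score. Latent stages (per region) are
    recorded in ``truth.subject_truth``. Reproducible under ``config.seed``.
    """
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    truth = generate_phantom(config)
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_subjects
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    sexes = (rng.random(n) < config.sex_ratio).astype(int)
    site_p = np.array([s.frac for s in config.sites], float)
    site_idx = rng.choice(len(config.sites), size=n, p=site_p / site_p.sum())
    group_p = np.array([g.frac for g in config.groups], float)
    group_idx = rng.choice(len(config.groups), size=n, p=group_p / group_p.sum())
    prs = rng.normal(size=n)
    if config.stage_mode == "independent":
        stages = rng.uniform(size=(n, config.k_true))
    else:
        stages = np.repeat(rng.uniform(size=(n, 1)), config.k_true, axis=1)

    volumes, rows, truth_rows = [], [], []
    for i in range(n):
        sid = f"sub-{i:04d}"
        sv = simulate_subject(
            truth,
            age=ages[i],
            sex=int(sexes[i]),
            site=config.sites[site_idx[i]],
            group=config.groups[group_idx[i]],
            latent_stage=stages[i],
            prs=float(prs[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=sid,
        )
        volumes.append(sv)
        rows.append(
            dict(
                id=sid,
                age=ages[i],
                sex=int(sexes[i]),
                site=config.sites[site_idx[i]].name,
                group=config.groups[group_idx[i]].name,
                prs_score=float(prs[i]),
            )
        )
        truth_rows.append(
            dict(id=sid, **{f"stage_region{c}": stages[i, c - 1] for c in range(1, config.k_true + 1)})
        )
    table = pd.DataFrame(rows)
    truth.subject_truth = pd.DataFrame(truth_rows)
    return truth, volumes, table


# --------------------------------------------------------------------------
# toy tractograms and spherical parcel maps (connectivity fixtures)
# --------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - y * y, 0.0))
    pts = np.stack([r * np.cos(phi * i), y, r * np.sin(phi * i)], axis=1)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def smooth_sphere_map(
    centroids: np.ndarray, autocorr: float, rng: np.random.Generator
) -> np.ndarray:
    """Spatially autocorrelated map: white noise smoothed with a geodesic kernel.

    ``autocorr`` is the kernel width in radians; 0 leaves the noise unsmoothed.
    """
    noise = rng.normal(size=len(centroids))
    if autocorr <= 0:
        return noise
    cosang = np.clip(centroids @ centroids.T, -1.0, 1.0)
    ang = np.arccos(cosang)
    k = np.exp(-(ang**2) / (2.0 * autocorr**2))
    out = k @ noise
    return (out - out.mean()) / max(out.std(), 1e-12)


def simulate_streamlines_and_maps(
    truth: PhantomTruth,
    n_streamlines: int = 200,
    n_parcels: int = 20,
    autocorr: float = 0.3,
    target_corr: float = 0.0,
    seed: int = 0,
):
    """Toy tractogram + parcel centroids + two autocorrelated parcel maps.

    Streamlines are straight polylines between two WM voxels, each labeled
    with endpoint parcels. ``target_corr`` sets the Pearson correlation of
    map_a to the tractogram's per-parcel streamline-count profile
    (``target_corr=1`` duplicates it); map_b is independent.
    """
    from .connectivity import Tractogram

    if n_parcels < 3:
        raise ValueError("need >= 3 parcels")
    rng = np.random.default_rng(seed)
    centroids = _fibonacci_sphere(n_parcels)
    coords = np.argwhere(truth.wm_mask)

    lines, endpoints = [], []
    for _ in range(n_streamlines):
        a, b = coords[rng.integers(len(coords))], coords[rng.integers(len(coords))]
        n_pts = max(int(np.linalg.norm(b - a)) * 2 + 2, 2)
        t = np.linspace(0.0, 1.0, n_pts)[:, None]
        lines.append(a[None, :] * (1 - t) + b[None, :] * t)
        endpoints.append(tuple(sorted(rng.choice(n_parcels, size=2, replace=False))))
    tract = Tractogram(streamlines=lines, endpoint_labels=endpoints)

    profile = np.zeros(n_parcels)
    for pa, pb in endpoints:
        profile[pa] += 1
        profile[pb] += 1
    prof_z = (profile - profile.mean()) / max(profile.std(), 1e-12)

    def make_map(target):
        noise = smooth_sphere_map(centroids, autocorr, rng)
        if target == 0.0:
            return noise
        if abs(target) >= 1.0:
            return np.sign(target) * prof_z.copy()
        noise = noise - prof_z * (noise @ prof_z) / max(prof_z @ prof_z, 1e-12)
        noise /= max(noise.std(), 1e-12)
        return target * prof_z + np.sqrt(1 - target**2) * noise

    map_a = make_map(target_corr)
    map_b = smooth_sphere_map(centroids, autocorr, rng)
    return tract, centroids, map_a, map_b


# --------------------------------------------------------------------------
# on-disk cohort representation (NIfTI + CSV)
# --------------------------------------------------------------------------


def write_cohort(out_dir, truth: PhantomTruth, volumes, table: pd.DataFrame) -> None:
    """Write label/marker NIfTI volumes per subject plus the subject table."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(truth.true_cluster_map.astype(np.int16), affine),
             out / "true_cluster_map.nii.gz")
    for sv in volumes:
        nib.save(nib.Nifti1Image(sv.label_volume.astype(np.int16), affine),
                 out / f"{sv.subject_id}_labels.nii.gz")
        for m, vol in sv.marker_volumes.items():
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                     out / f"{sv.subject_id}_{m}.nii.gz")
    table.to_csv(out / "subjects.csv", index=False)
    cfg = truth.config
    meta = dict(
        grid_shape=list(cfg.grid_shape),
        k_true=cfg.k_true,
        markers=list(cfg.markers),
        n_subjects=cfg.n_subjects,
        seed=cfg.seed,
    )
    (out / "phantom_config.json").write_text(json.dumps(meta, indent=2))
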