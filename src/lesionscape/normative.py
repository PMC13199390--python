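"""Voxel-wise normative modelling of NAWM microstructure and WMH z-scoring.

For every voxel and marker, a Bayesian linear regression (Gaussian conjugate
prior, hyperparameters by evidence maximization) is fitted to the marker
values of subjects whose voxel is labelled normal-appearing white matter
(NAWM), with covariates age — a 3rd-order (cubic) B-spline basis with 4
interior knots at the {0.2, 0.4, 0.6, 0.8} age quantiles of the training
sample — and sex. The spline basis forms a partition of unity, so the
intercept is implicit in its span.

Age/sex-specific mean and predictive-SD maps of expected normal tissue are
then used to z-score the same markers at a subject's lesion (WMH) voxels:
z = (x - mean) / SD with SD² = residual variance + parametric predictive
variance. Ages above the training maximum are clamped to it so the model is
never extrapolated. Models can be transferred to a second cohort by
estimating per-voxel residual location/scale shifts on an adaptation sample
of unaffected subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.linear_model import BayesianRidge

from .phantom import LABEL_NAWM, LABEL_WMH

SPLINE_DEGREE = 3
KNOT_QUANTILES = (0.2, 0.4, 0.6, 0.8)


def bspline_basis(ages: np.ndarray, knots: np.ndarray, a_min: float, a_max: float) -> np.ndarray:
    """Cubic B-spline design matrix over age; ages clamped into the fitted range."""
    a = np.clip(np.asarray(ages, float), a_min, a_max)
    t = np.r_[[a_min] * (SPLINE_DEGREE + 1), knots, [a_max] * (SPLINE_DEGREE + 1)]
    return BSpline.design_matrix(a, t, SPLINE_DEGREE).toarray()


def _design(ages, sexes, knots, a_min, a_max):
    B = bspline_basis(ages, knots, a_min, a_max)
    return np.column_stack([B, np.asarray(sexes, float)])


@dataclass
class AbnormalityMap:
    """Per-subject sparse voxel -> z map, defined on WMH voxels only."""

    subject_id: str
    markers: tuple
    flat_indices: np.ndarray  # flat voxel indices into the model grid
    z: np.ndarray  # (n_voxels, n_markers)
    n_omitted: int = 0  # WMH voxels dropped because the model was unfitted there

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.z, columns=list(self.markers))
        df.insert(0, "voxel", self.flat_indices)
        df.insert(0, "id", self.subject_id)
        return df


@dataclass
class NormativeResults:
    """Fitted voxel-wise normative model grid.

    Arrays are indexed over the fitted-voxel list ``flat_indices`` (flat
    indices into the 3D grid) and the marker panel.
    """

    grid_shape: tuple
    markers: tuple
    flat_indices: np.ndarray  # fitted voxels, shape (n_vox,)
    coefs: np.ndarray  # (n_vox, n_markers, p)
    coef_cov: np.ndarray  # (n_vox, n_markers, p, p)
    sigma2: np.ndarray  # residual variance, (n_vox, n_markers)
    n_train: np.ndarray  # NAWM observations per voxel, (n_vox,)
    knots: np.ndarray
    age_range: tuple  # (a_min, a_max) of the training sample
    unfitted_reasons: dict = field(default_factory=dict)  # flat index -> reason
    # transfer recalibration (identity until transfer() is called)
    shift: np.ndarray | None = None  # (n_vox, n_markers)
    scale: np.ndarray | None = None
    transfer_flags: np.ndarray | None = None  # voxels inheriting (0, 1)

    def __post_init__(self):
        if self.shift is None:
            self.shift = np.zeros_like(self.sigma2)
            self.scale = np.ones_like(self.sigma2)
            self.transfer_flags = np.zeros(len(self.flat_indices), dtype=bool)

    @property
    def n_voxels(self) -> int:
        return len(self.flat_indices)

    def _x(self, age: float, sex: int) -> np.ndarray:
        return _design([age], [sex], self.knots, *self.age_range)[0]

    def predict(self, age: float, sex: int):
        """Mean and predictive-SD maps at (age, sex) over the fitted voxels.

        Returns ``(mean, sd)`` arrays of shape (n_vox, n_markers). Ages above
        the training maximum are clamped (no extrapolation).
        """
        x = self._x(age, sex)
        mean = self.coefs @ x
        param_var = np.einsum("vmpq,p,q->vm", self.coef_cov, x, x)
        sd = np.sqrt(self.sigma2 + param_var)
        return mean, sd

    def predict_volume(self, age: float, sex: int):
        """Same as :meth:`predict` but scattered into full 3D grids (NaN elsewhere)."""
        mean, sd = self.predict(age, sex)
        out_m = np.full(self.grid_shape + (len(self.markers),), np.nan)
        out_s = np.full_like(out_m, np.nan)
        ijk = np.unravel_index(self.flat_indices, self.grid_shape)
        out_m[ijk] = mean
        out_s[ijk] = sd
        return out_m, out_s

    def zscore_wmh(self, subject) -> AbnormalityMap:
        """Z-score a subject's WMH voxels against the expected-normal maps.

        NAWM voxels are deliberately excluded: the map's domain is the
        subject's WMH voxels intersected with the fitted voxels. WMH voxels
        falling on unfitted voxels are omitted and counted.
        """
        wmh_flat = np.flatnonzero(subject.label_volume.ravel() == LABEL_WMH)
        pos = {int(f): i for i, f in enumerate(self.flat_indices)}
        keep = np.array([f in pos for f in wmh_flat], dtype=bool)
        sel = wmh_flat[keep]
        rows = np.array([pos[int(f)] for f in sel], dtype=int)
        age = getattr(subject, "age", None)
        raise_if_missing(age is not None, "subject must carry .age and .sex for z-scoring")
        mean, sd = self.predict(age, subject.sex)
        z = np.empty((len(sel), len(self.markers)))
        for j, m in enumerate(self.markers):
            x = subject.marker_volumes[m].ravel()[sel]
            z[:, j] = (x - mean[rows, j]) / sd[rows, j]
        z = (z - self.shift[rows]) / self.scale[rows]
        return AbnormalityMap(
            subject_id=subject.subject_id,
            markers=self.markers,
            flat_indices=sel,
            z=z,
            n_omitted=int((~keep).sum()),
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, m in enumerate(self.markers):
            rows.append(
                dict(
                    marker=m,
                    n_voxels=self.n_voxels,
                    mean_sigma=float(np.sqrt(self.sigma2[:, j]).mean()),
                    mean_shift=float(self.shift[:, j].mean()),
                    mean_scale=float(self.scale[:, j].mean()),
                )
            )
        return pd.DataFrame(rows)


def raise_if_missing(cond, msg):
    if not cond:
        raise ValueError(msg)


class NormativeModel:
    """Voxel-wise Bayesian normative model of NAWM microstructure.

    Parameters
    ----------
    volumes : list of SubjectVolumes
        Training cohort; each subject contributes its NAWM-labelled voxels.
    table : DataFrame
        Subject table with columns id, age, sex aligned to ``volumes``.
    min_nawm : int
        Minimum NAWM observations for a voxel to be fitted (default 50 for
        synthetic cohorts; real-data studies of this kind use 5000).
    """

    def __init__(self, volumes, table: pd.DataFrame, markers=None, min_nawm: int = 50):
        self.volumes = list(volumes)
        self.table = table.reset_index(drop=True)
        self.markers = tuple(markers or self.volumes[0].marker_volumes.keys())
        self.min_nawm = int(min_nawm)

    def fit(self) -> NormativeResults:
        ages = self.table["age"].to_numpy(float)
        sexes = self.table["sex"].to_numpy(float)
        a_min, a_max = float(ages.min()), float(ages.max())
        knots = np.quantile(ages, KNOT_QUANTILES)
        if np.unique(np.r_[a_min, knots, a_max]).size < 4:
            raise ValueError("training ages span fewer than 2 knot intervals")
        X_all = _design(ages, sexes, knots, a_min, a_max)

        n_subj = len(self.volumes)
        grid_shape = self.volumes[0].label_volume.shape
        labels = np.stack([sv.label_volume.ravel() for sv in self.volumes])
        nawm = labels == LABEL_NAWM
        counts = nawm.sum(axis=0)
        candidate = np.flatnonzero(counts >= self.min_nawm)
        unfitted = {
            int(v): "n_train below min_nawm"
            for v in np.flatnonzero((counts > 0) & (counts < self.min_nawm))
        }

        data = np.stack(
            [
                np.stack([sv.marker_volumes[m].ravel()[candidate] for m in self.markers], axis=-1)
                for sv in self.volumes
            ]
        )  # (n_subj, n_cand, n_markers)

        p = X_all.shape[1]
        n_m = len(self.markers)
        coefs = np.zeros((len(candidate), n_m, p))
        cov = np.zeros((len(candidate), n_m, p, p))
        sigma2 = np.zeros((len(candidate), n_m))
        fitted_ok = np.ones(len(candidate), dtype=bool)
        for i, v in enumerate(candidate):
            idx = nawm[:, v]
            if np.ptp(ages[idx]) == 0.0:
                fitted_ok[i] = False
                unfitted[int(v)] = "degenerate design (single age)"
                continue
            Xv = X_all[idx]
            for j in range(n_m):
                br = BayesianRidge(fit_intercept=False)
                br.fit(Xv, data[idx, i, j])
                coefs[i, j] = br.coef_
                cov[i, j] = br.sigma_
                sigma2[i, j] = 1.0 / br.alpha_
        keep = fitted_ok
        return NormativeResults(
            grid_shape=grid_shape,
            markers=self.markers,
            flat_indices=candidate[keep],
            coefs=coefs[keep],
            coef_cov=cov[keep],
            sigma2=sigma2[keep],
            n_train=counts[candidate[keep]],
            knots=knots,
            age_range=(a_min, a_max),
            unfitted_reasons=unfitted,
        )


def fit_voxelwise_normative(volumes, table, min_nawm: int = 50, markers=None) -> NormativeResults:
    """Functional wrapper around :class:`NormativeModel`."""
    return NormativeModel(volumes, table, markers=markers, min_nawm=min_nawm).fit()


def zscore_cohort(results: NormativeResults, volumes, table: pd.DataFrame):
    """Z-score every subject's WMH voxels; attaches age/sex from the table."""
    meta = table.set_index("id")
    maps = []
    for sv in volumes:
        sv.age = float(meta.loc[sv.subject_id, "age"])
        sv.sex = int(meta.loc[sv.subject_id, "sex"])
        maps.append(results.zscore_wmh(sv))
    return maps


def nawm_zscores(results: NormativeResults, volumes, table: pd.DataFrame) -> np.ndarray:
    """Pooled z-scores of NAWM voxels (calibration diagnostic).

    On healthy tissue the z-scores should be standard normal; this pools
    (z - shift)/scale over all NAWM voxels of all subjects. NAWM z-scores are
    never analysis outputs — lesion analyses use :meth:`zscore_wmh` — but they
    are the quantity that normative calibration and model transfer control.
    """
    meta = table.set_index("id")
    pos = np.full(int(np.prod(results.grid_shape)), -1, dtype=int)
    pos[results.flat_indices] = np.arange(results.n_voxels)
    out = []
    for sv in volumes:
        age = float(meta.loc[sv.subject_id, "age"])
        sex = int(meta.loc[sv.subject_id, "sex"])
        mean, sd = results.predict(age, sex)
        nawm_flat = np.flatnonzero(sv.label_volume.ravel() == LABEL_NAWM)
        rows = pos[nawm_flat]
        ok = rows >= 0
        rows, nawm_flat = rows[ok], nawm_flat[ok]
        z = np.empty((len(rows), len(results.markers)))
        for j, m in enumerate(results.markers):
            z[:, j] = (sv.marker_volumes[m].ravel()[nawm_flat] - mean[rows, j]) / sd[rows, j]
        out.append((z - results.shift[rows]) / results.scale[rows])
    return np.concatenate(out, axis=0)


def transfer_model(
    results: NormativeResults,
    adaptation_volumes,
    adaptation_table: pd.DataFrame,
    min_adapt: int = 10,
    shrinkage: float = 10.0,
) -> NormativeResults:
    """Recalibrate a fitted model to a new site from unaffected subjects.

    Per voxel and marker, the adaptation subjects' NAWM residual z-scores are
    summarised into a location shift m and scale s, shrunk toward (0, 1) with
    weight n/(n + ``shrinkage``); transferred z-scores are z' = (z - m)/s.
    Voxels with fewer than ``min_adapt`` adaptation observations inherit the
    identity recalibration and are flagged.
    """
    meta = adaptation_table.set_index("id")
    n_vox, n_m = results.sigma2.shape
    s_n = np.zeros((n_vox, n_m))
    s_sum = np.zeros((n_vox, n_m))
    s_sq = np.zeros((n_vox, n_m))
    pos = np.full(int(np.prod(results.grid_shape)), -1, dtype=int)
    pos[results.flat_indices] = np.arange(n_vox)

    for sv in adaptation_volumes:
        age = float(meta.loc[sv.subject_id, "age"])
        sex = int(meta.loc[sv.subject_id, "sex"])
        mean, sd = results.predict(age, sex)
        nawm_flat = np.flatnonzero(sv.label_volume.ravel() == LABEL_NAWM)
        rows = pos[nawm_flat]
        ok = rows >= 0
        rows, nawm_flat = rows[ok], nawm_flat[ok]
        for j, m in enumerate(results.markers):
            z = (sv.marker_volumes[m].ravel()[nawm_flat] - mean[rows, j]) / sd[rows, j]
            np.add.at(s_n[:, j], rows, 1.0)
            np.add.at(s_sum[:, j], rows, z)
            np.add.at(s_sq[:, j], rows, z * z)

    with np.errstate(invalid="ignore", divide="ignore"):
        zbar = s_sum / s_n
        zvar = np.maximum(s_sq / s_n - zbar**2, 0.0)
        zsd = np.sqrt(zvar * s_n / np.maximum(s_n - 1, 1))
    w = s_n / (s_n + shrinkage)
    shift = np.where(s_n >= min_adapt, w * zbar, 0.0)
    scale = np.where(s_n >= min_adapt, w * zsd + (1 - w) * 1.0, 1.0)
    scale = np.maximum(scale, 1e-6)
    flags = (s_n < min_adapt).any(axis=1)

    out = NormativeResults(
        grid_shape=results.grid_shape,
        markers=results.markers,
        flat_indices=results.flat_indices,
        coefs=results.coefs,
        coef_cov=results.coef_cov,
        sigma2=results.sigma2,
        n_train=results.n_train,
        knots=results.knots,
        age_range=results.age_range,
        unfitted_reasons=dict(results.unfitted_reasons),
    )
    out.shift = shift
    out.scale = scale
    out.transfer_flags = flags
    return out
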