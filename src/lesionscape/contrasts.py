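"""Effect-size patterns: standardized-beta linear models and FDR families.

Every contrast (diagnosis case-control, PRS extreme-group, sex difference,
group-by-sex interaction) fits one ordinary-least-squares model per
(measure, region) feature, with continuous variables z-scaled before the fit
so coefficients are standardized betas, and binary predictors kept 0/1.
p-values are corrected with Benjamini-Hochberg FDR jointly over the declared
family — e.g. a three-diagnosis analysis over 9 measures x 3 regions forms
one 81-p-value family. Patterns from different contrasts are compared by
Pearson correlation over the shared (measure, region) grid and grouped by
complete-linkage hierarchical clustering on 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class EffectPattern:
    """Standardized betas + FDR q per (measure, region) for one contrast."""

    contrast: str
    table: pd.DataFrame  # columns: measure, region, beta, p, q, n_case, n_control
    flags: list = field(default_factory=list)

    def beta_vector(self, index=None) -> pd.Series:
        s = self.table.set_index(["measure", "region"])["beta"]
        return s.reindex(index) if index is not None else s

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < alpha]


def _zscale(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def standardized_lm(y, predictors: pd.DataFrame, covariates: pd.DataFrame | None = None):
    """OLS with continuous columns z-scaled; returns (beta, p) per predictor.

    Binary (two-valued 0/1) columns are left unscaled; the outcome and all
    other continuous columns are standardized, so slopes are standardized
    betas. Collinear designs raise with the offending columns named.
    """
    X = pd.DataFrame(predictors).copy()
    if covariates is not None and len(covariates.columns):
        X = pd.concat([X, pd.DataFrame(covariates)], axis=1)
    y = _zscale(np.asarray(y, float))
    cols = list(X.columns)
    mat = np.empty((len(X), len(cols)))
    for j, c in enumerate(cols):
        v = X[c].to_numpy(float)
        is_binary = set(np.unique(v)) <= {0.0, 1.0}
        mat[:, j] = v if is_binary else _zscale(v)
    design = sm.add_constant(mat, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(mat, rowvar=False)
        bad = [
            (cols[i], cols[j])
            for i in range(len(cols))
            for j in range(i + 1, len(cols))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"collinear design; offending columns: {bad or cols}")
    if len(y) <= design.shape[1]:
        raise ValueError("need n > number of parameters")
    fit = sm.OLS(y, design).fit()
    betas = pd.Series(fit.params[1:], index=cols)
    pvals = pd.Series(fit.pvalues[1:], index=cols)
    return betas, pvals


def _split_measure_region(col: str):
    # feature columns are "<measure>_region<r>"
    measure, _, region = col.rpartition("_region")
    return measure, int(region)


def _pattern_from_rows(contrast, rows, flags):
    df = pd.DataFrame(rows)
    rej, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")[:4]
    df["q"] = np.maximum(q, df["p"])  # BH q is >= p by construction; guard fp error
    return EffectPattern(contrast=contrast, table=df, flags=flags)


def case_control_pattern(
    features: pd.DataFrame,
    group: pd.Series,
    case_labels,
    control_label,
    covariates: pd.DataFrame | None = None,
    contrast: str = "diagnosis",
) -> dict:
    """Case-control standardized-beta patterns, one per case label.

    Fits measure-by-measure OLS of feature ~ case + covariates (default
    covariates: pass an age/sex frame) for each case label vs the shared
    control group, and applies BH-FDR jointly over the full family
    (measures x regions x case labels). Returns ``{case_label: EffectPattern}``
    sharing one q-value family.
    """
    case_labels = list(np.atleast_1d(case_labels))
    rows, flags = [], []
    for lab in case_labels:
        sel = group.isin([lab, control_label]).to_numpy()
        if (group[sel] == lab).sum() == 0 or (group[sel] == control_label).sum() == 0:
            raise ValueError(f"empty group in contrast {lab} vs {control_label}")
        if (group[sel] == lab).sum() < 3:
            flags.append(f"{lab}: case n < 3 (low power)")
        is_case = (group[sel] == lab).astype(float).rename("case")
        cov = covariates.loc[sel] if covariates is not None else None
        for col in features.columns:
            beta, p = standardized_lm(
                features.loc[sel, col].to_numpy(), is_case.to_frame(), cov
            )
            measure, region = _split_measure_region(col)
            rows.append(
                dict(case=lab, measure=measure, region=region,
                     beta=beta["case"], p=p["case"],
                     n_case=int(is_case.sum()), n_control=int((1 - is_case).sum()))
            )
    family = _pattern_from_rows(contrast, rows, flags)
    out = {}
    for lab in case_labels:
        sub = family.table[family.table["case"] == lab].drop(columns="case").reset_index(drop=True)
        out[lab] = EffectPattern(contrast=f"{contrast}:{lab}", table=sub, flags=flags)
    return out


def prs_extreme_contrast(
    features: pd.DataFrame,
    prs: pd.Series,
    top_frac: float = 0.01,
    bottom_frac: float = 0.50,
    contrast: str = "prs",
) -> EffectPattern:
    """Extreme-percentile PRS contrast: top ``top_frac`` vs bottom ``bottom_frac``.

    Cases are subjects above the (1 - top_frac) empirical quantile of the
    score, controls below its ``bottom_frac`` quantile; the models carry no
    covariates. Alternative case cutoffs (e.g. 3%, 5%) are supported via
    ``top_frac``.
    """
    s = prs.to_numpy(float)
    hi = np.quantile(s, 1.0 - top_frac)
    lo = np.quantile(s, bottom_frac)
    is_case = s > hi
    is_control = s <= lo
    if is_case.sum() == 0:
        raise ValueError("top PRS group is empty")
    sel = is_case | is_control
    y_ind = pd.DataFrame({"case": is_case[sel].astype(float)})
    rows = []
    for col in features.columns:
        beta, p = standardized_lm(features.loc[sel, col].to_numpy(), y_ind, None)
        measure, region = _split_measure_region(col)
        rows.append(
            dict(measure=measure, region=region, beta=beta["case"], p=p["case"],
                 n_case=int(is_case.sum()), n_control=int(is_control.sum()))
        )
    return _pattern_from_rows(contrast, rows, [])


def sex_difference(
    features: pd.DataFrame,
    volumes: pd.DataFrame,
    sex: pd.Series,
    age: pd.Series,
    contrast: str = "sex",
):
    """Two sex-difference patterns: lesion volumes, then pathophysiology.

    Model 1: regional volume ~ sex + age. Model 2: each pathophysiology
    feature ~ sex + age + its region's volume, i.e. sex differences at
    matched lesion extent. Returns ``(volume_pattern, patho_pattern)``.
    """
    if sex.nunique() < 2:
        raise ValueError("both sexes must be present")
    sexf = sex.astype(float).rename("sex").to_frame()
    agef = age.astype(float).rename("age").to_frame()
    vol_rows = []
    for col in volumes.columns:
        beta, p = standardized_lm(volumes[col].to_numpy(), sexf, agef)
        measure, region = _split_measure_region(col)
        vol_rows.append(dict(measure=measure, region=region, beta=beta["sex"], p=p["sex"],
                             n_case=int(sexf["sex"].sum()), n_control=int((1 - sexf["sex"]).sum())))
    patho_rows = []
    for col in features.columns:
        measure, region = _split_measure_region(col)
        vcol = f"logvol_region{region}"
        cov = pd.concat([agef, volumes[vcol].rename("regional_volume")], axis=1)
        beta, p = standardized_lm(features[col].to_numpy(), sexf, cov)
        patho_rows.append(dict(measure=measure, region=region, beta=beta["sex"], p=p["sex"],
                               n_case=int(sexf["sex"].sum()), n_control=int((1 - sexf["sex"]).sum())))
    return (
        _pattern_from_rows(f"{contrast}:volume", vol_rows, []),
        _pattern_from_rows(f"{contrast}:pathophysiology", patho_rows, []),
    )


def interaction_scan(
    features: pd.DataFrame,
    group: pd.Series,
    sex: pd.Series,
    covariates: pd.DataFrame | None = None,
    contrast: str = "group_x_sex",
) -> EffectPattern:
    """Group-by-sex interaction betas per (measure, region), FDR per family."""
    g = group.astype(float)
    s = sex.astype(float)
    flags = []
    cells = pd.crosstab(g, s)
    if (cells == 0).any().any():
        flags.append("empty group-by-sex cell")
    pred = pd.DataFrame({"group": g, "sex": s, "group_x_sex": g * s})
    rows = []
    for col in features.columns:
        beta, p = standardized_lm(features[col].to_numpy(), pred, covariates)
        measure, region = _split_measure_region(col)
        rows.append(dict(measure=measure, region=region,
                         beta=beta["group_x_sex"], p=p["group_x_sex"],
                         n_case=int(g.sum()), n_control=int((1 - g).sum())))
    return _pattern_from_rows(contrast, rows, flags)


def pattern_similarity(patterns: dict):
    """Pearson correlation matrix of effect patterns + complete-linkage tree.

    Patterns are flattened over the (measure, region) grid shared by all of
    them (measures missing from any pattern are dropped). Returns
    ``(corr_df, linkage_matrix)`` with distance 1 - r. Zero-variance patterns
    raise.
    """
    if len(patterns) < 2:
        raise ValueError("need >= 2 patterns")
    vectors = {name: p.beta_vector() for name, p in patterns.items()}
    shared = None
    for v in vectors.values():
        shared = v.index if shared is None else shared.intersection(v.index)
    if len(shared) < 2:
        raise ValueError("patterns share fewer than 2 (measure, region) cells")
    mat = np.stack([vectors[n].reindex(shared).to_numpy() for n in patterns])
    sds = mat.std(axis=1)
    if np.any(sds == 0):
        bad = [n for n, s in zip(patterns, sds) if s == 0]
        raise ValueError(f"zero-variance pattern(s): {bad}")
    corr = np.corrcoef(mat)
    names = list(patterns)
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    Z = linkage(dist, method="complete")
    return corr_df, Z
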