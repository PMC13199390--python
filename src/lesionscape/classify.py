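"""Multi-site harmonization and disease classification of ROI features.

Harmonization is ComBat-style parametric empirical Bayes: per-site location
and scale effects are estimated on a reference set of control subjects
(preserving age and sex covariate effects), shrunk across features with the
standard normal / inverse-gamma priors, and the correction is applied to all
rows including the diseased groups. Classification is L1-penalized logistic
regression (C = 1, saga solver, balanced class weights, max_iter = 1000)
under stratified 5-fold cross-validation repeated 100 times, with the feature
scaler fit inside each training fold only and metrics computed from pooled
out-of-fold predictions. Predictor sets are compared with paired Wilcoxon
signed-rank tests across repeats, Bonferroni-corrected over all set pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler


# --------------------------------------------------------------------------
# ComBat with reference-batch (controls) fitting
# --------------------------------------------------------------------------


@dataclass
class HarmonizationModel:
    """Fitted ComBat parameters: standardization stats + per-site EB effects."""

    features: list
    sites: list
    covariates: list
    stand_mean_coef: np.ndarray  # (1 + n_cov, n_features): grand mean + cov betas
    pooled_sd: np.ndarray  # (n_features,)
    gamma_star: dict  # site -> (n_features,)
    delta_star: dict  # site -> (n_features,) (> 0)
    flags: list = field(default_factory=list)

    def apply(self, features: pd.DataFrame, site: pd.Series,
              covariates: pd.DataFrame | None = None) -> pd.DataFrame:
        """Remove the fitted site effects from ``features`` (any rows)."""
        X = features[self.features].to_numpy(float)
        C = _cov_design(covariates, self.covariates, len(X))
        stand = C @ self.stand_mean_coef
        Z = (X - stand) / self.pooled_sd
        out = np.empty_like(Z)
        for s in pd.unique(site):
            sel = (site == s).to_numpy()
            g = self.gamma_star.get(s)
            d = self.delta_star.get(s)
            if g is None:
                out[sel] = Z[sel]  # unseen site: passthrough
            else:
                out[sel] = (Z[sel] - g) / d
        adj = out * self.pooled_sd + stand
        return pd.DataFrame(adj, index=features.index, columns=self.features)


def _cov_design(covariates, names, n):
    if not names:
        return np.ones((n, 1))
    C = pd.DataFrame(covariates)[names].to_numpy(float)
    return np.column_stack([np.ones(n), C])


def _eb_iterate(gamma_hat, delta_hat_sq, n_site, tol=1e-6, max_iter=200):
    """Parametric EB shrinkage of one site's location/scale across features."""
    g_bar, t2 = gamma_hat.mean(), gamma_hat.var(ddof=1) if len(gamma_hat) > 1 else 1.0
    d_bar = delta_hat_sq.mean()
    s2 = delta_hat_sq.var(ddof=1) if len(delta_hat_sq) > 1 else 1.0
    # method-of-moments inverse-gamma hyperpriors
    lam = (2 * s2 + d_bar**2) / max(s2, 1e-12)
    theta = (d_bar**3 + d_bar * s2) / max(s2, 1e-12)
    g_star = gamma_hat.copy()
    d_star = delta_hat_sq.copy()
    for _ in range(max_iter):
        g_new = (n_site * t2 * gamma_hat + d_star * g_bar) / (n_site * t2 + d_star)
        ssq = delta_hat_sq * (n_site - 1) + n_site * (gamma_hat - g_new) ** 2
        d_new = (theta + 0.5 * ssq) / (n_site / 2.0 + lam - 1.0)
        if np.max(np.abs(g_new - g_star)) < tol and np.max(np.abs(d_new - d_star)) < tol:
            g_star, d_star = g_new, d_new
            break
        g_star, d_star = g_new, d_new
    return g_star, np.maximum(d_star, 1e-8)


def combat_fit_apply(
    features: pd.DataFrame,
    site: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference_mask: np.ndarray | None = None,
    min_reference: int = 10,
):
    """Fit ComBat on reference (control) rows and adjust all rows.

    Returns ``(harmonized_features, HarmonizationModel)``. Location/scale
    site effects are estimated only on ``reference_mask`` rows (all rows when
    omitted); covariate (age/sex) effects are estimated jointly and preserved
    in the output. A single-site input is returned unchanged with a warning.
    """
    sites = list(pd.unique(site))
    if len(sites) < 2:
        warnings.warn("single-site input: harmonization is the identity")
        model = HarmonizationModel(
            features=list(features.columns), sites=sites,
            covariates=list(covariates.columns) if covariates is not None else [],
            stand_mean_coef=np.zeros((1 + (len(covariates.columns) if covariates is not None else 0),
                                      features.shape[1])),
            pooled_sd=np.ones(features.shape[1]),
            gamma_star={s: np.zeros(features.shape[1]) for s in sites},
            delta_star={s: np.ones(features.shape[1]) for s in sites},
            flags=["single-site identity"],
        )
        return features.copy(), model
    ref = np.ones(len(features), bool) if reference_mask is None else np.asarray(reference_mask, bool)
    for s in sites:
        n_ref = int((ref & (site == s).to_numpy()).sum())
        if n_ref < min_reference:
            raise ValueError(f"site {s}: only {n_ref} reference subjects (need >= {min_reference})")

    cov_names = list(covariates.columns) if covariates is not None else []
    X = features.to_numpy(float)
    n, p = X.shape
    site_arr = site.to_numpy()
    # design on reference rows: per-site intercepts + covariates
    S = np.column_stack([(site_arr == s).astype(float) for s in sites])
    C = pd.DataFrame(covariates).to_numpy(float) if cov_names else np.empty((n, 0))
    D = np.column_stack([S, C])
    B = np.linalg.lstsq(D[ref], X[ref], rcond=None)[0]
    site_means = B[: len(sites)]
    cov_beta = B[len(sites):]
    n_ref_site = np.array([float((ref & (site_arr == s)).sum()) for s in sites])
    grand = (n_ref_site / n_ref_site.sum()) @ site_means
    stand_coef = np.vstack([grand[None, :], cov_beta])
    stand_all = _cov_design(covariates, cov_names, n) @ stand_coef
    resid_ref = X[ref] - D[ref] @ B
    pooled_sd = np.sqrt(np.maximum((resid_ref**2).mean(axis=0), 1e-12))

    Z = (X - stand_all) / pooled_sd
    gamma_star, delta_star = {}, {}
    for i, s in enumerate(sites):
        sel = ref & (site_arr == s)
        zs = Z[sel]
        gamma_hat = zs.mean(axis=0)
        delta_hat_sq = zs.var(axis=0, ddof=1)
        g, d = _eb_iterate(gamma_hat, delta_hat_sq, n_site=float(sel.sum()))
        gamma_star[s] = g
        delta_star[s] = np.sqrt(d)

    model = HarmonizationModel(
        features=list(features.columns), sites=sites, covariates=cov_names,
        stand_mean_coef=stand_coef, pooled_sd=pooled_sd,
        gamma_star=gamma_star, delta_star=delta_star,
    )
    return model.apply(features, site, covariates), model


# --------------------------------------------------------------------------
# repeated cross-validated classification
# --------------------------------------------------------------------------


@dataclass
class CVResult:
    """Out-of-fold metrics per predictor set and repeat."""

    metrics: pd.DataFrame  # columns: set, repeat, auroc, balanced_accuracy, f1
    convergence_flags: int = 0

    def summary(self) -> pd.DataFrame:
        agg = self.metrics.groupby("set")[["auroc", "balanced_accuracy", "f1"]]
        return agg.agg(["mean", "std"])

    def repeat_vectors(self, metric: str = "auroc") -> pd.DataFrame:
        return self.metrics.pivot(index="repeat", columns="set", values=metric)


def repeated_cv_classify(
    features: pd.DataFrame,
    labels,
    predictor_sets: dict,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> CVResult:
    """L1 logistic regression under repeated stratified cross-validation.

    ``predictor_sets`` maps set name -> list of feature columns. Per repeat,
    stratified ``folds``-fold splits (seeded as seed + repeat) are shared by
    all sets; the scaler and classifier see only training folds, and AUROC /
    balanced accuracy / F1 (positive = minority class, 0.5 threshold) are
    computed from the pooled out-of-fold predictions.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if counts.min() < folds:
        raise ValueError("both classes must have at least `folds` members")
    pos = classes[np.argmin(counts)]  # minority class is the positive class
    y_bin = (y == pos).astype(int)
    rows, n_flags = [], 0
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        splits = list(skf.split(features, y_bin))
        for set_name, cols in predictor_sets.items():
            X = features[list(cols)].to_numpy(float)
            score = np.empty(len(y_bin))
            pred = np.empty(len(y_bin), dtype=int)
            for tr, te in splits:
                scaler = StandardScaler().fit(X[tr])
                clf = LogisticRegression(
                    penalty="l1", C=1.0, solver="saga",
                    class_weight="balanced", max_iter=1000,
                    random_state=seed + rep,  # saga shuffles; pin for determinism
                )
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always", ConvergenceWarning)
                    clf.fit(scaler.transform(X[tr]), y_bin[tr])
                    n_flags += sum(
                        issubclass(w.category, ConvergenceWarning) for w in caught
                    )
                prob = clf.predict_proba(scaler.transform(X[te]))[:, 1]
                score[te] = prob
                pred[te] = (prob >= 0.5).astype(int)
            rows.append(
                dict(set=set_name, repeat=rep,
                     auroc=roc_auc_score(y_bin, score),
                     balanced_accuracy=balanced_accuracy_score(y_bin, pred),
                     f1=f1_score(y_bin, pred, zero_division=0))
            )
    return CVResult(metrics=pd.DataFrame(rows), convergence_flags=n_flags)


def compare_predictor_sets(cv: CVResult, metric: str = "auroc") -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests between all predictor-set pairs.

    Tests are paired across repeats; p-values are Bonferroni-corrected over
    the number of pairs. All-zero difference vectors get p = 1 and a flag.
    """
    vec = cv.repeat_vectors(metric)
    names = list(vec.columns)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        d = vec[a].to_numpy() - vec[b].to_numpy()
        if np.all(d == 0):
            rows.append(dict(set_a=a, set_b=b, median_diff=0.0, p=1.0,
                             p_bonferroni=1.0, flag="identical metrics"))
            continue
        stat, p = wilcoxon(vec[a], vec[b])
        rows.append(dict(set_a=a, set_b=b, median_diff=float(np.median(d)),
                         p=float(p), p_bonferroni=float(min(p * m, 1.0)), flag=""))
    return pd.DataFrame(rows)
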