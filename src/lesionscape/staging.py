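"""Piecewise-linear z-score event-based progression modelling.

A region's lesion pathophysiology is modelled as an ordered cascade of
threshold-crossing events: each (marker, z-threshold) pair is an event, and
every marker's expected abnormality rises piecewise-linearly with discrete
stage, passing through its thresholds at the positions the event sequence S
assigns them, from (0, 0) to (|E|, z_max). Under sequence S a subject at
stage k is modelled as

    x_m ~ Normal(traj_m(k | S), sigma_m^2),

with a uniform prior over stages 0..|E|, so the per-subject likelihood is
the stage-averaged product over markers. Sequences are inferred by greedy
pairwise-swap ascent from random start permutations followed by Metropolis
MCMC over swap proposals; subjects are staged at the posterior-mode stage of
the MAP sequence. Subjects with no lesion in the region (all-zero features)
are assigned stage and subtype 0. Subtype solutions are fitted by split-and-
refit EM and compared by cross-validated out-of-sample log-likelihood.

Marker noise SD defaults to 1 (the features are z-scores); configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import spearmanr

BASE_THRESHOLDS = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
MIN_THRESHOLD_FRACTION = 0.01  # >= 1% of subjects must reach a retained threshold


@dataclass
class EventThresholds:
    """Retained z thresholds and empirical maximum z per marker."""

    thresholds: dict  # marker -> ordered list of retained thresholds
    z_max: dict  # marker -> trajectory endpoint
    dropped: tuple = ()  # markers that reached no threshold

    @property
    def events(self) -> list:
        return [(m, t) for m in self.thresholds for t in self.thresholds[m]]


def derive_event_thresholds(
    features: pd.DataFrame | np.ndarray,
    base_set=BASE_THRESHOLDS,
    min_frac: float = MIN_THRESHOLD_FRACTION,
) -> EventThresholds:
    """Retain the base thresholds that at least ``min_frac`` of subjects reach.

    Features must already be oriented so abnormality is positive. The marker
    maximum z (trajectory endpoint) is the largest retained threshold.
    Markers reaching no threshold are excluded with a warning.
    """
    df = pd.DataFrame(features)
    thresholds, z_max, dropped = {}, {}, []
    n = len(df)
    for m in df.columns:
        x = df[m].to_numpy(float)
        kept = [t for t in base_set if np.sum(x >= t) / n >= min_frac]
        if not kept:
            dropped.append(m)
            continue
        thresholds[m] = kept
        z_max[m] = float(max(kept))
    if dropped:
        warnings.warn(f"markers reached no threshold and were excluded: {dropped}")
    return EventThresholds(thresholds=thresholds, z_max=z_max, dropped=tuple(dropped))


# --------------------------------------------------------------------------
# trajectories and likelihood
# --------------------------------------------------------------------------


def _trajectory_matrix(seq: np.ndarray, ev_marker: np.ndarray, ev_thr: np.ndarray,
                       z_max: np.ndarray, n_markers: int) -> np.ndarray:
    """Expected z at integer stages 0..|E| for every marker, given a sequence.

    ``seq`` lists event indices in temporal order.
    """
    n_e = len(seq)
    stages = np.arange(n_e + 1, dtype=float)
    T = np.zeros((n_e + 1, n_markers))
    for m in range(n_markers):
        xs, ys = [0.0], [0.0]
        for pos, e in enumerate(seq, start=1):
            if ev_marker[e] == m:
                xs.append(float(pos))
                ys.append(float(ev_thr[e]))
        if xs[-1] < n_e:
            xs.append(float(n_e))
            ys.append(float(z_max[m]))
        T[:, m] = np.interp(stages, xs, ys)
    return T


def _stage_logpdf(data: np.ndarray, T: np.ndarray, noise_sd: np.ndarray) -> np.ndarray:
    """log p(subject i | stage k) summed over markers; shape (n, |E|+1)."""
    resid = (data[:, None, :] - T[None, :, :]) / noise_sd[None, None, :]
    const = -0.5 * np.log(2 * np.pi) - np.log(noise_sd)
    return np.sum(-0.5 * resid**2 + const[None, None, :], axis=-1)


def _subject_loglik(data, seq, ev_marker, ev_thr, z_max, noise_sd) -> np.ndarray:
    """Per-subject log of the stage-averaged likelihood under sequence ``seq``."""
    T = _trajectory_matrix(seq, ev_marker, ev_thr, z_max, data.shape[1])
    lp = _stage_logpdf(data, T, noise_sd)
    return logsumexp(lp, axis=1) - np.log(T.shape[0])


def sequence_loglik(data, sequence, thresholds: EventThresholds, noise_sd=1.0,
                    weights=None) -> float:
    """Total (optionally weighted) data log-likelihood of one event sequence.

    ``sequence`` is a permutation of the event list, given either as event
    indices or as (marker, threshold) pairs.
    """
    X, ev_marker, ev_thr, z_max, sds, _ = _prepare(data, thresholds, noise_sd)
    seq = _as_indices(sequence, thresholds)
    ll = _subject_loglik(X, seq, ev_marker, ev_thr, z_max, sds)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, float)
    return float(np.sum(w * ll))


def _prepare(data, thresholds: EventThresholds, noise_sd):
    df = pd.DataFrame(data)
    markers = [m for m in df.columns if m in thresholds.thresholds]
    X = df[markers].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    m_index = {m: j for j, m in enumerate(markers)}
    events = thresholds.events
    ev_marker = np.array([m_index[m] for m, _ in events])
    ev_thr = np.array([t for _, t in events], float)
    z_max = np.array([thresholds.z_max[m] for m in markers], float)
    sds = np.broadcast_to(np.atleast_1d(np.asarray(noise_sd, float)), (len(markers),)).copy()
    if np.any(sds <= 0):
        raise ValueError("noise SD must be > 0")
    return X, ev_marker, ev_thr, z_max, sds, markers


def _as_indices(sequence, thresholds: EventThresholds) -> np.ndarray:
    events = thresholds.events
    seq = list(sequence)
    if seq and isinstance(seq[0], (tuple, list)):
        seq = [events.index((m, t)) for m, t in seq]
    return np.asarray(seq, dtype=int)


def _valid_sequence(seq: np.ndarray, ev_marker: np.ndarray, ev_thr: np.ndarray) -> bool:
    """A marker's events must cross their thresholds in increasing order."""
    for m in np.unique(ev_marker):
        thr_in_order = ev_thr[seq][ev_marker[seq] == m]
        if np.any(np.diff(thr_in_order) < 0):
            return False
    return True


def _canonicalize(seq: np.ndarray, ev_marker: np.ndarray, ev_thr: np.ndarray) -> np.ndarray:
    """Reassign each marker's events to its positions in increasing-threshold order."""
    seq = np.asarray(seq).copy()
    for m in np.unique(ev_marker):
        at = np.flatnonzero(ev_marker[seq] == m)
        evs = seq[at]
        seq[at] = evs[np.argsort(ev_thr[evs], kind="stable")]
    return seq


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------


@dataclass
class StageAssignment:
    stages: np.ndarray  # integer stage per subject, 0..|E|
    subtypes: np.ndarray  # subtype id per subject (0 = no lesion)
    stage_posterior: np.ndarray  # (n, |E|+1)


@dataclass
class EventModelResults:
    """Fitted event-based model: MAP sequence, MCMC samples, subtype mixture."""

    events: list  # (marker, threshold) pairs, baseline order
    markers: list
    sequence: np.ndarray  # MAP sequence (event indices)
    samples: np.ndarray  # MCMC sequence samples, (n_samples, |E|)
    log_likelihood: float
    noise_sd: np.ndarray
    thresholds: EventThresholds
    subtype_sequences: list = field(default_factory=list)  # per subtype
    subtype_fractions: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    cv_log_likelihood: float | None = None

    def __post_init__(self):
        if not self.subtype_sequences:
            self.subtype_sequences = [np.asarray(self.sequence)]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def sequence_events(self, subtype: int = 0) -> list:
        return [self.events[e] for e in self.subtype_sequences[subtype]]

    def expected_trajectory(self, marker: str, subtype: int = 0):
        """Piecewise-linear stage -> expected z function for one marker."""
        _, ev_marker, ev_thr, z_max, _, markers = _prepare(
            pd.DataFrame(np.zeros((1, len(self.markers))), columns=self.markers),
            self.thresholds,
            self.noise_sd,
        )
        T = _trajectory_matrix(
            self.subtype_sequences[subtype], ev_marker, ev_thr, z_max, len(markers)
        )
        j = markers.index(marker)
        stages = np.arange(self.n_events + 1, dtype=float)

        def f(stage):
            return np.interp(stage, stages, T[:, j])

        return f

    def stage_subjects(self, features) -> StageAssignment:
        """Posterior-mode stage under the MAP sequence; lesion-free rows get 0.

        For multi-subtype models, each subject is first assigned the subtype
        maximizing its likelihood, then staged under that subtype's sequence.
        Stage posterior ties break toward the lower stage.
        """
        X, ev_marker, ev_thr, z_max, sds, markers = _prepare(
            features, self.thresholds, self.noise_sd
        )
        n = len(X)
        n_sub = len(self.subtype_sequences)
        ll = np.zeros((n, n_sub))
        posts = []
        for c, seq in enumerate(self.subtype_sequences):
            T = _trajectory_matrix(seq, ev_marker, ev_thr, z_max, len(markers))
            lp = _stage_logpdf(X, T, sds) + np.log(self.subtype_fractions[c])
            posts.append(lp)
            ll[:, c] = logsumexp(lp, axis=1)
        subtype = np.argmax(ll, axis=1)
        lp_best = np.stack([posts[c][i] for i, c in enumerate(subtype)])
        post = np.exp(lp_best - logsumexp(lp_best, axis=1, keepdims=True))
        stages = np.argmax(post, axis=1)  # argmax -> first (lower) stage on ties
        zero = np.all(X == 0.0, axis=1)
        stages[zero] = 0
        subtype_ids = subtype + 1
        subtype_ids[zero] = 0
        return StageAssignment(stages=stages, subtypes=subtype_ids, stage_posterior=post)

    def positional_variance(self) -> pd.DataFrame:
        """P(event at position) over the MCMC sequence samples; rows sum to 1."""
        n_e = self.n_events
        counts = np.zeros((n_e, n_e))
        for s in self.samples:
            counts[s, np.arange(n_e)] += 1.0
        counts /= max(len(self.samples), 1)
        return pd.DataFrame(
            counts,
            index=[f"{m}>{t:g}" for m, t in self.events],
            columns=[f"pos{p + 1}" for p in range(n_e)],
        )

    def plot_positional_variance(self, ax=None):
        """Heatmap of the event-by-position posterior (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        pv = self.positional_variance()
        order = np.argsort([list(self.sequence).index(e) for e in range(self.n_events)])
        pv = pv.iloc[order]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * self.n_events + 1))
        im = ax.imshow(pv.to_numpy(), aspect="auto", cmap="Greys", vmin=0, vmax=1)
        ax.set_yticks(range(self.n_events), pv.index)
        ax.set_xlabel("sequence position")
        ax.figure.colorbar(im, ax=ax, label="posterior probability")
        return ax

    def summary(self) -> pd.DataFrame:
        pv = self.positional_variance()
        rows = []
        for pos, e in enumerate(self.sequence, start=1):
            m, t = self.events[e]
            rows.append(
                dict(position=pos, marker=m, threshold=t,
                     position_certainty=float(pv.iloc[e].max()))
            )
        return pd.DataFrame(rows)


class ZScoreEventModel:
    """Event-based progression model over one region's marker z features.

    Parameters
    ----------
    features : DataFrame (subjects x markers)
        Positive-oriented abnormality z features (inverted markers already
        sign-flipped upstream).
    thresholds : EventThresholds, optional
        Derived from the data with the 1%-reach rule when omitted.
    noise_sd : float or array
        Marker noise SD; defaults to 1 since features are z-scores.
    """

    def __init__(self, features, thresholds: EventThresholds | None = None, noise_sd=1.0):
        self.features = pd.DataFrame(features)
        self.thresholds = thresholds or derive_event_thresholds(self.features)
        self.noise_sd = noise_sd
        if len(self.features) < 20:
            warnings.warn("fewer than 20 subjects: sequence inference may be unstable")

    def fit(self, n_startpoints: int = 15, n_mcmc: int = 10000, seed: int = 0) -> EventModelResults:
        """Greedy pairwise-swap ascent from random starts, then Metropolis MCMC."""
        X, ev_marker, ev_thr, z_max, sds, markers = _prepare(
            self.features, self.thresholds, self.noise_sd
        )
        events = self.thresholds.events
        n_e = len(events)
        if n_e < 2:
            raise ValueError("need at least 2 events")
        rng = np.random.default_rng(seed)

        def loglik(seq):
            return float(np.sum(_subject_loglik(X, seq, ev_marker, ev_thr, z_max, sds)))

        def valid(seq):
            return _valid_sequence(seq, ev_marker, ev_thr)

        best_seq, best_ll = None, -np.inf
        for _ in range(n_startpoints):
            start = _canonicalize(rng.permutation(n_e), ev_marker, ev_thr)
            seq, ll = _greedy_ascent(start, loglik, valid)
            if ll > best_ll:
                best_seq, best_ll = seq, ll

        samples = np.empty((n_mcmc, n_e), dtype=int)
        cur, cur_ll = best_seq.copy(), best_ll
        map_seq, map_ll = best_seq.copy(), best_ll
        for it in range(n_mcmc):
            prop = cur.copy()
            i, j = rng.integers(0, n_e, size=2)
            prop[i], prop[j] = prop[j], prop[i]
            if not valid(prop):  # invalid orderings have prior mass 0: reject
                samples[it] = cur
                continue
            prop_ll = loglik(prop)
            if prop_ll >= cur_ll or rng.random() < np.exp(prop_ll - cur_ll):
                cur, cur_ll = prop, prop_ll
                if cur_ll > map_ll:
                    map_seq, map_ll = cur.copy(), cur_ll
            samples[it] = cur
        return EventModelResults(
            events=events,
            markers=markers,
            sequence=map_seq,
            samples=samples,
            log_likelihood=map_ll,
            noise_sd=sds,
            thresholds=self.thresholds,
        )


def _greedy_ascent(seq, loglik, valid=None):
    """Full pairwise-swap sweeps until no (valid) swap improves the log-likelihood."""
    seq = np.asarray(seq).copy()
    cur = loglik(seq)
    n = len(seq)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                seq[i], seq[j] = seq[j], seq[i]
                if valid is not None and not valid(seq):
                    seq[i], seq[j] = seq[j], seq[i]
                    continue
                ll = loglik(seq)
                if ll > cur:
                    cur = ll
                    improved = True
                else:
                    seq[i], seq[j] = seq[j], seq[i]
    return seq, cur


def fit_event_model(features, thresholds=None, n_startpoints: int = 15,
                    n_mcmc: int = 10000, seed: int = 0, noise_sd=1.0) -> EventModelResults:
    """Functional wrapper around :class:`ZScoreEventModel`."""
    return ZScoreEventModel(features, thresholds, noise_sd).fit(
        n_startpoints=n_startpoints, n_mcmc=n_mcmc, seed=seed
    )


# --------------------------------------------------------------------------
# subtypes
# --------------------------------------------------------------------------


def fit_subtypes(
    features,
    thresholds: EventThresholds | None = None,
    c_max: int = 3,
    folds: int = 10,
    n_startpoints: int = 15,
    n_mcmc: int = 10000,
    seed: int = 0,
    noise_sd=1.0,
    n_em_iter: int = 15,
):
    """Fit 1..c_max subtype solutions and score them by cross-validated log-lik.

    Subtypes are grown by splitting the worst-fit subtype in two and
    re-optimizing sequences and fractions with EM (responsibility-weighted
    greedy sequence refits). Returns ``{c: EventModelResults}`` with
    ``cv_log_likelihood`` filled from ``folds``-fold held-out evaluation.
    """
    if c_max < 1:
        raise ValueError("c_max must be >= 1")
    feats = pd.DataFrame(features)
    thresholds = thresholds or derive_event_thresholds(feats)
    results = {}
    for c in range(1, c_max + 1):
        model = _fit_mixture(feats, thresholds, c, n_startpoints, n_mcmc, seed, noise_sd, n_em_iter)
        model.cv_log_likelihood = _cv_loglik(
            feats, thresholds, c, folds, n_startpoints, n_mcmc, seed, noise_sd, n_em_iter
        )
        results[c] = model
    return results


def _mixture_loglik_rows(X, seqs, fracs, ev_marker, ev_thr, z_max, sds):
    comp = np.stack(
        [
            _subject_loglik(X, s, ev_marker, ev_thr, z_max, sds) + np.log(f)
            for s, f in zip(seqs, fracs)
        ],
        axis=1,
    )
    return comp  # (n, c)


def _fit_mixture(feats, thresholds, c, n_startpoints, n_mcmc, seed, noise_sd, n_em_iter):
    X, ev_marker, ev_thr, z_max, sds, markers = _prepare(feats, thresholds, noise_sd)
    base = ZScoreEventModel(feats, thresholds, noise_sd).fit(
        n_startpoints=n_startpoints, n_mcmc=n_mcmc, seed=seed
    )
    if c == 1:
        return base
    rng = np.random.default_rng(seed + 1)
    seqs = [base.sequence.copy()]
    fracs = np.array([1.0])

    def valid(seq):
        return _valid_sequence(seq, ev_marker, ev_thr)

    def weighted_fit(w, start):
        def ll(seq):
            return float(np.sum(w * _subject_loglik(X, seq, ev_marker, ev_thr, z_max, sds)))
        seq, _ = _greedy_ascent(start, ll, valid)
        return seq

    while len(seqs) < c:
        comp = _mixture_loglik_rows(X, seqs, fracs, ev_marker, ev_thr, z_max, sds)
        resp = np.exp(comp - logsumexp(comp, axis=1, keepdims=True))
        # split the subtype with the worst responsibility-weighted fit; seed the
        # new subtype from the subjects the current model explains worst
        fit_per = np.array([
            np.sum(resp[:, k] * comp[:, k]) / max(resp[:, k].sum(), 1e-9)
            for k in range(len(seqs))
        ])
        worst = int(np.argmin(fit_per))
        total_ll = logsumexp(comp, axis=1)
        poor = total_ll <= np.median(total_ll)
        start = _canonicalize(rng.permutation(len(ev_marker)), ev_marker, ev_thr)
        new_seq = weighted_fit(poor.astype(float), start)
        seqs.append(new_seq)
        fracs = np.r_[fracs, fracs[worst] / 2]
        fracs[worst] /= 2
        for _ in range(n_em_iter):
            comp = _mixture_loglik_rows(X, seqs, fracs, ev_marker, ev_thr, z_max, sds)
            resp = np.exp(comp - logsumexp(comp, axis=1, keepdims=True))
            new_fracs = resp.mean(axis=0)
            if np.any(new_fracs < 1e-3):  # empty subtype: re-seed it
                k = int(np.argmin(new_fracs))
                seqs[k] = _canonicalize(rng.permutation(len(ev_marker)), ev_marker, ev_thr)
                new_fracs = np.maximum(new_fracs, 0.05)
            fracs = new_fracs / new_fracs.sum()
            seqs = [weighted_fit(resp[:, k], seqs[k]) for k in range(len(seqs))]
    comp = _mixture_loglik_rows(X, seqs, fracs, ev_marker, ev_thr, z_max, sds)
    total = float(np.sum(logsumexp(comp, axis=1)))
    return EventModelResults(
        events=thresholds.events,
        markers=markers,
        sequence=seqs[int(np.argmax(fracs))],
        samples=base.samples,
        log_likelihood=total,
        noise_sd=sds,
        thresholds=thresholds,
        subtype_sequences=[np.asarray(s) for s in seqs],
        subtype_fractions=np.asarray(fracs),
    )


def _cv_loglik(feats, thresholds, c, folds, n_startpoints, n_mcmc, seed, noise_sd, n_em_iter):
    from sklearn.model_selection import KFold

    X_all = feats.reset_index(drop=True)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    total = 0.0
    for fold, (tr, te) in enumerate(kf.split(X_all)):
        model = _fit_mixture(
            X_all.iloc[tr], thresholds, c, n_startpoints, n_mcmc, seed + 100 + fold,
            noise_sd, n_em_iter,
        )
        X, ev_marker, ev_thr, z_max, sds, _ = _prepare(X_all.iloc[te], thresholds, noise_sd)
        comp = _mixture_loglik_rows(
            X, model.subtype_sequences, model.subtype_fractions, ev_marker, ev_thr, z_max, sds
        )
        total += float(np.sum(logsumexp(comp, axis=1)))
    return total


# --------------------------------------------------------------------------
# stage-volume relationships
# --------------------------------------------------------------------------


def stage_volume_association(stages, volumes):
    """Spearman rank correlation between assigned stages and regional volumes."""
    stages = np.asarray(stages, float)
    volumes = np.asarray(volumes, float)
    if np.ptp(stages) == 0 or np.ptp(volumes) == 0:
        return np.nan, np.nan
    rho, p = spearmanr(stages, volumes)
    return float(rho), float(p)


def spline_trajectories(features, log_volumes, degree: int = 4, n_interior_knots: int = 3):
    """Least-squares quartic B-spline curves of each marker vs log lesion volume.

    Returns ``{marker: BSpline}``. The quartic basis contains all polynomials
    up to degree 4 regardless of knot placement.
    """
    from scipy.interpolate import make_lsq_spline

    df = pd.DataFrame(features)
    x = np.asarray(log_volumes, float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    lo, hi = xs[0], xs[-1]
    interior = np.quantile(xs, np.linspace(0, 1, n_interior_knots + 2)[1:-1])
    interior = interior[(interior > lo) & (interior < hi)]
    t = np.r_[[lo] * (degree + 1), np.unique(interior), [hi] * (degree + 1)]
    out = {}
    for m in df.columns:
        out[m] = make_lsq_spline(xs, df[m].to_numpy(float)[order], t, k=degree)
    return out
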