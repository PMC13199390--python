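"""Event-based staging: thresholds, trajectories, likelihood oracle, recovery."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from lesionscape import staging
from lesionscape.staging import (
    EventThresholds,
    ZScoreEventModel,
    _canonicalize,
    _prepare,
    _trajectory_matrix,
    derive_event_thresholds,
    sequence_loglik,
)


def _tiny_thresholds():
    return EventThresholds(thresholds={"A": [1.0], "B": [0.5, 1.5]},
                           z_max={"A": 1.0, "B": 1.5})


def _simulate(thr, markers, n, sigma, rng):
    _, evm, evt, zm, _, _ = _prepare(
        pd.DataFrame(np.zeros((1, len(markers))), columns=markers), thr, 1.0)
    true_seq = _canonicalize(rng.permutation(len(thr.events)), evm, evt)
    T = _trajectory_matrix(true_seq, evm, evt, zm, len(markers))
    stage = rng.integers(0, len(thr.events) + 1, size=n)
    X = T[stage] + rng.normal(0, sigma, size=(n, len(markers)))
    return pd.DataFrame(X, columns=markers), true_seq, stage


class TestThresholds:
    def test_counting_rule(self):
        # 5% reach 0.5 and 1, 2% reach 1.5, 0.5% reach 2
        x = np.zeros(1000)
        x[:50] = 1.4
        x[:20] = 1.9
        x[:5] = 2.5
        thr = derive_event_thresholds(pd.DataFrame({"MD": x}))
        assert thr.thresholds["MD"] == [0.5, 1.0, 1.5]
        assert thr.z_max["MD"] == 1.5

    def test_unreachable_marker_dropped(self):
        df = pd.DataFrame({"MD": np.full(100, 0.1), "FA": np.full(100, 6.0)})
        with pytest.warns(UserWarning, match="excluded"):
            thr = derive_event_thresholds(df)
        assert "MD" not in thr.thresholds
        assert thr.thresholds["FA"] == list(staging.BASE_THRESHOLDS)


class TestTrajectory:
    def test_interpolation_example(self):
        # one marker's single event at position 2 of 4, threshold 1, z_max 1
        thr = EventThresholds(thresholds={"A": [1.0], "B": [0.5, 1.0, 1.5]},
                              z_max={"A": 1.0, "B": 1.5})
        seq = [("B", 0.5), ("A", 1.0), ("B", 1.0), ("B", 1.5)]
        _, evm, evt, zm, _, _ = _prepare(
            pd.DataFrame(np.zeros((1, 2)), columns=["A", "B"]), thr, 1.0)
        T = _trajectory_matrix(staging._as_indices(seq, thr), evm, evt, zm, 2)
        assert T[1, 0] == pytest.approx(0.5)  # halfway to the position-2 event
        assert T[0].tolist() == [0.0, 0.0]

    def test_trajectories_non_decreasing(self):
        rng = np.random.default_rng(0)
        thr = EventThresholds(
            thresholds={"A": [0.5, 2.0], "B": [1.0], "C": [0.5, 1.0, 3.0]},
            z_max={"A": 2.0, "B": 1.0, "C": 3.0})
        _, evm, evt, zm, _, _ = _prepare(
            pd.DataFrame(np.zeros((1, 3)), columns=["A", "B", "C"]), thr, 1.0)
        for _ in range(20):
            seq = _canonicalize(rng.permutation(6), evm, evt)
            T = _trajectory_matrix(seq, evm, evt, zm, 3)
            assert (np.diff(T, axis=0) >= -1e-12).all()


class TestLikelihood:
    def _brute_force(self, data, seq_events, thr):
        """Independent enumeration of the stage-averaged likelihood."""
        mk = list(thr.thresholds)
        n_e = len(thr.events)

        def traj(k, m):
            xs, ys = [0.0], [0.0]
            for p, (mm, t) in enumerate(seq_events, 1):
                if mm == m:
                    xs.append(float(p))
                    ys.append(t)
            if xs[-1] < n_e:
                xs.append(float(n_e))
                ys.append(thr.z_max[m])
            return np.interp(k, xs, ys)

        total = 0.0
        for i in range(len(data)):
            s = 0.0
            for k in range(n_e + 1):
                pr = 1.0
                for j, m in enumerate(mk):
                    x = data.iloc[i, j]
                    pr *= np.exp(-0.5 * (x - traj(k, m)) ** 2) / np.sqrt(2 * np.pi)
                s += pr
            total += np.log(s / (n_e + 1))
        return total

    def test_matches_enumeration_oracle(self):
        thr = _tiny_thresholds()
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(0, 1, (3, 2)), columns=["A", "B"])
        for perm in permutations(thr.events):
            got = sequence_loglik(data, list(perm), thr)
            want = self._brute_force(data, list(perm), thr)
            assert got == pytest.approx(want, abs=1e-10)

    def test_subject_permutation_invariance_and_additivity(self):
        thr = _tiny_thresholds()
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(0, 1, (5, 2)), columns=["A", "B"])
        seq = thr.events
        base = sequence_loglik(data, seq, thr)
        shuffled = data.sample(frac=1.0, random_state=2)
        assert sequence_loglik(shuffled, seq, thr) == pytest.approx(base, abs=1e-10)
        zero = pd.DataFrame([[0.0, 0.0]], columns=["A", "B"])
        with_zero = pd.concat([data, zero], ignore_index=True)
        own_term = sequence_loglik(zero, seq, thr)
        assert sequence_loglik(with_zero, seq, thr) == pytest.approx(
            base + own_term, abs=1e-10)


class TestFit:
    def test_noiseless_recovery_is_exact(self):
        thr = EventThresholds(
            thresholds={"MD": [0.5, 1.0, 2.0], "FA": [1.0, 2.0], "ISOVF": [0.5, 1.5]},
            z_max={"MD": 2.0, "FA": 2.0, "ISOVF": 1.5})
        markers = ["MD", "FA", "ISOVF"]
        for s in range(3):
            rng = np.random.default_rng(s)
            feats, true_seq, _ = _simulate(thr, markers, 200, 0.0, rng)
            res = ZScoreEventModel(feats, thr, noise_sd=0.05).fit(
                n_startpoints=5, n_mcmc=200, seed=s)
            assert np.array_equal(res.sequence, true_seq)

    def test_map_loglik_never_below_start(self):
        thr = _tiny_thresholds()
        rng = np.random.default_rng(3)
        feats, _, _ = _simulate(thr, ["A", "B"], 60, 1.0, rng)
        res = ZScoreEventModel(feats, thr).fit(n_startpoints=3, n_mcmc=300, seed=0)
        start = sequence_loglik(feats, list(range(3)), thr)
        assert res.log_likelihood >= start - 1e-9

    def test_fewer_than_two_events_rejected(self):
        thr = EventThresholds(thresholds={"A": [1.0]}, z_max={"A": 1.0})
        feats = pd.DataFrame({"A": np.random.default_rng(0).normal(size=30)})
        with pytest.raises(ValueError, match="2 events"):
            ZScoreEventModel(feats, thr).fit(n_startpoints=1, n_mcmc=10)

    def test_duplicated_markers_share_positional_mass(self):
        """Identical markers' events interchange freely in the posterior."""
        rng = np.random.default_rng(4)
        thr = EventThresholds(thresholds={"A": [1.0], "B": [1.0], "C": [2.0]},
                              z_max={"A": 1.0, "B": 1.0, "C": 2.0})
        x = rng.normal(0, 1, size=(150, 1))
        stage = rng.integers(0, 4, size=150)
        _, evm, evt, zm, _, _ = _prepare(
            pd.DataFrame(np.zeros((1, 3)), columns=["A", "B", "C"]), thr, 1.0)
        T = _trajectory_matrix(np.array([0, 1, 2]), evm, evt, zm, 3)
        X = T[stage] + rng.normal(0, 1, size=(150, 3))
        X[:, 1] = X[:, 0]  # B duplicates A exactly
        feats = pd.DataFrame(X, columns=["A", "B", "C"])
        res = ZScoreEventModel(feats, thr).fit(n_startpoints=3, n_mcmc=3000, seed=0)
        pv = res.positional_variance().to_numpy()
        assert np.abs(pv[0] - pv[1]).max() < 0.2


class TestStaging:
    def test_all_zero_subjects_get_stage_and_subtype_zero(self):
        thr = _tiny_thresholds()
        rng = np.random.default_rng(5)
        feats, _, _ = _simulate(thr, ["A", "B"], 80, 1.0, rng)
        feats.iloc[:5] = 0.0
        res = ZScoreEventModel(feats, thr).fit(n_startpoints=3, n_mcmc=300, seed=0)
        assign = res.stage_subjects(feats)
        assert (assign.stages[:5] == 0).all()
        assert (assign.subtypes[:5] == 0).all()

    def test_final_stage_subject_staged_at_max(self):
        thr = _tiny_thresholds()
        _, evm, evt, zm, _, _ = _prepare(
            pd.DataFrame(np.zeros((1, 2)), columns=["A", "B"]), thr, 1.0)
        seq = _canonicalize(np.arange(3), evm, evt)
        T = _trajectory_matrix(seq, evm, evt, zm, 2)
        rng = np.random.default_rng(6)
        feats, _, _ = _simulate(thr, ["A", "B"], 60, 1.0, rng)
        res = ZScoreEventModel(feats, thr, noise_sd=0.1).fit(
            n_startpoints=3, n_mcmc=200, seed=0)
        Tm = _trajectory_matrix(res.sequence, evm, evt, zm, 2)
        final = pd.DataFrame(Tm[[3]], columns=["A", "B"])
        assign = res.stage_subjects(final)
        assert assign.stages[0] == 3

    def test_stage_posterior_rows_normalized(self):
        thr = _tiny_thresholds()
        rng = np.random.default_rng(7)
        feats, _, _ = _simulate(thr, ["A", "B"], 40, 1.0, rng)
        res = ZScoreEventModel(feats, thr).fit(n_startpoints=2, n_mcmc=100, seed=0)
        post = res.stage_subjects(feats).stage_posterior
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)


class TestPositionalVariance:
    def test_rows_sum_to_one_and_degenerate_case(self):
        thr = _tiny_thresholds()
        rng = np.random.default_rng(8)
        feats, _, _ = _simulate(thr, ["A", "B"], 50, 0.3, rng)
        res = ZScoreEventModel(feats, thr).fit(n_startpoints=3, n_mcmc=500, seed=0)
        pv = res.positional_variance()
        assert np.allclose(pv.sum(axis=1), 1.0, atol=1e-12)
        res.samples = np.tile(res.sequence, (10, 1))  # degenerate posterior
        pv = res.positional_variance().to_numpy()
        assert set(np.unique(pv)) <= {0.0, 1.0}


def test_positional_variance_plot_returns_axes():
    import matplotlib

    matplotlib.use("Agg")
    thr = _tiny_thresholds()
    rng = np.random.default_rng(20)
    feats, _, _ = _simulate(thr, ["A", "B"], 40, 1.0, rng)
    res = ZScoreEventModel(feats, thr).fit(n_startpoints=2, n_mcmc=100, seed=0)
    ax = res.plot_positional_variance()
    assert ax.get_xlabel() == "sequence position"


class TestSubtypes:
    def test_c1_reduces_to_plain_fit(self):
        thr = _tiny_thresholds()
        rng = np.random.default_rng(9)
        feats, _, _ = _simulate(thr, ["A", "B"], 60, 0.5, rng)
        direct = staging.fit_event_model(feats, thr, n_startpoints=3, n_mcmc=200, seed=1)
        viasub = staging.fit_subtypes(feats, thr, c_max=1, folds=3,
                                      n_startpoints=3, n_mcmc=200, seed=1)[1]
        assert np.array_equal(direct.sequence, viasub.sequence)

    def test_single_sequence_data_prefers_one_subtype(self):
        thr = _tiny_thresholds()
        rng = np.random.default_rng(10)
        feats, _, _ = _simulate(thr, ["A", "B"], 120, 0.8, rng)
        out = staging.fit_subtypes(feats, thr, c_max=2, folds=3, n_startpoints=3,
                                   n_mcmc=200, seed=0, n_em_iter=5)
        assert out[1].cv_log_likelihood >= out[2].cv_log_likelihood - 5.0

    def test_two_reversed_sequences_recovered(self):
        markers = ["A", "B", "C", "D"]
        thr = EventThresholds(thresholds={m: [2.0] for m in markers},
                              z_max={m: 2.0 for m in markers})
        _, evm, evt, zm, _, _ = _prepare(
            pd.DataFrame(np.zeros((1, 4)), columns=markers), thr, 1.0)
        s1 = np.array([0, 1, 2, 3])
        s2 = s1[::-1].copy()
        rng = np.random.default_rng(11)
        X = []
        for seq in (s1, s2):
            T = _trajectory_matrix(seq, evm, evt, zm, 4)
            stage = rng.integers(0, 5, size=150)
            X.append(T[stage] + rng.normal(0, 0.5, size=(150, 4)))
        feats = pd.DataFrame(np.vstack(X), columns=markers)
        out = staging.fit_subtypes(feats, thr, c_max=2, folds=3, n_startpoints=5,
                                   n_mcmc=300, seed=0, n_em_iter=8)
        model = out[2]
        got = {tuple(s) for s in model.subtype_sequences}
        assert got == {tuple(s1), tuple(s2)}
        assert np.abs(model.subtype_fractions - 0.5).max() < 0.1


class TestStageVolume:
    def test_monotone_and_independent_pairs(self):
        rho, p = staging.stage_volume_association([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rng = np.random.default_rng(12)
        rho2, _ = staging.stage_volume_association(
            rng.normal(size=1000), rng.normal(size=1000))
        assert abs(rho2) < 0.1
        rho3, _ = staging.stage_volume_association([1, 1, 1], [2, 3, 4])
        assert np.isnan(rho3)

    def test_quartic_spline_fits_quartic_exactly(self):
        rng = np.random.default_rng(13)
        x = np.sort(rng.uniform(0, 3, 200))
        y = 0.3 * x**4 - x**3 + 2.0 * x - 1.0
        curves = staging.spline_trajectories(pd.DataFrame({"MD": y}), x)
        assert np.abs(curves["MD"](x) - y).max() < 1e-6
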