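"""Prevalence filters, mean maps, spectral clustering, Dice, search areas."""

import numpy as np
import pandas as pd
import pytest

from lesionscape import clusters, phantom
from lesionscape.clusters import ClusterParcellation

from conftest import make_abnormality_map


def _label_volume(shape, wmh_voxels, wm=True):
    lab = np.full(shape, phantom.LABEL_NAWM if wm else phantom.LABEL_BACKGROUND, int)
    for v in wmh_voxels:
        lab[v] = phantom.LABEL_WMH
    return lab


class TestPrevalence:
    def test_counts_and_conservation(self):
        shape = (4, 4, 4)
        vols = [
            _label_volume(shape, [(0, 0, 0), (1, 1, 1)]),
            _label_volume(shape, [(0, 0, 0)]),
            _label_volume(shape, []),
        ]
        prev = clusters.compute_prevalence(vols)
        assert prev.n_wmh[0, 0, 0] == 2
        assert prev.n_nawm[0, 0, 0] == 1
        total_wmh = sum((v == phantom.LABEL_WMH).sum() for v in vols)
        assert prev.n_wmh.sum() == total_wmh

    def test_voxel_outside_all_masks(self):
        lab = _label_volume((3, 3, 3), [], wm=False)
        prev = clusters.compute_prevalence([lab])
        assert prev.n_wmh.sum() == 0 and prev.n_nawm.sum() == 0


class TestMeanMaps:
    def test_single_subject_mean_is_subject_map(self):
        shape = (3, 3, 3)
        am = make_abnormality_map("s0", [0, 1], [[1.5], [2.5]])
        prev = clusters.PrevalenceMaps(
            n_wmh=np.array([[1]]).repeat(27).reshape(shape),
            n_nawm=np.full(shape, 5), n_subjects=1)
        mm = clusters.mean_patho_maps([am], prev, tau_wmh=1, tau_nawm=1)
        got = dict(zip(mm.flat_indices, mm.values[:, 0]))
        assert got[0] == 1.5 and got[1] == 2.5

    def test_mean_of_two_values(self):
        shape = (2, 2, 2)
        maps = [make_abnormality_map("a", [0], [[1.0]]),
                make_abnormality_map("b", [0], [[3.0]])]
        prev = clusters.PrevalenceMaps(np.full(shape, 2), np.full(shape, 5), 2)
        mm = clusters.mean_patho_maps(maps, prev, tau_wmh=1, tau_nawm=1)
        assert mm.values[mm.flat_indices == 0][0, 0] == 2.0

    def test_empty_inclusion_mask_raises(self):
        shape = (2, 2, 2)
        prev = clusters.PrevalenceMaps(np.zeros(shape, int), np.zeros(shape, int), 1)
        with pytest.raises(ValueError, match="exclude"):
            clusters.mean_patho_maps([make_abnormality_map("a", [0], [[1.0]])],
                                     prev, tau_wmh=1, tau_nawm=1)

    def test_phantom_means_match_signatures(self, cohort, mean_maps, truth_parcellation):
        """Included-voxel means reproduce the configured cluster signatures."""
        cfg, truth, _, _ = cohort
        lab = truth_parcellation.labels.ravel()[mean_maps.flat_indices]
        for c in range(1, cfg.k_true + 1):
            est = mean_maps.values[lab == c].mean(axis=0)
            # stages are uniform on [0,1]; expected mean = avg trajectory value
            expected = np.mean(
                [phantom.expected_abnormality(truth, c, t) for t in np.linspace(0, 1, 101)],
                axis=0)
            assert np.abs(est - expected).max() < 0.5


class TestSEMCurve:
    def test_sem_value_and_monotonicity(self):
        # fixed SD: z alternates +/-1, so SD-hat = sqrt(n/(n-1)), SEM = 1/sqrt(n-1)
        shape = (5, 1, 1)
        n_sub = 100
        maps = []
        for i in range(n_sub):
            # voxel v observed by the first 20*(v+1) subjects
            idx = [v for v in range(5) if i < 20 * (v + 1)]
            z = np.full((len(idx), 1), 1.0 if i % 2 == 0 else -1.0)
            maps.append(make_abnormality_map(f"s{i}", idx, z))
        prev = clusters.compute_prevalence(
            [_label_volume(shape, [(v, 0, 0) for v in range(5) if i < 20 * (v + 1)])
             for i in range(n_sub)])
        curve = clusters.sem_curve(maps, prev, bins=[0, 25, 45, 65, 85, 105])
        sems = curve["mean_sem"].to_numpy()
        ns = curve["mean_n"].to_numpy()
        assert list(ns) == [20, 40, 60, 80, 100]
        assert np.all(np.diff(sems) < 0)  # SEM falls with prevalence at fixed SD
        assert np.allclose(sems, 1 / np.sqrt(ns - 1), atol=1e-12)
        # and the SD = 1, n = 100 textbook value: SEM ~ 0.1
        assert sems[-1] == pytest.approx(0.1, rel=0.01)


class TestSpectral:
    def test_three_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [8, 0], [0, 8]], float)
        X = np.vstack([c + 0.3 * rng.normal(size=(30, 2)) for c in centers])
        flat = np.arange(90)
        mm = clusters.MeanPathoMaps((90, 1, 1), ("a", "b"), flat, X)
        parcel = clusters.spectral_cluster(mm, K=3, seed=0)
        truth = np.repeat([1, 2, 3], 30)
        ref = ClusterParcellation(
            labels=truth.reshape(90, 1, 1), provenance=np.ones((90, 1, 1), int), K=3)
        _, matched = clusters.match_clusters(ref, parcel)
        assert all(d == 1.0 for d in matched.values())

    def test_k_below_two_rejected(self, mean_maps):
        with pytest.raises(ValueError, match="K"):
            clusters.spectral_cluster(mean_maps, K=1)

    def test_phantom_recovery_dice(self, cohort, core_parcellation, truth_parcellation):
        _, matched = clusters.match_clusters(truth_parcellation, core_parcellation)
        assert min(matched.values()) >= 0.9

    def test_duplicate_rows_warn_not_crash(self):
        X = np.zeros((40, 2))
        X[20:] = 5.0
        mm = clusters.MeanPathoMaps((40, 1, 1), ("a", "b"), np.arange(40), X)
        with pytest.warns(UserWarning, match="duplicate"):
            parcel = clusters.spectral_cluster(mm, K=2, seed=0)
        assert set(np.unique(parcel.labels)) == {1, 2}


class TestEigengap:
    def _block_affinity(self, sizes):
        n = sum(sizes)
        A = np.zeros((n, n))
        start = 0
        for s in sizes:
            A[start:start + s, start:start + s] = 1.0
            start += s
        np.fill_diagonal(A, 0.0)
        return A

    def test_disconnected_components_force_k(self):
        for sizes in ([10, 12, 9], [8, 8, 8, 8]):
            k, gaps, weak = clusters.eigengap_select(self._block_affinity(sizes))
            assert k == len(sizes)
            assert not weak

    def test_single_blob_flagged_weak(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        A = clusters.self_tuning_affinity(X)
        k, gaps, weak = clusters.eigengap_select(A, k_max=6)
        assert gaps[k] < 0.3  # no dominant gap structure


class TestDice:
    def test_identical_disjoint_partial(self):
        a = np.zeros((4, 1, 1), int)
        a[:3] = 1
        b = a.copy()
        d = clusters.dice_overlap(a, b)
        assert d.loc[1, 1] == 1.0
        b2 = np.zeros_like(a)
        b2[3] = 1
        assert clusters.dice_overlap(a, b2).loc[1, 1] == 0.0
        # |A| = 3, |B| = 3, overlap 2
        b3 = np.zeros_like(a)
        b3[1:4] = 1
        assert clusters.dice_overlap(a, b3).loc[1, 1] == pytest.approx(2 * 2 / 6)

    def test_brute_force_oracle_on_random_partitions(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 3, size=(20, 1, 1))
            b = rng.integers(0, 3, size=(20, 1, 1))
            d = clusters.dice_overlap(a, b)
            for la in d.index:
                for lb in d.columns:
                    sa = {i for i in range(20) if a[i, 0, 0] == la}
                    sb = {i for i in range(20) if b[i, 0, 0] == lb}
                    expect = 2 * len(sa & sb) / (len(sa) + len(sb))
                    assert d.loc[la, lb] == pytest.approx(expect)

    def test_label_permutation_invariance(self, core_parcellation, truth_parcellation):
        d1 = clusters.dice_overlap(truth_parcellation, core_parcellation)
        swapped = core_parcellation.labels.copy()
        swapped[core_parcellation.labels == 1] = 2
        swapped[core_parcellation.labels == 2] = 1
        d2 = clusters.dice_overlap(truth_parcellation.labels, swapped)
        assert np.allclose(np.sort(d1.to_numpy(), axis=1), np.sort(d2.to_numpy(), axis=1))


class TestSearchArea:
    def test_surrounded_voxel_and_iterative_growth(self):
        shape = (9, 3, 3)
        core = np.zeros(shape, int)
        core[0] = 2  # slab of cluster 2 at x=0
        prov = (core > 0).astype(int)
        wm = np.ones(shape, bool)
        ext = clusters.assign_excluded_voxels(
            ClusterParcellation(core, prov, K=2), wm)
        assert (ext.labels > 0).all()
        assert (ext.labels[1:] == 2).all()
        # voxel at x=3 needed a 3-step expansion
        assert ext.provenance[3, 1, 1] == clusters.PROV_EXTENDED

    def test_tie_breaks_to_smallest_label(self):
        shape = (3, 1, 1)
        core = np.array([1, 0, 2]).reshape(shape)
        ext = clusters.assign_excluded_voxels(
            ClusterParcellation(core, (core > 0).astype(int), K=2),
            np.ones(shape, bool))
        assert ext.labels[1, 0, 0] == 1

    def test_core_labels_never_change(self, core_parcellation, cohort):
        _, truth, _, _ = cohort
        ext = clusters.assign_excluded_voxels(core_parcellation, truth.wm_mask)
        core_mask = core_parcellation.core_mask()
        assert np.array_equal(ext.labels[core_mask], core_parcellation.labels[core_mask])
        assert (ext.labels[truth.wm_mask] > 0).all()


class TestVarianceExplained:
    def test_perfect_and_oracle(self):
        vals = np.array([[1.0], [1.0], [5.0], [5.0]])
        mm = clusters.MeanPathoMaps((4, 1, 1), ("MD",), np.arange(4), vals)
        lab = np.array([1, 1, 2, 2]).reshape(4, 1, 1)
        p = ClusterParcellation(lab, (lab > 0).astype(int), K=2)
        assert clusters.cluster_variance_explained(mm, p)["MD"] == pytest.approx(1.0)

    def test_matches_ols_anova_oracle(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        vals = rng.normal(size=(12, 1))
        lab = np.array([1] * 4 + [2] * 4 + [3] * 4).reshape(12, 1, 1)
        mm = clusters.MeanPathoMaps((12, 1, 1), ("MD",), np.arange(12), vals)
        p = ClusterParcellation(lab, (lab > 0).astype(int), K=3)
        r2 = clusters.cluster_variance_explained(mm, p)["MD"]
        df = pd.DataFrame({"y": vals[:, 0], "g": lab.ravel().astype(str)})
        oracle = smf.ols("y ~ C(g)", df).fit().rsquared
        assert r2 == pytest.approx(oracle, abs=1e-12)

    def test_random_labels_explain_nothing(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(10000, 1))
        lab = rng.integers(1, 4, size=10000).reshape(-1, 1, 1)
        mm = clusters.MeanPathoMaps((10000, 1, 1), ("MD",), np.arange(10000), vals)
        p = ClusterParcellation(lab, (lab > 0).astype(int), K=3)
        assert clusters.cluster_variance_explained(mm, p)["MD"] < 0.02


class TestSubgroups:
    def test_volume_bin_rule(self):
        out = clusters.volume_bins([4000.0, 7000.0, 20000.0])
        assert list(out) == ["low", "medium", "high"]

    def test_full_cohort_subgroup_is_self_consistent(self, abnormality_maps, cohort):
        _, _, volumes, _ = cohort
        groups = ["all"] * len(volumes)
        table = clusters.subgroup_stability(
            abnormality_maps, volumes, groups, K=3, tau_wmh=10, tau_nawm=30, seed=0)
        assert (table["dice"] == 1.0).all()

    def test_shared_structure_across_sexes(self, abnormality_maps, cohort):
        _, _, volumes, table = cohort
        out = clusters.subgroup_stability(
            abnormality_maps, volumes, table["sex"].to_numpy(), K=3,
            tau_wmh=10, tau_nawm=30, seed=0)
        ok = out.dropna(subset=["dice"])
        assert (ok["dice"] >= 0.8).all()
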