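"""Shared phantom-cohort fixtures.

One small cohort is simulated once per session and threaded through the whole
pipeline (normative fit -> z maps -> prevalence -> mean maps -> clustering ->
ROI features) so integration-level fixtures stay cheap.
"""

import numpy as np
import pandas as pd
import pytest

from lesionscape import clusters, normative, phantom, roi


@pytest.fixture(scope="session")
def cohort():
    cfg = phantom.PhantomConfig(grid_shape=(16, 16, 16), k_true=3, n_subjects=120, seed=1)
    truth, volumes, table = phantom.simulate_cohort(cfg)
    return cfg, truth, volumes, table


@pytest.fixture(scope="session")
def normative_results(cohort):
    _, _, volumes, table = cohort
    return normative.fit_voxelwise_normative(volumes, table, min_nawm=30)


@pytest.fixture(scope="session")
def abnormality_maps(cohort, normative_results):
    _, _, volumes, table = cohort
    return normative.zscore_cohort(normative_results, volumes, table)


@pytest.fixture(scope="session")
def prevalence(cohort):
    _, _, volumes, _ = cohort
    return clusters.compute_prevalence(volumes)


@pytest.fixture(scope="session")
def mean_maps(abnormality_maps, prevalence):
    return clusters.mean_patho_maps(abnormality_maps, prevalence, tau_wmh=10, tau_nawm=30)


@pytest.fixture(scope="session")
def truth_parcellation(cohort):
    _, truth, _, _ = cohort
    return clusters.ClusterParcellation(
        labels=truth.true_cluster_map,
        provenance=(truth.true_cluster_map > 0).astype(int),
        K=truth.config.k_true,
    )


@pytest.fixture(scope="session")
def core_parcellation(mean_maps):
    return clusters.spectral_cluster(mean_maps, K=3, seed=0)


@pytest.fixture(scope="session")
def feature_matrix(abnormality_maps, cohort, truth_parcellation):
    _, _, volumes, _ = cohort
    return roi.assemble_feature_matrix(abnormality_maps, volumes, truth_parcellation)


def make_abnormality_map(subject_id, flat_indices, z, markers=("MD",)):
    """Hand-built sparse abnormality map for unit tests."""
    return normative.AbnormalityMap(
        subject_id=subject_id,
        markers=tuple(markers),
        flat_indices=np.asarray(flat_indices, dtype=int),
        z=np.asarray(z, dtype=float).reshape(len(flat_indices), len(markers)),
    )


def subject_table(n, seed=0, age_range=(45.0, 81.0)):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        dict(
            id=[f"s{i}" for i in range(n)],
            age=rng.uniform(*age_range, n),
            sex=rng.integers(0, 2, n),
        )
    )
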