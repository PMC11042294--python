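"""Shared fixtures: one small synthetic dataset and one trained model.

Session scope keeps the suite fast — the small model trains once (~2 s) and
is reused by every test that needs a trained classifier.
"""

import numpy as np
import pytest

from cyclestate import (
    AlignedMatrix,
    FeatureSpace,
    ModelConfig,
    SyntheticParams,
    align_features,
    build_model,
    generate_dataset,
    normalize,
    train,
)

SMALL_PARAMS = SyntheticParams(
    n_genes=120, markers_per_state=6, marker_log2fc=2.0, baseline_mean=1.0,
    dispersion=2.0, dropout_rate=0.1, seed=11,
)


@pytest.fixture(scope="session")
def small_params():
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL_PARAMS, 700)


@pytest.fixture(scope="session")
def small_space(small_dataset):
    return FeatureSpace(
        feature_ids=small_dataset.counts.gene_ids,
        state_names=SMALL_PARAMS.state_names,
        marker_sets=small_dataset.marker_sets,
    )


@pytest.fixture(scope="session")
def small_norm_logcpm(small_dataset):
    return normalize(small_dataset.counts, method="log_cpm")


@pytest.fixture(scope="session")
def small_norm_pearson(small_dataset):
    return normalize(small_dataset.counts, method="pearson_residual")


@pytest.fixture(scope="session")
def small_aligned(small_norm_pearson, small_space):
    return align_features(small_norm_pearson, small_space)


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig(n_features=120, hidden1=96, hidden2=24, seed=0)


@pytest.fixture(scope="session")
def small_model(small_config, small_space, small_aligned, small_dataset):
    model = build_model(small_config, small_space)
    return train(model, small_aligned, small_dataset.labels)


def subset_aligned(aligned: AlignedMatrix, idx) -> AlignedMatrix:
    idx = np.asarray(idx)
    return AlignedMatrix(aligned.values[idx], aligned.feature_ids,
                         aligned.cell_ids[idx], aligned.missing_fraction,
                         aligned.provenance)
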