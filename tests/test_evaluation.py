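"""Metrics, cross-validation, calibration simulation, sweeps, sensitivity."""

import numpy as np
import pytest

from cyclestate import (
    InvalidParameterError,
    ModelConfig,
    ami,
    classification_error,
    cross_validate,
    f1_per_state,
    grid_search_hidden,
    missing_gene_sensitivity,
    predict_likelihoods,
    simulate_ami_calibration,
    threshold_sweep,
)
from cyclestate.evaluation import DEFAULT_HIDDEN_GRID


# ---------------------------------------------------------------------------
# F1 and error rate
# ---------------------------------------------------------------------------

def test_perfect_prediction_gives_f1_one():
    y = ["A", "B", "A", "C"]
    assert (f1_per_state(y, y) == 1.0).all()


def test_constant_prediction_matches_closed_form():
    truth = np.array(["A"] * 3 + ["B"] * 7, dtype=object)
    pred = np.array(["A"] * 10, dtype=object)
    prev = 0.3
    f1 = f1_per_state(truth, pred)
    assert f1["A"] == pytest.approx(2 * prev / (1 + prev))
    assert f1["B"] == 0.0


def test_six_cell_toy_case_matches_hand_computation():
    truth = ["A", "A", "B", "B", "C", "C"]
    pred = ["A", "B", "B", "B", "C", "A"]
    f1 = f1_per_state(truth, pred)
    assert f1["A"] == pytest.approx(0.5)       # tp=1 fp=1 fn=1
    assert f1["B"] == pytest.approx(0.8)       # tp=2 fp=1 fn=0
    assert f1["C"] == pytest.approx(2 / 3)     # tp=1 fp=0 fn=1


def test_state_absent_from_both_is_not_reported():
    f1 = f1_per_state(["A", "B"], ["A", "B"])
    assert set(f1.index) == {"A", "B"}


def test_label_length_mismatch_and_unknown_in_truth_raise():
    with pytest.raises(InvalidParameterError):
        f1_per_state(["A"], ["A", "B"])
    with pytest.raises(InvalidParameterError):
        f1_per_state(["Unknown"], ["A"])


def test_error_rate_excludes_unknown():
    assert classification_error(["A", "A", "B"],
                                ["A", "Unknown", "A"]) == pytest.approx(0.5)
    assert classification_error(["A", "B"], ["A", "B"]) == 0.0
    assert np.isnan(classification_error(["A"], ["Unknown"]))


def test_error_rate_inclusive_mode_counts_unknown_as_error():
    err = classification_error(["A", "A", "B"], ["A", "Unknown", "A"],
                               include_unknown=True)
    assert err == pytest.approx(2 / 3)


# ---------------------------------------------------------------------------
# AMI
# ---------------------------------------------------------------------------

def test_ami_is_one_for_identical_and_relabeled_partitions():
    y = ["A", "A", "B", "B", "C", "C"]
    assert ami(y, y) == pytest.approx(1.0)
    relabeled = {"A": "x", "B": "y", "C": "z"}
    assert ami(y, [relabeled[v] for v in y]) == pytest.approx(1.0)


def test_ami_symmetric_without_unknowns():
    rng = np.random.default_rng(0)
    a = rng.choice(["x", "y", "z"], 40)
    b = rng.choice(["p", "q"], 40)
    assert ami(a, b, exclude_unknown=False) == \
        pytest.approx(ami(b, a, exclude_unknown=False))


def test_ami_drops_unknown_predictions_first():
    truth = ["A", "A", "B", "B", "A", "B"]
    pred = ["A", "Unknown", "B", "B", "A", "Unknown"]
    kept_truth = ["A", "B", "B", "A"]
    kept_pred = ["A", "B", "B", "A"]
    assert ami(truth, pred) == pytest.approx(ami(kept_truth, kept_pred,
                                                 exclude_unknown=False))


def test_ami_needs_two_cells_after_exclusion():
    with pytest.raises(InvalidParameterError):
        ami(["A", "B"], ["A", "Unknown"])


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_cross_validation_table_layout_and_accuracy():
    """Well-separated planted states give median macro-F1 >= 0.9."""
    from cyclestate import (FeatureSpace, SyntheticParams, align_features,
                            generate_dataset, normalize)

    params = SyntheticParams(n_genes=120, markers_per_state=6,
                             marker_log2fc=3.0, dropout_rate=0.05, seed=17)
    ds = generate_dataset(params, 600)
    space = FeatureSpace(feature_ids=ds.counts.gene_ids,
                         state_names=params.state_names)
    aligned = align_features(normalize(ds.counts, "pearson_residual"), space)
    cfg = ModelConfig(n_features=120, hidden1=96, hidden2=24)
    table = cross_validate(aligned, ds.labels, k=3, seed=0, config=cfg,
                           feature_space=space)
    for state in params.state_names:
        assert (table.state == state).sum() == 3
    macro = table.loc[table.state == "macro", "f1"]
    assert macro.median() >= 0.9


def test_cross_validation_small_class_is_named(small_aligned, small_dataset):
    labels = small_dataset.labels.copy()
    labels[labels == "S"] = "G1"
    labels[:4] = "S"
    with pytest.raises(InvalidParameterError, match="S"):
        cross_validate(small_aligned, labels, k=10)


# ---------------------------------------------------------------------------
# AMI calibration simulation
# ---------------------------------------------------------------------------

def test_full_similarity_with_matched_vocabulary_is_exactly_one():
    curve = simulate_ami_calibration(4, 4, similarities=[1.0], n_cells=300,
                                     n_reps=5, seed=0)
    assert curve.mean_ami.iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_zero_similarity_is_chance_level():
    curve = simulate_ami_calibration(4, 6, similarities=[0.0], n_cells=800,
                                     n_reps=30, seed=0)
    assert abs(curve.mean_ami.iloc[0]) < 0.02


def test_curve_monotone_in_similarity_within_error():
    curve = simulate_ami_calibration(5, 3, n_cells=500, n_reps=25, seed=1)
    m, s = curve.mean_ami.values, curve.sem_ami.values
    for i in range(len(m) - 1):
        assert m[i + 1] >= m[i] - 2 * (s[i] + s[i + 1])


def test_calibration_rejects_bad_grid():
    with pytest.raises(InvalidParameterError):
        simulate_ami_calibration(4, 4, similarities=[1.5])
    with pytest.raises(InvalidParameterError):
        simulate_ami_calibration(1, 4)


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

def test_sweep_at_zero_threshold_has_full_coverage(small_model, small_aligned,
                                                   small_dataset):
    lik = predict_likelihoods(small_model, small_aligned)
    table = threshold_sweep(lik, small_dataset.labels, subsample=None, seed=0)
    row0 = table.iloc[0]
    assert row0.threshold == 0.0
    assert row0.pct_predicted == pytest.approx(100.0)
    assert row0.baseline_ami == pytest.approx(row0.ami)
    assert (np.diff(table.pct_predicted) <= 1e-12).all()


def test_sweep_respects_min_cells(small_model, small_aligned, small_dataset):
    lik = predict_likelihoods(small_model, small_aligned)
    table = threshold_sweep(lik, small_dataset.labels, subsample=None,
                            min_cells=small_aligned.n_cells + 1, seed=0)
    assert table.ami.isna().all()


def test_sweep_subsample_bounds_cells(small_model, small_aligned,
                                      small_dataset):
    lik = predict_likelihoods(small_model, small_aligned)
    table = threshold_sweep(lik, small_dataset.labels, subsample=0.5, seed=0)
    # pct refers to the subsampled population
    assert table.pct_predicted.iloc[0] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# missing-gene sensitivity
# ---------------------------------------------------------------------------

def test_vanishing_fraction_recovers_unperturbed_error(small_model,
                                                       small_aligned,
                                                       small_dataset):
    from cyclestate import assign_states

    base = classification_error(
        small_dataset.labels,
        assign_states(predict_likelihoods(small_model, small_aligned),
                      0.5).labels)
    table = missing_gene_sensitivity(small_model, small_aligned,
                                     small_dataset.labels,
                                     fractions=[1 / 120], n_reps=5, seed=0)
    assert abs(table.error_rate.median() - base) < 0.02


def test_sensitivity_pct_predicted_monotone_in_threshold(small_model,
                                                         small_aligned,
                                                         small_dataset):
    table = missing_gene_sensitivity(small_model, small_aligned,
                                     small_dataset.labels, fractions=[0.9],
                                     n_reps=3, thresholds=[0.5, 0.9], seed=0)
    for rep, grp in table.groupby("replicate"):
        by_t = grp.set_index("threshold")
        assert by_t.loc[0.9, "pct_predicted"] <= by_t.loc[0.5, "pct_predicted"]


def test_sensitivity_rejects_bad_fraction(small_model, small_aligned,
                                          small_dataset):
    with pytest.raises(InvalidParameterError):
        missing_gene_sensitivity(small_model, small_aligned,
                                 small_dataset.labels, fractions=[1.0])


# ---------------------------------------------------------------------------
# hidden-layer grid search
# ---------------------------------------------------------------------------

def test_default_grid_is_the_18_funnel_configurations():
    assert len(DEFAULT_HIDDEN_GRID) == 18
    assert (600, 200) in DEFAULT_HIDDEN_GRID
    assert all(h1 > h2 for h1, h2 in DEFAULT_HIDDEN_GRID)


def test_two_point_grid_is_reproducible(small_aligned, small_dataset,
                                        small_space):
    cfg = ModelConfig(n_features=120, hidden1=64, hidden2=16, rounds=1,
                      epochs_per_round=5)
    kwargs = dict(grid=[(64, 16), (32, 12)], seed=0, config=cfg,
                  feature_space=small_space)
    a = grid_search_hidden(small_aligned, small_dataset.labels, **kwargs)
    b = grid_search_hidden(small_aligned, small_dataset.labels, **kwargs)
    assert a.equals(b)
    assert set(map(tuple, a[["hidden1", "hidden2"]].values)) == \
        {(64, 16), (32, 12)}


def test_degenerate_single_config_grid(small_aligned, small_dataset,
                                       small_space):
    cfg = ModelConfig(n_features=120, hidden1=64, hidden2=16, rounds=1,
                      epochs_per_round=3)
    table = grid_search_hidden(small_aligned, small_dataset.labels,
                               grid=[(48, 12)], seed=0, config=cfg,
                               feature_space=small_space)
    assert len(table) == 1
    assert (table.hidden1.iloc[0], table.hidden2.iloc[0]) == (48, 12)
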