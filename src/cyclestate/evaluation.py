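"""Quantitative evaluation machinery for the classifier.

Covers per-state F1 and error rate, adjusted mutual information (AMI) with
"Unknown" exclusion, repeated-holdout cross-validation, the AMI
similarity-calibration simulation used to compare classifiers with different
state vocabularies, the likelihood-threshold sweep with its random-removal
baseline, missing-gene sensitivity simulation, and the hidden-layer grid
search.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score

from .classifier import (
    UNKNOWN_LABEL,
    ClassifierModel,
    ModelConfig,
    assign_states,
    build_model,
    predict_likelihoods,
    train,
)
from .errors import InvalidParameterError
from .preprocess import AlignedMatrix, FeatureSpace

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))
DEFAULT_SIMILARITY_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))

#: All funnel-valid (hidden1, hidden2) pairs with hidden1 in 200..700 and
#: hidden2 in 100..400, both at increments of 100 — 18 configurations.
DEFAULT_HIDDEN_GRID = tuple(
    (h1, h2) for h1 in range(200, 701, 100) for h2 in range(100, 401, 100)
    if h1 > h2
)


def _check_labels(truth, pred):
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(truth) != len(pred):
        raise InvalidParameterError(
            f"label length mismatch: {len(truth)} vs {len(pred)}"
        )
    if UNKNOWN_LABEL in set(truth):
        raise InvalidParameterError(
            f'"{UNKNOWN_LABEL}" is allowed in predictions only'
        )
    return truth, pred


def f1_per_state(truth, pred) -> pd.Series:
    """One-vs-rest F1 per state; "Unknown" predictions count as negatives.

    States absent from both labelings are simply not reported (undefined, not
    0).  The macro average is ``result.mean()``.
    """
    truth, pred = _check_labels(truth, pred)
    states = sorted(set(truth) | (set(pred) - {UNKNOWN_LABEL}))
    out = {}
    for s in states:
        tp = int(((truth == s) & (pred == s)).sum())
        fp = int(((truth != s) & (pred == s)).sum())
        fn = int(((truth == s) & (pred != s)).sum())
        denom = 2 * tp + fp + fn
        out[s] = 2 * tp / denom if denom else np.nan
    return pd.Series(out, name="f1")


def classification_error(truth, pred, include_unknown: bool = False) -> float:
    """Misclassified / classified; "Unknown" cells excluded by default.

    With ``include_unknown=True``, "Unknown" predictions count as errors and
    every cell enters the denominator.  Returns NaN (with a warning) when no
    cell is classified.
    """
    truth, pred = _check_labels(truth, pred)
    if include_unknown:
        return float((truth != pred).mean())
    classified = pred != UNKNOWN_LABEL
    if not classified.any():
        logger.warning("no classified cells: error rate undefined")
        return float("nan")
    return float((truth[classified] != pred[classified]).mean())


def ami(truth, pred, exclude_unknown: bool = True) -> float:
    """Adjusted mutual information (permutation-model expected-MI correction,
    arithmetic-mean normalization).

    Cells whose *prediction* is "Unknown" are dropped first when
    ``exclude_unknown`` is set — rejected cells should not count against
    agreement with the reference.
    """
    truth, pred = _check_labels(truth, pred)
    if exclude_unknown:
        keep = pred != UNKNOWN_LABEL
        truth, pred = truth[keep], pred[keep]
    if len(truth) < 2:
        raise InvalidParameterError(
            f"only {len(truth)} cells after exclusion (>= 2 required)"
        )
    return float(adjusted_mutual_info_score(truth, pred,
                                            average_method="arithmetic"))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(data: AlignedMatrix, labels, k: int = 10,
                   holdout: float = 0.2, seed: int = 0,
                   config: ModelConfig | None = None,
                   feature_space: FeatureSpace | None = None) -> pd.DataFrame:
    """k independent repetitions of (stratified 80/20 split, train, F1 on 20%).

    Returns a long table: ``fold, state, f1`` (plus a ``macro`` row per fold).
    """
    labels = np.asarray(labels, dtype=object)
    states, counts = np.unique(labels, return_counts=True)
    too_small = states[counts < k]
    if too_small.size:
        raise InvalidParameterError(
            f"class(es) with fewer than k={k} cells: {list(too_small)}"
        )
    if config is None:
        config = ModelConfig(n_features=data.n_features,
                             n_classes=len(states))
    if feature_space is None:
        feature_space = FeatureSpace(feature_ids=data.feature_ids,
                                     state_names=tuple(states))
    rng = np.random.default_rng([seed, 3])
    rows = []
    for fold in range(k):
        test_idx = []
        for s in states:
            members = np.flatnonzero(labels == s)
            n_test = max(1, int(round(holdout * members.size)))
            test_idx.append(rng.choice(members, size=n_test, replace=False))
        test_idx = np.concatenate(test_idx)
        test_mask = np.zeros(len(labels), dtype=bool)
        test_mask[test_idx] = True

        fold_cfg = replace(config, seed=int(rng.integers(2 ** 31)))
        model = build_model(fold_cfg, feature_space)
        sub_train = AlignedMatrix(data.values[~test_mask], data.feature_ids,
                                  data.cell_ids[~test_mask],
                                  data.missing_fraction, data.provenance)
        train(model, sub_train, labels[~test_mask])
        sub_test = AlignedMatrix(data.values[test_mask], data.feature_ids,
                                 data.cell_ids[test_mask],
                                 data.missing_fraction, data.provenance)
        assign = assign_states(predict_likelihoods(model, sub_test),
                               threshold=0.0)
        f1 = f1_per_state(labels[test_mask], assign.labels)
        for s, v in f1.items():
            rows.append((fold, s, float(v)))
        rows.append((fold, "macro", float(f1.mean())))
    return pd.DataFrame(rows, columns=["fold", "state", "f1"])


# ---------------------------------------------------------------------------
# AMI similarity calibration
# ---------------------------------------------------------------------------

def simulate_ami_calibration(k_ref: int, k_pred: int,
                             similarities=DEFAULT_SIMILARITY_GRID,
                             n_cells: int = 1000, n_reps: int = 100,
                             seed: int = 0) -> pd.DataFrame:
    """Expected AMI for a classifier with a given similarity to the reference.

    Reference labels are drawn uniformly over ``k_ref`` states.  For
    similarity ``s``, exactly ``round(s * n_cells)`` cells copy the reference
    label (mapped through the fixed surjection ``i -> i mod k_pred`` when the
    vocabularies differ) and the rest draw uniformly from the ``k_pred``
    vocabulary.  Returns rows of ``(k_ref, k_pred, similarity, mean_ami,
    sem_ami, n_reps)``.  At similarity 1.0 with matched vocabularies the AMI
    is exactly 1; at 0.0 it is ~0 by chance correction.
    """
    if k_ref < 2 or k_pred < 2:
        raise InvalidParameterError("k_ref and k_pred must be >= 2")
    if n_cells < 2 or n_reps < 1:
        raise InvalidParameterError("invalid n_cells or n_reps")
    sims = [float(s) for s in similarities]
    if any(s < 0 or s > 1 for s in sims):
        raise InvalidParameterError("similarities must lie in [0, 1]")
    rng = np.random.default_rng([seed, k_ref, k_pred])
    rows = []
    for s in sims:
        n_copy = int(round(s * n_cells))
        amis = np.empty(n_reps)
        for r in range(n_reps):
            ref = rng.integers(k_ref, size=n_cells)
            pred = rng.integers(k_pred, size=n_cells)
            copy_idx = rng.choice(n_cells, size=n_copy, replace=False)
            pred[copy_idx] = ref[copy_idx] % k_pred
            amis[r] = adjusted_mutual_info_score(ref, pred,
                                                 average_method="arithmetic")
        rows.append((k_ref, k_pred, s, float(amis.mean()),
                     float(amis.std(ddof=1) / np.sqrt(n_reps))
                     if n_reps > 1 else 0.0, n_reps))
    return pd.DataFrame(rows, columns=["k_ref", "k_pred", "similarity",
                                       "mean_ami", "sem_ami", "n_reps"])


def calibration_grid(k_refs=range(3, 9), k_preds=range(3, 9),
                     similarities=DEFAULT_SIMILARITY_GRID,
                     n_cells: int = 1000, n_reps: int = 100,
                     seed: int = 0) -> pd.DataFrame:
    """Full calibration surface over reference/predicted state counts."""
    frames = [simulate_ami_calibration(kr, kp, similarities, n_cells, n_reps,
                                       seed)
              for kr in k_refs for kp in k_preds]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

def threshold_sweep(lik, reference, thresholds=DEFAULT_THRESHOLD_GRID,
                    subsample: float | None = 0.9, min_cells: int = 20,
                    seed: int = 0) -> pd.DataFrame:
    """AMI and percent-predicted across the likelihood-threshold grid.

    ``baseline_ami`` removes the same *number* of cells uniformly at random
    (keeping the unthresholded labels), isolating whether the AMI gain comes
    specifically from discarding low-likelihood cells.  AMI is NaN whenever
    ``min_cells`` or fewer cells survive.  ``subsample`` optionally keeps a
    random fraction of cells first, for probing the variance of the sweep
    across repeated subsamples; pass ``None`` to use all cells.
    """
    reference = np.asarray(reference, dtype=object)
    if len(reference) != len(lik.cell_ids):
        raise InvalidParameterError("reference must cover all cells")
    rng = np.random.default_rng([seed, 5])
    n = len(reference)
    if subsample is not None:
        if not (0.0 < subsample <= 1.0):
            raise InvalidParameterError("subsample must be in (0, 1]")
        keep = rng.choice(n, size=max(2, int(round(subsample * n))),
                          replace=False)
    else:
        keep = np.arange(n)
    V = lik.values[keep]
    ref = reference[keep]
    from .classifier import LikelihoodMatrix  # local to avoid cycle at import
    sub_lik = LikelihoodMatrix(values=V, state_names=lik.state_names,
                               cell_ids=lik.cell_ids[keep])
    base_assign = assign_states(sub_lik, threshold=0.0)
    rows = []
    for t in thresholds:
        assign = assign_states(sub_lik, threshold=float(t))
        predicted = assign.labels != UNKNOWN_LABEL
        n_pred = int(predicted.sum())
        pct = 100.0 * n_pred / len(ref)
        if n_pred > min_cells:
            a = ami(ref[predicted], assign.labels[predicted])
            rand_keep = rng.choice(len(ref), size=n_pred, replace=False)
            b = ami(ref[rand_keep], base_assign.labels[rand_keep])
        else:
            a, b = float("nan"), float("nan")
        rows.append((float(t), a, pct, b))
    return pd.DataFrame(rows, columns=["threshold", "ami", "pct_predicted",
                                       "baseline_ami"])


# ---------------------------------------------------------------------------
# missing-gene sensitivity
# ---------------------------------------------------------------------------

def missing_gene_sensitivity(model: ClassifierModel, data: AlignedMatrix,
                             truth, fractions, n_reps: int = 10,
                             thresholds=(0.5,), seed: int = 0) -> pd.DataFrame:
    """Error rate and percent predicted under simulated gene dropout.

    For each (fraction, replicate) a seeded random subset of feature columns
    is zeroed for all cells (at the classifier-input scale, i.e. after
    normalization/alignment); states are assigned at each threshold and the
    error rate (excluding "Unknown") and percent predicted are recorded.
    """
    truth = np.asarray(truth, dtype=object)
    for f in fractions:
        if not (0.0 < f < 1.0):
            raise InvalidParameterError(
                f"fraction {f} outside the open interval (0, 1)"
            )
    rng = np.random.default_rng([seed, 9])
    n_feat = data.n_features
    rows = []
    for f in fractions:
        n_zero = int(round(f * n_feat))
        for rep in range(n_reps):
            zero_cols = rng.choice(n_feat, size=n_zero, replace=False)
            X = data.values.copy()
            X[:, zero_cols] = 0.0
            perturbed = AlignedMatrix(X, data.feature_ids, data.cell_ids,
                                      missing_fraction=f,
                                      provenance=data.provenance)
            lik = predict_likelihoods(model, perturbed)
            for t in thresholds:
                assign = assign_states(lik, threshold=float(t))
                err = classification_error(truth, assign.labels)
                pct = 100.0 * float(
                    (assign.labels != UNKNOWN_LABEL).mean())
                rows.append((float(f), rep, float(t), err, pct))
    return pd.DataFrame(rows, columns=["fraction_missing", "replicate",
                                       "threshold", "error_rate",
                                       "pct_predicted"])


# ---------------------------------------------------------------------------
# hidden-layer grid search
# ---------------------------------------------------------------------------

def grid_search_hidden(data: AlignedMatrix, labels,
                       grid=DEFAULT_HIDDEN_GRID, eval_sets=None,
                       holdout: float = 0.2, seed: int = 0,
                       config: ModelConfig | None = None,
                       feature_space: FeatureSpace | None = None,
                       threshold: float = 0.5) -> pd.DataFrame:
    """Train one model per (hidden1, hidden2) and rank configurations.

    ``mean_f1`` is the macro F1 on a held-out split of the labeled data;
    ``mean_ami`` averages AMI over ``eval_sets`` (pairs of aligned matrix and
    reference labels), when given.  Ranking is by mean F1, then mean AMI.
    """
    grid = list(grid)
    if not grid:
        raise InvalidParameterError("grid must be non-empty")
    labels = np.asarray(labels, dtype=object)
    states = sorted(set(labels))
    if config is None:
        config = ModelConfig(n_features=data.n_features,
                             n_classes=len(states))
    if feature_space is None:
        feature_space = FeatureSpace(feature_ids=data.feature_ids,
                                     state_names=tuple(states))
    rng = np.random.default_rng([seed, 11])
    n = len(labels)
    test_idx = rng.choice(n, size=max(1, int(round(holdout * n))),
                          replace=False)
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    sub_train = AlignedMatrix(data.values[~test_mask], data.feature_ids,
                              data.cell_ids[~test_mask],
                              data.missing_fraction, data.provenance)
    sub_test = AlignedMatrix(data.values[test_mask], data.feature_ids,
                             data.cell_ids[test_mask],
                             data.missing_fraction, data.provenance)
    rows = []
    for h1, h2 in grid:
        cfg = replace(config, hidden1=int(h1), hidden2=int(h2))
        model = build_model(cfg, feature_space)
        train(model, sub_train, labels[~test_mask])
        assign = assign_states(predict_likelihoods(model, sub_test),
                               threshold=0.0)
        mean_f1 = float(f1_per_state(labels[test_mask], assign.labels).mean())
        amis = []
        for eval_data, ref in (eval_sets or []):
            a = assign_states(predict_likelihoods(model, eval_data),
                              threshold=threshold)
            amis.append(ami(np.asarray(ref, dtype=object), a.labels))
        rows.append((int(h1), int(h2), mean_f1,
                     float(np.mean(amis)) if amis else float("nan")))
    table = pd.DataFrame(rows, columns=["hidden1", "hidden2", "mean_f1",
                                        "mean_ami"])
    return table.sort_values(["mean_f1", "mean_ami"],
                             ascending=False, kind="stable",
                             na_position="last").reset_index(drop=True)
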