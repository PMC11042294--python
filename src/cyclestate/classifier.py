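"""The cell-cycle state classifier: a dense network with threshold rejection.

Architecture
------------
``dense(n_features -> hidden1, ReLU) -> dropout -> dense(hidden1 -> hidden2,
ReLU) -> dropout -> dense(hidden2 -> n_classes, softmax)``, defaults 600/200
hidden neurons and 50% dropout.  Training minimizes categorical cross-entropy
by minibatch stochastic gradient descent with momentum.  The process runs
``rounds`` (default 5) consecutive rounds of ``epochs_per_round`` (default 10)
epochs; at the start of each round the data is randomly re-partitioned into
80% training / 20% held-out, weights carry over across rounds, and held-out
accuracy is recorded per epoch.  No class rebalancing is applied: balancing
label proportions was found to worsen performance, and the F1 metric already
accounts for class imbalance.

Decision rule
-------------
A cell is assigned the state with the highest softmax likelihood if that
likelihood is at least the threshold (default 0.5, adjustable in [0, 1]);
otherwise it is labeled ``"Unknown"``.  Neural G0 / G1 / Late G1 can be
collapsed into a single ``"G0/G1"`` call for non-neuroepithelial cell types,
where misclassification is systematic among exactly those three states.
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import (
    InvalidParameterError,
    ModelFormatError,
    ShapeMismatchError,
    UnknownStateError,
)
from .preprocess import AlignedMatrix, FeatureSpace, IdMaps

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "Unknown"
COLLAPSED_LABEL = "G0/G1"
G0G1_STATES = ("Neural G0", "G1", "Late G1")

_ARCHIVE_FORMAT = "cyclestate-model"
_ARCHIVE_VERSION = 1

_PREDICT_CHUNK = 4096  # cells per forward-pass chunk, bounds peak memory


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier.

    ``hidden1 > hidden2 > n_classes`` is enforced (funnel shape).  Learning
    rate, momentum, and batch size are conventional defaults for a small dense
    network and are exposed for tuning.
    """

    n_features: int = 861
    hidden1: int = 600
    hidden2: int = 200
    n_classes: int = 7
    dropout_rate: float = 0.5
    epochs_per_round: int = 10
    rounds: int = 5
    holdout_fraction: float = 0.2
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise InvalidParameterError("n_classes must be >= 2")
        if not (self.hidden1 > self.hidden2 > self.n_classes):
            raise InvalidParameterError(
                "funnel shape required: hidden1 > hidden2 > n_classes"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise InvalidParameterError("dropout_rate must be in [0, 1)")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise InvalidParameterError("holdout_fraction must be in (0, 1)")
        for name in ("n_features", "epochs_per_round", "rounds", "batch_size"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")


@dataclass
class ClassifierModel:
    config: ModelConfig
    feature_space: FeatureSpace
    weights: dict
    training_history: list = field(default_factory=list)
    trained: bool = False

    def parameter_count(self) -> int:
        return int(sum(w.size for w in self.weights.values()))


@dataclass
class LikelihoodMatrix:
    """Cells x states softmax likelihoods; each row sums to 1."""

    values: np.ndarray
    state_names: tuple
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.state_names = tuple(self.state_names)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.cell_ids), len(self.state_names)):
            raise ShapeMismatchError("likelihood matrix shape mismatch")


@dataclass
class StateAssignment:
    """Per-cell label (state name or "Unknown") with its winning likelihood."""

    cell_ids: np.ndarray
    labels: np.ndarray
    max_likelihood: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        self.max_likelihood = np.asarray(self.max_likelihood, dtype=float)


# ---------------------------------------------------------------------------
# construction and forward pass
# ---------------------------------------------------------------------------

def _he_uniform(rng: np.random.Generator, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build_model(config: ModelConfig,
                feature_space: FeatureSpace | None = None) -> ClassifierModel:
    """Initialize an untrained model with He-style fan-in uniform weights."""
    if feature_space is None:
        feature_space = FeatureSpace(
            feature_ids=np.array([f"feature_{i}" for i in range(config.n_features)],
                                 dtype=object),
            state_names=tuple(f"class_{i}" for i in range(config.n_classes)),
        )
    if feature_space.n_features != config.n_features:
        raise InvalidParameterError(
            f"feature space has {feature_space.n_features} genes but config "
            f"declares n_features={config.n_features}"
        )
    if len(feature_space.state_names) != config.n_classes:
        raise InvalidParameterError(
            f"feature space has {len(feature_space.state_names)} states but "
            f"config declares n_classes={config.n_classes}"
        )
    rng = np.random.default_rng(config.seed)
    weights = {
        "W1": _he_uniform(rng, config.n_features, config.hidden1),
        "b1": np.zeros(config.hidden1),
        "W2": _he_uniform(rng, config.hidden1, config.hidden2),
        "b2": np.zeros(config.hidden2),
        "W3": _he_uniform(rng, config.hidden2, config.n_classes),
        "b3": np.zeros(config.n_classes),
    }
    return ClassifierModel(config=config, feature_space=feature_space,
                           weights=weights)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights: dict, X: np.ndarray) -> np.ndarray:
    h1 = np.maximum(X @ weights["W1"] + weights["b1"], 0.0)
    h2 = np.maximum(h1 @ weights["W2"] + weights["b2"], 0.0)
    return _softmax(h2 @ weights["W3"] + weights["b3"])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _encode_labels(labels, state_names) -> np.ndarray:
    index = {s: i for i, s in enumerate(state_names)}
    labels = np.asarray(labels, dtype=object)
    bad = sorted(set(labels) - set(state_names))
    if bad:
        raise UnknownStateError(f"labels outside the class vocabulary: {bad}")
    return np.array([index[l] for l in labels], dtype=np.intp)


def train(model: ClassifierModel, data: AlignedMatrix, labels) -> ClassifierModel:
    """Train the model in place; returns it for chaining.

    Deterministic under ``config.seed``: the same seed reproduces the same
    splits, shuffles, dropout masks, and hence the identical
    ``training_history`` and weights.
    """
    cfg = model.config
    X = np.asarray(data.values, dtype=float)
    if X.shape[1] != cfg.n_features:
        raise ShapeMismatchError(
            f"data has {X.shape[1]} features, model expects {cfg.n_features}"
        )
    y = _encode_labels(labels, model.feature_space.state_names)
    classes, counts = np.unique(y, return_counts=True)
    small = counts < 2
    if small.any():
        names = [model.feature_space.state_names[c]
                 for c in classes[small]]
        raise InvalidParameterError(
            f"fewer than 2 cells in class(es): {names}"
        )

    n = X.shape[0]
    rng = np.random.default_rng([cfg.seed, 1])
    W = model.weights
    vel = {k: np.zeros_like(v) for k, v in W.items()}
    lr, mom, p_drop = cfg.learning_rate, cfg.momentum, cfg.dropout_rate
    onehot = np.eye(cfg.n_classes)

    model.training_history = []
    for rnd in range(cfg.rounds):
        perm = rng.permutation(n)
        n_hold = max(1, int(round(cfg.holdout_fraction * n)))
        hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
        if train_idx.size == 0:
            raise InvalidParameterError("holdout_fraction leaves no training cells")
        X_hold, y_hold = X[hold_idx], y[hold_idx]
        for epoch in range(cfg.epochs_per_round):
            order = rng.permutation(train_idx)
            losses = []
            for start in range(0, order.size, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                B = xb.shape[0]
                # forward with inverted dropout
                z1 = xb @ W["W1"] + W["b1"]
                a1 = np.maximum(z1, 0.0)
                if p_drop > 0:
                    m1 = (rng.random(a1.shape) >= p_drop) / (1.0 - p_drop)
                    a1d = a1 * m1
                else:
                    a1d = a1
                z2 = a1d @ W["W2"] + W["b2"]
                a2 = np.maximum(z2, 0.0)
                if p_drop > 0:
                    m2 = (rng.random(a2.shape) >= p_drop) / (1.0 - p_drop)
                    a2d = a2 * m2
                else:
                    a2d = a2
                probs = _softmax(a2d @ W["W3"] + W["b3"])
                eps = 1e-12
                losses.append(float(-np.log(probs[np.arange(B), yb] + eps).mean()))
                # backward (categorical cross-entropy)
                dz3 = (probs - onehot[yb]) / B
                grads = {
                    "W3": a2d.T @ dz3,
                    "b3": dz3.sum(axis=0),
                }
                da2d = dz3 @ W["W3"].T
                da2 = da2d * m2 if p_drop > 0 else da2d
                dz2 = da2 * (z2 > 0)
                grads["W2"] = a1d.T @ dz2
                grads["b2"] = dz2.sum(axis=0)
                da1d = dz2 @ W["W2"].T
                da1 = da1d * m1 if p_drop > 0 else da1d
                dz1 = da1 * (z1 > 0)
                grads["W1"] = xb.T @ dz1
                grads["b1"] = dz1.sum(axis=0)
                for k in W:
                    vel[k] = mom * vel[k] - lr * grads[k]
                    W[k] += vel[k]
            hold_pred = _forward(W, X_hold).argmax(axis=1)
            acc = float((hold_pred == y_hold).mean())
            model.training_history.append({
                "round": rnd, "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "holdout_accuracy": acc,
            })
        logger.debug("round %d done, holdout accuracy %.3f", rnd, acc)
    model.trained = True
    return model


# ---------------------------------------------------------------------------
# prediction and decision rule
# ---------------------------------------------------------------------------

def predict_likelihoods(model: ClassifierModel,
                        data: AlignedMatrix) -> LikelihoodMatrix:
    """Forward pass with dropout disabled; rows sum to 1."""
    X = np.asarray(data.values, dtype=float)
    if X.shape[1] != model.config.n_features:
        raise ShapeMismatchError(
            f"data has {X.shape[1]} features, model expects "
            f"{model.config.n_features}"
        )
    out = np.empty((X.shape[0], model.config.n_classes))
    for start in range(0, X.shape[0], _PREDICT_CHUNK):
        out[start:start + _PREDICT_CHUNK] = _forward(
            model.weights, X[start:start + _PREDICT_CHUNK])
    return LikelihoodMatrix(values=out,
                            state_names=model.feature_space.state_names,
                            cell_ids=data.cell_ids)


def assign_states(lik: LikelihoodMatrix,
                  threshold: float = 0.5) -> StateAssignment:
    """Argmax with rejection: below-threshold winners become "Unknown".

    Ties are broken by the first state in ``state_names`` order (argmax's
    first-occurrence rule); a tie is logged when detected.
    """
    if not (0.0 <= threshold <= 1.0):
        raise InvalidParameterError("threshold must be in [0, 1]")
    V = lik.values
    winner = V.argmax(axis=1)
    max_lik = V[np.arange(V.shape[0]), winner]
    n_ties = int(((V == max_lik[:, None]).sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("%d cells had tied maximum likelihoods; first state in "
                    "canonical order used", n_ties)
    names = np.asarray(lik.state_names, dtype=object)
    labels = names[winner]
    labels[max_lik < threshold] = UNKNOWN_LABEL
    return StateAssignment(cell_ids=lik.cell_ids, labels=labels,
                           max_likelihood=max_lik, threshold_used=threshold)


def collapse_g0g1(assign: StateAssignment) -> StateAssignment:
    """Merge Neural G0 / G1 / Late G1 into "G0/G1"; idempotent."""
    labels = assign.labels.copy()
    for s in G0G1_STATES:
        labels[labels == s] = COLLAPSED_LABEL
    return StateAssignment(cell_ids=assign.cell_ids, labels=labels,
                           max_likelihood=assign.max_likelihood.copy(),
                           threshold_used=assign.threshold_used)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: ClassifierModel, path) -> None:
    """Write a single-file archive: JSON header + weight arrays (npz)."""
    header = {
        "format": _ARCHIVE_FORMAT,
        "version": _ARCHIVE_VERSION,
        "config": asdict(model.config),
        "state_names": list(model.feature_space.state_names),
        "feature_ids": [str(g) for g in model.feature_space.feature_ids],
        "marker_sets": {k: list(map(str, v))
                        for k, v in model.feature_space.marker_sets.items()},
        "id_type": model.feature_space.id_type,
        "id_maps": {
            "symbol_to_ensembl": model.feature_space.id_maps.symbol_to_ensembl,
            "mouse_to_human": model.feature_space.id_maps.mouse_to_human,
        },
        "trained": model.trained,
        "training_history": model.training_history,
    }
    with open(path, "wb") as fh:  # file handle: keep the exact path, no .npz suffix
        np.savez(fh, header=np.array(json.dumps(header)), **model.weights)


def load_model(path) -> ClassifierModel:
    """Load an archive written by :func:`save_model`; round-trips bit-for-bit."""
    try:
        with np.load(path, allow_pickle=False) as archive:
            if "header" not in archive:
                raise ModelFormatError(f"{path}: not a model archive")
            header = json.loads(str(archive["header"]))
            weights = {k: archive[k] for k in
                       ("W1", "b1", "W2", "b2", "W3", "b3")}
    except ModelFormatError:
        raise
    except (zipfile.BadZipFile, OSError, ValueError, KeyError,
            json.JSONDecodeError) as exc:
        raise ModelFormatError(f"{path}: unreadable model archive "
                               f"({exc})") from exc
    if header.get("format") != _ARCHIVE_FORMAT:
        raise ModelFormatError(f"{path}: unrecognized archive format")
    if header.get("version") != _ARCHIVE_VERSION:
        raise ModelFormatError(
            f"{path}: archive version {header.get('version')} not supported "
            f"(expected {_ARCHIVE_VERSION})"
        )
    config = ModelConfig(**header["config"])
    space = FeatureSpace(
        feature_ids=np.asarray(header["feature_ids"], dtype=object),
        state_names=tuple(header["state_names"]),
        marker_sets=header.get("marker_sets", {}),
        id_maps=IdMaps(**header.get("id_maps", {})),
        id_type=header.get("id_type", "symbol"),
    )
    return ClassifierModel(config=config, feature_space=space, weights=weights,
                           training_history=header.get("training_history", []),
                           trained=header.get("trained", False))
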