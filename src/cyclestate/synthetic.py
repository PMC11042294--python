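"""Labeled synthetic scRNA-seq count matrices with planted cell-cycle states.

The generator emulates the key features of a UMI count matrix that the rest of
the package exercises: a small set of transcriptional states, each marked by a
disjoint set of up-regulated marker genes; overdispersed negative-binomial
counts; and independent zero-inflation (dropout).  One state ("Neural G0")
plays the quiescent role with no proliferation markers beyond its own set, so
threshold/collapse logic is exercised realistically.

A single seed drives state assignment, counts, and dropout, in that fixed
order, so identical parameters reproduce bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio, sparse

from .errors import InvalidParameterError, UnknownStateError
from .preprocess import CountMatrix

#: Canonical seven-state cell-cycle vocabulary, ordered around the cycle.
DEFAULT_STATES = ("Neural G0", "G1", "Late G1", "S", "S/G2", "G2/M",
                  "M/Early G1")

#: The five actively cycling states used for cell-cycle signal regression.
CYCLING_STATES = ("Late G1", "S", "S/G2", "G2/M", "M/Early G1")


@dataclass(frozen=True)
class SyntheticParams:
    """Study conditions for the synthetic generator.

    Parameters
    ----------
    n_states, state_names, state_proportions
        Number of planted states, their labels, and their simplex weights
        (uniform when omitted).
    n_genes, markers_per_state
        Total genes and the size of each state's disjoint planted marker set.
    marker_log2fc
        Planted effect size: markers of a cell's state have negative-binomial
        mean ``baseline_mean * 2**marker_log2fc``; all other genes have mean
        ``baseline_mean``.
    dispersion
        Negative-binomial inverse-overdispersion theta
        (``var = mu + mu^2/theta``).
    dropout_rate
        Probability that an observed count is independently forced to zero.
    """

    n_states: int = 7
    state_names: tuple = DEFAULT_STATES
    state_proportions: tuple | None = None
    n_genes: int = 600
    markers_per_state: int = 15
    marker_log2fc: float = 2.0
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise InvalidParameterError("n_states must be >= 1")
        if len(self.state_names) != self.n_states:
            raise InvalidParameterError(
                f"{len(self.state_names)} state_names for n_states="
                f"{self.n_states}"
            )
        props = self.state_proportions
        if props is None:
            props = tuple(np.full(self.n_states, 1.0 / self.n_states))
        else:
            props = tuple(float(p) for p in props)
        object.__setattr__(self, "state_proportions", props)
        arr = np.asarray(props, dtype=float)
        if len(arr) != self.n_states:
            raise InvalidParameterError("state_proportions length mismatch")
        if abs(arr.sum() - 1.0) > 1e-12 or np.any(arr <= 0):
            raise InvalidParameterError(
                "state_proportions must be positive and sum to 1 within 1e-12"
            )
        if self.markers_per_state * self.n_states > self.n_genes:
            raise InvalidParameterError(
                "markers_per_state * n_states exceeds n_genes"
            )
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise InvalidParameterError("dropout_rate must be in [0, 1]")
        for name, val in (("marker_log2fc", self.marker_log2fc),
                          ("baseline_mean", self.baseline_mean),
                          ("dispersion", self.dispersion)):
            if val <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass
class LabeledDataset:
    """A generated count matrix with per-cell state labels and its truth."""

    counts: CountMatrix
    labels: np.ndarray
    truth: SyntheticParams

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.counts.n_cells:
            raise InvalidParameterError("one label per cell required")
        bad = set(self.labels) - set(self.truth.state_names)
        if bad:
            raise InvalidParameterError(f"labels outside state_names: {bad}")

    @property
    def marker_sets(self) -> dict:
        return planted_marker_sets(self.truth)


def gene_names(params: SyntheticParams) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(params.n_genes)], dtype=object)


def planted_marker_sets(params: SyntheticParams) -> dict:
    """Disjoint marker gene ids per state: state k owns genes [k*m, (k+1)*m)."""
    names = gene_names(params)
    m = params.markers_per_state
    return {s: list(names[k * m:(k + 1) * m])
            for k, s in enumerate(params.state_names)}


def state_mean_matrix(params: SyntheticParams) -> np.ndarray:
    """(n_genes, n_states) negative-binomial mean for each gene in each state."""
    mu = np.full((params.n_genes, params.n_states), params.baseline_mean)
    m = params.markers_per_state
    up = params.baseline_mean * 2.0 ** params.marker_log2fc
    for k in range(params.n_states):
        mu[k * m:(k + 1) * m, k] = up
    return mu


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               theta: float) -> np.ndarray:
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def generate_dataset(params: SyntheticParams, n_cells: int) -> LabeledDataset:
    """Draw a labeled genes x cells count matrix under ``params``.

    Cells are assigned states by a multinomial draw over
    ``state_proportions``; counts are negative-binomial with the planted state
    means; each observed count is then independently zeroed with probability
    ``dropout_rate``.
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(params.seed)
    state_idx = rng.choice(params.n_states, size=n_cells,
                           p=np.asarray(params.state_proportions))
    mu = state_mean_matrix(params)[:, state_idx]  # genes x cells
    counts = _nb_sample(rng, mu, params.dispersion)
    if params.dropout_rate > 0:
        keep = rng.random(counts.shape) >= params.dropout_rate
        counts = counts * keep
    labels = np.asarray(params.state_names, dtype=object)[state_idx]
    cells = np.array([f"cell_{i:05d}" for i in range(n_cells)], dtype=object)
    cm = CountMatrix(values=counts.astype(np.int64), gene_ids=gene_names(params),
                     cell_ids=cells, id_type="symbol", species="human")
    return LabeledDataset(counts=cm, labels=labels, truth=params)


def inject_ambiguity(dataset: LabeledDataset, fraction: float = 0.2,
                     seed: int = 0) -> tuple[LabeledDataset, np.ndarray]:
    """Blend a fraction of cells halfway toward another state's profile.

    The selected cells keep their original (true) labels but their counts are
    redrawn from a 50/50 mixture of their own state's mean profile and a
    randomly chosen other state's, then subjected to the same dropout.  Such
    cells are genuinely intermediate, so a trained classifier assigns them low
    winning likelihoods and mislabels them more often — the regime in which
    likelihood-threshold rejection pays off.

    Returns the modified dataset and a boolean mask of the blended cells.
    """
    if not (0.0 <= fraction <= 1.0):
        raise InvalidParameterError("fraction must be in [0, 1]")
    params = dataset.truth
    rng = np.random.default_rng(seed)
    n_cells = dataset.counts.n_cells
    n_blend = int(round(fraction * n_cells))
    chosen = rng.choice(n_cells, size=n_blend, replace=False)
    state_index = {s: k for k, s in enumerate(params.state_names)}
    mu_states = state_mean_matrix(params)

    counts = dataset.counts.values.copy()
    for c in chosen:
        own = state_index[dataset.labels[c]]
        other = rng.integers(params.n_states - 1)
        if other >= own:
            other += 1
        mu = 0.5 * (mu_states[:, own] + mu_states[:, other])
        col = _nb_sample(rng, mu, params.dispersion)
        if params.dropout_rate > 0:
            col = col * (rng.random(col.shape) >= params.dropout_rate)
        counts[:, c] = col
    mask = np.zeros(n_cells, dtype=bool)
    mask[chosen] = True
    cm = CountMatrix(values=counts, gene_ids=dataset.counts.gene_ids,
                     cell_ids=dataset.counts.cell_ids,
                     id_type=dataset.counts.id_type,
                     species=dataset.counts.species)
    return LabeledDataset(counts=cm, labels=dataset.labels.copy(),
                          truth=params), mask


def generate_bulk_signature(dataset: LabeledDataset, state: str,
                            n_replicates: int, seed: int = 0,
                            resample_fraction: float = 0.8,
                            noise_cv: float = 0.05) -> pd.DataFrame:
    """Emulate bulk RNA-seq replicates of one sorted state.

    Each replicate is the gene-wise mean of a bootstrap-resampled subset of
    that state's cells, multiplied by small lognormal gene-wise noise.
    Returns a genes x replicates DataFrame in the dataset's gene order.
    """
    if state not in dataset.truth.state_names:
        raise UnknownStateError(f"state {state!r} not in dataset vocabulary")
    cells = np.flatnonzero(dataset.labels == state)
    if cells.size == 0:
        raise UnknownStateError(f"state {state!r} has no cells in dataset")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_take = max(1, int(round(resample_fraction * cells.size)))
    cols = {}
    for r in range(n_replicates):
        take = rng.choice(cells, size=n_take, replace=True)
        mean = dataset.counts.values[:, take].mean(axis=1)
        noise = rng.lognormal(mean=0.0, sigma=noise_cv, size=mean.shape)
        cols[f"rep_{r + 1}"] = mean * noise
    return pd.DataFrame(cols, index=dataset.counts.gene_ids)


def write_dataset(dataset: LabeledDataset, directory) -> Path:
    """Write a 10x-style MTX triplet plus a (barcode, state) labels TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(dataset.counts.values)
    spio.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.DataFrame({
        0: dataset.counts.gene_ids,
        1: dataset.counts.gene_ids,
        2: "Gene Expression",
    }).to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({0: dataset.counts.cell_ids}).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": dataset.counts.cell_ids,
                  "state": dataset.labels}).to_csv(
        directory / "labels.tsv", sep="\t", index=False)
    return directory


def read_labels(path) -> pd.Series:
    """Read a (barcode, state) TSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"barcode", "state"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "state"],
                         dtype=str)
    return df.set_index("barcode")["state"]
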