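"""Marker discovery, gene-set overlap tests, and bulk-signature mapping.

Marker discovery is a one-vs-rest two-sided Wilcoxon rank-sum test per gene
per state with Benjamini-Hochberg correction across genes within each state —
the distribution-free default used throughout the single-cell field.  Bulk
quiescence (G0) signatures from sorted cells are mapped onto single cells by
Spearman correlation on a shared, filtered gene set; a cell is called
signature-positive only when it clears the cutoff in every bulk replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

#: Pseudo-count on de-logged normalized means in the fold-change ratio.
LOG2FC_EPS = 1e-9


def _delogged_means(norm: NormalizedMatrix) -> np.ndarray:
    """Per-entry expression on a nonnegative scale suitable for fold changes.

    Log-CPM values are exponentiated back (expm1); other scales (e.g. Pearson
    residuals, which may be negative) are used directly with negatives clipped
    at zero.
    """
    if norm.method == "log_cpm":
        return np.expm1(norm.values)
    return np.clip(norm.values, 0.0, None)


def find_state_markers(norm: NormalizedMatrix, labels,
                       logfc_min: float = 0.25,
                       padj_max: float = 0.05) -> pd.DataFrame:
    """One-vs-rest upregulated marker genes per state.

    Returns a table with one row per retained (gene, state) pair:
    ``gene, state, log2fc, p, p_adj, mean_in, mean_out``.  Genes constant
    across all cells are excluded outright.  Rows are retained when
    ``log2fc >= logfc_min`` and ``p_adj <= padj_max``.

    Raises
    ------
    InvalidParameterError
        If fewer than two states are present or any state has < 3 cells.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != norm.n_cells:
        raise InvalidParameterError("one label per cell required")
    states, counts = np.unique(labels, return_counts=True)
    if len(states) < 2:
        raise InvalidParameterError("at least 2 states required")
    too_small = states[counts < 3]
    if too_small.size:
        raise InvalidParameterError(
            f"state(s) with fewer than 3 cells: {list(too_small)}"
        )

    X = norm.values  # genes x cells (test scale)
    E = _delogged_means(norm)  # genes x cells (fold-change scale)
    variable = np.ptp(X, axis=1) > 0
    rows = []
    for state in states:
        in_mask = labels == state
        x_in = X[variable][:, in_mask].T     # cells_in x genes
        x_out = X[variable][:, ~in_mask].T
        res = stats.mannwhitneyu(x_in, x_out, axis=0,
                                 alternative="two-sided",
                                 method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        p = np.nan_to_num(p, nan=1.0)
        p_adj = multipletests(p, method="fdr_bh")[1]
        mean_in = E[variable][:, in_mask].mean(axis=1)
        mean_out = E[variable][:, ~in_mask].mean(axis=1)
        log2fc = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))
        keep = (log2fc >= logfc_min) & (p_adj <= padj_max)
        genes = norm.gene_ids[variable][keep]
        for g, lfc, pv, pa, mi, mo in zip(genes, log2fc[keep], p[keep],
                                          p_adj[keep], mean_in[keep],
                                          mean_out[keep]):
            rows.append((g, state, float(lfc), float(pv), float(pa),
                         float(mi), float(mo)))
    return pd.DataFrame(rows, columns=["gene", "state", "log2fc", "p",
                                       "p_adj", "mean_in", "mean_out"])


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two gene sets in a common universe."""

    n_overlap: int
    universe_size: int
    set_sizes: tuple
    p_value: float


def hypergeometric_overlap(set_a, set_b, universe) -> OverlapResult:
    """Upper-tail hypergeometric enrichment of ``set_a`` overlap ``set_b``.

    ``p = P(X >= n_overlap)`` where ``X ~ Hypergeom(|universe|, |set_a|,
    |set_b|)``.  Elements outside the universe raise, listing the offenders.
    """
    universe = set(universe)
    if not universe:
        raise InvalidParameterError("universe must be non-empty")
    a, b = set(set_a), set(set_b)
    offenders = sorted((a | b) - universe)
    if offenders:
        raise InvalidParameterError(
            f"elements outside the universe: {offenders}"
        )
    k = len(a & b)
    M, nA, nB = len(universe), len(a), len(b)
    p = float(stats.hypergeom.sf(k - 1, M, nA, nB))
    return OverlapResult(n_overlap=k, universe_size=M, set_sizes=(nA, nB),
                         p_value=min(p, 1.0))


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=1)


def select_signature_genes(norm: NormalizedMatrix, signature: pd.DataFrame,
                           hvg_top: int = 2000, bulk_min_count: float = 10.0,
                           extra_genes=None) -> np.ndarray:
    """Shared gene filter for bulk-signature correlation.

    Highly variable single-cell genes (top ``hvg_top`` by variance-to-mean
    ranking on the normalized data) that exceed ``bulk_min_count`` in every
    bulk replicate, unioned with any ``extra_genes`` (e.g. the classifier
    input genes) present in the bulk profile.
    """
    mean = norm.values.mean(axis=1)
    var = norm.values.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(dispersion)[::-1]
    hvg = set(norm.gene_ids[order[:hvg_top]])
    bulk_ok = set(signature.index[(signature.values >
                                   bulk_min_count).all(axis=1)])
    chosen = (hvg & bulk_ok)
    if extra_genes is not None:
        chosen |= set(extra_genes) & set(signature.index)
    chosen &= set(norm.gene_ids)
    return np.asarray([g for g in norm.gene_ids if g in chosen], dtype=object)


def correlate_signature(norm: NormalizedMatrix, signature: pd.DataFrame,
                        gene_filter=None) -> pd.DataFrame:
    """Spearman correlation of each cell against each bulk replicate.

    ``signature`` is a genes x replicates frame.  ``gene_filter`` restricts
    the comparison; when omitted it defaults to
    :func:`select_signature_genes`.  Requires at least 10 shared genes.
    Returns a cells x replicates frame of correlations.
    """
    if signature.shape[1] < 1:
        raise InvalidParameterError("at least one bulk replicate required")
    if gene_filter is None:
        gene_filter = select_signature_genes(norm, signature)
    shared = [g for g in gene_filter
              if g in set(norm.gene_ids) and g in set(signature.index)]
    if len(shared) < 10:
        raise InvalidParameterError(
            f"only {len(shared)} shared genes after filtering (>= 10 required)"
        )
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    idx = [gene_pos[g] for g in shared]
    cells = norm.values[idx, :].T                     # cells x shared
    bulk = signature.loc[shared].to_numpy(dtype=float)  # shared x reps

    cell_ranks = _rank_rows(cells)
    bulk_ranks = _rank_rows(bulk.T)                   # reps x shared
    cr = cell_ranks - cell_ranks.mean(axis=1, keepdims=True)
    br = bulk_ranks - bulk_ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((cr ** 2).sum(axis=1))[:, None] * \
        np.sqrt((br ** 2).sum(axis=1))[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (cr @ br.T) / denom
    return pd.DataFrame(corr, index=norm.cell_ids, columns=signature.columns)


def call_signature_positive(correlations: pd.DataFrame,
                            cutoff: float = 0.1) -> pd.Series:
    """A cell is signature-positive iff correlation >= cutoff in ALL replicates."""
    if correlations.shape[1] < 1:
        raise InvalidParameterError("at least one replicate required")
    return (correlations >= cutoff).all(axis=1)
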