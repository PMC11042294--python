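"""Removing cell-cycle transcriptional signal from expression matrices.

The procedure mirrors the standard module-score workflow: (1) per-cell module
scores for each cell-cycle state's marker set — mean expression of the set
minus the mean of expression-matched control genes drawn from average-
expression bins; (2) per-gene ordinary least-squares residualization on the
chosen scores; (3) success is judged by the variance explained by the first
principal component of the marker genes, compared against randomly sampled
gene sets of the same size (an empirical p-value).  Removal is declared
successful when the empirical p-value becomes non-significant (> 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class RegressionReport:
    """Before/after PC1 variance-explained and empirical p-values."""

    variance_explained_before: float
    variance_explained_after: float
    empirical_p_before: float
    empirical_p_after: float
    n_random: int


def module_score(norm: NormalizedMatrix, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> np.ndarray:
    """Per-cell module score for one gene set.

    Genes are binned into ``n_bins`` bins by average expression; for each set
    gene, ``n_ctrl`` control genes are drawn (seeded, set genes excluded) from
    its bin.  The score is ``mean(set genes) - mean(control draws)`` per cell.
    The defaults (24 bins, 100 controls per gene) are the published defaults
    of the standard module-score method.
    """
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    idx = [gene_pos[g] for g in gene_set if g in gene_pos]
    if not idx:
        raise InvalidParameterError("gene_set entirely absent from matrix")
    if n_bins < 1 or n_ctrl < 1:
        raise InvalidParameterError("n_bins and n_ctrl must be >= 1")

    X = norm.values
    data_avg = X.mean(axis=1)
    # equal-occupancy bins on the rank of average expression
    order = np.argsort(data_avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    bins = (ranks * n_bins) // len(order)

    rng = np.random.default_rng(seed)
    set_mask = np.zeros(norm.n_genes, dtype=bool)
    set_mask[idx] = True
    ctrl_idx = []
    for g in idx:
        pool = np.flatnonzero((bins == bins[g]) & ~set_mask)
        if pool.size == 0:
            pool = np.flatnonzero(~set_mask)
        if pool.size == 0:
            raise InvalidParameterError("no control genes available")
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)
    return X[idx].mean(axis=0) - X[ctrl_idx].mean(axis=0)


def module_scores(norm: NormalizedMatrix, marker_sets: dict, states,
                  n_bins: int = 24, n_ctrl: int = 100,
                  seed: int = 0) -> pd.DataFrame:
    """Cells x states frame of module scores for the requested states."""
    cols = {}
    for k, state in enumerate(states):
        if state not in marker_sets:
            raise InvalidParameterError(f"no marker set for state {state!r}")
        cols[state] = module_score(norm, marker_sets[state], n_bins=n_bins,
                                   n_ctrl=n_ctrl, seed=seed + k)
    return pd.DataFrame(cols, index=norm.cell_ids)


def regress_out(norm: NormalizedMatrix,
                covariates: pd.DataFrame) -> NormalizedMatrix:
    """Per-gene OLS residuals on the covariate scores (with intercept).

    Identically-zero covariate columns are dropped (logged) so that an
    all-zero covariate set reduces to mean-centering; genuinely collinear
    covariates raise with a suggestion to drop one.
    """
    C = covariates.to_numpy(dtype=float)
    if C.shape[0] != norm.n_cells:
        raise InvalidParameterError("covariate rows must match cells")
    nonzero = ~(C == 0).all(axis=0)
    if not nonzero.all():
        dropped = list(covariates.columns[~nonzero])
        logger.info("dropping identically-zero covariate column(s): %s",
                    dropped)
        C = C[:, nonzero]
    design = np.column_stack([np.ones(norm.n_cells), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InvalidParameterError(
            "rank-deficient covariates; consider dropping a collinear score"
        )
    Y = norm.values.T  # cells x genes
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    return NormalizedMatrix(values=resid.T, gene_ids=norm.gene_ids,
                            cell_ids=norm.cell_ids,
                            method=norm.method + "+regressed")


def pc1_variance_explained(norm: NormalizedMatrix, gene_set) -> float:
    """Fraction of variance on PC1 of the mean-centered cells x set submatrix.

    A high value means the set's genes co-vary along one axis — the signature
    of a coordinated transcriptional program such as the cell cycle.
    """
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    idx = [gene_pos[g] for g in gene_set if g in gene_pos]
    if len(idx) < 2:
        raise InvalidParameterError(">= 2 set genes must be present")
    if norm.n_cells < 3:
        raise InvalidParameterError(">= 3 cells required")
    sub = norm.values[idx].T  # cells x set genes
    sub = sub - sub.mean(axis=0)
    total = (sub ** 2).sum()
    if total == 0:
        raise InvalidParameterError("constant submatrix: no variance")
    cov = sub.T @ sub
    eigvals = np.linalg.eigvalsh(cov)
    return float(eigvals[-1] / eigvals.sum())


def empirical_variance_test(norm: NormalizedMatrix, gene_set,
                            n_random: int = 1000, seed: int = 0) -> float:
    """Empirical p for the observed PC1 variance-explained.

    ``p = (1 + #{random same-size sets with variance >= observed}) /
    (1 + n_random)``, random sets drawn uniformly without replacement from
    all genes present in the matrix.  The +1 convention prevents p = 0.
    """
    if n_random < 1:
        raise InvalidParameterError("n_random must be >= 1")
    present = [g for g in gene_set if g in set(norm.gene_ids)]
    size = len(present)
    if norm.n_genes < 2 * size:
        raise InvalidParameterError("gene universe smaller than 2x set size")
    observed = pc1_variance_explained(norm, present)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_random):
        rand = rng.choice(norm.gene_ids, size=size, replace=False)
        if pc1_variance_explained(norm, rand) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_random)


def remove_cycle_signal(norm: NormalizedMatrix, marker_sets: dict, states,
                        n_random: int = 1000, seed: int = 0,
                        n_bins: int = 24, n_ctrl: int = 100,
                        ) -> tuple[NormalizedMatrix, RegressionReport]:
    """End-to-end removal: scores -> regression -> before/after report.

    The tested gene set is the union of the chosen states' marker sets.
    """
    scores = module_scores(norm, marker_sets, states, n_bins=n_bins,
                           n_ctrl=n_ctrl, seed=seed)
    union = sorted({g for s in states for g in marker_sets[s]})
    before_ve = pc1_variance_explained(norm, union)
    before_p = empirical_variance_test(norm, union, n_random=n_random,
                                       seed=seed + 1)
    resid = regress_out(norm, scores)
    after_ve = pc1_variance_explained(resid, union)
    after_p = empirical_variance_test(resid, union, n_random=n_random,
                                      seed=seed + 2)
    report = RegressionReport(
        variance_explained_before=before_ve,
        variance_explained_after=after_ve,
        empirical_p_before=before_p,
        empirical_p_after=after_p,
        n_random=n_random,
    )
    return resid, report
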