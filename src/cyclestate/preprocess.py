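"""Reading, normalizing, and aligning expression matrices.

Conventions
-----------
Matrices are stored **genes x cells** on disk and in :class:`CountMatrix` /
:class:`NormalizedMatrix` (the MatrixMarket convention for 10x triplets), and
**cells x features** after alignment to a classifier feature space
(:class:`AlignedMatrix`), which is the orientation the classifier consumes.

Two normalizations are provided:

``log_cpm``
    ``log(1 + 10,000 * count / cell_total)`` — depth normalization to counts
    per 10k followed by a natural-log transform.

``pearson_residual``
    Analytic Pearson residuals under an offset negative-binomial model:
    the expected count for gene *g* in cell *c* is
    ``mu_gc = (gene_total_g * cell_total_c) / grand_total`` and the residual
    is ``(x - mu) / sqrt(mu + mu^2 / theta)`` with a single, strongly
    regularized dispersion ``theta`` (default 100), clipped to
    ``+/- sqrt(n_cells)``.  This standardizes datasets to a common
    variance-stabilized scale regardless of sequencing depth.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio

from .errors import (
    AlignmentError,
    FormatError,
    InvalidParameterError,
    NormalizationError,
)

logger = logging.getLogger(__name__)

VALID_SPECIES = ("human", "mouse")
VALID_ID_TYPES = ("ensembl", "symbol")
NORMALIZATION_METHODS = ("pearson_residual", "log_cpm")

#: Warn when more than this fraction of classifier genes is absent from the
#: input; beyond ~20% missing genes the error rate degrades substantially.
DEFAULT_MISSING_WARN_FRACTION = 0.2


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw gene-by-cell nonnegative counts with identifiers.

    Parameters
    ----------
    values
        ``(n_genes, n_cells)`` nonnegative matrix.
    gene_ids, cell_ids
        Ordered, unique identifier arrays matching ``values``.
    id_type
        ``"ensembl"`` or ``"symbol"``.
    species
        ``"human"`` or ``"mouse"``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    id_type: str = "symbol"
    species: str = "human"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("count matrix must be two-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers after loading")
        if self.id_type not in VALID_ID_TYPES:
            raise InvalidParameterError(f"unknown id_type {self.id_type!r}")
        if self.species not in VALID_SPECIES:
            raise InvalidParameterError(f"unknown species {self.species!r}")
        if np.any(np.asarray(self.values) < 0):
            raise FormatError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizedMatrix:
    """Genes x cells normalized expression with provenance tag."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError("normalized matrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_index) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_index)
        return NormalizedMatrix(
            self.values[:, idx], self.gene_ids, self.cell_ids[idx], self.method
        )


@dataclass
class IdMaps:
    """Gene identifier translation tables.

    ``symbol_to_ensembl`` maps human symbols to Ensembl gene IDs (inverted on
    demand); ``mouse_to_human`` maps mouse gene IDs to their one-to-one human
    ortholog in the same ID system.  Genes with ambiguous orthology should be
    omitted from the table; unmapped genes are dropped (with a logged count)
    rather than guessed, since silent mis-mapping is worse than a missing gene.
    """

    symbol_to_ensembl: dict = field(default_factory=dict)
    mouse_to_human: dict = field(default_factory=dict)

    @property
    def ensembl_to_symbol(self) -> dict:
        return {v: k for k, v in self.symbol_to_ensembl.items()}

    @classmethod
    def from_tsv(cls, symbol_map_path=None, ortholog_map_path=None) -> "IdMaps":
        """Load two-column TSVs (no header): source id, target id."""
        def _load(path):
            df = pd.read_csv(path, sep="\t", header=None, dtype=str)
            if df.shape[1] < 2:
                raise FormatError(f"{path}: expected two columns")
            return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))

        return cls(
            symbol_to_ensembl=_load(symbol_map_path) if symbol_map_path else {},
            mouse_to_human=_load(ortholog_map_path) if ortholog_map_path else {},
        )


@dataclass
class FeatureSpace:
    """The classifier's input gene list, class vocabulary, and marker sets."""

    feature_ids: np.ndarray
    state_names: tuple
    marker_sets: dict = field(default_factory=dict)
    id_maps: IdMaps = field(default_factory=IdMaps)
    id_type: str = "symbol"

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.state_names = tuple(self.state_names)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise InvalidParameterError("feature_ids contains duplicates")
        if self.id_type not in VALID_ID_TYPES:
            raise InvalidParameterError(f"unknown id_type {self.id_type!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @classmethod
    def from_marker_table(cls, marker_table: pd.DataFrame, state_names,
                          id_maps: IdMaps | None = None,
                          id_type: str = "symbol") -> "FeatureSpace":
        """Build a feature space from a marker table (see ``markers``).

        The classifier input genes are the union of per-state upregulated
        markers, in first-appearance order — mirroring how the canonical
        861-gene input list was derived from state markers.
        """
        feature_ids = list(dict.fromkeys(marker_table["gene"]))
        marker_sets = {
            s: list(g["gene"]) for s, g in marker_table.groupby("state", sort=False)
        }
        return cls(feature_ids=np.asarray(feature_ids, dtype=object),
                   state_names=tuple(state_names), marker_sets=marker_sets,
                   id_maps=id_maps or IdMaps(), id_type=id_type)


@dataclass
class AlignedMatrix:
    """Cells x features matrix in exact feature-space column order."""

    values: np.ndarray
    feature_ids: np.ndarray
    cell_ids: np.ndarray
    missing_fraction: float
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise FormatError("aligned matrix shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def as_normalized(self) -> NormalizedMatrix:
        """Re-express as a genes x cells :class:`NormalizedMatrix`."""
        return NormalizedMatrix(self.values.T, self.feature_ids, self.cell_ids,
                                self.provenance)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _find_member(directory: Path, stem_options) -> Path:
    for stem in stem_options:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FormatError(
        f"{directory}: none of {list(stem_options)} found (plain or .gz)"
    )


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rb")
    return open(path, "rb")


def _collapse_duplicate_genes(values: np.ndarray, gene_ids: np.ndarray):
    """Sum rows sharing a gene id; preserves counts for collapsed annotations."""
    ids = np.asarray(gene_ids, dtype=object)
    uniq, inverse = np.unique(ids, return_inverse=True)
    if len(uniq) == len(ids):
        return values, ids
    n_dup = len(ids) - len(uniq)
    logger.warning("summed %d duplicated gene id rows", n_dup)
    out = np.zeros((len(uniq), values.shape[1]), dtype=float)
    np.add.at(out, inverse, values)
    # keep first-appearance order rather than np.unique's sorted order
    first_pos = np.full(len(uniq), values.shape[0], dtype=int)
    np.minimum.at(first_pos, inverse, np.arange(len(ids)))
    order = np.argsort(first_pos, kind="stable")
    return out[order], uniq[order]


def read_matrix(path, format: str | None = None, id_type: str = "symbol",
                species: str = "human") -> CountMatrix:
    """Read a 10x-style MTX triplet directory or a delimited text matrix.

    Parameters
    ----------
    path
        A directory containing ``matrix.mtx[.gz]``, ``features.tsv[.gz]`` (or
        ``genes.tsv``), and ``barcodes.tsv[.gz]``; or a CSV/TSV file with gene
        rows, a header row of cell barcodes, and gene ids in the first column.
    format
        ``"mtx_dir"``, ``"csv"``, or ``"tsv"``; inferred from ``path`` when
        omitted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file or directory")
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix.lower() == ".csv" or str(path).endswith(".csv.gz"):
            format = "csv"
        else:
            format = "tsv"

    if format == "mtx_dir":
        mtx_path = _find_member(path, ("matrix.mtx",))
        feat_path = _find_member(path, ("features.tsv", "genes.tsv"))
        bc_path = _find_member(path, ("barcodes.tsv",))
        try:
            with _open_maybe_gz(mtx_path) as fh:
                mat = spio.mmread(fh)
        except ValueError as exc:
            raise FormatError(f"{mtx_path}: {exc}") from exc
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat,
                            dtype=float)
        try:
            feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{feat_path}: empty features file") from exc
        try:
            barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{bc_path}: empty barcodes file") from exc
        # 10x features files carry Ensembl ids in column 0, symbols in column 1
        col = 1 if (id_type == "symbol" and feats.shape[1] > 1) else 0
        gene_ids = feats.iloc[:, col].to_numpy(dtype=object)
        cell_ids = barcodes.iloc[:, 0].to_numpy(dtype=object)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise FormatError(
                f"{mtx_path}: matrix is {values.shape} but id files declare "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.empty or df.shape[1] == 0:
            raise FormatError(f"{path}: no cells found")
        values = df.to_numpy(dtype=float)
        gene_ids = df.index.to_numpy(dtype=object)
        cell_ids = df.columns.to_numpy(dtype=object)
    else:
        raise InvalidParameterError(f"unknown format {format!r}")

    values, gene_ids = _collapse_duplicate_genes(values, gene_ids)
    return CountMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids,
                       id_type=id_type, species=species)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(counts: CountMatrix, method: str = "pearson_residual",
              theta: float = 100.0) -> NormalizedMatrix:
    """Normalize a count matrix (see module docstring for the two contracts).

    Raises
    ------
    NormalizationError
        If any cell has zero total counts (names the first such barcode).
    """
    if method not in NORMALIZATION_METHODS:
        raise InvalidParameterError(f"unknown normalization method {method!r}")
    X = np.asarray(counts.values, dtype=float)
    cell_totals = X.sum(axis=0)
    zero = np.flatnonzero(cell_totals == 0)
    if zero.size:
        raise NormalizationError(
            f"cell {counts.cell_ids[zero[0]]!r} has zero total counts "
            f"({zero.size} such cells)"
        )

    if method == "log_cpm":
        out = np.log1p(1e4 * X / cell_totals)
    else:  # pearson_residual
        if theta <= 0:
            raise InvalidParameterError("theta must be positive")
        gene_totals = X.sum(axis=1)
        grand = cell_totals.sum()
        mu = np.outer(gene_totals, cell_totals) / grand
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (X - mu) / np.sqrt(mu + mu * mu / theta)
        out[gene_totals == 0, :] = 0.0  # all-zero genes map to all-zero rows
        clip = np.sqrt(counts.n_cells)
        np.clip(out, -clip, clip, out=out)

    return NormalizedMatrix(values=out, gene_ids=counts.gene_ids,
                            cell_ids=counts.cell_ids, method=method)


# ---------------------------------------------------------------------------
# feature alignment
# ---------------------------------------------------------------------------

def _translate_ids(gene_ids: np.ndarray, values: np.ndarray, species: str,
                   id_type: str, space: FeatureSpace):
    """Map input gene ids into the feature space's id system.

    Unmapped genes are dropped with a logged count; duplicates created by the
    mapping are summed.
    """
    if species not in VALID_SPECIES:
        raise InvalidParameterError(f"unknown species {species!r}")
    if id_type not in VALID_ID_TYPES:
        raise InvalidParameterError(f"unknown id_type {id_type!r}")

    ids = np.asarray(gene_ids, dtype=object)
    if species == "mouse":
        table = space.id_maps.mouse_to_human
        if not table:
            raise InvalidParameterError(
                "species='mouse' requires a mouse->human ortholog table in "
                "FeatureSpace.id_maps"
            )
        keep = np.array([g in table for g in ids], dtype=bool)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d genes without a one-to-one human ortholog",
                        dropped)
        ids = np.array([table[g] for g in ids[keep]], dtype=object)
        values = values[keep]

    if id_type != space.id_type:
        table = (space.id_maps.symbol_to_ensembl if space.id_type == "ensembl"
                 else space.id_maps.ensembl_to_symbol)
        if not table:
            raise InvalidParameterError(
                f"translating {id_type} -> {space.id_type} requires a "
                "symbol/Ensembl lookup in FeatureSpace.id_maps"
            )
        keep = np.array([g in table for g in ids], dtype=bool)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d genes absent from the id lookup", dropped)
        ids = np.array([table[g] for g in ids[keep]], dtype=object)
        values = values[keep]

    return _collapse_duplicate_genes(values, ids)


def align_features(expr: NormalizedMatrix, space: FeatureSpace,
                   species: str = "human", id_type: str | None = None,
                   missing_warn_fraction: float = DEFAULT_MISSING_WARN_FRACTION,
                   ) -> AlignedMatrix:
    """Project a normalized genes x cells matrix onto the classifier genes.

    Gene ids are translated into the feature space's id system (mouse genes
    through the ortholog table, symbol<->Ensembl through the lookup), columns
    are reordered to exactly ``space.feature_ids``, classifier genes absent
    from the input are zero-filled, and the zero-filled share is reported as
    ``missing_fraction``.  A warning is emitted above ``missing_warn_fraction``
    because classification error grows quickly once ~20% of classifier genes
    are missing.

    Raises
    ------
    AlignmentError
        If no classifier gene is present in the input at all.
    """
    if id_type is None:
        id_type = space.id_type
    values, ids = _translate_ids(expr.gene_ids, expr.values, species, id_type,
                                 space)
    index = {g: i for i, g in enumerate(ids)}
    n_feat = space.n_features
    out = np.zeros((expr.n_cells, n_feat), dtype=float)
    present = 0
    for j, g in enumerate(space.feature_ids):
        i = index.get(g)
        if i is not None:
            out[:, j] = values[i]
            present += 1
    missing_fraction = 1.0 - present / n_feat
    if present == 0:
        raise AlignmentError("no overlap between input genes and the "
                             "classifier feature space")
    if missing_fraction > missing_warn_fraction:
        logger.warning(
            "%.1f%% of classifier genes missing from input (warn threshold "
            "%.0f%%); expect degraded accuracy", 100 * missing_fraction,
            100 * missing_warn_fraction,
        )
    return AlignedMatrix(values=out, feature_ids=space.feature_ids.copy(),
                         cell_ids=expr.cell_ids, missing_fraction=missing_fraction,
                         provenance=expr.method)
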