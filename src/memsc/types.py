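"""Core in-memory containers shared by every pipeline stage.

The substrate of the whole pipeline is a sparse gene x cell expression
matrix plus a per-cell annotation table.  Both are deliberately thin
wrappers over :mod:`scipy.sparse` and :class:`pandas.DataFrame` so every
stage can use the usual numerical tooling directly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("memsc")

RAW = "raw"
NORMALIZED = "normalized"

CONDITIONS = ("normal", "inflamed")


class ValidationError(ValueError):
    """Raised when a container violates its structural contract."""


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared format."""


@dataclass
class ExpressionMatrix:
    """Gene x cell expression values with a layer tag.

    Parameters
    ----------
    gene_ids, cell_ids
        Ordered, unique string identifiers for rows and columns.
    values
        ``(n_genes, n_cells)`` sparse matrix, non-negative; integral when
        ``layer == "raw"``.
    layer
        Either ``"raw"`` (UMI counts) or ``"normalized"``
        (log1p of total-count scaled expression).
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    values: sp.csr_matrix
    layer: str = RAW

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        if self.layer not in (RAW, NORMALIZED):
            raise ValidationError(f"unknown layer {self.layer!r}")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"id/value shape mismatch: {len(self.gene_ids)} genes, "
                f"{len(self.cell_ids)} cells vs values {self.values.shape}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene_ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell_ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("negative expression values")
        if self.layer == RAW and self.values.nnz:
            if not np.allclose(self.values.data, np.round(self.values.data)):
                raise ValidationError("raw layer requires integer counts")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            self.gene_ids, self.cell_ids[idx], self.values[:, idx], self.layer
        )

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            self.gene_ids[idx], self.cell_ids, self.values[idx, :], self.layer
        )

    # -- summaries -------------------------------------------------------
    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def gene_means(self) -> np.ndarray:
        return np.asarray(self.values.mean(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


# Canonical per-cell annotation columns.  A CellTable is an ordinary
# pandas DataFrame indexed by cell_id; this listing documents the schema.
CELL_TABLE_COLUMNS = [
    "sample_id",
    "condition",
    "n_features",
    "total_counts",
    "mito_fraction",
    "cluster",
    "doublet",
    "truth_type",
    "truth_dual",
]


def new_cell_table(cell_ids, **columns) -> pd.DataFrame:
    """Build a cell table indexed by ``cell_id`` with the given columns."""
    table = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    for name, values in columns.items():
        table[name] = values
    return table


def check_cell_table(table: pd.DataFrame, matrix: ExpressionMatrix) -> None:
    """Check that a cell table annotates exactly the cells of ``matrix``."""
    if not np.array_equal(table.index.to_numpy(dtype=object), matrix.cell_ids):
        raise ValidationError("cell table index does not match matrix cell_ids")
    if "mito_fraction" in table:
        mf = table["mito_fraction"].to_numpy(float)
        if np.any((mf < 0) | (mf > 1)):
            raise ValidationError("mito_fraction outside [0, 1]")
    if "n_features" in table:
        if table["n_features"].max() > matrix.n_genes:
            raise ValidationError("n_features exceeds gene count")


@dataclass
class GeneSignature:
    """A named target gene set (the Gt of a cell score)."""

    name: str
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        # preserve order, drop duplicates
        seen: dict = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)
        if not self.genes:
            raise ValidationError(f"gene signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def as_dict(obj) -> dict:
    """Recursively convert a dataclass (tree) to plain dicts/lists."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: as_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: as_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [as_dict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
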