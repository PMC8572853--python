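"""Readers and writers for the pipeline's on-disk formats.

Formats are the community-standard plain-text ones: Matrix Market MTX
with sidecar ``features.tsv``/``barcodes.tsv`` for expression matrices
(genes as rows, cells as columns), GMT for gene sets, and CSV for every
tabular output.  Each CSV written here starts with a comment line
recording the RNG seed and configuration hash so stochastic stages can
be replayed.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import NORMALIZED, RAW, ExpressionMatrix, FormatError, GeneSignature

logger = logging.getLogger("memsc")

_GENE_SYMBOL_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9._\-]*$")


# ---------------------------------------------------------------------------
# Matrix Market trio
# ---------------------------------------------------------------------------

def _read_id_file(path) -> np.ndarray:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return np.asarray(ids, dtype=object)


def read_matrix(mtx_path, features_path, barcodes_path, layer: str = RAW) -> ExpressionMatrix:
    """Read a genes x cells Matrix Market file with its id sidecars."""
    try:
        values = scipy.io.mmread(str(mtx_path))
    except ValueError as exc:
        raise FormatError(f"invalid Matrix Market file {mtx_path}: {exc}") from exc
    values = sp.csr_matrix(values)
    genes = _read_id_file(features_path)
    cells = _read_id_file(barcodes_path)
    if values.shape[0] != len(genes):
        raise FormatError(
            f"{features_path}: {len(genes)} features but matrix declares "
            f"{values.shape[0]} rows"
        )
    if values.shape[1] != len(cells):
        raise FormatError(
            f"{barcodes_path}: {len(cells)} barcodes but matrix declares "
            f"{values.shape[1]} columns"
        )
    return ExpressionMatrix(genes, cells, values, layer)


def write_matrix(matrix: ExpressionMatrix, out_dir) -> dict:
    """Write the MTX trio into ``out_dir``; returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    coo = matrix.values.tocoo()
    if matrix.layer == RAW:
        coo = coo.astype(np.int64)
        scipy.io.mmwrite(str(paths["mtx"]), coo, field="integer")
    else:
        scipy.io.mmwrite(str(paths["mtx"]), coo, precision=12)
    paths["features"].write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in matrix.cell_ids))
    return paths


def read_matrix_dir(dir_path, layer: str = RAW) -> ExpressionMatrix:
    dir_path = Path(dir_path)
    return read_matrix(
        dir_path / "matrix.mtx",
        dir_path / "features.tsv",
        dir_path / "barcodes.tsv",
        layer=layer,
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT dialect)
# ---------------------------------------------------------------------------

def _looks_like_description(token: str) -> bool:
    # GMT's second column is free text (URLs, sentences, "na"); gene
    # symbols never contain spaces, colons or slashes.
    if token == "" or token.lower() in {"na", "none", "-"}:
        return True
    return _GENE_SYMBOL_RE.match(token) is None


def read_gene_sets(path) -> list:
    """Read gene signatures from a GMT-dialect file.

    Each tab-separated record is ``name [description] gene...``; the
    description column is detected by content (empty / free text) so both
    strict GMT files and bare ``name<TAB>gene...`` records parse.
    Duplicate genes within a record are dropped, order preserved.
    """
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            name, rest = fields[0], fields[1:]
            if rest and _looks_like_description(rest[0]):
                rest = rest[1:]
            rest = [g for g in rest if g]
            if not rest:
                raise FormatError(
                    f"{path}:{lineno}: gene set {name!r} has no genes"
                )
            signatures.append(GeneSignature(name, rest))
    if not signatures:
        logger.warning("gene-set file %s contains no records", path)
    return signatures


def write_gene_sets(signatures, path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, ""] + list(sig.genes)) + "\n")


# ---------------------------------------------------------------------------
# Provenance-stamped CSV tables
# ---------------------------------------------------------------------------

def provenance_header(seed, config_hash) -> str:
    return f"# seed={seed} config_hash={config_hash}\n"


def write_table(table: pd.DataFrame, path, seed="NA", config_hash="NA",
                index: bool = True) -> None:
    """Write a DataFrame as CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config_hash))
        table.to_csv(fh, index=index, lineterminator="\n")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def write_cell_table(table: pd.DataFrame, path, seed="NA", config_hash="NA") -> None:
    write_table(table, path, seed=seed, config_hash=config_hash)


def read_cell_table(path) -> pd.DataFrame:
    table = read_table(path, index_col=0)
    table.index.name = "cell_id"
    return table


def write_scores(score_table: pd.DataFrame, path, seed="NA", config_hash="NA") -> None:
    write_table(score_table, path, seed=seed, config_hash=config_hash)


def read_scores(path) -> pd.DataFrame:
    return read_table(path, index_col=0)


# ---------------------------------------------------------------------------
# Ligand-receptor pair tables
# ---------------------------------------------------------------------------

def read_lr_pairs(path=None) -> pd.DataFrame:
    """Read a ligand-receptor pair table (columns ``ligand,receptor``).

    Without a path, the small pair table shipped with the package is
    used; it holds the interactions highlighted in the middle-ear study
    (Csf1-Csf1r, Il34-Csf1r, Ccl3-Ccr5, Cxcl1-Cxcr2, Il1b-Il1r2,
    Igf1-Igf1r) plus synthetic pairs for testing.
    """
    if path is None:
        from importlib.resources import files

        path = files("memsc.data") / "lr_pairs.csv"
    pairs = pd.read_csv(path, comment="#")
    missing = {"ligand", "receptor"} - set(pairs.columns)
    if missing:
        raise FormatError(f"pair table {path} lacks columns: {sorted(missing)}")
    return pairs[["ligand", "receptor"]]
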