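"""Per-cell QC statistics, the study's cell filters, normalization,
highly variable gene selection and PCA.

The cell filters follow the study arms exactly: inflamed tissue drops
cells with a unique feature count >4000 or <200 or mitochondrial
fraction >20%; normal tissue uses >3000 or <200 and >40%.  Inequalities
are strict, so boundary cells are kept.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import QCThresholds
from .types import NORMALIZED, RAW, ExpressionMatrix, ValidationError

logger = logging.getLogger("memsc")


def mito_gene_mask(gene_ids, prefix: str = "Mt-") -> np.ndarray:
    """Mitochondrial genes by symbol prefix (case-insensitive)."""
    prefix = prefix.lower()
    return np.array([str(g).lower().startswith(prefix) for g in gene_ids])


def compute_cell_qc(matrix: ExpressionMatrix, cell_table: pd.DataFrame | None = None,
                    mito_prefix: str = "Mt-") -> pd.DataFrame:
    """Fill n_features, total_counts and mito_fraction for every cell.

    ``mito_fraction`` is the mitochondrial share of a cell's total UMI
    counts, defined as 0 for an all-zero cell.
    """
    if matrix.layer != RAW:
        raise ValidationError("QC statistics require the raw count layer")
    csc = matrix.values.tocsc()
    n_features = np.diff(csc.indptr)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    mito = mito_gene_mask(matrix.gene_ids, mito_prefix)
    mito_counts = np.asarray(csc[mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore"):
        mito_fraction = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    n_empty = int(np.sum(totals == 0))
    if n_empty:
        logger.warning("%d all-zero cells present before filtering", n_empty)
    if cell_table is None:
        cell_table = pd.DataFrame(index=pd.Index(matrix.cell_ids, name="cell_id"))
    else:
        cell_table = cell_table.copy()
    cell_table["n_features"] = n_features.astype(int)
    cell_table["total_counts"] = totals.astype(int)
    cell_table["mito_fraction"] = mito_fraction
    return cell_table


# Removal reasons are reported with a fixed precedence so that the
# per-reason counts partition the removed set.
REMOVAL_REASONS = ("low_features", "high_features", "high_mito")


def filter_cells(matrix: ExpressionMatrix, cell_table: pd.DataFrame,
                 thresholds: QCThresholds):
    """Remove cells failing the QC filters (strict inequalities).

    Returns ``(filtered_matrix, filtered_table, report)`` where the
    report counts removals by reason (precedence: low features, high
    features, high mito) plus totals.
    """
    if thresholds is None:
        raise ValidationError("QC thresholds are required")
    for col in ("n_features", "mito_fraction"):
        if col not in cell_table:
            raise ValidationError(f"cell table lacks QC column {col!r}")
    feats = cell_table["n_features"].to_numpy()
    mito = cell_table["mito_fraction"].to_numpy(float)
    low = feats < thresholds.min_features
    high = feats > thresholds.max_features
    hi_mito = mito > thresholds.max_mito_fraction
    removed = low | high | hi_mito
    reason = np.full(len(feats), "", dtype=object)
    reason[hi_mito] = "high_mito"
    reason[high] = "high_features"
    reason[low] = "low_features"
    report = {r: int(np.sum(reason == r)) for r in REMOVAL_REASONS}
    report["removed"] = int(removed.sum())
    report["kept"] = int((~removed).sum())
    keep = ~removed
    logger.info("QC removed %d/%d cells (%s)", report["removed"], len(feats), report)
    return matrix.subset_cells(keep), cell_table.loc[keep].copy(), report


def filter_by_condition(matrix: ExpressionMatrix, cell_table: pd.DataFrame,
                        presets: dict):
    """Apply per-condition threshold presets; returns merged results."""
    keep = np.zeros(matrix.n_cells, dtype=bool)
    reports = {}
    cond = cell_table["condition"].to_numpy(dtype=object)
    for c, thr in presets.items():
        rows = cond == c
        if not rows.any():
            continue
        sub_tab = cell_table.loc[rows]
        feats = sub_tab["n_features"].to_numpy()
        mito = sub_tab["mito_fraction"].to_numpy(float)
        ok = ((feats >= thr.min_features) & (feats <= thr.max_features)
              & (mito <= thr.max_mito_fraction))
        keep[np.flatnonzero(rows)[ok]] = True
        reports[c] = {"removed": int((~ok).sum()), "kept": int(ok.sum())}
    return matrix.subset_cells(keep), cell_table.loc[keep].copy(), reports


def normalize_total(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Total-count normalize and log-transform: ln(1 + scale*count/total)."""
    if matrix.layer != RAW:
        raise ValidationError("normalize_total expects the raw layer")
    if matrix.n_cells == 0:
        raise ValidationError("empty cell subset; nothing to normalize")
    totals = matrix.cell_totals()
    if np.any(totals == 0):
        raise ValidationError(
            "all-zero cells present; run QC filtering before normalization")
    csc = matrix.values.tocsc().astype(float)
    csc.data *= np.repeat(scale / totals, np.diff(csc.indptr))
    np.log1p(csc.data, out=csc.data)
    return ExpressionMatrix(matrix.gene_ids, matrix.cell_ids, csc.tocsr(),
                            layer=NORMALIZED)


def select_hvg(matrix: ExpressionMatrix, n: int = 2000,
               lowess_frac: float = 0.3) -> np.ndarray:
    """Top-``n`` genes by standardized variance.

    A lowess mean-variance trend is fitted on log scale over genes with
    positive variance; the standardized variance of a gene is its
    variance divided by the trend's expectation at its mean, i.e. the
    variance of trend-z-scored expression.  Ties break by gene id.
    Returns gene indices sorted by gene id.
    """
    if matrix.layer != NORMALIZED:
        raise ValidationError("select_hvg expects the normalized layer")
    if n > matrix.n_genes:
        logger.warning("n=%d exceeds gene count %d; returning all genes",
                       n, matrix.n_genes)
        n = matrix.n_genes
    X = matrix.values
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(sq - mean ** 2, 0.0) * (matrix.n_cells / max(matrix.n_cells - 1, 1))
    positive = var > 0
    std_var = np.zeros(matrix.n_genes)
    if positive.sum() >= 2:
        lx = np.log10(mean[positive] + 1e-12)
        ly = np.log10(var[positive])
        fitted = lowess(ly, lx, frac=lowess_frac, return_sorted=False)
        expected = 10.0 ** fitted
        std_var[positive] = var[positive] / np.maximum(expected, 1e-12)
    elif positive.any():
        std_var[positive] = 1.0
    order = sorted(range(matrix.n_genes),
                   key=lambda i: (-std_var[i], str(matrix.gene_ids[i])))
    chosen = np.sort(np.asarray(order[:n], dtype=int))
    return chosen


def embed_pca(matrix: ExpressionMatrix, genes: np.ndarray | None = None,
              n_pcs: int = 30, clip: float = 10.0):
    """Z-score the (HVG) genes, clip at +-``clip``, and project on PCs.

    Component signs are fixed by making each component's
    largest-magnitude gene loading positive, so results are fully
    deterministic.  Returns ``(coords, explained_variance_ratio)``.
    """
    if matrix.layer != NORMALIZED:
        raise ValidationError("embed_pca expects the normalized layer")
    sub = matrix if genes is None else matrix.subset_genes(np.asarray(genes))
    X = sub.dense().T  # cells x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    max_pcs = min(Z.shape) - 1
    if n_pcs > max_pcs:
        logger.warning("n_pcs=%d reduced to %d for a %s matrix",
                       n_pcs, max_pcs, Z.shape)
        n_pcs = max(max_pcs, 1)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(Z)
    flip = np.sign(pca.components_[
        np.arange(n_pcs), np.argmax(np.abs(pca.components_), axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip
    return coords, pca.explained_variance_ratio_
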