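"""Dual-feature (non-professional phagocyte) analysis.

Mirrors the study's headline analysis: extract marker-positive (Cd68+)
cells, exclude doublets, score each lineage program and the
phagocytosis program per cell, and call a cell "dual-feature" when both
scores exceed their thresholds (default: the within-dataset 75th
percentile of each score).  Composition shifts between conditions are
summarized per cluster or per cell type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import RAW, ExpressionMatrix, ValidationError

logger = logging.getLogger("memsc")


def extract_positive_cells(matrix: ExpressionMatrix, cell_table: pd.DataFrame,
                           gene: str = "Cd68", min_count: int = 1):
    """Cells whose raw count of ``gene`` is >= ``min_count``.

    Returns the subset matrix and cell table.  An absent gene raises an
    error listing case-insensitive near-matches.
    """
    if matrix.layer != RAW:
        raise ValidationError("extract_positive_cells expects raw counts")
    index = matrix.gene_index()
    if gene not in index:
        near = [g for g in matrix.gene_ids
                if str(g).lower().startswith(str(gene).lower()[:3])][:5]
        raise ValidationError(
            f"gene {gene!r} absent from matrix; near matches: {near}")
    counts = np.asarray(matrix.values[index[gene], :].todense()).ravel()
    keep = counts >= min_count
    if not keep.any():
        logger.warning("no %s-positive cells at min_count=%d", gene, min_count)
    return matrix.subset_cells(keep), cell_table.loc[keep].copy()


def flag_doublets_heuristic(cell_table: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Flag feature-rich cells as doublets.

    Within each condition, a cell is flagged when its ``n_features``
    strictly exceeds ``median + k * MAD`` (raw median absolute
    deviation).  With MAD = 0 only cells strictly above the median can
    be flagged; ``k = inf`` flags nothing.
    """
    if "n_features" not in cell_table:
        raise ValidationError("cell table lacks n_features; run QC first")
    table = cell_table.copy()
    flags = np.zeros(len(table), dtype=bool)
    if not math.isinf(k):
        groups = (table["condition"] if "condition" in table
                  else pd.Series("all", index=table.index))
        for _, rows in table.groupby(groups, observed=True).groups.items():
            feats = table.loc[rows, "n_features"].to_numpy(float)
            med = np.median(feats)
            mad = np.median(np.abs(feats - med))
            cutoff = med + k * mad
            flags[table.index.get_indexer(rows)] = feats > cutoff
    table["doublet_flag"] = flags
    return table


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    valid: bool = True


def correlate_scores(scores_a, scores_b) -> CorrelationResult:
    """Pearson correlation of two aligned score vectors."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("score vectors must be aligned 1-d arrays")
    if a.size < 3:
        raise ValidationError("need at least 3 cells for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("zero-variance score vector; correlation undefined")
        return CorrelationResult(np.nan, np.nan, a.size, valid=False)
    res = stats.pearsonr(a, b)
    return CorrelationResult(float(res.statistic), float(res.pvalue), a.size)


def call_dual_feature(lineage_scores, phago_scores, t_lineage: float | None = None,
                      t_phago: float | None = None, quantile: float = 0.75,
                      cell_ids=None, lineage_name: str = "lineage") -> pd.DataFrame:
    """Call cells dual-feature when BOTH scores strictly exceed thresholds.

    Missing thresholds default to the given within-dataset quantile
    (75th percentile) of each score vector.
    """
    lin = np.asarray(lineage_scores, dtype=float)
    pha = np.asarray(phago_scores, dtype=float)
    if lin.shape != pha.shape:
        raise ValidationError("score vectors must be aligned")
    if t_lineage is None:
        t_lineage = float(np.quantile(lin, quantile))
    if t_phago is None:
        t_phago = float(np.quantile(pha, quantile))
    if not (np.isfinite(t_lineage) and np.isfinite(t_phago)):
        raise ValidationError("thresholds must be finite")
    if cell_ids is None:
        cell_ids = np.arange(lin.size)
    calls = pd.DataFrame({
        "lineage_signature": lineage_name,
        "lineage_score": lin,
        "phago_score": pha,
        "dual": (lin > t_lineage) & (pha > t_phago),
    }, index=pd.Index(cell_ids, name="cell_id"))
    calls.attrs["t_lineage"] = t_lineage
    calls.attrs["t_phago"] = t_phago
    return calls


def compare_score_distributions(scores, group_labels):
    """Two-sided Wilcoxon rank-sum between exactly two groups of scores.

    Returns ``(statistic, p_value, medians)`` with per-group medians.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels, dtype=object)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {len(groups)}")
    a = scores[labels == groups[0]]
    b = scores[labels == groups[1]]
    if min(a.size, b.size) < 3:
        raise ValidationError("each group needs at least 3 cells")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
    medians = {groups[0]: float(np.median(a)), groups[1]: float(np.median(b))}
    return float(stat), float(p), medians


def proportions_by_condition(cell_table: pd.DataFrame, by: str = "cluster") -> pd.DataFrame:
    """Cell counts and within-condition fractions per cluster/type.

    Unlabeled cells are counted under an explicit ``unassigned`` row;
    fractions sum to 1 within each condition.
    """
    if by not in cell_table:
        raise ValidationError(f"cell table lacks a {by!r} column")
    labels = cell_table[by].astype(object).where(
        cell_table[by].notna() & (cell_table[by].astype(str) != ""), "unassigned")
    conditions = pd.unique(cell_table["condition"])
    rows = []
    for cond in conditions:
        sub = labels[cell_table["condition"] == cond]
        if sub.empty:
            logger.warning("condition %s has no cells", cond)
            continue
        counts = sub.value_counts()
        for label, count in counts.items():
            rows.append({
                "condition": cond,
                by: label,
                "count": int(count),
                "fraction": count / len(sub),
            })
    return pd.DataFrame(rows)
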