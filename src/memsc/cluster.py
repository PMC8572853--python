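"""Graph clustering and per-cluster marker genes.

Clustering is Leiden community detection on a k-nearest-neighbour graph
built in PC space (resolution 0.6 by default, matching the study's
stated clustering resolution).  Markers are one-vs-rest two-sided
Wilcoxon rank-sum tests with a tie-corrected normal approximation, a
pseudocount-1 log2 fold change on de-logged means, and
Benjamini-Hochberg adjustment within each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .types import NORMALIZED, ExpressionMatrix, ValidationError

logger = logging.getLogger("memsc")


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels, size-ordered C0, C1, ..."""

    labels: np.ndarray  # str per cell
    resolution: float
    seed: int

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()


def knn_graph(coords: np.ndarray, k_neighbors: int = 20) -> ig.Graph:
    """Undirected kNN graph (Euclidean) over rows of ``coords``."""
    n = coords.shape[0]
    if k_neighbors >= n:
        logger.warning("k_neighbors=%d >= n_cells=%d; reduced", k_neighbors, n)
        k_neighbors = max(n - 1, 1)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {(min(i, j), max(i, j))
             for i in range(n) for j in idx[i, 1:]}
    graph = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return graph


def cluster_cells(coords: np.ndarray, resolution: float = 0.6,
                  k_neighbors: int = 20, seed: int = 0) -> ClusterAssignment:
    """Leiden clustering of cells in PC space; labels ordered by size."""
    graph = knn_graph(np.asarray(coords, dtype=float), k_neighbors)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    # relabel by decreasing size (ties: lowest original id first)
    ids, counts = np.unique(membership, return_counts=True)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    remap = {ids[rank_i]: f"C{new}" for new, rank_i in enumerate(order)}
    labels = np.asarray([remap[m] for m in membership], dtype=object)
    logger.info("Leiden at resolution %.2f: %d clusters", resolution, len(ids))
    return ClusterAssignment(labels=labels, resolution=resolution, seed=int(seed))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum markers
# ---------------------------------------------------------------------------

def _tie_terms(values: np.ndarray) -> np.ndarray:
    """Sum of t^3 - t over tied groups, per row."""
    srt = np.sort(values, axis=1)
    out = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        t = counts[counts > 1].astype(float)
        out[i] = np.sum(t ** 3 - t)
    return out


def _exact_u_pmf(n_in: int, n: int) -> np.ndarray:
    """PMF of the rank-sum U statistic under the tie-free null."""
    n_out = n - n_in
    # ways[k][u]: choices of k ranks giving Mann-Whitney statistic u
    ways = np.zeros((n_in + 1, n_in * n_out + 1))
    ways[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n_in), 0, -1):
            shift = rank - k  # u contribution of taking this rank k-th
            ways[k, shift:] += ways[k - 1, : ways.shape[1] - shift]
    return ways[n_in] / ways[n_in].sum()


def rank_sum_p(values: np.ndarray, in_mask: np.ndarray,
               exact_limit: int = 25) -> np.ndarray:
    """Two-sided rank-sum p per row of ``values`` for group ``in_mask``.

    Small tie-free samples (``n <= exact_limit``) use the exact null
    enumeration, the field convention for Wilcoxon tests; otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    n = values.shape[1]
    n_in = int(in_mask.sum())
    n_out = n - n_in
    ranks = stats.rankdata(values, axis=1)
    r_in = ranks[:, in_mask].sum(axis=1)
    u = r_in - n_in * (n_in + 1) / 2.0
    mu = n_in * n_out / 2.0
    tie = _tie_terms(values)
    var = n_in * n_out / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u - mu) - 0.5) / sigma
    z = np.where(sigma > 0, np.maximum(z, 0.0), 0.0)
    p = np.where(sigma > 0, np.minimum(2.0 * stats.norm.sf(z), 1.0), 1.0)
    if n <= exact_limit and 0 < n_in < n:
        tiefree = np.flatnonzero(tie == 0)
        if tiefree.size:
            pmf = _exact_u_pmf(n_in, n)
            support = np.arange(pmf.size)
            for i in tiefree:
                p[i] = pmf[np.abs(support - mu) >= abs(u[i] - mu)].sum()
    return p


def rank_sum_markers(matrix: ExpressionMatrix, clusters: ClusterAssignment,
                     min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest marker statistics per gene per cluster.

    log2_fc uses pseudocount-1 de-logged means:
    ``log2((mean(expm1 in)+1) / (mean(expm1 out)+1))``.  BH adjustment
    is applied across genes within each cluster.
    """
    if matrix.layer != NORMALIZED:
        raise ValidationError("rank_sum_markers expects the normalized layer")
    labels = np.asarray(clusters.labels, dtype=object)
    uniq = [c for c in pd.unique(labels)]
    usable = [c for c in uniq if np.sum(labels == c) >= min_cells]
    for c in set(uniq) - set(usable):
        logger.warning("cluster %s has <%d cells; skipped", c, min_cells)
    if len(usable) < 2:
        raise ValidationError("need at least 2 clusters with enough cells")
    usable = sorted(usable, key=lambda c: (len(c), c))

    values = matrix.dense()  # genes x cells
    expm1 = np.expm1(values)
    nonzero = values > 0
    records = []
    for c in usable:
        in_mask = labels == c
        p = rank_sum_p(values, in_mask)
        m_in = expm1[:, in_mask].mean(axis=1)
        m_out = expm1[:, ~in_mask].mean(axis=1)
        log2_fc = np.log2((m_in + 1.0) / (m_out + 1.0))
        rec = pd.DataFrame({
            "gene": matrix.gene_ids,
            "cluster": c,
            "log2_fc": log2_fc,
            "p_value": p,
            "p_adjusted": bh_adjust(p),
            "pct_in": nonzero[:, in_mask].mean(axis=1),
            "pct_out": nonzero[:, ~in_mask].mean(axis=1),
        })
        records.append(rec)
    return pd.concat(records, ignore_index=True)


def significant_markers(records: pd.DataFrame, alpha: float = 0.05,
                        min_abs_log2fc: float = 2.0) -> pd.DataFrame:
    """Study filter: adjusted p < alpha AND |log2 fold change| > 2 (strict)."""
    keep = (records["p_adjusted"] < alpha) & (records["log2_fc"].abs() > min_abs_log2fc)
    return records.loc[keep].reset_index(drop=True)
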