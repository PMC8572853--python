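"""Cluster-level ligand-receptor screen with a permutation null.

For each annotated (ligand, receptor) pair and each ordered cluster
pair (sender, receiver) the interaction score is the product of the
sender's mean ligand expression and the receiver's mean receptor
expression (normalized layer).  A record is *valid* only when both
means reach the expression cutoff (0.2, the study's stated validity
threshold).  Significance comes from shuffling cluster labels over
cells and recomputing the score, with the add-one estimator
``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` and BH adjustment
across valid records.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cluster import bh_adjust
from .types import NORMALIZED, ExpressionMatrix, ValidationError

logger = logging.getLogger("memsc")


def cluster_means(matrix: ExpressionMatrix, labels) -> pd.DataFrame:
    """Mean normalized expression per cluster: genes x clusters frame."""
    if matrix.layer != NORMALIZED:
        raise ValidationError("cluster_means expects the normalized layer")
    labels = np.asarray(labels, dtype=object)
    if labels.size != matrix.n_cells:
        raise ValidationError("labels do not match the number of cells")
    out = {}
    for c in sorted(pd.unique(labels), key=str):
        mask = labels == c
        if not mask.any():
            raise ValidationError(f"cluster {c!r} is empty")
        out[c] = np.asarray(matrix.values[:, mask].mean(axis=1)).ravel()
    return pd.DataFrame(out, index=pd.Index(matrix.gene_ids, name="gene"))


def _label_means(X: np.ndarray, labels_int: np.ndarray, n_clusters: int) -> np.ndarray:
    """(n_clusters x n_genes) means of cells x genes array X."""
    sums = np.zeros((n_clusters, X.shape[1]))
    np.add.at(sums, labels_int, X)
    counts = np.bincount(labels_int, minlength=n_clusters).astype(float)
    return sums / counts[:, None]


def screen_interactions(matrix: ExpressionMatrix, labels, pairs: pd.DataFrame,
                        cutoff: float = 0.2, n_perm: int = 1000,
                        seed: int = 0) -> pd.DataFrame:
    """Score every (pair, sender, receiver) combination.

    Pairs whose ligand or receptor is absent from the matrix are
    skipped with a log message.  Permutation p-values are only computed
    for valid records (both cluster means >= cutoff).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = np.asarray(labels, dtype=object)
    gene_index = matrix.gene_index()
    usable = []
    for _, row in pairs.iterrows():
        lig, rec = str(row["ligand"]), str(row["receptor"])
        if lig not in gene_index or rec not in gene_index:
            logger.info("skipping pair %s-%s: gene absent from matrix", lig, rec)
            continue
        usable.append((lig, rec))
    if not usable:
        raise ValidationError("no ligand-receptor pair has both genes present")

    genes = sorted({g for pair in usable for g in pair})
    gpos = {g: i for i, g in enumerate(genes)}
    rows = np.asarray([gene_index[g] for g in genes], dtype=int)
    X = np.asarray(matrix.values[rows, :].todense()).T  # cells x genes(sub)

    clusters = sorted(pd.unique(labels), key=str)
    cpos = {c: i for i, c in enumerate(clusters)}
    labels_int = np.asarray([cpos[c] for c in labels], dtype=int)
    obs_means = _label_means(X, labels_int, len(clusters))

    records = []
    for lig, rec in usable:
        for sender in clusters:
            for receiver in clusters:
                mean_l = obs_means[cpos[sender], gpos[lig]]
                mean_r = obs_means[cpos[receiver], gpos[rec]]
                records.append({
                    "ligand": lig, "receptor": rec,
                    "sender": sender, "receiver": receiver,
                    "mean_l": mean_l, "mean_r": mean_r,
                    "score": mean_l * mean_r,
                    "valid": bool(mean_l >= cutoff and mean_r >= cutoff),
                })
    table = pd.DataFrame(records)

    valid_idx = np.flatnonzero(table["valid"].to_numpy())
    if valid_idx.size:
        li = table["ligand"].map(gpos).to_numpy()[valid_idx]
        ri = table["receptor"].map(gpos).to_numpy()[valid_idx]
        si = table["sender"].map(cpos).to_numpy()[valid_idx]
        vi = table["receiver"].map(cpos).to_numpy()[valid_idx]
        obs = table["score"].to_numpy()[valid_idx]
        exceed = np.zeros(valid_idx.size, dtype=int)
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(labels_int)
            means_b = _label_means(X, perm, len(clusters))
            scores_b = means_b[si, li] * means_b[vi, ri]
            exceed += scores_b >= obs
        p = (1.0 + exceed) / (n_perm + 1.0)
        table["p_value"] = np.nan
        table.loc[valid_idx, "p_value"] = p
        table["p_adjusted"] = np.nan
        table.loc[valid_idx, "p_adjusted"] = bh_adjust(p)
    else:
        table["p_value"] = np.nan
        table["p_adjusted"] = np.nan
    return table


def interaction_counts(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Sender x receiver matrix of significant valid interactions."""
    clusters = sorted(set(records["sender"]) | set(records["receiver"]), key=str)
    counts = pd.DataFrame(0, index=pd.Index(clusters, name="sender"),
                          columns=pd.Index(clusters, name="receiver"))
    sig = records[(records["valid"]) & (records["p_adjusted"] < alpha)]
    for _, row in sig.iterrows():
        counts.loc[row["sender"], row["receiver"]] += 1
    return counts
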