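"""Benchmarks of the pipeline against the generator's planted truth.

These are the package's standard evaluation experiments: null
calibration of the cell score, recovery of a planted uniform score
elevation, and end-to-end detection of the planted dual-feature
populations.  Each function regenerates its data from a seed, so
results are reproducible and never cached.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from . import qc as qcmod
from .config import QC_PRESETS
from .dual import call_dual_feature
from .scoring import assign_bins, per_target_differences, score_cells, score_many
from .simulate import default_study_config, generate_dataset, signatures_from_config
from .types import ExpressionMatrix, GeneSignature

logger = logging.getLogger("memsc")

# lineage signature -> planted population it should recover
LINEAGE_TO_DUAL = {
    "proliferation": "mki67_progenitor",
    "epithelial": "epithelial_phagocyte",
    "osteoblastic": "osteoblastic_stromal",
}


def cs_null_zscores(n_seeds: int = 20, n_cells_per_condition: int = 500,
                    n_genes: int = 2000, signature_size: int = 50,
                    base_seed: int = 0) -> np.ndarray:
    """Calibration z of the mean cell score on effect-free data.

    For each seed, a dataset with all planted effects at zero is
    generated, a random signature is scored, and the across-cell mean
    CS is standardized by the SE over per-target-gene differences
    (which carries the control-draw and target-draw variance that the
    across-cell SE misses).  Well-calibrated scores give z ~ N(0, 1).
    """
    zs = []
    for i in range(n_seeds):
        seed = (base_seed + i) % (2 ** 31)
        cfg = default_study_config(
            n_genes=n_genes, n_cells_per_condition=n_cells_per_condition,
            seed=seed, program_log2_effect=0.0, dual_specs=[], doublet_rate=0.0)
        matrix, _, _ = generate_dataset(cfg)
        norm = qcmod.normalize_total(matrix)
        rng = np.random.default_rng(seed + 10_000)
        sig = GeneSignature(
            "null", list(rng.choice(norm.gene_ids, signature_size, replace=False)))
        d = per_target_differences(norm, sig, seed=seed)
        zs.append(float(d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))))
    return np.asarray(zs)


def cs_signal_recovery(seed: int = 0, n_cells: int = 1000, n_genes: int = 2000,
                       signature_size: int = 50, delta: float = 0.5) -> float:
    """Mean CS when signature genes are uniformly elevated by ``delta``.

    All genes share one baseline distribution (normalized units) so the
    signature's bin-mates are exchangeable controls; the analytic
    expectation of the mean CS is ``delta``.
    """
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.5, 1.5, size=(n_genes, n_cells))
    sig_idx = rng.choice(n_genes, signature_size, replace=False)
    values[sig_idx] += delta
    gene_ids = np.asarray([f"g{i:05d}" for i in range(n_genes)], dtype=object)
    matrix = ExpressionMatrix(gene_ids, [f"c{i:05d}" for i in range(n_cells)],
                              sp.csr_matrix(values), layer="normalized")
    sig = GeneSignature("planted", list(gene_ids[sig_idx]))
    return float(score_cells(matrix, sig, seed=seed).mean())


def cs_exhaustion_error(seed: int = 0, n_genes: int = 400, n_cells: int = 50,
                        signature_size: int = 15, n_bins: int = 10) -> float:
    """Max |CS - direct oracle| with exhaustive controls.

    With ``n_ctrl`` at least the bin size, control sampling is forced to
    the full non-signature bin content and CS reduces to the
    deterministic mean(Gt) - mean(pooled bin-mates), recomputed here
    gene by gene without the scoring code path.
    """
    rng = np.random.default_rng(seed)
    values = rng.gamma(1.0, 1.0, size=(n_genes, n_cells))
    gene_ids = np.asarray([f"g{i:05d}" for i in range(n_genes)], dtype=object)
    matrix = ExpressionMatrix(gene_ids, [f"c{i:05d}" for i in range(n_cells)],
                              sp.csr_matrix(values), layer="normalized")
    sig_idx = rng.choice(n_genes, signature_size, replace=False)
    sig = GeneSignature("s", list(gene_ids[sig_idx]))
    bins = assign_bins(matrix, n_bins=n_bins)
    cs = score_cells(matrix, sig, bins=bins, n_ctrl=10 * n_genes, seed=seed)
    sig_set = set(sig.genes)
    gi = {g: i for i, g in enumerate(gene_ids)}
    pooled = []
    for g in sig.genes:
        pooled.extend(gi[x] for x in bins.genes_in_bin(bins.bin_of[g])
                      if x not in sig_set)
    oracle = values[sig_idx].mean(axis=0) - values[pooled].mean(axis=0)
    return float(np.max(np.abs(cs - oracle)))


def dual_feature_recovery(seeds, n_cells_per_condition: int = 1000,
                          quantile: float = 0.75) -> pd.DataFrame:
    """End-to-end planted dual-feature recovery per seed and lineage.

    simulate -> per-condition QC -> normalize -> score phagocytosis and
    each lineage signature -> percentile-threshold dual calls, compared
    against the planted truth.  Returns sensitivity, specificity and
    the ROC AUC of the min-of-both-scores statistic.
    """
    rows = []
    for seed in seeds:
        cfg = default_study_config(
            n_cells_per_condition=n_cells_per_condition, seed=int(seed) % (2 ** 31))
        matrix, cells, _ = generate_dataset(cfg)
        cells = qcmod.compute_cell_qc(matrix, cells)
        filtered, table, _ = qcmod.filter_by_condition(matrix, cells, QC_PRESETS)
        norm = qcmod.normalize_total(filtered)
        sigs = {s.name: s for s in signatures_from_config(cfg)}
        bins = assign_bins(norm)
        wanted = [sigs[n] for n in (*LINEAGE_TO_DUAL, "phagocytosis")]
        scores = score_many(norm, wanted, bins=bins, seed=int(seed) % (2 ** 31))
        phago = scores["phagocytosis"].to_numpy()
        for lineage, dual_name in LINEAGE_TO_DUAL.items():
            lin = scores[lineage].to_numpy()
            calls = call_dual_feature(lin, phago, quantile=quantile,
                                      cell_ids=scores.index,
                                      lineage_name=lineage)
            truth = (table["dual_name"] == dual_name).to_numpy()
            called = calls["dual"].to_numpy()
            rows.append({
                "seed": seed,
                "lineage": lineage,
                "n_planted": int(truth.sum()),
                "sensitivity": float(called[truth].mean()),
                "specificity": float(1.0 - called[~truth].mean()),
                "min_score_auc": float(roc_auc_score(truth, np.minimum(lin, phago))),
            })
    return pd.DataFrame(rows)
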