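"""Shared fixtures: one session-wide synthetic study dataset plus helpers."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from memsc import qc as qcmod
from memsc.config import QC_PRESETS
from memsc.scoring import assign_bins
from memsc.simulate import default_study_config, generate_dataset, signatures_from_config
from memsc.types import ExpressionMatrix


def make_matrix(values, layer="normalized", gene_ids=None, cell_ids=None):
    """Build an ExpressionMatrix from a dense genes x cells array."""
    values = np.asarray(values)
    n_genes, n_cells = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"c{i:04d}" for i in range(n_cells)]
    return ExpressionMatrix(gene_ids, cell_ids, sp.csr_matrix(values), layer)


@pytest.fixture(scope="session")
def study():
    """Default-config synthetic study, QC'd, normalized, binned and scored."""
    cfg = default_study_config(n_cells_per_condition=500, seed=0)
    matrix, cells, truth = generate_dataset(cfg)
    cells = qcmod.compute_cell_qc(matrix, cells)
    filtered, table, reports = qcmod.filter_by_condition(matrix, cells, QC_PRESETS)
    norm = qcmod.normalize_total(filtered)
    bins = assign_bins(norm)
    return {
        "config": cfg,
        "raw": matrix,
        "cells": cells,
        "truth": truth,
        "filtered": filtered,
        "table": table,
        "qc_reports": reports,
        "norm": norm,
        "bins": bins,
        "signatures": {s.name: s for s in signatures_from_config(cfg)},
    }
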