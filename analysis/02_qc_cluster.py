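#!/usr/bin/env python
"""QC-filter, normalize, cluster, and detect marker genes.

Applies the per-condition cell filters (inflamed 200-4000 features,
mito <= 20%; normal 200-3000, mito <= 40%), log-normalizes, selects
highly variable genes, clusters the kNN graph at resolution 0.6, and
reports rank-sum markers (BH-adjusted p < 0.05, |log2FC| > 2).
"""

import argparse
from pathlib import Path

import pandas as pd

from memsc import cluster as cl
from memsc import io as mio
from memsc import qc as qcmod
from memsc.config import QC_PRESETS
from memsc.pipeline import stage_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    matrix = mio.read_matrix_dir(args.data)
    cells = mio.read_cell_table(args.data / "cells.csv")
    cells = qcmod.compute_cell_qc(matrix, cells)
    filtered, table, reports = qcmod.filter_by_condition(matrix, cells, QC_PRESETS)
    print(f"QC kept {filtered.n_cells}/{matrix.n_cells} cells: {reports}")

    norm = qcmod.normalize_total(filtered)
    hvg = qcmod.select_hvg(norm, 1000)
    coords, evr = qcmod.embed_pca(norm, hvg, n_pcs=30)
    print(f"top PCs explain {100 * evr[:5].sum():.1f}% variance (first five)")

    assign = cl.cluster_cells(coords, resolution=0.6, k_neighbors=20,
                              seed=stage_seed(args.seed, "cluster"))
    table = table.copy()
    table["cluster"] = assign.labels
    purity = (table.groupby("cluster")["truth_type"]
              .agg(lambda s: s.value_counts(normalize=True).iloc[0]))
    print(f"{assign.sizes().size} clusters; median truth purity "
          f"{purity.median():.2f}")

    markers = cl.rank_sum_markers(norm, assign)
    sig = cl.significant_markers(markers)
    print(f"{len(sig)} significant markers across clusters; top per cluster:")
    top = (sig.sort_values("log2_fc", ascending=False)
           .groupby("cluster").head(1)[["cluster", "gene", "log2_fc"]])
    print(top.to_string(index=False))

    args.out.mkdir(parents=True, exist_ok=True)
    mio.write_matrix(norm, args.out / "normalized")
    mio.write_cell_table(table, args.out / "cells_clustered.csv", seed=args.seed)
    mio.write_table(sig.round(9), args.out / "significant_markers.csv",
                    seed=args.seed, index=False)


if __name__ == "__main__":
    main()
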