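#!/usr/bin/env python
"""Ligand-receptor screen per condition.

Runs the product-score permutation screen separately on the inflamed
and normal cells (truth cell types as cluster labels), with the 0.2
expression validity cutoff, and reports the significant interactions
and their sender/receiver counts.
"""

import argparse
from pathlib import Path

import pandas as pd

from memsc import io as mio
from memsc import lr as lrmod
from memsc import qc as qcmod
from memsc.pipeline import stage_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--nperm", type=int, default=1000)
    args = ap.parse_args()

    matrix = mio.read_matrix_dir(args.data)
    cells = mio.read_cell_table(args.data / "cells.csv")
    pairs = mio.read_lr_pairs()

    for condition in ("inflamed", "normal"):
        mask = (cells["condition"] == condition).to_numpy()
        sub = matrix.subset_cells(mask)
        labels = cells.loc[mask, "truth_type"].to_numpy(dtype=object)
        norm = qcmod.normalize_total(sub)
        rec = lrmod.screen_interactions(
            norm, labels, pairs, cutoff=0.2, n_perm=args.nperm,
            seed=stage_seed(args.seed, f"lr-{condition}"))
        sig = rec[(rec["valid"]) & (rec["p_adjusted"] < 0.05)]
        mio.write_table(rec.round(9), args.out / f"lr_{condition}.csv",
                        seed=args.seed, index=False)
        counts = lrmod.interaction_counts(rec)
        mio.write_table(counts, args.out / f"lr_{condition}_counts.csv",
                        seed=args.seed)
        print(f"{condition}: {len(sig)} significant of "
              f"{int(rec['valid'].sum())} valid records; strongest:")
        top = sig.sort_values("score", ascending=False).head(5)
        print(top[["ligand", "receptor", "sender", "receiver",
                   "score", "p_adjusted"]].to_string(index=False))


if __name__ == "__main__":
    main()
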