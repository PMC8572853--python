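"""End-to-end orchestration with digest-based stage skipping.

``run_pipeline`` executes simulate -> qc -> reduce -> cluster ->
markers -> score -> dualfeature -> lrscreen from one configuration,
records a manifest of input/output file digests, and on rerun skips
any stage whose inputs and outputs are unchanged.  One global seed
spawns a per-stage substream (stage name hashed into the stream id),
so adding a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import dual as df
from . import io as mio
from . import lr as lrmod
from . import qc as qcmod
from . import scoring as sc
from . import simulate as sim
from .config import PipelineConfig, config_hash
from .types import NORMALIZED, RAW

logger = logging.getLogger("memsc")


class PipelineError(RuntimeError):
    pass


def stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0]) % (2 ** 31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage implementations (paths are relative to the run directory)
# ---------------------------------------------------------------------------

def _stage_simulate(ctx):
    gen = ctx["generator"]
    matrix, cells, truth = sim.generate_dataset(gen)
    out = ctx["dir"] / "sim"
    mio.write_matrix(matrix, out)
    mio.write_cell_table(cells, out / "cells.csv", seed=gen.seed, config_hash=ctx["hash"])
    mio.write_table(truth.genes, out / "truth_genes.csv", seed=gen.seed,
                    config_hash=ctx["hash"])
    mio.write_gene_sets(sim.signatures_from_config(gen), out / "signatures.gmt")


def _stage_qc(ctx):
    cfg = ctx["config"]
    matrix = mio.read_matrix_dir(ctx["dir"] / "sim")
    cells = mio.read_cell_table(ctx["dir"] / "sim" / "cells.csv")
    cells = qcmod.compute_cell_qc(matrix, cells, mito_prefix=cfg.mito_prefix)
    filtered, ftable, reports = qcmod.filter_by_condition(matrix, cells, cfg.qc)
    out = ctx["dir"] / "qc"
    mio.write_matrix(filtered, out)
    mio.write_cell_table(ftable, out / "cells.csv", seed=cfg.seed, config_hash=ctx["hash"])
    report = pd.DataFrame(reports).T
    report.index.name = "condition"
    mio.write_table(report, out / "qc_report.csv", seed=cfg.seed, config_hash=ctx["hash"])


def _stage_reduce(ctx):
    cfg = ctx["config"]
    matrix = mio.read_matrix_dir(ctx["dir"] / "qc")
    norm = qcmod.normalize_total(matrix, scale=cfg.scale_factor)
    out = ctx["dir"] / "reduce"
    mio.write_matrix(norm, out)
    hvg = qcmod.select_hvg(norm, n=min(cfg.n_hvg, norm.n_genes))
    (out / "hvg.tsv").write_text(
        "".join(f"{norm.gene_ids[i]}\n" for i in hvg))
    coords, evr = qcmod.embed_pca(norm, hvg, n_pcs=cfg.n_pcs)
    pcs = pd.DataFrame(coords, index=pd.Index(norm.cell_ids, name="cell_id"),
                       columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    mio.write_table(pcs.round(9), out / "pca.csv", seed=cfg.seed, config_hash=ctx["hash"])


def _stage_cluster(ctx):
    cfg = ctx["config"]
    pcs = mio.read_table(ctx["dir"] / "reduce" / "pca.csv")
    assign = cl.cluster_cells(pcs.to_numpy(), resolution=cfg.resolution,
                              k_neighbors=cfg.k_neighbors,
                              seed=stage_seed(cfg.seed, "cluster"))
    table = pd.DataFrame({"cluster": assign.labels},
                         index=pd.Index(pcs.index, name="cell_id"))
    mio.write_table(table, ctx["dir"] / "cluster" / "clusters.csv",
                    seed=cfg.seed, config_hash=ctx["hash"])


def _stage_markers(ctx):
    cfg = ctx["config"]
    norm = mio.read_matrix_dir(ctx["dir"] / "reduce", layer=NORMALIZED)
    clusters = mio.read_table(ctx["dir"] / "cluster" / "clusters.csv")
    assign = cl.ClusterAssignment(clusters["cluster"].to_numpy(dtype=object),
                                  cfg.resolution, cfg.seed)
    markers = cl.rank_sum_markers(norm, assign)
    sig = cl.significant_markers(markers)
    out = ctx["dir"] / "markers"
    mio.write_table(markers.round(9), out / "markers.csv", seed=cfg.seed,
                    config_hash=ctx["hash"], index=False)
    mio.write_table(sig.round(9), out / "significant_markers.csv", seed=cfg.seed,
                    config_hash=ctx["hash"], index=False)


def _stage_score(ctx):
    cfg = ctx["config"]
    norm = mio.read_matrix_dir(ctx["dir"] / "reduce", layer=NORMALIZED)
    signatures = mio.read_gene_sets(ctx["dir"] / "sim" / "signatures.gmt")
    bins = sc.assign_bins(norm, n_bins=cfg.n_bins)
    scores = sc.score_many(norm, signatures, bins=bins, n_ctrl=cfg.n_ctrl,
                           seed=stage_seed(cfg.seed, "score"))
    mio.write_scores(scores.round(9), ctx["dir"] / "score" / "scores.csv",
                     seed=cfg.seed, config_hash=ctx["hash"])


_LINEAGES = ("proliferation", "epithelial", "osteoblastic")


def _stage_dualfeature(ctx):
    cfg = ctx["config"]
    matrix = mio.read_matrix_dir(ctx["dir"] / "qc")
    cells = mio.read_cell_table(ctx["dir"] / "qc" / "cells.csv")
    out = ctx["dir"] / "dualfeature"
    out.mkdir(parents=True, exist_ok=True)

    # composition shift across conditions on the full filtered data
    props = df.proportions_by_condition(cells, by="truth_type")
    mio.write_table(props.round(9), out / "proportions.csv", seed=cfg.seed,
                    config_hash=ctx["hash"], index=False)

    # Cd68+ subset, heuristic doublet exclusion, rescore, call duals
    sub, sub_cells = df.extract_positive_cells(
        matrix, cells, gene=cfg.cd68_gene, min_count=cfg.min_marker_count)
    sub_cells = df.flag_doublets_heuristic(sub_cells)
    keep = ~sub_cells["doublet_flag"].to_numpy()
    sub, sub_cells = sub.subset_cells(keep), sub_cells.loc[keep]
    norm = qcmod.normalize_total(sub, scale=cfg.scale_factor)
    signatures = {s.name: s for s in mio.read_gene_sets(
        ctx["dir"] / "sim" / "signatures.gmt")}
    bins = sc.assign_bins(norm, n_bins=cfg.n_bins)
    wanted = [signatures[n] for n in (*_LINEAGES, "phagocytosis")
              if n in signatures]
    scores = sc.score_many(norm, wanted, bins=bins, n_ctrl=cfg.n_ctrl,
                           seed=stage_seed(cfg.seed, "dualfeature"))
    phago = scores["phagocytosis"].to_numpy()
    calls_frames, corr_rows = [], []
    for lineage in _LINEAGES:
        if lineage not in scores:
            continue
        lin = scores[lineage].to_numpy()
        calls = df.call_dual_feature(lin, phago, quantile=cfg.dual_quantile,
                                     cell_ids=scores.index, lineage_name=lineage)
        calls_frames.append(calls.reset_index())
        corr = df.correlate_scores(lin, phago)
        corr_rows.append({"lineage_signature": lineage, "pearson_r": corr.r,
                          "p_value": corr.p_value, "n": corr.n})
    mio.write_table(pd.concat(calls_frames, ignore_index=True).round(9),
                    out / "calls.csv", seed=cfg.seed, config_hash=ctx["hash"],
                    index=False)
    mio.write_table(pd.DataFrame(corr_rows).round(9), out / "correlations.csv",
                    seed=cfg.seed, config_hash=ctx["hash"], index=False)

    # re-cluster the Cd68+ subset at the same resolution
    hvg = qcmod.select_hvg(norm, n=min(cfg.n_hvg, norm.n_genes))
    coords, _ = qcmod.embed_pca(norm, hvg, n_pcs=min(cfg.n_pcs, norm.n_cells - 2))
    assign = cl.cluster_cells(coords, resolution=cfg.resolution,
                              k_neighbors=min(cfg.k_neighbors, norm.n_cells - 1),
                              seed=stage_seed(cfg.seed, "dual-cluster"))
    sub_cells = sub_cells.copy()
    sub_cells["cluster"] = assign.labels
    sub_props = df.proportions_by_condition(sub_cells, by="cluster")
    mio.write_table(sub_props.round(9), out / "cd68_cluster_proportions.csv",
                    seed=cfg.seed, config_hash=ctx["hash"], index=False)


def _stage_lrscreen(ctx):
    cfg = ctx["config"]
    norm = mio.read_matrix_dir(ctx["dir"] / "reduce", layer=NORMALIZED)
    clusters = mio.read_table(ctx["dir"] / "cluster" / "clusters.csv")
    pairs = mio.read_lr_pairs(ctx.get("pairs_path"))
    records = lrmod.screen_interactions(
        norm, clusters["cluster"].to_numpy(dtype=object), pairs,
        cutoff=cfg.lr_cutoff, n_perm=cfg.n_perm,
        seed=stage_seed(cfg.seed, "lrscreen"))
    out = ctx["dir"] / "lrscreen"
    mio.write_table(records.round(9), out / "interactions.csv", seed=cfg.seed,
                    config_hash=ctx["hash"], index=False)
    counts = lrmod.interaction_counts(records)
    mio.write_table(counts, out / "counts.csv", seed=cfg.seed, config_hash=ctx["hash"])


STAGES = [
    ("simulate", _stage_simulate, [],
     ["sim/matrix.mtx", "sim/features.tsv", "sim/barcodes.tsv",
      "sim/cells.csv", "sim/truth_genes.csv", "sim/signatures.gmt"]),
    ("qc", _stage_qc,
     ["sim/matrix.mtx", "sim/features.tsv", "sim/barcodes.tsv", "sim/cells.csv"],
     ["qc/matrix.mtx", "qc/features.tsv", "qc/barcodes.tsv",
      "qc/cells.csv", "qc/qc_report.csv"]),
    ("reduce", _stage_reduce,
     ["qc/matrix.mtx", "qc/features.tsv", "qc/barcodes.tsv"],
     ["reduce/matrix.mtx", "reduce/features.tsv", "reduce/barcodes.tsv",
      "reduce/hvg.tsv", "reduce/pca.csv"]),
    ("cluster", _stage_cluster, ["reduce/pca.csv"], ["cluster/clusters.csv"]),
    ("markers", _stage_markers,
     ["reduce/matrix.mtx", "cluster/clusters.csv"],
     ["markers/markers.csv", "markers/significant_markers.csv"]),
    ("score", _stage_score,
     ["reduce/matrix.mtx", "sim/signatures.gmt"],
     ["score/scores.csv"]),
    ("dualfeature", _stage_dualfeature,
     ["qc/matrix.mtx", "qc/cells.csv", "sim/signatures.gmt"],
     ["dualfeature/proportions.csv", "dualfeature/calls.csv",
      "dualfeature/correlations.csv", "dualfeature/cd68_cluster_proportions.csv"]),
    ("lrscreen", _stage_lrscreen,
     ["reduce/matrix.mtx", "cluster/clusters.csv"],
     ["lrscreen/interactions.csv", "lrscreen/counts.csv"]),
]


def stage_names() -> list:
    return [name for name, *_ in STAGES]


def run_pipeline(config, out_dir, generator: sim.GeneratorConfig | None = None,
                 pairs_path=None, force: bool = False) -> dict:
    """Run all stages into ``out_dir``; returns the manifest.

    ``config`` may be a :class:`PipelineConfig` or a YAML path.  A stage
    is skipped when its recorded input and output digests are unchanged
    since the previous run.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if generator is None:
        generator = sim.default_study_config(seed=stage_seed(config.seed, "simulate"))
    ctx = {"config": config, "generator": generator, "dir": out_dir,
           "hash": config.hash(), "pairs_path": pairs_path}

    manifest_path = out_dir / "manifest.json"
    previous = {}
    if manifest_path.exists() and not force:
        previous = {s["name"]: s for s in json.loads(manifest_path.read_text()).get("stages", [])}

    producer = {}
    for name, _, _, outputs in STAGES:
        for p in outputs:
            producer[p] = name
    ran = set()
    stages_out = []
    for name, func, inputs, outputs in STAGES:
        in_paths = [out_dir / p for p in inputs]
        out_paths = [out_dir / p for p in outputs]
        prev = previous.get(name)
        current_in = {p: _digest(out_dir / p) for p in inputs if (out_dir / p).exists()}
        upstream_ran = any(producer.get(p) in ran for p in inputs)
        unchanged = (
            not upstream_ran
            and prev is not None
            and all((out_dir / p).exists() for p in outputs)
            and prev.get("inputs") == current_in
            and prev.get("outputs") == {p: _digest(out_dir / p) for p in outputs}
        )
        if unchanged:
            logger.info("stage %s: up to date, skipped", name)
            stages_out.append(prev)
            continue
        ran.add(name)
        missing = [str(p) for p in in_paths if not p.exists()]
        if missing:
            raise PipelineError(f"stage {name}: missing inputs {missing}")
        logger.info("stage %s: running", name)
        try:
            func(ctx)
        except Exception as exc:
            for p in out_paths:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        stages_out.append({
            "name": name,
            "inputs": {p: _digest(out_dir / p) for p in inputs},
            "outputs": {p: _digest(out_dir / p) for p in outputs},
        })

    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "generator_hash": config_hash(generator),
        "ran": sorted(ran),
        "stages": stages_out,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
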