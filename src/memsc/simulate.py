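"""Synthetic two-condition scRNA-seq counts with planted ground truth.

The generator emulates the structure of a middle-ear mucosa experiment:
a *normal* condition dominated by epithelial cells and fibroblasts and
an *inflamed* condition dominated by infiltrating neutrophils and
macrophages, with a shared phagocytosis program expressed by
professional phagocytes, three planted rare dual-feature populations
that co-express a lineage program with the phagocytosis program,
mitochondrial genes, log-normal library sizes, and summed-then-thinned
doublets.  Counts follow a gamma-Poisson (negative binomial) law with a
shared dispersion.

Every cell's expected total count equals its drawn library size
regardless of cell type, so composition effects are never confounded
with depth effects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import CONDITIONS, ExpressionMatrix, GeneSignature, ValidationError, new_cell_table

logger = logging.getLogger("memsc")


class ConfigError(ValidationError):
    pass


@dataclass
class CellTypeSpec:
    """A cell type: the programs it expresses and its per-condition share."""

    name: str
    programs: list
    composition: dict  # condition -> fraction


@dataclass
class DualFeatureSpec:
    """A planted dual-feature population inside a host cell type.

    Member cells multiplicatively elevate BOTH their lineage program and
    the phagocytosis program (programs the host type already expresses
    are left at the host level), so they are genuinely co-expressing
    cells rather than doublet-like mixtures.
    """

    name: str
    host_type: str
    lineage_program: str
    phago_program: str = "phagocytosis"
    fraction: float = 0.05
    lineage_log2_effect: float = 4.0
    phago_log2_effect: float = 4.0


@dataclass
class GeneratorConfig:
    n_genes: int = 2000
    n_cells: dict = field(default_factory=lambda: {"normal": 1000, "inflamed": 1000})
    programs: dict = field(default_factory=dict)  # name -> list of gene indices
    cell_types: list = field(default_factory=list)
    dual_specs: list = field(default_factory=list)
    gene_names: list = field(default_factory=list)
    program_log2_effect: float = 4.0
    dispersion: float = 5.0
    libsize_log_mean: float = math.log(2500.0)
    libsize_log_sigma: float = 0.25
    mito_program: str = "mito"
    mito_fraction: float = 0.05
    doublet_rate: float = 0.05
    # a droplet holding two cells captures both cells' transcripts, so the
    # summed parent counts are thinned to this multiple of a fresh
    # library-size draw (realized doublet libraries ~1.5-2x a singlet's)
    doublet_libsize_factor: float = 2.0
    samples_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        for name, idx in self.programs.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_genes):
                raise ConfigError(f"program {name!r} has gene index out of range")
        for cond in self.n_cells:
            total = sum(t.composition.get(cond, 0.0) for t in self.cell_types)
            if self.cell_types and abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"compositions for condition {cond!r} sum to {total}, not 1"
                )
        for t in self.cell_types:
            for p in t.programs:
                if p not in self.programs:
                    raise ConfigError(f"cell type {t.name!r}: unknown program {p!r}")
        for d in self.dual_specs:
            if not 0 <= d.fraction <= 1:
                raise ConfigError(f"dual spec {d.name!r}: fraction outside [0,1]")
            if d.lineage_log2_effect < 0 or d.phago_log2_effect < 0:
                raise ConfigError(f"dual spec {d.name!r}: negative effect size")
            for p in (d.lineage_program, d.phago_program):
                if p not in self.programs:
                    raise ConfigError(f"dual spec {d.name!r}: unknown program {p!r}")
            if d.host_type not in {t.name for t in self.cell_types}:
                raise ConfigError(f"dual spec {d.name!r}: unknown host type")
        if self.program_log2_effect < 0:
            raise ConfigError("program_log2_effect must be >= 0")
        if not 0 <= self.doublet_rate < 1:
            raise ConfigError("doublet_rate must be in [0, 1)")
        if not 0 <= self.mito_fraction < 1:
            raise ConfigError("mito_fraction must be in [0, 1)")


@dataclass
class TruthTable:
    """Planted ground truth: per-cell labels and per-gene program map."""

    cells: pd.DataFrame  # index cell_id: truth_type, dual, dual_name, doublet, parent_types
    genes: pd.DataFrame  # index gene_id: programs, mito


# ---------------------------------------------------------------------------
# Default study-shaped configuration
# ---------------------------------------------------------------------------

_NAMED_GENES = {
    "neutrophil": ["Cxcr2", "Il1r2", "S100a8"],
    "macrophage": ["Csf1r", "Ccl3", "Il1b", "Igf1", "C1qc"],
    "fibroblast": ["Col1a1", "Sfrp4", "Csf1", "Pdgfra"],
    "epithelial": ["Epcam", "Krt18", "Cxcl1", "Il34", "Igf1r"],
    "T": ["Cd3e", "Ccr5"],
    "dendritic": ["Flt3", "Cd83"],
    "endothelial": ["Pecam1", "Cdh5"],
    "B": ["Cd79a", "Ms4a1"],
    "phagocytosis": ["Cd68", "Cd14"],
    "proliferation": ["Mki67", "Ccna2", "Ccnb1", "Cdk1", "Aspm"],
    "osteoblastic": ["Bmp5", "Cdh11", "Col5a2", "Col12a1", "Mmp2"],
    "M1": ["Nos2", "Tnf", "Il6", "Cd86"],
    "M2": ["Mrc1", "Cd163", "Arg1", "Retnla"],
}

_MITO_NAMES = ["Mt-nd1", "Mt-nd2", "Mt-co1", "Mt-co2", "Mt-co3",
               "Mt-atp6", "Mt-cyb", "Mt-nd4", "Mt-nd5", "Mt-rnr1"]

# normal mucosa: epithelium + fibroblasts are ~two thirds of cells;
# inflamed mucosa: neutrophils + macrophages dominate.
_COMPOSITION = {
    "epithelial":  {"normal": 0.36, "inflamed": 0.12},
    "fibroblast":  {"normal": 0.32, "inflamed": 0.08},
    "neutrophil":  {"normal": 0.04, "inflamed": 0.35},
    "macrophage":  {"normal": 0.05, "inflamed": 0.25},
    "T":           {"normal": 0.06, "inflamed": 0.07},
    "dendritic":   {"normal": 0.05, "inflamed": 0.05},
    "endothelial": {"normal": 0.08, "inflamed": 0.05},
    "B":           {"normal": 0.04, "inflamed": 0.03},
}

# programs beyond the lineage marker block expressed by each type:
# professional phagocytes carry the phagocytosis program, and the
# macrophages of this tissue skew M2.
_EXTRA_PROGRAMS = {
    "macrophage": ["phagocytosis", "M2"],
    "dendritic": ["phagocytosis"],
}


def default_study_config(n_genes: int = 2000, n_cells_per_condition: int = 1000,
                         seed: int = 0, **overrides) -> GeneratorConfig:
    """Study-shaped defaults: 8 cell types, 3 dual-feature populations.

    Block layout: 40-gene marker programs for the 8 types, a 40-gene
    phagocytosis program, 40-gene proliferation and osteoblastic
    programs, 20-gene M1/M2 polarization programs, and 10 mitochondrial
    genes; the remainder are housekeeping genes.
    """
    blocks = [("neutrophil", 40), ("macrophage", 40), ("fibroblast", 40),
              ("epithelial", 40), ("T", 40), ("dendritic", 40),
              ("endothelial", 40), ("B", 40), ("phagocytosis", 40),
              ("proliferation", 40), ("osteoblastic", 40),
              ("M1", 20), ("M2", 20), ("mito", 10)]
    needed = sum(n for _, n in blocks)
    if n_genes < needed + 100:
        raise ConfigError(f"n_genes must be at least {needed + 100}")
    programs, gene_names, start = {}, [], 0
    for name, size in blocks:
        programs[name] = list(range(start, start + size))
        if name == "mito":
            named = _MITO_NAMES[:size]
        else:
            named = _NAMED_GENES.get(name, [])
        for j in range(size):
            if j < len(named):
                gene_names.append(named[j])
            else:
                gene_names.append(f"{name.capitalize()}g{j + 1}")
        start += size
    gene_names.extend(f"Gene{i + 1:04d}" for i in range(n_genes - start))

    cell_types = [
        CellTypeSpec(name, [name] + _EXTRA_PROGRAMS.get(name, []), dict(comp))
        for name, comp in _COMPOSITION.items()
    ]
    dual_specs = [
        DualFeatureSpec("mki67_progenitor", "epithelial", "proliferation"),
        DualFeatureSpec("epithelial_phagocyte", "epithelial", "epithelial"),
        DualFeatureSpec("osteoblastic_stromal", "fibroblast", "osteoblastic"),
    ]
    kwargs = dict(
        n_genes=n_genes,
        n_cells={"normal": n_cells_per_condition, "inflamed": n_cells_per_condition},
        programs=programs,
        cell_types=cell_types,
        dual_specs=dual_specs,
        gene_names=gene_names,
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def signatures_from_config(config: GeneratorConfig) -> list:
    """One gene signature per program, using the generated gene names."""
    names = config.gene_names or [f"Gene{i + 1:04d}" for i in range(config.n_genes)]
    return [
        GeneSignature(prog, [names[i] for i in idx])
        for prog, idx in config.programs.items()
        if prog != config.mito_program and len(idx) > 0
    ]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _base_weights(config: GeneratorConfig, rng) -> np.ndarray:
    w = rng.lognormal(0.0, 1.0, config.n_genes)
    mito = np.asarray(config.programs.get(config.mito_program, []), dtype=int)
    if mito.size and config.mito_fraction > 0:
        non_mito = np.setdiff1d(np.arange(config.n_genes), mito)
        target = config.mito_fraction / (1 - config.mito_fraction) * w[non_mito].sum()
        w[mito] *= target / w[mito].sum()
    return w


def generate_dataset(config: GeneratorConfig):
    """Draw counts for both conditions; returns (matrix, cell_table, truth).

    Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w = _base_weights(config, rng)
    type_names = [t.name for t in config.cell_types]
    type_by_name = {t.name: t for t in config.cell_types}
    mult_effect = 2.0 ** config.program_log2_effect

    counts_blocks, cell_rows = [], []
    for cond in CONDITIONS:
        if cond not in config.n_cells:
            continue
        n = int(config.n_cells[cond])
        probs = np.array([type_by_name[t].composition.get(cond, 0.0)
                          for t in type_names])
        types = rng.choice(np.asarray(type_names, dtype=object), size=n, p=probs)

        # dual-feature membership: floor(fraction * n_host) per spec,
        # drawn without replacement and disjoint across specs
        dual_name = np.full(n, "", dtype=object)
        taken = np.zeros(n, dtype=bool)
        for spec in config.dual_specs:
            host_idx = np.flatnonzero((types == spec.host_type) & ~taken)
            k = int(np.floor(spec.fraction * np.sum(types == spec.host_type)))
            chosen = rng.permutation(host_idx)[:k]
            dual_name[chosen] = spec.name
            taken[chosen] = True

        # multiplicative program elevation
        mult = np.ones((n, config.n_genes))
        for t in config.cell_types:
            rows = np.flatnonzero(types == t.name)
            if rows.size == 0:
                continue
            for prog in t.programs:
                mult[np.ix_(rows, config.programs[prog])] *= mult_effect
        for spec in config.dual_specs:
            rows = np.flatnonzero(dual_name == spec.name)
            if rows.size == 0:
                continue
            host_programs = set(type_by_name[spec.host_type].programs)
            if spec.lineage_program not in host_programs:
                idx = config.programs[spec.lineage_program]
                mult[np.ix_(rows, idx)] *= 2.0 ** spec.lineage_log2_effect
            if spec.phago_program not in host_programs:
                idx = config.programs[spec.phago_program]
                mult[np.ix_(rows, idx)] *= 2.0 ** spec.phago_log2_effect

        profile = w[None, :] * mult
        profile /= profile.sum(axis=1, keepdims=True)
        libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sigma, n)
        mu = libsize[:, None] * profile
        lam = rng.gamma(config.dispersion, mu / config.dispersion)
        counts = rng.poisson(lam).astype(np.int64)

        # doublets: sum two random singlet parents, thin back to a
        # freshly drawn single-cell library size
        doublet = np.zeros(n, dtype=bool)
        parent_types = np.full(n, "", dtype=object)
        n_doub = int(round(config.doublet_rate * n))
        if n_doub:
            doub_idx = rng.choice(n, size=n_doub, replace=False)
            singlets = np.setdiff1d(np.arange(n), doub_idx)
            p1 = rng.choice(singlets, size=n_doub)
            p2 = rng.choice(singlets, size=n_doub)
            summed = counts[p1] + counts[p2]
            targets = config.doublet_libsize_factor * rng.lognormal(
                config.libsize_log_mean, config.libsize_log_sigma, n_doub)
            totals = summed.sum(axis=1)
            p_thin = np.clip(targets / np.maximum(totals, 1), 0.0, 1.0)
            counts[doub_idx] = rng.binomial(summed, p_thin[:, None])
            doublet[doub_idx] = True
            parent_types[doub_idx] = [f"{types[a]}+{types[b]}"
                                      for a, b in zip(p1, p2)]
            types[doub_idx] = types[p1]
            dual_name[doub_idx] = ""

        counts_blocks.append(counts)
        start = len(cell_rows)
        for i in range(n):
            cell_rows.append({
                "cell_id": f"{cond}_{i:05d}",
                "sample_id": f"{cond}_{i % config.samples_per_condition + 1}",
                "condition": cond,
                "truth_type": types[i],
                "truth_dual": bool(dual_name[i]),
                "dual_name": dual_name[i],
                "doublet": bool(doublet[i]),
                "parent_types": parent_types[i],
            })
        logger.info("generated %d cells (%d doublets) for condition %s",
                    n, n_doub, cond)

    cells = pd.DataFrame(cell_rows).set_index("cell_id")
    gene_names = list(config.gene_names) if config.gene_names else [
        f"Gene{i + 1:04d}" for i in range(config.n_genes)]
    all_counts = np.vstack(counts_blocks)  # cells x genes
    matrix = ExpressionMatrix(
        np.asarray(gene_names, dtype=object),
        cells.index.to_numpy(dtype=object),
        sp.csr_matrix(all_counts.T),
        layer="raw",
    )

    prog_per_gene = [[] for _ in range(config.n_genes)]
    for prog, idx in config.programs.items():
        for i in idx:
            prog_per_gene[i].append(prog)
    mito_idx = set(config.programs.get(config.mito_program, []))
    genes = pd.DataFrame({
        "gene_id": gene_names,
        "programs": [";".join(p) for p in prog_per_gene],
        "mito": [i in mito_idx for i in range(config.n_genes)],
    }).set_index("gene_id")

    truth = TruthTable(cells=cells.copy(), genes=genes)
    cell_table = new_cell_table(
        cells.index,
        sample_id=cells["sample_id"].to_numpy(),
        condition=cells["condition"].to_numpy(),
        truth_type=cells["truth_type"].to_numpy(),
        truth_dual=cells["truth_dual"].to_numpy(),
        dual_name=cells["dual_name"].to_numpy(),
        doublet=cells["doublet"].to_numpy(),
    )
    return matrix, cell_table, truth
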