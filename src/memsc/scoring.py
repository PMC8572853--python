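"""Cell Score: signature scoring against expression-binned controls.

For a target gene set Gt, all genes are partitioned into ``n_bins``
(default 25) bins of near-equal size by their mean expression across
all cells.  For each target gene, ``n_ctrl`` (default 100) control
genes are drawn at random, without replacement, from that gene's bin
(signature genes excluded); the pooled control multiset is Gc.  The
score of a cell is

    CS = mean over Gt of expression - mean over Gc of expression,

computed on the log-normalized ("relative expression") layer.  Binned
controls make the null expectation of CS zero for an arbitrary gene
set, regardless of its overall expression level.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import NORMALIZED, ExpressionMatrix, GeneSignature, ValidationError

logger = logging.getLogger("memsc")


@dataclass
class BinAssignment:
    """Partition of all genes into expression bins 1..n_bins."""

    n_bins: int
    bin_of: dict  # gene id -> bin index (1-based)
    bins: list = field(default_factory=list)  # index b-1 -> list of gene ids

    def genes_in_bin(self, b: int) -> list:
        return self.bins[b - 1]


@dataclass
class ControlSet:
    """Per-target control draws and the pooled control multiset Gc."""

    per_target: dict  # target gene -> list of control genes
    n_ctrl: int
    seed: int

    @property
    def pooled(self) -> list:
        out = []
        for target in self.per_target:
            out.extend(self.per_target[target])
        return out


def assign_bins(matrix: ExpressionMatrix, n_bins: int = 25) -> BinAssignment:
    """Equal-size rank bins of mean normalized expression.

    Genes are ranked by mean expression (ties broken by gene id,
    ascending) and the rank order is cut into ``n_bins`` contiguous
    groups; when ``n_genes`` is not divisible, the remainder ``r`` genes
    are distributed one extra to the ``r`` lowest bins.  Bin ``n_bins``
    therefore holds the most expressed genes.
    """
    if matrix.layer != NORMALIZED:
        raise ValidationError("assign_bins expects the normalized layer")
    n_genes = matrix.n_genes
    if n_bins > n_genes:
        raise ValidationError(f"n_bins={n_bins} exceeds n_genes={n_genes}")
    means = matrix.gene_means()
    order = sorted(range(n_genes),
                   key=lambda i: (means[i], str(matrix.gene_ids[i])))
    base, rem = divmod(n_genes, n_bins)
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    bins, bin_of, pos = [], {}, 0
    for b, size in enumerate(sizes, start=1):
        members = [matrix.gene_ids[i] for i in order[pos:pos + size]]
        bins.append(members)
        for g in members:
            bin_of[g] = b
        pos += size
    return BinAssignment(n_bins=n_bins, bin_of=bin_of, bins=bins)


def _effective_targets(signature: GeneSignature, bins: BinAssignment) -> list:
    present = [g for g in signature.genes if g in bins.bin_of]
    missing = [g for g in signature.genes if g not in bins.bin_of]
    if missing:
        logger.warning("signature %s: %d/%d genes absent from matrix: %s",
                       signature.name, len(missing), len(signature.genes),
                       ", ".join(map(str, missing[:10])))
    if not present:
        raise ValidationError(
            f"signature {signature.name!r}: no genes present in the matrix")
    return present


def sample_controls(bins: BinAssignment, signature: GeneSignature,
                    n_ctrl: int = 100, seed: int = 0) -> ControlSet:
    """Draw expression-matched control genes for each target gene.

    For each target, ``min(n_ctrl, available)`` genes are sampled
    uniformly without replacement from the target's bin excluding every
    signature gene.  Deterministic given ``seed``.
    """
    targets = _effective_targets(signature, bins)
    sig_set = set(signature.genes)
    rng = np.random.default_rng(seed)
    per_target = {}
    for target in targets:
        b = bins.bin_of[target]
        pool = [g for g in bins.genes_in_bin(b) if g not in sig_set]
        if not pool:
            raise ValidationError(
                f"bin {b} holds no non-signature genes for target {target!r}")
        k = min(n_ctrl, len(pool))
        if k == len(pool):
            drawn = list(pool)
        else:
            drawn = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        per_target[target] = drawn
    return ControlSet(per_target=per_target, n_ctrl=n_ctrl, seed=seed)


def _mean_over(matrix: ExpressionMatrix, genes: list) -> np.ndarray:
    index = matrix.gene_index()
    rows = np.asarray([index[g] for g in genes], dtype=int)
    return np.asarray(matrix.values[rows, :].mean(axis=0)).ravel()


def score_cells(matrix: ExpressionMatrix, signature: GeneSignature,
                bins: BinAssignment | None = None, n_ctrl: int = 100,
                seed: int = 0, n_bins: int = 25,
                controls: ControlSet | None = None) -> np.ndarray:
    """Cell Scores of one signature: mean(Gt) - mean(pooled Gc) per cell."""
    if matrix.layer != NORMALIZED:
        raise ValidationError("score_cells expects the normalized layer")
    if bins is None:
        bins = assign_bins(matrix, n_bins=n_bins)
    targets = _effective_targets(signature, bins)
    if controls is None:
        controls = sample_controls(bins, signature, n_ctrl=n_ctrl, seed=seed)
    return _mean_over(matrix, targets) - _mean_over(matrix, controls.pooled)


def per_target_differences(matrix: ExpressionMatrix, signature: GeneSignature,
                           bins: BinAssignment | None = None, n_ctrl: int = 100,
                           seed: int = 0, n_bins: int = 25) -> pd.Series:
    """Across-cell mean of (target - own controls) for each target gene.

    The across-cell mean CS equals the mean of these per-target
    differences whenever every target draws the same number of
    controls, so their spread gives a standard error for testing the
    mean CS against zero that includes the control-draw and
    target-sampling variance (the across-cell SE alone omits both).
    """
    if bins is None:
        bins = assign_bins(matrix, n_bins=n_bins)
    controls = sample_controls(bins, signature, n_ctrl=n_ctrl, seed=seed)
    out = {}
    for target, ctrl in controls.per_target.items():
        out[target] = float(_mean_over(matrix, [target]).mean()
                            - _mean_over(matrix, ctrl).mean())
    return pd.Series(out, name=signature.name)


def signature_seed(seed: int, name: str) -> int:
    """Stable per-signature substream seed (independent of list order)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(str(name).encode())])
    return int(ss.generate_state(1)[0]) % (2 ** 31)


def score_many(matrix: ExpressionMatrix, signatures: list,
               bins: BinAssignment | None = None, n_ctrl: int = 100,
               seed: int = 0, n_bins: int = 25) -> pd.DataFrame:
    """Score several signatures; one column each, independent controls.

    Each signature draws its controls from a substream derived from
    ``(seed, signature name)``, so a column is identical to running
    :func:`score_cells` alone with :func:`signature_seed`.
    """
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate signature names")
    if bins is None:
        bins = assign_bins(matrix, n_bins=n_bins)
    table = pd.DataFrame(index=pd.Index(matrix.cell_ids, name="cell_id"))
    for sig in signatures:
        table[sig.name] = score_cells(
            matrix, sig, bins=bins, n_ctrl=n_ctrl,
            seed=signature_seed(seed, sig.name))
    table.attrs["n_bins"] = bins.n_bins
    table.attrs["n_ctrl"] = n_ctrl
    table.attrs["seed"] = seed
    table.attrs["layer"] = matrix.layer
    return table
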