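"""Cell Score: binning, control sampling, and score properties."""

import numpy as np
import pandas as pd
import pytest

from memsc.scoring import (
    assign_bins,
    per_target_differences,
    sample_controls,
    score_cells,
    score_many,
    signature_seed,
)
from memsc.types import GeneSignature, ValidationError
from tests.conftest import make_matrix


def _ladder_matrix(n_genes, n_cells=4, seed=0):
    """Matrix whose gene means are distinct and increasing with index."""
    rng = np.random.default_rng(seed)
    base = np.linspace(0.1, 5.0, n_genes)[:, None]
    noise = rng.uniform(0.0, 0.01, size=(n_genes, n_cells))
    return make_matrix(base + noise)


class TestBins:
    def test_even_split(self):
        bins = assign_bins(_ladder_matrix(250), n_bins=25)
        assert [len(b) for b in bins.bins] == [10] * 25

    def test_remainder_goes_to_lowest_bins(self):
        bins = assign_bins(_ladder_matrix(252), n_bins=25)
        assert [len(b) for b in bins.bins] == [11, 11] + [10] * 23

    def test_highest_mean_gene_in_top_bin(self):
        m = _ladder_matrix(250)
        bins = assign_bins(m, n_bins=25)
        top_gene = m.gene_ids[np.argmax(m.gene_means())]
        assert bins.bin_of[top_gene] == 25

    def test_bins_partition_all_genes(self):
        m = _ladder_matrix(203)
        bins = assign_bins(m, n_bins=25)
        seen = [g for b in bins.bins for g in b]
        assert sorted(seen) == sorted(m.gene_ids)
        assert all(abs(len(a) - len(b)) <= 1
                   for a in bins.bins for b in bins.bins)

    def test_more_bins_than_genes_rejected(self):
        with pytest.raises(ValidationError):
            assign_bins(_ladder_matrix(10), n_bins=25)


class TestControls:
    def test_forced_exhaustion_is_seed_independent(self):
        m = _ladder_matrix(101)
        bins = assign_bins(m, n_bins=1)
        target = m.gene_ids[50]
        sig = GeneSignature("s", [target])
        c1 = sample_controls(bins, sig, n_ctrl=100, seed=1)
        c2 = sample_controls(bins, sig, n_ctrl=100, seed=99)
        expected = sorted(set(m.gene_ids) - {target})
        assert sorted(c1.per_target[target]) == expected
        assert sorted(c2.per_target[target]) == expected

    def test_seed_determinism_and_divergence(self):
        m = _ladder_matrix(500)
        bins = assign_bins(m, n_bins=2)
        sig = GeneSignature("s", [m.gene_ids[10]])
        a = sample_controls(bins, sig, n_ctrl=50, seed=3)
        b = sample_controls(bins, sig, n_ctrl=50, seed=3)
        c = sample_controls(bins, sig, n_ctrl=50, seed=4)
        assert a.per_target == b.per_target
        assert a.per_target != c.per_target

    def test_pooled_control_multiset_size(self):
        m = _ladder_matrix(2000)
        bins = assign_bins(m, n_bins=5)  # 400-gene bins
        sig = GeneSignature("s", list(m.gene_ids[[5, 6, 7]]))
        ctrl = sample_controls(bins, sig, n_ctrl=100, seed=0)
        assert len(ctrl.pooled) == 300

    def test_signature_genes_never_drawn_as_controls(self):
        m = _ladder_matrix(300)
        bins = assign_bins(m, n_bins=3)
        sig = GeneSignature("s", list(m.gene_ids[:30]))
        ctrl = sample_controls(bins, sig, n_ctrl=100, seed=0)
        assert not set(ctrl.pooled) & set(sig.genes)

    def test_exhausted_bin_raises(self):
        m = _ladder_matrix(50)
        bins = assign_bins(m, n_bins=5)
        whole_bin = GeneSignature("s", list(bins.bins[0]))
        with pytest.raises(ValidationError, match="bin 1"):
            sample_controls(bins, whole_bin, n_ctrl=10, seed=0)


class TestScores:
    def test_flat_within_cell_expression_scores_zero(self):
        # every gene identical within each cell, different across cells
        values = np.tile(np.array([0.5, 1.5, 2.0, 0.2]), (60, 1))
        m = make_matrix(values)
        cs = score_cells(m, GeneSignature("s", list(m.gene_ids[:7])),
                         n_bins=5, n_ctrl=4, seed=0)
        np.testing.assert_allclose(cs, 0.0, atol=1e-14)

    def test_per_cell_location_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(1, 1, size=(100, 20))
        shifted = values.copy()
        shifted[:, 3] += 2.5  # constant added to every gene of one cell
        sig = GeneSignature("s", [f"g{i:04d}" for i in range(0, 40, 4)])
        cs_a = score_cells(make_matrix(values), sig, n_bins=10, n_ctrl=5, seed=1)
        cs_b = score_cells(make_matrix(shifted), sig, n_bins=10, n_ctrl=5, seed=1)
        assert cs_b[3] == pytest.approx(cs_a[3], abs=1e-12)

    def test_exhaustive_controls_match_direct_oracle(self):
        """With n_ctrl >= bin size the score is the deterministic
        mean(Gt) - mean(pooled bin-mates), computed independently."""
        rng = np.random.default_rng(5)
        values = rng.gamma(1.0, 1.0, size=(200, 30))
        m = make_matrix(values)
        sig = GeneSignature("s", list(m.gene_ids[rng.choice(200, 12, replace=False)]))
        bins = assign_bins(m, n_bins=10)
        cs = score_cells(m, sig, bins=bins, n_ctrl=10_000, seed=0)
        # independent brute-force computation
        gi = {g: i for i, g in enumerate(m.gene_ids)}
        target_rows = [gi[g] for g in sig.genes]
        pooled = []
        for g in sig.genes:
            mates = [x for x in bins.genes_in_bin(bins.bin_of[g])
                     if x not in set(sig.genes)]
            pooled.extend(gi[x] for x in mates)
        oracle = values[target_rows].mean(axis=0) - values[pooled].mean(axis=0)
        np.testing.assert_allclose(cs, oracle, atol=1e-12)

    def test_seed_reproducibility_bit_identical(self, study):
        norm, bins = study["norm"], study["bins"]
        sig = study["signatures"]["phagocytosis"]
        a = score_cells(norm, sig, bins=bins, seed=123)
        b = score_cells(norm, sig, bins=bins, seed=123)
        assert np.array_equal(a, b)

    def test_absent_signature_genes_dropped_with_warning(self, study, caplog):
        sig = GeneSignature("s", ["Cd68", "NotARealGene"])
        with caplog.at_level("WARNING", logger="memsc"):
            cs = score_cells(study["norm"], sig, bins=study["bins"], seed=0)
        assert np.isfinite(cs).all()
        assert any("absent" in r.message for r in caplog.records)

    def test_fully_absent_signature_errors(self, study):
        with pytest.raises(ValidationError, match="no genes"):
            score_cells(study["norm"], GeneSignature("s", ["Nope1", "Nope2"]),
                        bins=study["bins"], seed=0)


class TestScoreMany:
    def test_columns_match_single_runs(self, study):
        norm, bins = study["norm"], study["bins"]
        sigs = [study["signatures"]["M1"], study["signatures"]["M2"]]
        table = score_many(norm, sigs, bins=bins, seed=77)
        assert list(table.columns) == ["M1", "M2"]
        lone = score_cells(norm, sigs[1], bins=bins,
                           seed=signature_seed(77, "M2"))
        np.testing.assert_array_equal(table["M2"].to_numpy(), lone)

    def test_duplicate_names_rejected(self, study):
        sig = study["signatures"]["M1"]
        with pytest.raises(ValidationError, match="duplicate"):
            score_many(study["norm"], [sig, sig], bins=study["bins"])

    def test_macrophages_score_m2_over_m1(self, study):
        """Macrophages planted with the M2 program score higher on M2."""
        table = score_many(study["norm"],
                           [study["signatures"]["M1"], study["signatures"]["M2"]],
                           bins=study["bins"], seed=5)
        mac = (study["table"]["truth_type"] == "macrophage").to_numpy()
        assert table["M2"].to_numpy()[mac].mean() > table["M1"].to_numpy()[mac].mean()


def test_null_calibration_gene_level(study):
    """Random signatures on null data have mean CS within 3 SE of zero,
    with the SE taken over per-target-gene differences."""
    from memsc import qc as qcmod
    from memsc.simulate import default_study_config, generate_dataset

    for seed in range(3):
        cfg = default_study_config(n_cells_per_condition=300, seed=seed,
                                   program_log2_effect=0.0, dual_specs=[],
                                   doublet_rate=0.0)
        m, _, _ = generate_dataset(cfg)
        norm = qcmod.normalize_total(m)
        rng = np.random.default_rng(100 + seed)
        sig = GeneSignature("null", list(rng.choice(norm.gene_ids, 50, replace=False)))
        d = per_target_differences(norm, sig, seed=seed)
        z = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert abs(z) <= 3.0


def test_scanpy_cross_check(study):
    """Independent implementation of binned-control scoring (scanpy's
    score_genes) ranks cells the same way on a planted signature."""
    sc = pytest.importorskip("scanpy")
    import anndata as ad
    from scipy.stats import spearmanr

    norm = study["norm"]
    sig = study["signatures"]["phagocytosis"]
    cs = score_cells(norm, sig, bins=study["bins"], n_ctrl=100, seed=0)

    adata = ad.AnnData(X=norm.values.T.tocsr())
    adata.var_names = [str(g) for g in norm.gene_ids]
    adata.obs_names = [str(c) for c in norm.cell_ids]
    sc.tl.score_genes(adata, sig.genes, ctrl_size=100, n_bins=25,
                      score_name="ref", random_state=0)
    rho = spearmanr(cs, adata.obs["ref"].to_numpy()).statistic
    assert rho > 0.95
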