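"""Dual-feature extraction, doublet heuristic, score comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from memsc import dual as df
from memsc import qc as qcmod
from memsc.config import QC_PRESETS
from memsc.scoring import assign_bins, score_many
from memsc.simulate import default_study_config, generate_dataset, signatures_from_config
from memsc.types import ValidationError, new_cell_table
from tests.conftest import make_matrix


def _cd68_matrix(counts):
    values = np.zeros((3, len(counts)))
    values[1] = counts
    m = make_matrix(values, layer="raw", gene_ids=["Actb", "Cd68", "Epcam"])
    table = new_cell_table(m.cell_ids, condition=["normal"] * len(counts))
    return m, table


class TestExtract:
    def test_threshold_rule(self):
        m, table = _cd68_matrix([0, 1, 5])
        sub, sub_table = df.extract_positive_cells(m, table, "Cd68", min_count=1)
        assert list(sub.cell_ids) == list(m.cell_ids[1:])
        assert len(sub_table) == 2

    def test_min_count_zero_is_identity(self):
        m, table = _cd68_matrix([0, 1, 5])
        sub, _ = df.extract_positive_cells(m, table, "Cd68", min_count=0)
        assert sub.n_cells == 3

    def test_no_positive_cells_warns_and_returns_empty(self, caplog):
        m, table = _cd68_matrix([0, 0, 0])
        with caplog.at_level("WARNING", logger="memsc"):
            sub, sub_table = df.extract_positive_cells(m, table, "Cd68")
        assert sub.n_cells == 0 and len(sub_table) == 0
        # downstream stages refuse an empty subset
        with pytest.raises(ValidationError):
            qcmod.normalize_total(sub)
        with pytest.raises(ValidationError):
            df.correlate_scores([], [])

    def test_absent_gene_lists_near_matches(self):
        m, table = _cd68_matrix([1, 1, 1])
        with pytest.raises(ValidationError, match="Cd68"):
            df.extract_positive_cells(m, table, "Cd6")


class TestDoubletHeuristic:
    def test_recall_and_fpr_on_planted_doublets(self):
        cfg = default_study_config(n_cells_per_condition=1000, seed=0)
        m, cells, _ = generate_dataset(cfg)
        cells = qcmod.compute_cell_qc(m, cells)
        _, table, _ = qcmod.filter_by_condition(m, cells, QC_PRESETS)
        flagged = df.flag_doublets_heuristic(table, k=3)
        truth = flagged["doublet"].to_numpy()
        call = flagged["doublet_flag"].to_numpy()
        recall = call[truth].mean()
        fpr = call[~truth].mean()
        assert recall >= 0.5
        assert fpr <= 0.05

    def test_doublets_flagged_more_than_dual_cells(self):
        """Planted doublets trip the heuristic far more often than the
        planted dual-feature cells, so dual calls survive doublet
        exclusion."""
        rates_doublet, rates_dual = [], []
        for seed in (0, 1):
            cfg = default_study_config(n_cells_per_condition=1000, seed=seed)
            m, cells, _ = generate_dataset(cfg)
            cells = qcmod.compute_cell_qc(m, cells)
            _, table, _ = qcmod.filter_by_condition(m, cells, QC_PRESETS)
            flagged = df.flag_doublets_heuristic(table)
            rates_doublet.append(
                flagged.loc[flagged["doublet"], "doublet_flag"].mean())
            rates_dual.append(
                flagged.loc[flagged["truth_dual"], "doublet_flag"].mean())
        assert np.mean(rates_doublet) > np.mean(rates_dual)
        assert np.mean(rates_dual) < 0.1

    def test_infinite_k_flags_nothing(self):
        table = new_cell_table([f"c{i}" for i in range(10)],
                               condition=["normal"] * 10,
                               n_features=np.arange(100, 1100, 100))
        out = df.flag_doublets_heuristic(table, k=math.inf)
        assert not out["doublet_flag"].any()

    def test_constant_features_flags_nothing(self):
        table = new_cell_table([f"c{i}" for i in range(10)],
                               condition=["normal"] * 10,
                               n_features=[500] * 10)
        out = df.flag_doublets_heuristic(table, k=3)
        assert not out["doublet_flag"].any()


class TestCorrelation:
    def test_affine_relation_is_perfect(self):
        a = np.linspace(0, 1, 50)
        res = df.correlate_scores(a, 2 * a + 1)
        assert res.r == pytest.approx(1.0)
        res_neg = df.correlate_scores(a, -a)
        assert res_neg.r == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        res = df.correlate_scores(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(res.r) < 0.05
        assert res.n == 10_000

    def test_zero_variance_flagged(self):
        res = df.correlate_scores([1.0, 1.0, 1.0], [0.1, 0.5, 0.9])
        assert not res.valid and np.isnan(res.r)


class TestDualCalls:
    def test_explicit_thresholds(self):
        calls = df.call_dual_feature([0.8, 0.1], [0.6, 0.9],
                                     t_lineage=0.2, t_phago=0.2)
        assert calls["dual"].tolist() == [True, False]

    def test_cell_exactly_at_threshold_not_flagged(self):
        calls = df.call_dual_feature([0.2, 0.3], [0.5, 0.2],
                                     t_lineage=0.2, t_phago=0.2)
        assert calls["dual"].tolist() == [False, False]

    def test_default_thresholds_recorded(self):
        rng = np.random.default_rng(0)
        calls = df.call_dual_feature(rng.normal(size=100), rng.normal(size=100))
        assert calls.attrs["t_lineage"] == pytest.approx(
            np.quantile(calls["lineage_score"], 0.75))

    def test_min_score_separates_planted_duals(self, study):
        """ROC AUC of min(lineage, phagocytosis) for planted
        epithelial-phagocyte cells is >= 0.9."""
        from sklearn.metrics import roc_auc_score

        sigs = study["signatures"]
        table = score_many(study["norm"], [sigs["epithelial"], sigs["phagocytosis"]],
                           bins=study["bins"], seed=3)
        truth = (study["table"]["dual_name"] == "epithelial_phagocyte").to_numpy()
        stat = np.minimum(table["epithelial"], table["phagocytosis"])
        assert roc_auc_score(truth, stat) >= 0.9

    def test_detection_improves_with_effect_size(self):
        from sklearn.metrics import roc_auc_score

        aucs = []
        for effect in (1.0, 4.0):
            cfg = default_study_config(n_cells_per_condition=400, seed=21)
            for spec in cfg.dual_specs:
                spec.phago_log2_effect = effect
                spec.lineage_log2_effect = effect
            m, cells, _ = generate_dataset(cfg)
            norm = qcmod.normalize_total(m)
            sigs = {s.name: s for s in signatures_from_config(cfg)}
            scores = score_many(norm, [sigs["proliferation"], sigs["phagocytosis"]],
                                bins=assign_bins(norm), seed=2)
            truth = (cells["dual_name"] == "mki67_progenitor").to_numpy()
            stat = np.minimum(scores["proliferation"], scores["phagocytosis"])
            aucs.append(roc_auc_score(truth, stat))
        assert aucs[0] < aucs[1]
        assert aucs[1] >= 0.9


class TestCompareDistributions:
    def test_identical_multisets_give_p_near_one(self):
        scores = np.r_[np.arange(10.0), np.arange(10.0)]
        labels = ["a"] * 10 + ["b"] * 10
        _, p, med = df.compare_score_distributions(scores, labels)
        assert p > 0.9
        assert med["a"] == med["b"]

    def test_strong_shift_is_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        _, p, _ = df.compare_score_distributions(np.r_[a, b],
                                                 ["a"] * 50 + ["b"] * 50)
        assert p < 1e-10

    def test_label_exchange_symmetric(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = np.asarray(["a"] * 15 + ["b"] * 15)
        _, p1, _ = df.compare_score_distributions(scores, labels)
        _, p2, _ = df.compare_score_distributions(scores, labels[::-1])
        assert p1 == pytest.approx(p2)

    def test_wrong_group_count_rejected(self):
        with pytest.raises(ValidationError):
            df.compare_score_distributions([1, 2, 3], ["a", "a", "a"])


class TestProportions:
    def test_simple_fractions(self):
        table = new_cell_table([f"c{i}" for i in range(10)],
                               condition=["normal"] * 10,
                               cluster=["C0"] * 6 + ["C1"] * 4)
        props = df.proportions_by_condition(table, by="cluster")
        by_label = props.set_index("cluster")["fraction"]
        assert by_label["C0"] == pytest.approx(0.6)
        assert by_label["C1"] == pytest.approx(0.4)

    def test_unlabeled_cells_counted_as_unassigned(self):
        table = new_cell_table(["c0", "c1", "c2"], condition=["normal"] * 3,
                               cluster=["C0", None, ""])
        props = df.proportions_by_condition(table, by="cluster")
        assert set(props["cluster"]) == {"C0", "unassigned"}
        assert props["count"].sum() == 3

    def test_fractions_sum_to_one_and_conserve_cells(self, study):
        table = study["table"].copy()
        table["cluster"] = table["truth_type"]
        props = df.proportions_by_condition(table, by="cluster")
        sums = props.groupby("condition")["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert props["count"].sum() == len(table)

    def test_infiltration_shift_recovered(self, study):
        """Inflamed tissue holds a larger neutrophil+macrophage share."""
        props = df.proportions_by_condition(study["table"], by="truth_type")
        pivot = props.pivot(index="truth_type", columns="condition",
                            values="fraction").fillna(0.0)
        innate = pivot.loc[["neutrophil", "macrophage"]].sum()
        assert innate["inflamed"] > innate["normal"]
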