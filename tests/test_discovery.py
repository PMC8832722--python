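"""Discovery-phase statistics: differential expression, per-miRNA AUC against
a pair-enumeration oracle, the three-criterion candidate filter, panel
overlap, and cross-validated multivariate evaluation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import auc_by_pairs
from mirsign import discovery
from mirsign.discovery import (
    ExpressionMatrix,
    FilterThresholds,
    MiRNAPanel,
    benjamini_hochberg,
    candidate_stats,
    cross_validated_auc,
    differential_expression,
    filter_candidates,
    intersect_panels,
    per_mirna_auc,
    train_apply_cross_dataset,
)
from mirsign.synthetic import TISSUE_PANEL_18, TissueDesign, simulate_tissue_dataset


def _matrix(tumor: np.ndarray, normal: np.ndarray, ids=None) -> ExpressionMatrix:
    tumor, normal = np.atleast_2d(tumor), np.atleast_2d(normal)
    values = np.concatenate([tumor, normal], axis=1)
    samples = [f"T{i}" for i in range(tumor.shape[1])] + [f"N{i}" for i in range(normal.shape[1])]
    ids = ids or [f"m{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=samples),
        labels=pd.Series(["tumor"] * tumor.shape[1] + ["normal"] * normal.shape[1], index=samples),
    )


class TestDifferentialExpression:
    def test_identical_groups_give_zero_fold_change_and_p_one(self):
        block = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        stats = differential_expression(_matrix(block, block.copy()))
        assert np.allclose(stats["log2fc"], 0.0)
        assert np.allclose(stats["p_raw"], 1.0)
        assert stats.loc["m1", "zero_variance"]

    def test_forced_unit_fold_change(self):
        rng = np.random.default_rng(0)
        tum = 2.0 + rng.normal(0, 1e-3, (1, 3))
        nor = 1.0 + rng.normal(0, 1e-3, (1, 3))
        stats = differential_expression(_matrix(tum, nor))
        assert abs(stats["log2fc"].iloc[0] - 1.0) < 0.01
        assert stats["p_raw"].iloc[0] < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            differential_expression(_matrix(np.ones((2, 1)), np.ones((2, 3))))

    def test_bh_step_up_hand_example(self):
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_bh_matches_step_up_oracle(self, pvals):
        adj = benjamini_hochberg(pvals)
        # independent step-up computation: sort, scale by n/rank, cumulative
        # minimum from the largest p down, clip at 1
        p = np.asarray(pvals, float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        scaled = p[order] * n / np.arange(1, n + 1)
        stepped = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(adj, expected, atol=1e-12)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in raw order
        assert np.all(adj >= p - 1e-12)


class TestPerMiRNAAuc:
    @pytest.mark.parametrize(
        "tumor,normal,expected",
        [
            ([2.0, 3.0], [1.0, 2.0], 0.875),
            ([5.0, 6.0, 7.0], [1.0, 2.0], 1.0),
            ([3.0, 3.0], [3.0, 3.0, 3.0], 0.5),
        ],
    )
    def test_hand_examples(self, tumor, normal, expected):
        auc = per_mirna_auc(_matrix(np.array([tumor]), np.array([normal])))
        assert auc.iloc[0] == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
    )
    def test_matches_pair_enumeration(self, tumor, normal):
        auc = per_mirna_auc(_matrix(np.array([tumor], float), np.array([normal], float)))
        assert auc.iloc[0] == pytest.approx(auc_by_pairs(tumor, normal), abs=1e-12)


class TestFilterCandidates:
    @staticmethod
    def _stats():
        return pd.DataFrame(
            {
                "log2fc": [0.6, 0.4, 0.6],
                "p_adj": [0.01, 0.01, 0.01],
                "auc": [0.8, 0.9, 0.65],
                "mean_expr": [10.0, 10.0, 8.0],
            },
            index=["A", "B", "C"],
        )

    def test_direct_rule_application(self):
        panel = filter_candidates(self._stats())
        assert panel.mirna_ids == ["A"]

    def test_row_order_invariance(self):
        stats = self._stats()
        shuffled = stats.loc[["C", "A", "B"]]
        assert filter_candidates(stats).mirna_ids == filter_candidates(shuffled).mirna_ids

    def test_no_de_pass_gives_empty_panel_with_warning(self):
        stats = self._stats()
        stats["p_adj"] = 0.9
        with pytest.warns(UserWarning, match="empty panel"):
            panel = filter_candidates(stats)
        assert panel.mirna_ids == []

    def test_planted_panel_passes_in_each_dataset(self, tissue_matrices):
        for mat in tissue_matrices.values():
            panel = filter_candidates(candidate_stats(mat))
            assert set(TISSUE_PANEL_18) <= set(panel.mirna_ids)
            # every extra candidate is a planted dataset-specific distractor
            extras = set(panel.mirna_ids) - set(TISSUE_PANEL_18)
            assert all(("decoy" in m or "lowde" in m) for m in extras)


class TestIntersect:
    def test_ordered_intersection(self):
        panels = [MiRNAPanel(list(p)) for p in (["a", "b", "c"], ["b", "c", "d"], ["c", "b"])]
        assert intersect_panels(panels).mirna_ids == ["b", "c"]

    def test_disjoint_empty(self):
        assert intersect_panels([MiRNAPanel(["a"]), MiRNAPanel(["b"])]).mirna_ids == []

    def test_recovers_planted_overlap_exactly(self, overlap_panel):
        assert sorted(overlap_panel.mirna_ids) == sorted(TISSUE_PANEL_18)


class TestCrossValidation:
    def test_planted_signal_highly_discriminative(self, tissue_matrices, overlap_panel):
        cv = cross_validated_auc(tissue_matrices["tcga"], overlap_panel, repeats=20, seed=4)
        assert cv.mean_auc >= 0.95

    def test_permuted_labels_near_chance(self):
        mat = simulate_tissue_dataset(
            TissueDesign(n_tumor=50, n_normal=50, n_mirna=120, planted_log2fc=0.0,
                         n_decoy=5, n_low_abundance_de=5, seed=9)
        )
        panel = MiRNAPanel(list(mat.values.index[:5]))
        cv = cross_validated_auc(mat, panel, repeats=50, seed=10)
        assert abs(cv.mean_auc - 0.5) < 0.05

    def test_same_seed_reproduces_per_repeat_aucs(self, tissue_matrices, overlap_panel):
        a = cross_validated_auc(tissue_matrices["tcga"], overlap_panel, repeats=5, seed=42)
        b = cross_validated_auc(tissue_matrices["tcga"], overlap_panel, repeats=5, seed=42)
        assert np.array_equal(a.per_repeat_auc, b.per_repeat_auc)


class TestTrainApply:
    def test_transfer_of_shared_signal(self, tissue_matrices, overlap_panel):
        train = tissue_matrices["ds55856"]
        aucs, _ = train_apply_cross_dataset(train, tissue_matrices.values(), overlap_panel)
        assert all(a >= 0.9 for a in aucs.values())
        # resubstitution on the training dataset is at least as optimistic
        cv = cross_validated_auc(train, overlap_panel, repeats=10, seed=0)
        assert aucs["ds55856"] >= cv.mean_auc - 1e-9

    def test_train_only_signal_does_not_transfer(self):
        signal = simulate_tissue_dataset(TissueDesign(dataset_id="sig", seed=1))
        null = simulate_tissue_dataset(TissueDesign(dataset_id="null", planted_log2fc=0.0, seed=2))
        panel = MiRNAPanel(list(TISSUE_PANEL_18[:8]))
        aucs, _ = train_apply_cross_dataset(signal, [null], panel)
        assert abs(aucs["null"] - 0.5) < 0.1

    def test_missing_panel_member_lists_ids(self, tissue_matrices, overlap_panel):
        bad = MiRNAPanel(overlap_panel.mirna_ids + ["miR-unseen"])
        with pytest.raises(ValueError, match="miR-unseen"):
            train_apply_cross_dataset(tissue_matrices["tcga"], [], bad)
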