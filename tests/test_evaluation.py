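"""Performance statistics against independent oracles: pair-enumeration AUC,
brute-force DeLong structural components, bootstrap behaviour, confusion
matrices, subgroup/premalignant analyses and marker regression."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import auc_by_pairs, delong_variance_by_components, scores_and_meta
from mirsign import evaluation as ev
from mirsign.signature import load_frozen_model
from mirsign.synthetic import SERUM_PANEL_8


class TestRocAuc:
    def test_tied_pairs_hand_example(self):
        summary = ev.roc_auc([2.0, 3.0, 1.0, 2.0], ["case", "case", "control", "control"])
        assert summary.auc == pytest.approx(0.875)

    def test_separable_and_anti_separable(self):
        assert ev.roc_auc([5, 6, 1, 2], [1, 1, 0, 0]).auc == 1.0
        with pytest.warns(UserWarning, match="oriented"):
            assert ev.roc_auc([1, 2, 5, 6], [1, 1, 0, 0]).auc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.roc_auc([1, 2], [1, 1])

    def test_curve_bounds_and_trapezoid_equality(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.normal(size=60), 1)  # rounding forces ties
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        summary = ev.roc_auc(scores + labels, labels)
        curve = summary.curve
        assert curve.iloc[0].tolist() == [0.0, 0.0]
        assert curve.iloc[-1].tolist() == [1.0, 1.0]
        assert np.all(np.diff(curve["fpr"]) >= 0) and np.all(np.diff(curve["tpr"]) >= 0)
        assert summary.auc == pytest.approx(np.trapezoid(curve["tpr"], curve["fpr"]), abs=1e-10)

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=8),
        st.lists(st.integers(0, 8), min_size=2, max_size=8),
    )
    def test_auc_invariant_under_monotone_transform(self, cases, controls):
        scores = np.array(cases + controls, dtype=float)
        labels = np.array([1] * len(cases) + [0] * len(controls))
        a = ev.mann_whitney_auc(scores[labels == 1], scores[labels == 0])
        t = np.exp(scores / 2.0) + 3.0
        b = ev.mann_whitney_auc(t[labels == 1], t[labels == 0])
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(auc_by_pairs(cases, controls), abs=1e-12)


class TestBootstrap:
    def test_separable_data_hits_ceiling(self):
        lo, hi = ev.bootstrap_ci([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0], n_boot=200, seed=0)
        assert hi == 1.0

    def test_seed_reproducibility(self):
        scores = np.random.default_rng(1).normal(size=40)
        labels = [1] * 20 + [0] * 20
        assert ev.bootstrap_ci(scores, labels, seed=3) == ev.bootstrap_ci(scores, labels, seed=3)

    def test_null_coverage(self):
        """CI covers 0.5 for null scores in >= 93% of simulation replicates."""
        rng = np.random.default_rng(12)
        labels = np.array([1] * 200 + [0] * 200)
        n_rep = 400
        covered = 0
        for rep in range(n_rep):
            scores = rng.normal(size=400)
            lo, hi = ev.bootstrap_ci(scores, labels, n_boot=1000, seed=rep)
            covered += lo <= 0.5 <= hi
        assert covered / n_rep >= 0.93

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)
        widths = {}
        for n in (200, 800):
            scores = np.concatenate([rng.normal(0.5, 1, n // 2), rng.normal(0, 1, n // 2)])
            labels = [1] * (n // 2) + [0] * (n // 2)
            lo, hi = ev.bootstrap_ci(scores, labels, n_boot=1000, seed=n)
            widths[n] = hi - lo
        assert widths[800] < widths[200]


class TestDeLong:
    def test_identical_scores_give_null_comparison(self):
        scores = [0.3, 0.6, 0.2, 0.1, 0.9, 0.4]
        labels = [1, 1, 1, 0, 0, 0]
        res = ev.delong_test(scores, scores, labels, paired=True)
        assert res.z_statistic == 0.0 and res.p_value == 1.0

    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
    )
    def test_variance_matches_brute_force_oracle(self, cases, controls):
        scores = np.array(cases + controls, dtype=float)
        labels = [1] * len(cases) + [0] * len(controls)
        assert ev.delong_variance(scores, labels) == pytest.approx(
            delong_variance_by_components(cases, controls), abs=1e-12
        )

    def test_z_sign_matches_auc_difference(self):
        rng = np.random.default_rng(8)
        labels = np.array([1] * 50 + [0] * 50)
        strong = labels * 1.5 + rng.normal(size=100)
        weak = labels * 0.2 + rng.normal(size=100)
        res = ev.delong_test(strong, weak, labels, paired=True)
        assert (res.auc_a - res.auc_b) * res.z_statistic > 0

    def test_planted_signature_beats_marker(self, serum_study):
        frame, meta = scores_and_meta(serum_study, "validation")
        res = ev.delong_test(
            frame["probability"].to_numpy(),
            meta["scc_ag"].to_numpy(),
            meta["group"],
            paired=True,
        )
        assert res.auc_a > res.auc_b
        assert res.p_value < 0.01

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            ev.delong_test([1.0, 0.0], [0.5, 0.4], [1, 0], paired=True)


class TestConfusion:
    def test_all_correct(self):
        cm = ev.confusion_matrix(["high", "high", "low"], ["case", "case", "control"])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 0, 1, 0)

    def test_hand_rates(self):
        pred = ["high"] * 9 + ["low"] * 1 + ["low"] * 8 + ["high"] * 2
        labels = ["case"] * 10 + ["control"] * 10
        cm = ev.confusion_matrix(pred, labels)
        assert cm.sensitivity == pytest.approx(0.9)
        assert cm.specificity == pytest.approx(0.8)

    def test_empty_prediction_class_flags_undefined_ppv(self):
        cm = ev.confusion_matrix(["low", "low"], ["case", "control"])
        assert np.isnan(cm.ppv)
        assert "ppv" in cm.undefined_rates


class TestSubgroupsAndGroups:
    def test_all_stage_subgroup_equals_full_roc(self, serum_study):
        frame, meta = scores_and_meta(serum_study, "validation")
        scores = frame["probability"].to_numpy()
        full = ev.roc_auc(scores, meta["group"])
        sub = ev.subgroup_eval(scores, meta["group"], meta["stage"], ["I", "II", "III", "IV"])
        assert sub.auc == pytest.approx(full.auc)

    def test_stage_graded_effect_orders_aucs(self, serum_study):
        frame, meta = scores_and_meta(serum_study, "validation")
        scores = frame["probability"].to_numpy()
        auc_i = ev.subgroup_eval(scores, meta["group"], meta["stage"], ["I"]).auc
        auc_iv = ev.subgroup_eval(scores, meta["group"], meta["stage"], ["IV"]).auc
        assert auc_i < auc_iv

    def test_empty_subgroup_rejected(self, serum_study):
        frame, meta = scores_and_meta(serum_study, "validation")
        with pytest.raises(ValueError, match="no cases"):
            ev.subgroup_eval(frame["probability"].to_numpy(), meta["group"], meta["stage"], ["HGIN"])

    def test_copied_group_is_null(self):
        rng = np.random.default_rng(3)
        healthy = rng.normal(size=200)
        scores = np.concatenate([healthy, healthy])
        stages = np.array(["healthy"] * 200 + ["copied"] * 200)
        p = ev.group_compare(scores, stages)["copied"]
        assert 0.4 < p < 0.6

    def test_premalignant_pattern(self, serum_study):
        frame, meta = scores_and_meta(serum_study, "premalignant")
        p = ev.group_compare(frame["probability"].to_numpy(), meta["stage"].to_numpy())
        assert p["HGIN"] < 0.01
        assert p["LGIN"] > 0.05 and p["esophagitis"] > 0.05

    def test_tiny_group_rejected(self):
        scores = np.arange(5.0)
        stages = np.array(["healthy", "healthy", "healthy", "healthy", "I"])
        with pytest.raises(ValueError, match="fewer than 2"):
            ev.group_compare(scores, stages, groups=["I"])


class TestMarkerRegression:
    def test_null_predictor_or_ci_covers_one(self):
        rng = np.random.default_rng(9)
        predictors = pd.DataFrame({"x": rng.normal(size=400)})
        y = rng.integers(0, 2, 400)
        row = ev.marker_regression(predictors, y, mode="univariate").loc["x"]
        assert row["or_ci_low"] <= 1.0 <= row["or_ci_high"]

    def test_only_planted_signature_significant_multivariately(self, serum_study):
        # comparator markers planted with no discriminative power (AUC 0.5)
        from mirsign.synthetic import SerumDesign, child_seed, simulate_serum_cohort
        from mirsign.quantification import (
            CtTable, NormalizationScheme, delta_delta_ct, impute_undetermined,
        )
        from mirsign.signature import score, scores_frame

        design = SerumDesign(
            n_case=200, n_control=200,
            marker_auc={"cea": 0.5, "ca72_4": 0.5},
            seed=child_seed("null-marker-cohort", 1),
        )
        ct, meta = simulate_serum_cohort(design)
        table, _ = impute_undetermined(CtTable(ct))
        meta = meta.set_index("sample_id")
        expr = delta_delta_ct(table, NormalizationScheme(["miR-16"]), groups=meta["group"].to_dict())
        frame = scores_frame(score(serum_study["model"], expr))
        meta = meta.loc[frame.index]
        predictors = pd.DataFrame(
            {
                "signature": frame["logit"].to_numpy(),
                "cea": np.log(meta["cea"].to_numpy()),
                "ca72_4": np.log(meta["ca72_4"].to_numpy()),
            },
            index=frame.index,
        )
        table = ev.marker_regression(predictors, meta["group"], mode="multivariate")
        assert table.loc["signature", "p_value"] < 0.001
        assert table.loc["cea", "p_value"] > 0.05
        assert table.loc["ca72_4", "p_value"] > 0.05

    def test_duplicate_predictors_warn(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        predictors = pd.DataFrame({"a": x, "b": x})
        y = (x + rng.normal(size=100) > 0).astype(int)
        with pytest.warns(UserWarning, match="collinear"):
            ev.marker_regression(predictors, y, mode="multivariate")


class TestCrossCancer:
    def test_frozen_formula_specific_to_planted_disease(self, serum_study):
        model = load_frozen_model("beijing1-prospective")
        rng = np.random.default_rng(15)
        n = 150

        def cohort(effect):
            # log2 fold changes per panel miRNA; effect>0 shifts cases along
            # the signed direction of the frozen coefficients so the frozen
            # formula discriminates without refitting
            X = rng.normal(size=(2 * n, 8))
            signs = np.sign([model.coefficients[m] for m in model.panel])
            X[:n] += effect * signs
            frame = pd.DataFrame(2.0 ** X, columns=model.panel,
                                 index=[f"s{i}" for i in range(2 * n)])
            labels = np.array([1] * n + [0] * n)
            return frame, labels

        summaries, comparisons = ev.cross_cancer_specificity(
            model,
            {"escc": cohort(2.0), "other": cohort(0.0)},
            reference="escc",
            n_boot=300,
            seed=1,
        )
        assert summaries["escc"].auc >= 0.85
        assert abs(summaries["other"].auc - 0.5) < 0.08
        assert comparisons["other"].p_value < 0.05
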