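import numpy as np
import pandas as pd
import pytest

from tertscape import errors
from tertscape.datasets import expand_cohort_to_samples, load_cohort_table
from tertscape.screen import (
    ScreenConfig,
    annotate_tf,
    classify_tert,
    cohort_summary,
    correlation_screen,
    marker_expression_transform,
    tf_counts,
)


class TestClassify:
    def test_raw_zero_mode(self):
        cm = pd.DataFrame([[0, 5, 0, 12]], index=["TERT"], columns=list("abcd"))
        assert list(classify_tert(cm)) == ["neg", "pos", "neg", "pos"]

    def test_all_zero_all_negative(self):
        cm = pd.DataFrame([[0, 0]], index=["TERT"], columns=["a", "b"])
        assert set(classify_tert(cm)) == {"neg"}

    def test_norm_threshold_tau_zero_equals_raw_zero(self):
        cm = pd.DataFrame([[0, 3, 7]], index=["TERT"], columns=list("abc"))
        sf = pd.Series([0.5, 1.0, 2.0], index=list("abc"))
        raw = classify_tert(cm)
        norm = classify_tert(cm, mode="norm_threshold", tau=0.0, size_factors=sf)
        pd.testing.assert_series_equal(raw, norm)

    def test_idempotent_and_deterministic(self):
        cm = pd.DataFrame([[0, 5]], index=["TERT"], columns=["a", "b"])
        pd.testing.assert_series_equal(classify_tert(cm), classify_tert(cm))

    def test_missing_marker_rejected(self):
        with pytest.raises(errors.DataContractError):
            classify_tert(pd.DataFrame([[1]], index=["A"], columns=["a"]))


class TestCohortSummary:
    def test_published_cohort_total_percentages(self):
        samples = expand_cohort_to_samples()
        summary = cohort_summary(samples).set_index("tumor_type")
        total = summary.loc["Total"]
        assert total["n_total"] == 1039
        assert total["n_pos"] == 761 and total["n_neg"] == 278
        assert total["pct_pos"] == 73.2
        assert total["n_mut_C250"] == 4 and total["n_mut_C228"] == 9
        assert total["n_wt"] == 101

    def test_fully_positive_type(self):
        samples = expand_cohort_to_samples()
        summary = cohort_summary(samples).set_index("tumor_type")
        row = summary.loc["Acute lymphoblastic leukemia"]
        assert row["pct_pos"] == 100.0 and row["n_total"] == 44

    def test_per_type_totals_reconcile(self):
        summary = cohort_summary(expand_cohort_to_samples()).set_index("tumor_type")
        body = summary.drop(index="Total")
        assert (body["n_pos"] + body["n_neg"] == body["n_total"]).all()
        assert body["n_total"].sum() == summary.loc["Total", "n_total"]

    def test_empty_table(self):
        empty = pd.DataFrame(
            columns=["tumor_type", "role", "tert_stratum", "mutation_status"]
        )
        summary = cohort_summary(empty)
        assert summary.iloc[-1]["n_total"] == 0


class TestMarkerTransform:
    def test_values(self):
        cm = pd.DataFrame([[0, np.e - 1, 10]], index=["TERT"], columns=list("abc"))
        out = marker_expression_transform(cm)
        assert out["a"] == 0.0
        assert out["b"] == pytest.approx(1.0)
        assert out["c"] > out["b"] > out["a"]  # monotone


class TestCorrelationScreen:
    def _features(self, target, extra_rows):
        return pd.DataFrame(extra_rows, columns=target.index)

    def test_feature_equal_to_target_passes_with_rho_one(self):
        target = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        feats = pd.DataFrame([target.values], index=["f1"], columns=target.index)
        res = correlation_screen(target, feats)
        assert res.loc["f1", "rho"] == 1.0 and bool(res.loc["f1", "passes"])

    def test_marker_excluded_from_features(self):
        target = pd.Series(np.arange(5.0), index=[f"s{i}" for i in range(5)])
        feats = pd.DataFrame(
            [target.values, target.values[::-1]], index=["TERT", "f"], columns=target.index
        )
        res = correlation_screen(target, feats)
        assert "TERT" not in res.index

    def test_untestable_features_flagged_and_outside_bh_family(self):
        target = pd.Series(np.arange(6.0), index=[f"s{i}" for i in range(6)])
        rows = np.vstack([np.arange(6.0), np.full(6, 3.0)])
        feats = pd.DataFrame(rows, index=["ok", "constant"], columns=target.index)
        feats.loc["sparse"] = [1.0, 2.0] + [np.nan] * 4
        res = correlation_screen(target, feats)
        assert not res.loc["constant", "testable"]
        assert not res.loc["sparse", "testable"]
        assert np.isnan(res.loc["constant", "p_adj"])
        # BH family of one testable feature: p_adj equals p_raw
        assert res.loc["ok", "p_adj"] == pytest.approx(res.loc["ok", "p_raw"])

    def test_direction_equals_sign_of_rho(self):
        rng = np.random.default_rng(5)
        target = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        feats = pd.DataFrame(
            rng.normal(size=(20, 40)), index=[f"f{i}" for i in range(20)], columns=target.index
        )
        res = correlation_screen(target, feats)
        assert (res.loc[res["rho"] > 0, "direction"] == "pos").all()
        assert (res.loc[res["rho"] < 0, "direction"] == "neg").all()

    def test_null_features_pass_at_most_alpha_rate(self):
        rng = np.random.default_rng(17)
        n = 50
        target = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        feats = pd.DataFrame(
            rng.normal(size=(200, n)), index=[f"f{i}" for i in range(200)], columns=target.index
        )
        res = correlation_screen(target, feats)
        # expected pass rate under the global null is below alpha; allow
        # 3 binomial SDs of slack around it
        assert res["passes"].mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)


class TestAnnotateTf:
    def _results(self):
        return pd.DataFrame(
            {
                "rho": [0.9, 0.8, -0.7, 0.6, 0.5],
                "p_raw": [1e-9] * 5,
                "p_adj": [1e-8] * 5,
                "direction": ["pos", "pos", "neg", "pos", "pos"],
                "passes": [True] * 5,
                "tier": ["strong"] * 5,
                "testable": [True] * 5,
            },
            index=[f"g{i}" for i in range(5)],
        )

    def test_partition_sizes(self):
        res = annotate_tf(self._results(), {"g0", "g2"})
        assert int(res["is_tf"].sum()) == 2
        counts = tf_counts(res)
        assert counts["n_tf_pass"] == 2
        assert counts["n_tf_pos"] == 1 and counts["n_tf_neg"] == 1

    def test_empty_intersection(self):
        res = annotate_tf(self._results(), {"zzz"})
        assert not res["is_tf"].any()

    def test_empty_tf_list_rejected(self):
        with pytest.raises(errors.DataContractError):
            annotate_tf(self._results(), set())


def test_screen_config_threshold_ordering_enforced():
    with pytest.raises(errors.ConfigError):
        ScreenConfig(rho_threshold=0.5, tf_rho_tier=0.4)
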