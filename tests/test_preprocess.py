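import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tertscape import errors, preprocess as pp


class TestQcFilter:
    def test_boundary_inclusive(self):
        cm = pd.DataFrame({"keep": [3_500_000], "drop": [3_499_999]}, index=["G"])
        kept, report = pp.qc_filter_samples(cm, 3_500_000)
        assert list(kept.columns) == ["keep"]
        assert report.loc["drop", "gene_mapped_reads"] == 3_499_999
        assert not report.loc["drop", "retained"]

    def test_zero_threshold_is_identity(self):
        cm = pd.DataFrame({"a": [0], "b": [1]}, index=["G"])
        kept, _ = pp.qc_filter_samples(cm, 0)
        assert list(kept.columns) == ["a", "b"]


class TestAggregateGeneIds:
    def test_shared_target_counts_summed(self):
        cm = pd.DataFrame({"s": [3, 4]}, index=["ENSG1", "ENSG2"])
        out = pp.aggregate_gene_ids(cm, pd.Series({"ENSG1": "A", "ENSG2": "A"}))
        assert out.loc["A", "s"] == 7

    def test_identity_map_unchanged(self):
        cm = pd.DataFrame({"s": [3, 4]}, index=["A", "B"])
        out = pp.aggregate_gene_ids(cm, pd.Series({"A": "A", "B": "B"}))
        pd.testing.assert_frame_equal(out, cm.rename_axis("gene_id"))

    def test_unmapped_drop_vs_keep(self):
        cm = pd.DataFrame({"s": [3, 4]}, index=["ENSG1", "ENSG3"])
        mapped = pd.Series({"ENSG1": "A"})
        assert "ENSG3" not in pp.aggregate_gene_ids(cm, mapped, unmapped="drop").index
        kept = pp.aggregate_gene_ids(cm, mapped, unmapped="keep")
        assert kept.loc["ENSG3", "s"] == 4

    def test_total_reads_preserved(self):
        cm = pd.DataFrame({"s": [3, 4, 5]}, index=["E1", "E2", "E3"])
        out = pp.aggregate_gene_ids(cm, pd.Series({"E1": "A", "E2": "A", "E3": "B"}))
        assert out["s"].sum() == cm["s"].sum()


class TestSizeFactors:
    def test_hand_computed_two_sample_doubling(self):
        cm = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        s = pp.size_factors(cm)
        assert np.allclose(s.values, [0.7071, 1.4142], atol=5e-5)

    def test_single_sample_is_one(self):
        s = pp.size_factors(pd.DataFrame({"s1": [10, 20]}))
        assert np.allclose(s.values, [1.0])

    def test_identical_samples_all_one(self):
        cm = pd.DataFrame({"s1": [5, 9], "s2": [5, 9], "s3": [5, 9]})
        assert np.allclose(pp.size_factors(cm).values, 1.0)

    @given(k=st.floats(min_value=0.1, max_value=10.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_equivariance(self, k):
        # multiplying one sample by k multiplies the size-factor *ratios*
        # involving it by k; median-of-ratios factors as a whole are defined
        # only up to the geometric-mean rescaling of the reference, so the
        # normalized matrix is invariant up to one common scalar
        cm = pd.DataFrame({"s1": [10, 20, 30], "s2": [12, 25, 28]}, dtype=float)
        base = pp.size_factors(cm)
        scaled = cm.copy()
        scaled["s2"] = scaled["s2"] * k
        s = pp.size_factors(scaled)
        assert np.isclose(s["s2"] / s["s1"], k * base["s2"] / base["s1"], rtol=1e-9)
        norm, ref = pp.normalize(scaled, s), pp.normalize(cm, base)
        common = (norm / ref).to_numpy().ravel()
        assert np.allclose(common, common[0], rtol=1e-9)

    def test_no_common_positive_gene_requires_fallback(self):
        cm = pd.DataFrame({"s1": [10, 0], "s2": [0, 10]})
        with pytest.raises(errors.DataContractError, match="fallback"):
            pp.size_factors(cm)
        s = pp.size_factors(cm, fallback=True)
        assert (s > 0).all()

    def test_agrees_with_pydeseq2(self, cohort200):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        cm = cohort200.counts.iloc[1:201, :30]
        meta = pd.DataFrame({"condition": ["A", "B"] * 15}, index=cm.columns)
        dds = DeseqDataSet(counts=cm.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        ours = pp.size_factors(cm)
        assert np.allclose(ours.values, dds.obs["size_factors"].values, rtol=1e-6)


class TestCnr:
    def test_direct_formula(self, tiny_samples):
        nm = pd.DataFrame(
            {"t1": [30.0], "t2": [10.0], "c1": [10.0], "c2": [30.0]}, index=["A"]
        )
        out = pp.cnr(nm, tiny_samples, pseudocount=1.0)
        assert np.isclose(out.loc["A", "t1"], 31.0 / 21.0)

    def test_all_zero_gene_gives_unit_ratio(self, tiny_samples):
        nm = pd.DataFrame({c: [0.0] for c in ["t1", "t2", "c1", "c2"]}, index=["A"])
        out = pp.cnr(nm, tiny_samples, pseudocount=1.0)
        assert np.allclose(out.values, 1.0)

    def test_zero_pseudocount_with_zero_controls_rejected(self, tiny_samples):
        nm = pd.DataFrame(
            {"t1": [5.0], "t2": [5.0], "c1": [0.0], "c2": [0.0]}, index=["A"]
        )
        with pytest.raises(errors.DataContractError):
            pp.cnr(nm, tiny_samples, pseudocount=0.0)

    def test_missing_control_group_names_the_type(self, tiny_samples):
        samples = tiny_samples.copy()
        samples.loc[["c1", "c2"], "tumor_type"] = "breast"
        nm = pd.DataFrame({c: [1.0] for c in samples.index}, index=["A"])
        with pytest.raises(errors.DataContractError, match="lung"):
            pp.cnr(nm, samples)

    def test_tumor_equal_to_control_mean_is_all_ones(self, tiny_samples):
        rng = np.random.default_rng(0)
        ctrl = rng.uniform(1, 50, size=(5, 2))
        nm = pd.DataFrame(ctrl.mean(axis=1)[:, None].repeat(2, axis=1), columns=["t1", "t2"])
        nm[["c1", "c2"]] = ctrl
        out = pp.cnr(nm, tiny_samples)
        assert np.allclose(out.values, 1.0)

    def test_monotone_in_tumor_value(self, tiny_samples):
        base = pd.DataFrame(
            {"t1": [5.0], "t2": [9.0], "c1": [4.0], "c2": [6.0]}, index=["A"]
        )
        lo = pp.cnr(base, tiny_samples).loc["A", "t1"]
        base.loc["A", "t1"] = 7.0
        hi = pp.cnr(base, tiny_samples).loc["A", "t1"]
        assert hi > lo
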