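import math

import numpy as np
import pandas as pd
import pytest

from tertscape import errors
from tertscape.differential import (
    DiffConfig,
    differential_genes,
    differential_pal,
    enrich_list,
    group_report,
    log2fc,
)
from tertscape.io import PathwayLibrary


class TestLog2Fc:
    def test_direct_formula(self):
        assert log2fc(0, 4, 1.0) == pytest.approx(math.log2(5))

    def test_equal_means_zero(self):
        assert log2fc(7.3, 7.3) == 0.0

    def test_swap_flips_sign(self):
        assert log2fc(2, 9) == pytest.approx(-log2fc(9, 2))

    def test_zero_pseudocount_rejected(self):
        with pytest.raises(errors.ConfigError):
            log2fc(1, 2, pseudocount=0)


class TestDifferentialGenes:
    def test_identical_gene_not_significant(self):
        nm = pd.DataFrame(
            {f"s{i}": [3.0, float(i)] for i in range(8)}, index=["flat", "vary"]
        )
        res = differential_genes(nm, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert res.loc["flat", "p_raw"] == 1.0
        assert res.loc["flat", "log2fc"] == 0.0
        assert not res.loc["flat", "significant"]
        assert res.loc["flat", "up_in"] == "none"

    def test_planted_eightfold_shift_detected(self):
        rng = np.random.default_rng(42)
        n = 20
        base = rng.negative_binomial(10, 10 / (10 + 50), size=(30, 2 * n)).astype(float)
        shifted = base.copy()
        shifted[0, n:] *= 8  # 8-fold shift in the alt group for gene 0
        nm = pd.DataFrame(shifted, index=[f"g{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(2 * n)])
        res = differential_genes(nm, [f"s{i}" for i in range(n)],
                                 [f"s{i}" for i in range(n, 2 * n)])
        assert bool(res.loc["g0", "significant"])
        assert res.loc["g0", "up_in"] == "alt"

    def test_global_null_fdr_controlled(self):
        rng = np.random.default_rng(7)
        fdps = []
        for _ in range(60):
            nm = pd.DataFrame(
                rng.negative_binomial(10, 0.1, size=(40, 20)).astype(float),
                index=[f"g{i}" for i in range(40)],
                columns=[f"s{i}" for i in range(20)],
            )
            res = differential_genes(nm, [f"s{i}" for i in range(10)],
                                     [f"s{i}" for i in range(10, 20)])
            n_sig = int(res["significant"].sum())
            fdps.append(n_sig / max(n_sig, 1) if n_sig else 0.0)
        assert np.mean(fdps) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        nm = pd.DataFrame(
            rng.uniform(1, 100, size=(10, 12)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(12)],
        )
        a, b = [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)]
        fwd = differential_genes(nm, a, b)
        rev = differential_genes(nm, b, a)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p_raw"], rev["p_raw"])
        swapped = fwd["up_in"].map({"alt": "ref", "ref": "alt", "none": "none"})
        assert (swapped == rev["up_in"]).all()

    def test_significant_set_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        nm = pd.DataFrame(
            rng.uniform(1, 100, size=(50, 16)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(16)],
        )
        nm.iloc[:5, 8:] *= 6
        a, b = [f"s{i}" for i in range(8)], [f"s{i}" for i in range(8, 16)]
        strict = differential_genes(nm, a, b, DiffConfig(alpha=0.01))
        loose = differential_genes(nm, a, b, DiffConfig(alpha=0.2))
        assert set(strict.index[strict["significant"]]) <= set(loose.index[loose["significant"]])


class TestDifferentialPal:
    def _pal(self):
        return pd.DataFrame(
            {
                "a1": [1.0, 0.0], "a2": [2.0, 0.0], "a3": [3.0, 0.0],
                "b1": [4.0, 0.0], "b2": [5.0, 0.0], "b3": [6.0, 0.0],
            },
            index=["shifted", "flat"],
        )

    def test_constructed_fixture_exact_p_and_mean_difference(self):
        res, untestable = differential_pal(self._pal(), ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert untestable == []
        assert res.loc["shifted", "p_raw"] == pytest.approx(0.1)
        assert res.loc["shifted", "delta_pal"] == pytest.approx(3.0)
        assert res.loc["flat", "p_raw"] == 1.0

    def test_mean_pal_equals_cell_means(self):
        pal = self._pal()
        res, _ = differential_pal(pal, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert res.loc["shifted", "mean_ref"] == pytest.approx(
            pal.loc["shifted", ["a1", "a2", "a3"]].mean(), abs=1e-12
        )

    def test_undefined_cells_can_make_pathway_untestable(self):
        pal = self._pal()
        pal.loc["shifted", ["a2", "a3"]] = np.nan
        res, untestable = differential_pal(pal, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert untestable == ["shifted"]
        assert "shifted" not in res.index

    def test_up_in_is_group_with_larger_mean(self):
        res, _ = differential_pal(
            self._pal(), ["a1", "a2", "a3"], ["b1", "b2", "b3"], DiffConfig(alpha=0.25)
        )
        assert res.loc["shifted", "significant"]
        assert res.loc["shifted", "up_in"] == "alt"


class TestEnrichList:
    def test_full_term_top_ranked(self):
        universe = {f"g{i}" for i in range(20)}
        lib = PathwayLibrary({"hit": {f"g{i}": 1 for i in range(5)},
                              "other": {f"g{i}": 1 for i in range(10, 18)}})
        res = enrich_list({f"g{i}" for i in range(5)}, lib, universe)
        assert res.index[0] == "hit"

    def test_disjoint_list_nothing_flagged(self):
        universe = {f"g{i}" for i in range(20)}
        lib = PathwayLibrary({"t": {f"g{i}": 1 for i in range(5)}})
        res = enrich_list({"g10", "g11"}, lib, universe)
        assert not res["flagged"].any()

    def test_hand_counted_hypergeometric_tail(self):
        # universe 20, term 8, query 6, overlap 5:
        # p = sum_{k=5}^{6} C(8,k) C(12,6-k) / C(20,6)
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:8])
        query = set(universe[:5]) | {universe[10]}
        expected = (math.comb(8, 5) * math.comb(12, 1) + math.comb(8, 6)) / math.comb(20, 6)
        lib = PathwayLibrary({"t": {g: 1 for g in term}})
        res = enrich_list(query, lib, set(universe))
        assert res.loc["t", "p_raw"] == pytest.approx(expected)
        assert res.loc["t", "overlap"] == 5

    def test_empty_list_empty_table(self):
        res = enrich_list(set(), PathwayLibrary({"t": {"a": 1}}), {"a"})
        assert res.empty


class TestGroupReport:
    def test_counts_by_direction(self):
        genes = pd.DataFrame(
            {"significant": [True, True, False], "up_in": ["alt", "ref", "none"]}
        )
        pal = pd.DataFrame({"significant": [True], "up_in": ["alt"]})
        rep = group_report(genes, pal)
        assert rep["genes_total"] == 2 and rep["genes_up_alt"] == 1
        assert rep["pathways_total"] == 1

    def test_empty_inputs_zero(self):
        rep = group_report(None, None)
        assert all(v == 0 for v in rep.values())
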