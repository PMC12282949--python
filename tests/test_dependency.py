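"""Dependency associations: differential tests, ranking, GSEA, candidates,
co-occurrence, expression and stratified analyses."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnagain import dependency, simulate


def _status_dep(gain_scores, neutral_scores, gene="G"):
    scores = list(gain_scores) + list(neutral_scores)
    status = ["arm_gain"] * len(gain_scores) + ["neutral"] * len(neutral_scores)
    idx = [f"L{i}" for i in range(len(scores))]
    return (pd.DataFrame({gene: scores}, index=idx),
            pd.DataFrame({gene: status}, index=idx))


class TestDifferentialDependency:
    def test_small_example_matches_welch_oracle(self):
        dep, status = _status_dep([-1.0, -0.8, -0.9], [0.0, 0.1, -0.1])
        rec = dependency.differential_dependency(dep, status)
        ref = sps.ttest_ind([-1.0, -0.8, -0.9], [0.0, 0.1, -0.1], equal_var=False)
        assert rec.loc["G", "delta"] == pytest.approx(-0.9)
        assert rec.loc["G", "p"] == pytest.approx(ref.pvalue, rel=1e-10)
        assert rec.loc["G", "n_gain"] == 3 and rec.loc["G", "n_neutral"] == 3

    def test_identical_groups_give_zero_delta(self):
        dep, status = _status_dep([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        rec = dependency.differential_dependency(dep, status)
        assert rec.loc["G", "delta"] == pytest.approx(0.0, abs=1e-12)
        assert rec.loc["G", "p"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_loop_with_missing_values(self, rng):
        n, g = 40, 25
        lines = [f"L{i}" for i in range(n)]
        genes = [f"G{j}" for j in range(g)]
        status = pd.DataFrame(
            rng.choice(["arm_gain", "focal_gain", "neutral", "loss", "amplification"],
                       size=(n, g), p=[0.2, 0.15, 0.45, 0.1, 0.1]),
            index=lines, columns=genes)
        dep = pd.DataFrame(rng.normal(size=(n, g)), index=lines, columns=genes)
        dep[rng.random((n, g)) < 0.1] = np.nan
        rec = dependency.differential_dependency(dep, status)
        for gene in genes:
            a = dep[gene][status[gene].isin(("arm_gain", "focal_gain")) & dep[gene].notna()]
            b = dep[gene][(status[gene] == "neutral") & dep[gene].notna()]
            if len(a) < 2 or len(b) < 2:
                assert np.isnan(rec.loc[gene, "p"])
                continue
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert rec.loc[gene, "p"] == pytest.approx(ref.pvalue, rel=1e-9)
            assert rec.loc[gene, "delta"] == pytest.approx(a.mean() - b.mean(), abs=1e-12)

    def test_arm_only_contrast_excludes_focal(self):
        dep = pd.DataFrame({"G": [-1.0, -0.9, 5.0, 5.0, 0.0, 0.1, -0.1, 0.05]},
                           index=[f"L{i}" for i in range(8)])
        status = pd.DataFrame(
            {"G": ["arm_gain", "arm_gain", "focal_gain", "focal_gain",
                   "neutral", "neutral", "neutral", "neutral"]}, index=dep.index)
        rec = dependency.differential_dependency(dep, status, contrast="arm_only")
        assert rec.loc["G", "n_gain"] == 2
        assert rec.loc["G", "delta"] == pytest.approx(-0.95 - 0.0125)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(7)
        status = pd.DataFrame(
            {"G": ["arm_gain"] * 150 + ["neutral"] * 150},
            index=[f"L{i}" for i in range(300)])
        dep = simulate.simulate_dependency(status, {"G": {"arm_gain": -0.4}}, sd=0.3, rng=rng)
        rec = dependency.differential_dependency(dep, status)
        assert rec.loc["G", "delta"] == pytest.approx(-0.4, abs=0.07)
        assert rec.loc["G", "p"] < 1e-10


class TestFilterConfounded:
    def test_strict_cutoff(self):
        rec = pd.DataFrame({"q": [0.1, 0.1, 0.1]}, index=["A", "B", "C"])
        imp = pd.Series({"A": 0.06, "B": 0.05})
        out = dependency.filter_confounded(rec, imp)
        assert list(out.index) == ["B", "C"]  # 0.05 retained (strict >), missing retained


class TestRankGenes:
    def test_metric_formula_and_ties(self):
        rec = pd.DataFrame(
            {"q": [0.01, 1.0, 0.01, 0.01], "delta": [-0.5, -0.3, 0.2, -0.9]},
            index=["A", "B", "C", "D"])
        ranked = dependency.rank_genes(rec)
        assert ranked["A"] == pytest.approx(-2.0)
        assert ranked["B"] == pytest.approx(0.0)
        assert ranked["C"] == pytest.approx(2.0)
        # equal metric: larger |delta| first
        assert list(ranked.index).index("D") < list(ranked.index).index("A")

    def test_zero_q_clamped(self):
        rec = pd.DataFrame({"q": [0.0], "delta": [-1.0]}, index=["A"])
        val = dependency.rank_genes(rec)["A"]
        assert np.isfinite(val) and val < -300


class TestGsea:
    @staticmethod
    def _direct_es(ranked, members):
        """Brute-force running-sum from the definition."""
        w = ranked.abs()
        hit = ranked.index.isin(members)
        run, best, p_hit, p_miss = 0.0, 0.0, 0.0, 0.0
        tot_hit = w[hit].sum()
        n_miss = (~hit).sum()
        for i, g in enumerate(ranked.index):
            if hit[i]:
                p_hit += w.iloc[i] / tot_hit
            else:
                p_miss += 1.0 / n_miss
            if abs(p_hit - p_miss) > abs(best):
                best = p_hit - p_miss
        return best

    def test_es_matches_direct_definition(self, rng):
        metric = pd.Series(rng.normal(size=60), index=[f"G{i}" for i in range(60)])
        ranked = metric.sort_values(ascending=False)
        members = list(rng.choice(ranked.index, size=12, replace=False))
        res = dependency.gsea_preranked(ranked, {"s": members}, n_perm=10, seed=0)
        assert res.loc["s", "ES"] == pytest.approx(self._direct_es(ranked, members), abs=1e-12)

    def test_extreme_negative_set(self, rng):
        metric = pd.Series(np.linspace(3, -3, 200), index=[f"G{i}" for i in range(200)])
        members = [f"G{i}" for i in range(180, 200)]  # most negative tail
        res = dependency.gsea_preranked(metric, {"neg": members}, n_perm=500, seed=1)
        assert res.loc["neg", "ES"] < -0.9
        assert res.loc["neg", "p"] <= 1 / 100
        assert res.loc["neg", "NES"] < 0

    def test_disjoint_set_untestable(self):
        metric = pd.Series([1.0, -1.0], index=["A", "B"])
        res = dependency.gsea_preranked(metric, {"s": ["ZZZ"]}, n_perm=10, seed=0)
        assert not res.loc["s", "testable"]

    def test_nes_sign_follows_es(self, rng):
        metric = pd.Series(rng.normal(size=300), index=[f"G{i}" for i in range(300)])
        sets = {f"s{k}": list(rng.choice(metric.index, 20, replace=False)) for k in range(5)}
        res = dependency.gsea_preranked(metric.sort_values(ascending=False), sets,
                                        n_perm=100, seed=2)
        ok = res[res.testable]
        assert (np.sign(ok.NES) == np.sign(ok.ES)).all()


class TestSelectCandidates:
    def _mk(self, qs, deltas):
        return pd.DataFrame({"q": qs, "delta": deltas}, index=["A", "B", "C"])

    def test_two_of_three_rule(self):
        d1 = self._mk([0.1, 0.29, 0.1], [-0.2, -0.04, -0.2])
        d2 = self._mk([0.1, 0.29, 0.5], [-0.2, -0.04, -0.2])
        d3 = self._mk([0.9, 0.29, 0.5], [-0.2, -0.04, -0.2])
        out = dependency.select_candidates({"x": d1, "y": d2, "z": d3})
        assert list(out.index) == ["A"]  # A in 2/3; B fails delta; C in 1/3
        assert out.loc["A", "n_datasets_significant"] == 2

    def test_order_invariance(self):
        d1 = self._mk([0.1, 0.1, 0.5], [-0.2, -0.2, -0.2])
        d2 = self._mk([0.1, 0.5, 0.1], [-0.2, -0.2, -0.2])
        d3 = self._mk([0.5, 0.1, 0.1], [-0.2, -0.2, -0.2])
        a = dependency.select_candidates({"x": d1, "y": d2, "z": d3})
        b = dependency.select_candidates({"z": d3, "x": d1, "y": d2})
        pd.testing.assert_frame_equal(a, b)

    def test_requires_two_datasets(self):
        with pytest.raises(ValueError):
            dependency.select_candidates({"only": self._mk([1, 1, 1], [0, 0, 0])})


class TestCooccurrence:
    def test_odds_ratio_closed_form(self):
        # 2x2 table [[40, 60], [23, 77]] -> OR = 40*77/(60*23)
        mut = ["M"] * 100 + ["W"] * 100
        gain = ["g"] * 40 + ["n"] * 60 + ["g"] * 23 + ["n"] * 77
        mutations = pd.DataFrame({"G": [int(m == "M") for m in mut]},
                                 index=[f"L{i}" for i in range(200)])
        status = pd.DataFrame({"G": ["arm_gain" if g == "g" else "neutral" for g in gain]},
                              index=mutations.index)
        rec = dependency.mutation_gain_cooccurrence(mutations, status)
        assert rec.loc["G", "odds_ratio"] == pytest.approx(40 * 77 / (60 * 23))
        assert rec.loc["G", "direction"] == "co-occurring"

    def test_all_mutated_untestable(self):
        mutations = pd.DataFrame({"G": [1] * 10}, index=[f"L{i}" for i in range(10)])
        status = pd.DataFrame({"G": ["arm_gain"] * 5 + ["neutral"] * 5}, index=mutations.index)
        rec = dependency.mutation_gain_cooccurrence(mutations, status)
        assert not rec.loc["G", "testable"]

    def test_independent_null_rarely_significant(self):
        rng = np.random.default_rng(3)
        n, g = 300, 60
        lines = [f"L{i}" for i in range(n)]
        mutations = pd.DataFrame(
            (rng.random((n, g)) < 0.3).astype(int), index=lines,
            columns=[f"G{j}" for j in range(g)])
        status = pd.DataFrame(
            np.where(rng.random((n, g)) < 0.3, "arm_gain", "neutral"),
            index=lines, columns=mutations.columns)
        rec = dependency.mutation_gain_cooccurrence(mutations, status)
        assert (rec["q"] < 0.1).mean() <= 0.10


class TestExpression:
    def test_planted_upregulation_detected(self):
        rng = np.random.default_rng(9)
        status = pd.DataFrame({"G": ["arm_gain"] * 100 + ["neutral"] * 100},
                              index=[f"L{i}" for i in range(200)])
        expr = simulate.simulate_expression(status, {"G": {"arm_gain": 1.5}}, rng=rng)
        rec = dependency.expression_by_gain_status(expr, status)
        assert rec.loc["G", "label"] == "upregulated"

    def test_identical_distributions_not_upregulated(self):
        rng = np.random.default_rng(9)
        status = pd.DataFrame({"G": ["arm_gain"] * 50 + ["neutral"] * 50},
                              index=[f"L{i}" for i in range(100)])
        expr = simulate.simulate_expression(status, {}, rng=rng)
        rec = dependency.expression_by_gain_status(expr, status)
        assert rec.loc["G", "label"] == "not_upregulated"

    def test_single_gained_sample_unevaluable(self):
        status = pd.DataFrame({"G": ["arm_gain"] + ["neutral"] * 9},
                              index=[f"L{i}" for i in range(10)])
        expr = pd.DataFrame({"G": np.arange(10.0)}, index=status.index)
        rec = dependency.expression_by_gain_status(expr, status)
        assert rec.loc["G", "label"] == "unevaluable"


class TestStratified:
    def test_effect_only_in_mutant_stratum(self):
        rng = np.random.default_rng(21)
        n = 400
        lines = [f"L{i}" for i in range(n)]
        mutant = pd.Series([True] * (n // 2) + [False] * (n // 2), index=lines)
        status = pd.DataFrame({"G": np.where(rng.random(n) < 0.5, "arm_gain", "neutral")},
                              index=lines)
        dep = pd.DataFrame({"G": rng.normal(0, 0.3, n)}, index=lines)
        dep.loc[mutant & (status["G"] == "arm_gain"), "G"] -= 0.5
        rec = dependency.stratified_dependency(dep, status, mutant)
        rec = rec.reset_index().set_index(["stratum"])
        assert rec.loc[True, "p"] < 1e-6
        assert rec.loc[False, "p"] > 0.01

    def test_tiny_stratum_skipped(self):
        lines = ["L0", "L1", "L2"]
        dep = pd.DataFrame({"G": [0.1, 0.2, 0.3]}, index=lines)
        status = pd.DataFrame({"G": ["arm_gain", "neutral", "neutral"]}, index=lines)
        strata = pd.Series(["a", "b", "b"], index=lines)
        rec = dependency.stratified_dependency(dep, status, strata)
        assert set(rec["stratum"].unique()) == {"b"}
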