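"""Discrete call rules: states, arm gains, amplifications, gene status, tracks."""
import numpy as np
import pandas as pd
import pytest

from cnagain import calling, genome
from cnagain.calling import CallThresholds

MB = 1_000_000


def _profile(segs, sample="S1"):
    return genome.SegmentedProfile(
        sample, pd.DataFrame(segs, columns=["chrom", "start", "end", "cn"]))


@pytest.fixture(scope="module")
def build():
    from cnagain.simulate import toy_build

    return toy_build(n_chrom=1)


class TestCallStates:
    def test_threshold_rules(self, thresholds):
        cn = pd.DataFrame({"b1": [0.25, 0.1, -0.25, np.nan]}, index=list("ABCD"))
        states = calling.call_states(cn, thresholds)
        assert list(states["b1"]) == ["gain", "neutral", "loss", "missing"]

    def test_exact_threshold_is_neutral(self, thresholds):
        cn = pd.DataFrame({"b": [thresholds.t_gain, thresholds.t_loss]})
        assert list(calling.call_states(cn, thresholds)["b"]) == ["neutral", "neutral"]

    def test_raising_gain_threshold_never_adds_gains(self, rng):
        cn = pd.DataFrame(rng.normal(0, 0.3, size=(30, 10)))
        cn.columns = [f"b{i}" for i in range(10)]
        counts = []
        for t in (0.05, 0.1, 0.2, 0.4):
            th = CallThresholds(t_gain=t)
            counts.append((calling.call_states(cn, th) == "gain").sum().sum())
        assert counts == sorted(counts, reverse=True)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            CallThresholds(t_gain=-0.1)
        with pytest.raises(ValueError):
            CallThresholds(arm_fraction=1.5)


class TestArmGains:
    # toy chr1: p arm [0, 55 Mb), q arm [65, 120 Mb)

    def test_85pct_above_threshold_is_gained(self, build, thresholds):
        prof = _profile([("chr1", 0, 46_750_000, 0.3), ("chr1", 46_750_000, 55 * MB, 0.0)])
        row = calling.call_arm_gains(prof, build, thresholds).set_index("arm").loc["p"]
        assert row["gained"]

    def test_79pct_above_threshold_is_not_gained(self, build, thresholds):
        prof = _profile([("chr1", 0, 43_450_000, 0.3), ("chr1", 43_450_000, 55 * MB, 0.0)])
        row = calling.call_arm_gains(prof, build, thresholds).set_index("arm").loc["p"]
        assert not row["gained"]

    def test_denominator_is_covered_length(self, build, thresholds):
        # only 50% of the arm covered, but all covered bases above threshold
        prof = _profile([("chr1", 0, 27_500_000, 0.3)])
        row = calling.call_arm_gains(prof, build, thresholds).set_index("arm").loc["p"]
        assert row["gained"]
        assert row["covered_fraction_gained"] == pytest.approx(1.0)

    def test_uncovered_arm_flagged_missing(self, build, thresholds):
        prof = _profile([("chr1", 0, 10 * MB, 0.3)])
        row = calling.call_arm_gains(prof, build, thresholds).set_index("arm").loc["q"]
        assert row["missing"] and not row["gained"]

    def test_exactly_80pct_is_not_gained(self, build, thresholds):
        prof = _profile([("chr1", 0, 44 * MB, 0.3), ("chr1", 44 * MB, 55 * MB, 0.0)])
        row = calling.call_arm_gains(prof, build, thresholds).set_index("arm").loc["p"]
        assert row["covered_fraction_gained"] == pytest.approx(0.8)
        assert not row["gained"]

    def test_matches_per_base_oracle_on_random_arms(self, build, thresholds, rng):
        """Arm calls equal a brute-force per-unit covered/gained computation."""
        unit = 100_000
        chrom = build["chr1"]
        for _ in range(100):
            bounds = np.sort(rng.choice(np.arange(1, 550), size=5, replace=False)) * unit
            bounds = np.concatenate([[0], bounds, [chrom.cen_start]])
            segs, base = [], np.full(chrom.cen_start // unit, np.nan)
            for s, e in zip(bounds[:-1], bounds[1:]):
                if rng.random() > 0.3:
                    v = rng.normal(0.1, 0.2)
                    segs.append(("chr1", int(s), int(e), v))
                    base[s // unit:e // unit] = v
            if not segs:
                continue
            row = calling.call_arm_gains(_profile(segs), build, thresholds).set_index("arm").loc["p"]
            covered = np.isfinite(base)
            expect = (base[covered] > thresholds.t_gain).mean() > thresholds.arm_fraction
            assert bool(row["gained"]) == bool(expect)


class TestAmplifications:
    def _arm_table(self, max_cn=0.45, gained=True):
        return pd.DataFrame(
            {"sample": ["A"], "chrom": ["chr1"], "arm": ["p"], "arm_cn": [max_cn],
             "covered_fraction_gained": [0.9 if gained else 0.1],
             "gained": [gained], "missing": [False]})

    def test_above_max_armgain_is_amplified(self, thresholds):
        gene_cn = pd.DataFrame({"G": [0.9]}, index=["A"])
        amp = calling.call_amplifications(gene_cn, self._arm_table(), thresholds)
        assert amp.loc["A", "G"]

    def test_equal_to_max_armgain_is_not_amplified(self, thresholds):
        gene_cn = pd.DataFrame({"G": [0.45]}, index=["A"])
        amp = calling.call_amplifications(gene_cn, self._arm_table(), thresholds)
        assert not amp.loc["A", "G"]

    def test_fallback_when_no_gained_arm(self, thresholds):
        gene_cn = pd.DataFrame({"G": [1.0, 0.5]}, index=["A", "A2"])
        table = self._arm_table(gained=False)
        amp = calling.call_amplifications(gene_cn, table, thresholds)
        assert amp.loc["A", "G"] and not amp.loc["A2", "G"]

    def test_missing_gene_cn_not_amplified(self, thresholds):
        gene_cn = pd.DataFrame({"G": [np.nan]}, index=["A"])
        assert not calling.call_amplifications(gene_cn, self._arm_table(), thresholds).loc["A", "G"]


class TestGeneStatus:
    @pytest.fixture()
    def setup(self):
        gene_cn = pd.DataFrame(
            {"G1": [0.3, 0.3, 0.0, -0.3, 1.5], "G2": [0.3, np.nan, 0.0, 0.0, 0.0]},
            index=list("ABCDE"))
        gene_arm = pd.Series({"G1": "chr1:p", "G2": "chr1:q"})
        arm_table = pd.DataFrame({
            "sample": list("ABCDE") * 2,
            "chrom": ["chr1"] * 10,
            "arm": ["p"] * 5 + ["q"] * 5,
            "arm_cn": [0.3, 0.0, 0.3, 0.0, 0.3] + [0.0] * 5,
            "covered_fraction_gained": [0.9, 0.1, 0.9, 0.1, 0.9] + [0.1] * 5,
            "gained": [True, False, True, False, True] + [False] * 5,
            "missing": [False] * 10,
        })
        amp = pd.DataFrame(False, index=list("ABCDE"), columns=["G1", "G2"])
        amp.loc["E", "G1"] = True
        return gene_cn, gene_arm, arm_table, amp

    def test_precedence(self, setup, thresholds):
        gene_cn, gene_arm, arm_table, amp = setup
        status = calling.classify_gene_status(gene_cn, gene_arm, arm_table, amp, thresholds)
        assert status.loc["A", "G1"] == "arm_gain"        # gained arm + gene above t_gain
        assert status.loc["B", "G1"] == "focal_gain"      # arm not gained
        assert status.loc["C", "G1"] == "neutral"         # gained arm but gene at 0
        assert status.loc["D", "G1"] == "loss"
        assert status.loc["E", "G1"] == "amplification"   # amp beats arm_gain
        assert status.loc["B", "G2"] == "missing"

    def test_exactly_one_status_per_cell(self, setup, thresholds):
        gene_cn, gene_arm, arm_table, amp = setup
        status = calling.classify_gene_status(gene_cn, gene_arm, arm_table, amp, thresholds)
        counts = status.apply(pd.Series.value_counts).fillna(0).sum(axis=0)
        assert (counts == len(gene_cn)).all()

    def test_unknown_gene_arm_errors(self, setup, thresholds):
        gene_cn, gene_arm, arm_table, amp = setup
        with pytest.raises(ValueError):
            calling.classify_gene_status(
                gene_cn.rename(columns={"G1": "GX"}), gene_arm, arm_table, amp, thresholds)


class TestAmplificationInvariant:
    def test_amplified_gene_exceeds_every_gained_arm(self, small_cohort, thresholds):
        build = small_cohort["build"]
        genes = small_cohort["genes"]
        gbins = genome.gene_bins(genes, build)
        gmat = genome.bin_copy_matrix(small_cohort["profiles"], gbins, build)
        arm_table = calling.arm_call_table(small_cohort["profiles"], build, thresholds)
        amp = calling.call_amplifications(gmat.cn, arm_table, thresholds)
        maxarm = calling.max_armgain_cn(arm_table)
        for sample in amp.index:
            if np.isnan(maxarm.get(sample, np.nan)):
                continue
            amped = amp.loc[sample]
            if amped.any():
                assert (gmat.cn.loc[sample, amped[amped].index] > maxarm[sample]).all()


class TestFrequencyTracks:
    def test_frequencies_and_sum_bound(self):
        states = pd.DataFrame(
            {"b1": ["gain", "gain", "loss", "missing"], "b2": ["neutral"] * 4})
        track = calling.cna_frequencies(states)
        assert track.loc["b1", "f_gain"] == pytest.approx(2 / 3)
        assert track.loc["b1", "f_loss"] == pytest.approx(1 / 3)
        assert ((track.f_gain + track.f_loss) <= 1 + 1e-12).all()

    def test_identical_frequencies_give_zero_z(self):
        states = pd.DataFrame({"b1": ["gain", "neutral"], "b2": ["gain", "neutral"]})
        with pytest.warns(UserWarning):
            track = calling.frequency_zscores(calling.cna_frequencies(states))
        assert (track.z_gain == 0).all()

    @pytest.mark.filterwarnings("ignore:zero variance in f_loss")
    def test_universally_gained_bin_has_max_z(self, rng):
        n = 40
        data = {"hot": ["gain"] * n}
        for j in range(9):
            data[f"b{j}"] = np.where(rng.random(n) < 0.1, "gain", "neutral")
        track = calling.frequency_zscores(calling.cna_frequencies(pd.DataFrame(data)))
        assert track["z_gain"].idxmax() == "hot"

    def test_planted_frequency_within_binomial_ci(self):
        rng = np.random.default_rng(5)
        n = 500
        hot = np.where(rng.random(n) < 0.5, "gain", "neutral")
        cold = [np.where(rng.random(n) < 0.1, "gain", "neutral") for _ in range(5)]
        states = pd.DataFrame({"hot": hot, **{f"b{j}": c for j, c in enumerate(cold)}})
        track = calling.cna_frequencies(states)
        assert abs(track.loc["hot", "f_gain"] - 0.5) < 3 * np.sqrt(0.25 / n)
        for j in range(5):
            assert abs(track.loc[f"b{j}", "f_gain"] - 0.1) < 3 * np.sqrt(0.09 / n)

    def test_needs_two_bins(self):
        with pytest.raises(ValueError):
            calling.cna_frequencies(pd.DataFrame({"b1": ["gain"]}))
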