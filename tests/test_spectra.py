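import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from mitospectra.spectra import (
    FOREBRAIN_BASELINE_BP,
    fit_rate_model,
    fold_change,
    hotspot_3243,
    mann_whitney_exact,
    pathogenicity_summary,
    rate_model_from_table,
    strand_bias,
    summarize_spectrum,
    synthetic_score_table,
)


def table(rows):
    df = pd.DataFrame(rows, columns=["pos", "ref", "alt", "frequency"])
    df["count"] = 1
    df["depth"] = 1000
    df["change"] = df["ref"] + ">" + df["alt"]
    df["transition"] = df["change"].isin({"A>G", "G>A", "C>T", "T>C"})
    return df


class TestSummaries:
    def test_burden_arithmetic(self, annot):
        t = table([(3000, "G", "A", 1e-4)])
        s = summarize_spectrum(t, annot).set_index("region")
        assert s.loc["coding", "burden_bp"] == pytest.approx(1e-4 / 15447)
        assert s.loc["coding", "burden_mtdna"] == pytest.approx(1e-4)
        # per-mtDNA / per-bp equals the region length exactly
        assert s.loc["coding", "burden_mtdna"] / s.loc["coding", "burden_bp"] == (
            pytest.approx(15447)
        )
        assert s.loc["control", "burden_bp"] == 0.0

    def test_transversions_zero_in_pure_transition_table(self, annot):
        t = table([(3000, "G", "A", 1e-4), (4000, "T", "C", 2e-4)])
        s = summarize_spectrum(t, annot).set_index("region")
        for change in ("G>T", "C>A", "A>T"):
            assert s.loc["all", change] == 0.0
        assert s.loc["all", "G>A"] == pytest.approx(1e-4 / 16569)


class TestStrandBias:
    def test_single_position_definition(self, annot):
        # only m.64C>T at frequency f: control-region dGA-CT = -f / 1122
        f = 3e-4
        t = table([(64, "C", "T", f)])
        b = strand_bias(t, annot, region="control")
        assert b.delta_ga_ct == pytest.approx(-f / 1122)
        assert b.delta_tc_ag == 0.0

    def test_antisymmetry(self, annot, rng):
        rows = []
        for _ in range(50):
            pos = int(rng.integers(600, 16000))
            change = ("G", "A") if rng.random() < 0.5 else ("C", "T")
            rows.append((pos, change[0], change[1], float(rng.random() * 1e-4)))
        t = table(rows)
        # relabel every G>A observation as C>T and vice versa
        swapped = t.copy()
        swapped["ref"] = t["ref"].map({"G": "C", "C": "G"})
        swapped["alt"] = t["alt"].map({"A": "T", "T": "A"})
        swapped["change"] = swapped["ref"] + ">" + swapped["alt"]
        b1 = strand_bias(t, annot)
        b2 = strand_bias(swapped, annot)
        assert b1.delta_ga_ct == pytest.approx(-b2.delta_ga_ct)

    def test_exclusion_option(self, annot):
        t = table([(64, "C", "T", 1e-3), (16148, "C", "T", 1e-3)])
        b = strand_bias(t, annot, region="control",
                        exclude_positions=(64, 16148))
        assert b.delta_ga_ct == 0.0

    def test_rolling_track(self, annot):
        t = table([(8000, "G", "A", 1e-3)])
        b = strand_bias(t, annot, region="coding", window=25)
        assert b.track is not None
        peak = b.track.set_index("pos")["bias"]
        assert peak.loc[8000] > 0
        assert peak.loc[10000] == 0.0


class TestHotspot:
    def test_mixture_arithmetic(self):
        # planted G:C:T = 8:1:1 at m.3243 -> A>B = 1.25 x A>G
        t = table(
            [(3243, "A", "G", 8e-4), (3243, "A", "C", 1e-4), (3243, "A", "T", 1e-4)]
        )
        h = hotspot_3243(t).set_index("pos")
        assert h.loc[3243, "top_alt"] == "G"
        assert h.loc[3243, "a_to_b"] == pytest.approx(1.25 * 8e-4)

    def test_zero_depth_reported_missing(self):
        h = hotspot_3243(table([(3243, "A", "G", 1e-4)])).set_index("pos")
        assert np.isnan(h.loc[3242, "top_freq"])
        assert h.loc[3243, "top_freq"] == pytest.approx(1e-4)


class TestPathogenicity:
    def _scores(self):
        return pd.DataFrame(
            {
                "pos": np.arange(1, 10),
                "score": [0.9, 0.7, 0.5, 0.3, 0.05, 0.8, 0.2, 0.15, 0.99],
                "nonsense": [False] * 4 + [True] + [False] * 4,
                "synonymous": [False] * 6 + [True, False, False],
            }
        )

    def test_bin_bookkeeping(self):
        bins = pathogenicity_summary(table([]), self._scores())
        # >0.667 or nonsense: pos 1, 2, 5, 6, 9; synonymous or <0.100: 7
        assert bins.counts == {"high": 5, "mid": 3, "low": 1}

    def test_uniform_rate_equal_means(self):
        scores = self._scores()
        t = table([(int(p), "G", "A", 1e-4) for p in scores["pos"]])
        bins = pathogenicity_summary(t, scores)
        assert bins.mean_freq["high"] == pytest.approx(1e-4)
        assert bins.mean_freq["mid"] == pytest.approx(1e-4)
        assert bins.mean_freq["low"] == pytest.approx(1e-4)

    def test_rate_ordering_recovered(self):
        scores = self._scores()
        bin_of = {1: 3, 2: 3, 5: 3, 6: 3, 9: 3, 3: 2, 4: 2, 8: 2, 7: 1}
        t = table([(p, "G", "A", b * 1e-4) for p, b in bin_of.items()])
        bins = pathogenicity_summary(t, scores)
        assert bins.mean_freq["high"] > bins.mean_freq["mid"] > bins.mean_freq["low"]

    def test_synthetic_table_covers_protein_sites(self, genome, annot):
        scores = synthetic_score_table(genome, annot, seed=1)
        assert len(scores) == len(annot.protein_coding_positions())
        bins = pathogenicity_summary(table([]), scores)
        assert sum(bins.counts.values()) == len(scores)


class TestRateModel:
    def test_noiseless_exact(self):
        ages = np.array([20, 40, 60, 80.0])
        y = 1e-4 + 2e-6 * ages
        m = fit_rate_model(ages, y)
        assert m.slope == pytest.approx(2e-6)
        assert m.intercept == pytest.approx(1e-4)
        assert m.slope_ci[1] - m.slope_ci[0] == pytest.approx(0.0, abs=1e-12)
        assert m.rmse == pytest.approx(0.0, abs=1e-12)

    def test_published_deletion_models(self):
        cd = rate_model_from_table(3.35e-5, 0.16e-3, 25)
        assert cd.predict(80) == pytest.approx(2.00e-3, abs=0.005e-3)
        assert fold_change(cd) == pytest.approx(12.5, abs=0.05)
        ma = rate_model_from_table(22.36e-5, 4.71e-3, 25)
        assert ma.predict(80) == pytest.approx(17.01e-3, abs=0.005e-3)
        assert fold_change(ma) == pytest.approx(3.6, abs=0.05)

    def test_anchored_snv_models(self):
        snv = rate_model_from_table(4.02e-7, 0, 0, anchored_baseline=FOREBRAIN_BASELINE_BP)
        assert snv.predict(25) == pytest.approx(1.38e-5, abs=0.005e-5)
        assert snv.predict(80) == pytest.approx(3.59e-5, abs=0.005e-5)
        assert fold_change(snv) == pytest.approx(2.6, abs=0.05)
        ts = rate_model_from_table(2.22e-7, 0, 0, anchored_baseline=FOREBRAIN_BASELINE_BP)
        assert fold_change(ts) == pytest.approx(2.3, abs=0.05)

    def test_zero_slope_fold_one(self):
        m = rate_model_from_table(0.0, 1e-3, 25)
        assert fold_change(m) == 1.0

    def test_fold_change_scale_invariant(self):
        m1 = rate_model_from_table(3.35e-5, 0.16e-3, 25)
        m2 = rate_model_from_table(3.35e-2, 0.16, 25)
        assert fold_change(m1) == fold_change(m2)

    def test_nonpositive_anchor_rejected(self):
        m = rate_model_from_table(1e-5, 0.0, 0)
        with pytest.raises(ValueError):
            fold_change(m, 0, 80)

    def test_equal_ages_rejected(self):
        with pytest.raises(ValueError):
            fit_rate_model([50, 50, 50], [1, 2, 3])

    def test_recovery_with_noise(self, rng):
        ages = np.array([20, 25, 34, 70, 78, 85.0])
        hits = 0
        for _ in range(50):
            y = 1e-5 + 4e-7 * ages + rng.normal(0, 5e-7, len(ages))
            m = fit_rate_model(ages, y)
            hits += m.ci_contains(4e-7)
        assert hits >= 40  # ~95% nominal coverage


class TestMannWhitney:
    def test_separated_groups_of_five(self):
        r = mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert r.p_value == pytest.approx(2 / 252)

    def test_identical_groups(self):
        assert mann_whitney_exact([3, 3, 3], [3, 3, 3]).p_value == 1.0

    def test_swap_reduces_extremity(self):
        r0 = mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        r1 = mann_whitney_exact([1, 2, 3, 4, 6], [5, 7, 8, 9, 10])
        assert r1.p_value > r0.p_value

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.lists(st.integers(0, 40), min_size=2, max_size=6),
        b=st.lists(st.integers(0, 40), min_size=2, max_size=6),
    )
    def test_matches_scipy_exact_without_ties(self, a, b):
        pooled = a + b
        if len(set(pooled)) != len(pooled):
            return  # scipy's exact method excludes ties
        r = mann_whitney_exact(a, b)
        expected = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.p_value == pytest.approx(expected.pvalue)
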