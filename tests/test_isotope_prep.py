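import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichemix.errors import (
    ConfigurationError,
    DataQualityWarning,
    DegenerateDataError,
)
from nichemix.isotope_prep import (
    SourceDistribution,
    TrophicDiscrimination,
    WhiskerProfile,
    anthropogenic_threshold,
    back_calculate_diet_from_tissue,
    classify_consumers,
    combine_sources,
    delta_value,
    summarize_sources,
    tdf_correct_source,
)
from nichemix.reference import DEFAULT_TDF, NATURAL_PREY_SOURCES

SETTINGS = settings(derandomize=True, max_examples=50, deadline=None)


class TestDeltaValue:
    def test_identity(self):
        assert delta_value(0.011, 0.011) == 0.0

    def test_closed_forms(self):
        assert delta_value(1.01 * 0.011, 0.011) == pytest.approx(10.0)
        assert delta_value(0.98 * 0.011, 0.011) == pytest.approx(-20.0)

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(ConfigurationError):
            delta_value(0.011, 0.0)


class TestSummarize:
    def test_two_sample_stats(self):
        df = pd.DataFrame({"source": ["x", "x"], "d13c": [-23.0, -22.0],
                           "d15n": [5.0, 6.0]})
        s = summarize_sources(df)["x"]
        assert s.mean_d13c == pytest.approx(-22.5)
        assert s.sd_d13c == pytest.approx(math.sqrt(0.5), abs=1e-9)
        assert s.n == 2

    def test_single_sample_flagged(self):
        df = pd.DataFrame({"source": ["x"], "d13c": [-23.0], "d15n": [5.0]})
        with pytest.warns(DataQualityWarning, match="single sample"):
            s = summarize_sources(df)["x"]
        assert s.sd_d13c == 0.0
        assert s.sd_flagged

    def test_recovers_generating_distribution(self):
        # fig-like tissue: -28.3 +/- 2.2, n = 7; mean within 3 SE
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "source": "fig",
                "d13c": rng.normal(-28.3, 2.2, 7),
                "d15n": rng.normal(5.5, 3.4, 7),
            }
        )
        s = summarize_sources(df)["fig"]
        assert abs(s.mean_d13c + 28.3) < 3 * 2.2 / math.sqrt(7)

    def test_empty_table_rejected(self):
        with pytest.raises(DegenerateDataError):
            summarize_sources(pd.DataFrame(columns=["source", "d13c", "d15n"]))


class TestCombine:
    def test_self_combination_is_idempotent_in_moments(self):
        a = SourceDistribution("a", -23.0, 1.5, 5.0, 1.0, 10)
        c = combine_sources(a, a)
        assert c.mean_d13c == pytest.approx(-23.0)
        # pooling two identical groups keeps the same mean; SD shrinks
        # slightly because the (n-1) weights change, never the mean
        assert c.n == 20

    def test_rabbit_gopher_pooled_mean(self):
        rabbit = SourceDistribution("rabbit", -23.0, 2.0, 4.9, 2.1, 12)
        gopher = SourceDistribution("pocket_gopher", -23.6, 2.2, 5.0, 1.3, 11)
        c = combine_sources(rabbit, gopher, name="rabbit_gopher")
        assert c.mean_d13c == pytest.approx(-535.6 / 23, abs=1e-9)
        assert c.n == 23

    def test_moment_pooling_matches_raw_sample_oracle(self):
        rng = np.random.default_rng(3)
        xa = rng.normal(-23.0, 2.0, 12)
        xb = rng.normal(-23.6, 2.2, 11)
        a = SourceDistribution("a", xa.mean(), xa.std(ddof=1), 0, 1, 12)
        b = SourceDistribution("b", xb.mean(), xb.std(ddof=1), 0, 1, 11)
        c = combine_sources(a, b)
        pooled = np.concatenate([xa, xb])
        assert c.mean_d13c == pytest.approx(pooled.mean(), abs=1e-12)
        assert c.sd_d13c == pytest.approx(pooled.std(ddof=1), abs=1e-12)

    def test_raw_samples_path(self):
        df = pd.DataFrame(
            {
                "source": ["a", "a", "b", "b"],
                "d13c": [-23.0, -22.0, -24.0, -25.0],
                "d15n": [5.0, 6.0, 4.0, 3.0],
            }
        )
        a = summarize_sources(df)["a"]
        b = summarize_sources(df)["b"]
        c = combine_sources(a, b, name="ab", samples=df)
        assert c.mean_d13c == pytest.approx(-23.5)
        assert c.n == 4

    def test_flag_mismatch_rejected(self):
        a = SourceDistribution("a", -23.0, 1.0, 5.0, 1.0, 5, anthropogenic=True)
        b = SourceDistribution("b", -23.0, 1.0, 5.0, 1.0, 5, anthropogenic=False)
        with pytest.raises(ConfigurationError, match="flags differ"):
            combine_sources(a, b)


class TestTdfCorrection:
    def test_ground_squirrel_shift(self):
        gs = SourceDistribution("gs", -22.7, 0.9, 6.6, 1.4, 12)
        corrected = tdf_correct_source(gs, DEFAULT_TDF)
        assert corrected.mean_d13c == pytest.approx(-21.2)
        assert corrected.mean_d15n == pytest.approx(10.1)

    def test_zero_tdf_is_identity(self):
        gs = SourceDistribution("gs", -22.7, 0.9, 6.6, 1.4, 12)
        same = tdf_correct_source(gs, TrophicDiscrimination(0, 0, 0, 0))
        assert same == gs

    def test_sd_quadrature(self):
        gs = SourceDistribution("gs", -22.7, 0.9, 6.6, 1.4, 12)
        corrected = tdf_correct_source(gs, DEFAULT_TDF)
        assert corrected.sd_d13c == pytest.approx(math.sqrt(0.81 + 0.25), abs=1e-9)

    @SETTINGS
    @given(
        sd=st.floats(min_value=0, max_value=5),
        sd_tdf=st.floats(min_value=0, max_value=2),
    )
    def test_sd_never_decreases(self, sd, sd_tdf):
        src = SourceDistribution("s", -20.0, sd, 5.0, sd, 3)
        tdf = TrophicDiscrimination(1.5, 3.5, sd_tdf, sd_tdf)
        assert tdf_correct_source(src, tdf).sd_d13c >= sd


class TestBackCalculation:
    def test_human_hair_to_food(self):
        hair = SourceDistribution("hair", -18.9, 0.9, 8.5, 0.7, 14)
        food = back_calculate_diet_from_tissue(hair, 2.0, 3.5)
        assert food.mean_d13c == pytest.approx(-20.9)
        assert food.mean_d15n == pytest.approx(8.5 - 3.5)
        assert food.sd_d13c == 0.9  # carried through unchanged

    def test_zero_delta_identity(self):
        hair = SourceDistribution("hair", -18.9, 0.9, 8.5, 0.7, 14)
        assert back_calculate_diet_from_tissue(hair, 0.0, 0.0) == hair

    def test_round_trip_with_tdf(self):
        hair = SourceDistribution("hair", -18.9, 0.9, 8.5, 0.7, 14)
        food = back_calculate_diet_from_tissue(hair, 2.0, 3.5)
        back = tdf_correct_source(food, TrophicDiscrimination(2.0, 3.5, 0, 0))
        assert back.mean_d13c == pytest.approx(hair.mean_d13c)
        assert back.mean_d15n == pytest.approx(hair.mean_d15n)


class TestThreshold:
    def test_published_value(self):
        th = anthropogenic_threshold(NATURAL_PREY_SOURCES, DEFAULT_TDF, k_sd=1.0)
        assert th == pytest.approx(-20.3, abs=1e-9)

    def test_zero_k_sd(self):
        th = anthropogenic_threshold(NATURAL_PREY_SOURCES, DEFAULT_TDF, k_sd=0.0)
        assert th == pytest.approx(-21.2, abs=1e-9)

    def test_uses_highest_mean_source(self):
        sources = [
            SourceDistribution("low", -25.0, 1.0, 5.0, 1.0, 5),
            SourceDistribution("high", -23.0, 2.0, 5.0, 1.0, 5),
        ]
        th = anthropogenic_threshold(sources, TrophicDiscrimination(1.5, 3.5), 1.0)
        assert th == pytest.approx(-19.5)

    def test_empty_list_rejected(self):
        with pytest.raises(DegenerateDataError):
            anthropogenic_threshold([], DEFAULT_TDF)

    @SETTINGS
    @given(
        k1=st.floats(min_value=0, max_value=3),
        k2=st.floats(min_value=0, max_value=3),
        dc1=st.floats(min_value=0, max_value=3),
        dc2=st.floats(min_value=0, max_value=3),
    )
    def test_monotone_in_k_and_tdf(self, k1, k2, dc1, dc2):
        lo_k, hi_k = sorted([k1, k2])
        lo_d, hi_d = sorted([dc1, dc2])
        t_lo = anthropogenic_threshold(
            NATURAL_PREY_SOURCES, TrophicDiscrimination(lo_d, 3.5), lo_k
        )
        t_hi = anthropogenic_threshold(
            NATURAL_PREY_SOURCES, TrophicDiscrimination(hi_d, 3.5), hi_k
        )
        assert t_hi >= t_lo - 1e-12


class TestClassification:
    def profile(self, name, area, mean_c):
        return WhiskerProfile(name, area, "F", np.full(3, mean_c), np.full(3, 8.0))

    def test_labels_and_fractions(self):
        profiles = [
            self.profile("u1", "urban", -18.0),   # above -20.3
            self.profile("r1", "rural", -21.6),   # below
            self.profile("r2", "rural", -19.0),   # above
        ]
        per_ind, fractions = classify_consumers(profiles, -20.3)
        labels = dict(zip(per_ind["individual"], per_ind["label"]))
        assert labels["u1"] == "anthropogenic-leaning"
        assert labels["r1"] == "natural-leaning"
        assert fractions["urban"] == 1.0
        assert fractions["rural"] == 0.5

    def test_tie_is_natural(self):
        per_ind, _ = classify_consumers([self.profile("x", "urban", -20.3)], -20.3)
        assert per_ind["label"].iloc[0] == "natural-leaning"

    def test_empty_rejected(self):
        with pytest.raises(DegenerateDataError):
            classify_consumers([], -20.3)
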