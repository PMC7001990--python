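import numpy as np
import pandas as pd
import pytest

from nichemix.errors import ConfigurationError
from nichemix.isotope_prep import SourceDistribution, TrophicDiscrimination
from nichemix.mixing_model import corrected_source_arrays
from nichemix.synthetic_data import (
    CovariateSimConfig,
    ScatSimConfig,
    WhiskerSimConfig,
    gen_covariate_table,
    gen_scat_dataset,
    gen_whisker_dataset,
)

A = SourceDistribution("A", -25.0, 1.0, 3.0, 1.0, 10)
B = SourceDistribution("B", -15.0, 1.0, 9.0, 1.0, 10)
NO_TDF = TrophicDiscrimination(0.0, 0.0, 0.0, 0.0)


def scat_config(p_rabbit, p_trash=0.3, **kwargs):
    probs = {
        "urban": {
            season: {"rabbit": p_rabbit, "trash": p_trash}
            for season in ("wet", "dry")
        }
    }
    return ScatSimConfig(probabilities=probs, **kwargs)


class TestScatGenerator:
    def test_forced_occurrence(self):
        records, _ = gen_scat_dataset(scat_config(1.0, seed=1))
        assert (records["rabbit"] == 1).all()

    def test_fo_within_binomial_error(self):
        cfg = scat_config(0.5, transects_per_area=5, scats_per_transect=1000, seed=2)
        records, truth = gen_scat_dataset(cfg)
        n = len(records)
        fo = records["rabbit"].mean()
        assert abs(fo - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_seed_determinism(self):
        cfg = scat_config(0.4, seed=9)
        r1, t1 = gen_scat_dataset(cfg)
        r2, t2 = gen_scat_dataset(cfg)
        assert r1.to_csv() == r2.to_csv()
        assert t1.to_csv() == t2.to_csv()

    def test_truth_table_mirrors_config(self):
        _, truth = gen_scat_dataset(scat_config(0.4, seed=1))
        assert set(truth.columns) == {"area", "season", "item", "probability"}
        assert (
            truth.set_index(["season", "item"]).loc[("wet", "rabbit"), "probability"]
            == 0.4
        )

    def test_empty_scats_flagged_and_resampled(self):
        cfg = scat_config(0.05, p_trash=0.05, scats_per_transect=200, seed=3)
        records, _ = gen_scat_dataset(cfg)
        assert records["is_empty"].any()
        cfg2 = scat_config(
            0.05, p_trash=0.05, scats_per_transect=200, seed=3, resample_empty=True
        )
        records2, _ = gen_scat_dataset(cfg2)
        assert not records2["is_empty"].any()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError, match="outside"):
            scat_config(1.2)

    def test_item_lists_must_match(self):
        probs = {
            "urban": {"wet": {"a": 0.5}, "dry": {"b": 0.5}},
        }
        with pytest.raises(ConfigurationError, match="one item list"):
            ScatSimConfig(probabilities=probs)

    def test_covariate_slope_shifts_anthro_items(self):
        cov = pd.DataFrame(
            {
                "buffer": ["urban-T01", "urban-T02"],
                "prop_altered": [0.0, 0.4],
            }
        )
        cfg = scat_config(
            0.5, transects_per_area=2, scats_per_transect=2000, seed=4,
            anthro_slope=-4.0, anthropogenic_items=("trash",),
        )
        records, _ = gen_scat_dataset(cfg, covariates=cov)
        fo = records.groupby("transect")["trash"].mean()
        assert fo["urban-T01"] > fo["urban-T02"]  # more altered space, less trash


class TestWhiskerGenerator:
    def test_zero_noise_reproduces_forward_model(self):
        cfg = WhiskerSimConfig(
            sources=[A, B],
            diet_proportions={"urban": [0.3, 0.7]},
            tdf=NO_TDF,
            between_sd=(0.0, 0.0),
            within_sd=(0.0, 0.0),
            individuals_per_area=3,
            subsamples_mean=4,
            subsamples_sd=0,
            seed=5,
        )
        whiskers, truth = gen_whisker_dataset(cfg)
        _, mu, _ = corrected_source_arrays([A, B], NO_TDF)
        expected = np.array([0.3, 0.7]) @ mu
        assert np.abs(whiskers["d13c"] - expected[0]).max() < 1e-9
        assert np.abs(whiskers["d15n"] - expected[1]).max() < 1e-9

    def test_single_source_centers_on_corrected_mean(self):
        tdf = TrophicDiscrimination(1.5, 3.5, 0.0, 0.0)
        cfg = WhiskerSimConfig(
            sources=[A],
            diet_proportions={"rural": [1.0]},
            tdf=tdf,
            between_sd=(0.0, 0.0),
            within_sd=(0.5, 0.5),
            individuals_per_area=10,
            subsamples_mean=50,
            subsamples_sd=0,
            seed=6,
        )
        whiskers, _ = gen_whisker_dataset(cfg)
        assert whiskers["d13c"].mean() == pytest.approx(-23.5, abs=0.1)
        assert whiskers["d15n"].mean() == pytest.approx(6.5, abs=0.1)

    def test_variance_components_recovered(self):
        cfg = WhiskerSimConfig(
            sources=[A, B],
            diet_proportions={"urban": [0.5, 0.5]},
            tdf=NO_TDF,
            between_sd=(1.0, 2.0),
            within_sd=(0.8, 0.5),
            individuals_per_area=200,
            subsamples_mean=16,
            subsamples_sd=0,
            seed=7,
        )
        whiskers, _ = gen_whisker_dataset(cfg)
        per_ind = whiskers.groupby("individual")["d13c"]
        within_est = per_ind.var(ddof=1).mean()
        between_est = per_ind.mean().var(ddof=1) - within_est / 16
        assert within_est == pytest.approx(0.8**2, rel=0.2)
        assert between_est == pytest.approx(1.0**2, rel=0.2)

    def test_off_simplex_proportions_rejected(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            WhiskerSimConfig(
                sources=[A, B],
                diet_proportions={"urban": [0.5, 0.6]},
                tdf=NO_TDF,
            )

    def test_seed_determinism(self):
        cfg = WhiskerSimConfig(
            sources=[A, B],
            diet_proportions={"urban": [0.4, 0.6]},
            tdf=NO_TDF,
            individuals_per_area=4,
            seed=8,
        )
        w1, t1 = gen_whisker_dataset(cfg)
        w2, t2 = gen_whisker_dataset(cfg)
        assert w1.to_csv() == w2.to_csv()
        assert t1.to_csv() == t2.to_csv()

    def test_truth_contains_latent_means(self):
        cfg = WhiskerSimConfig(
            sources=[A, B],
            diet_proportions={"urban": [0.4, 0.6]},
            tdf=NO_TDF,
            between_sd=(0.0, 0.0),
            within_sd=(0.0, 0.0),
            individuals_per_area=2,
            subsamples_mean=3,
            subsamples_sd=0,
            seed=9,
        )
        whiskers, truth = gen_whisker_dataset(cfg)
        one = truth[truth["individual"] == truth["individual"].iloc[0]]
        obs = whiskers[whiskers["individual"] == truth["individual"].iloc[0]]
        assert one["latent_d13c"].iloc[0] == pytest.approx(obs["d13c"].iloc[0])


class TestCovariateGenerator:
    def test_degenerate_ranges_give_constants(self):
        cfg = CovariateSimConfig(
            n_buffers=10,
            prop_urban_range=(0.5, 0.5),
            road_density_range=(3.0, 3.0),
            seed=10,
        )
        table = gen_covariate_table(cfg)
        assert table["prop_urban"].nunique() == 1
        assert table["road_density"].nunique() == 1

    def test_configured_correlation_recovered(self):
        cfg = CovariateSimConfig(
            n_buffers=500, roads_humans_correlation=0.9, seed=11
        )
        table = gen_covariate_table(cfg)
        r = np.corrcoef(table["road_density"], table["human_density"])[0, 1]
        assert 0.8 < r < 0.97

    def test_out_of_range_proportions_rejected(self):
        with pytest.raises(ConfigurationError, match="within"):
            CovariateSimConfig(prop_urban_range=(0.2, 1.4))

    def test_negative_density_rejected(self):
        with pytest.raises(ConfigurationError, match="non-negative"):
            CovariateSimConfig(road_density_range=(-1.0, 5.0))

    def test_seed_determinism(self):
        cfg = CovariateSimConfig(n_buffers=20, seed=12)
        assert gen_covariate_table(cfg).to_csv() == gen_covariate_table(cfg).to_csv()
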