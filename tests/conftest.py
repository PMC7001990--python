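import numpy as np
import pandas as pd
import pytest

from nichemix.isotope_prep import SourceDistribution, TrophicDiscrimination
from nichemix.reference import DEFAULT_DIET_PROPORTIONS, mixing_tdfs, pooled_sources
from nichemix.scat_diet import FoodItemTaxonomy


@pytest.fixture(scope="session")
def six_sources() -> list[SourceDistribution]:
    """The six pooled diet-space sources (rabbit-gopher combined)."""
    return pooled_sources()


@pytest.fixture(scope="session")
def six_tdfs(six_sources):
    return mixing_tdfs([s.name for s in six_sources])


@pytest.fixture(scope="session")
def urban_truth(six_sources) -> np.ndarray:
    props = DEFAULT_DIET_PROPORTIONS["urban"]
    return np.array([props[s.name] for s in six_sources])


@pytest.fixture()
def zero_tdf() -> TrophicDiscrimination:
    return TrophicDiscrimination(0.0, 0.0, 0.0, 0.0)


@pytest.fixture()
def toy_scat_records() -> pd.DataFrame:
    """Four scats: {A}, {A,B}, {A}, {B} on one transect, mixed months."""
    return pd.DataFrame(
        {
            "scat_id": ["s1", "s2", "s3", "s4"],
            "transect": ["t1"] * 4,
            "area": ["urban"] * 4,
            "year_month": ["2017-11", "2017-12", "2017-01", "2017-02"],
            "A": [1, 1, 1, 0],
            "B": [0, 1, 0, 1],
        }
    )


@pytest.fixture()
def toy_taxonomy() -> FoodItemTaxonomy:
    return FoodItemTaxonomy(
        category={"A": "rabbit", "B": "trash"},
        anthropogenic={"A": False, "B": True},
    )
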