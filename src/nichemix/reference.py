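"""Reference values for the southern California coyote diet system.

Default trophic discrimination factors, published-style source tissue
statistics, the nine scat analysis categories, and the default wet/dry
season rule. These serve as sensible defaults for the pipeline and as the
configuration of the synthetic-data generators; every value is overridable.
"""

from __future__ import annotations

from dataclasses import replace

from .isotope_prep import (
    SourceDistribution,
    TrophicDiscrimination,
    back_calculate_diet_from_tissue,
)

#: Keratin trophic discrimination used for prey sources (‰), SD 0.5‰ each.
DEFAULT_TDF = TrophicDiscrimination(d13c=1.5, d15n=3.5, sd_d13c=0.5, sd_d15n=0.5)

#: The human-food source enters the mixing model with a larger carbon TDF
#: (2.5‰), typical of mammalian carnivore keratins feeding on processed food.
HUMAN_FOOD_TDF = TrophicDiscrimination(d13c=2.5, d15n=3.5, sd_d13c=0.5, sd_d15n=0.5)

#: Discrimination factors used to back-calculate human *food* from human
#: *hair* (hair is one trophic step above the diet): δ13C − 2.0‰, δ15N − 3.5‰.
HAIR_TO_DIET_D13C = 2.0
HAIR_TO_DIET_D15N = 3.5

#: Human hair measured from Southern California residents (tissue space).
HUMAN_HAIR = SourceDistribution(
    name="human_hair",
    mean_d13c=-18.9,
    sd_d13c=0.9,
    mean_d15n=8.5,
    sd_d15n=0.7,
    n=14,
    anthropogenic=True,
)

#: Diet-space source statistics (mean ± SD ‰, n) for potential coyote foods.
NATURAL_PREY_SOURCES = [
    SourceDistribution("ground_squirrel", -22.7, 0.9, 6.6, 1.4, 12),
    SourceDistribution("rabbit", -23.0, 2.0, 4.9, 2.1, 12),
    SourceDistribution("pocket_gopher", -23.6, 2.2, 5.0, 1.3, 11),
    SourceDistribution("jerusalem_cricket", -25.9, 1.1, 3.6, 1.6, 10),
]

#: Figs: the dominant ornamental fruit; a C3 plant, so isotopically natural.
FIG_SOURCE = SourceDistribution("fig", -28.3, 2.2, 5.5, 3.4, 7)

DOMESTIC_CAT_SOURCE = SourceDistribution(
    "domestic_cat", -16.7, 1.7, 6.6, 0.74, 12, anthropogenic=True
)

# Human food in diet space: back-calculated from hair. The published food
# values are −20.9 ± 0.9 (= −18.9 − 2.0 exactly) and 4.9 ± 0.7; the nitrogen
# value reflects the unrounded hair mean (the rounded 8.5 − 3.5 would give
# 5.0), so the food-source values are stored as published rather than
# re-derived from the rounded hair mean.
HUMAN_FOOD_SOURCE = replace(
    back_calculate_diet_from_tissue(HUMAN_HAIR, HAIR_TO_DIET_D13C, HAIR_TO_DIET_D15N),
    name="human_food",
    mean_d15n=4.9,
)

#: The full seven-source diet-space set (before the rabbit/gopher pooling).
ALL_SOURCES = NATURAL_PREY_SOURCES + [FIG_SOURCE, DOMESTIC_CAT_SOURCE, HUMAN_FOOD_SOURCE]

#: Per-source TDFs for the mixing model: human food uses the 2.5‰ carbon TDF.
def mixing_tdfs(source_names) -> dict[str, TrophicDiscrimination]:
    return {
        name: (HUMAN_FOOD_TDF if name == "human_food" else DEFAULT_TDF)
        for name in source_names
    }


#: The nine food categories used for niche-breadth (B); each occurred in
#: >10% of scats across the study areas.
NINE_CATEGORIES = (
    "birds",
    "reptiles",
    "invertebrates",
    "trash",
    "ornamental_fruit_seeds",
    "domestic_cat",
    "rabbit",
    "ground_squirrel",
    "pocket_gopher",
)

#: Categories counted as anthropogenic subsidies in scat analyses.
ANTHROPOGENIC_CATEGORIES = (
    "trash",
    "ornamental_fruit_seeds",
    "domestic_cat",
)

#: Wet season = November–April (cool, rainy); dry season = May–October.
WET_MONTHS = frozenset({11, 12, 1, 2, 3, 4})


def pooled_sources() -> list[SourceDistribution]:
    """The six mixing-model sources: rabbits and pocket gophers pooled
    a priori into "rabbit_gopher" (their isotope values are statistically
    indistinguishable), alphabetically ordered."""
    from .isotope_prep import combine_sources

    by_name = {s.name: s for s in ALL_SOURCES}
    pooled = combine_sources(
        by_name.pop("rabbit"), by_name.pop("pocket_gopher"), name="rabbit_gopher"
    )
    return sorted([pooled, *by_name.values()], key=lambda s: s.name)


# Estimated diet proportions per study area over the six pooled sources
# (human food and domestic cats dominate urban diets; natural prey and figs
# grow with decreasing urbanization). The five named shares sum to 1; a 2%
# Jerusalem-cricket share is carved out so no component sits exactly on the
# simplex boundary, which would make it unreachable by any positive draw.
_BASE_DIET = {
    "urban": {"human_food": 0.376, "domestic_cat": 0.395, "fig": 0.056,
              "rabbit_gopher": 0.090, "ground_squirrel": 0.083},
    "suburban": {"human_food": 0.338, "domestic_cat": 0.158, "fig": 0.117,
                 "rabbit_gopher": 0.227, "ground_squirrel": 0.160},
    "rural": {"human_food": 0.273, "domestic_cat": 0.093, "fig": 0.256,
              "rabbit_gopher": 0.231, "ground_squirrel": 0.147},
}
_CRICKET_SHARE = 0.02

DEFAULT_DIET_PROPORTIONS: dict[str, dict[str, float]] = {
    area: {
        **{k: v * (1.0 - _CRICKET_SHARE) for k, v in shares.items()},
        "jerusalem_cricket": _CRICKET_SHARE,
    }
    for area, shares in _BASE_DIET.items()
}
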