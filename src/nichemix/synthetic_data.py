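"""Synthetic diet datasets with known ground truth.

Three generators emulate the study's four input tables: scat records with
per-area/per-season item occurrence probabilities, whisker (vibrissa)
subsample series with hierarchical between/within-individual isotope
variance, and land-use covariate tables for transect buffers. Each returns
the generated table together with the truth used to generate it, so every
downstream statistic can be checked against a known answer.

A single master seed spawns independent substreams per generator, so the
generators can be used together or in isolation with stable results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError
from .isotope_prep import SourceDistribution, TrophicDiscrimination
from .mixing_model import corrected_source_arrays
from .reference import WET_MONTHS

_WET = sorted(WET_MONTHS)
_DRY = sorted(set(range(1, 13)) - WET_MONTHS)


def spawn_rngs(master_seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


@dataclass
class ScatSimConfig:
    """Occurrence probabilities per (area, season, item) plus sampling effort.

    ``probabilities`` maps area -> season -> item -> probability of that
    item appearing in a scat. Items are generated independently per scat
    (only marginal occurrence rates are consumed downstream); empty scats
    are allowed and kept in the denominator N unless ``resample_empty``.
    """

    probabilities: Mapping[str, Mapping[str, Mapping[str, float]]]
    transects_per_area: int = 5
    scats_per_transect: int = 40
    anthro_slope: float | None = None  # logit-scale effect of altered open space
    anthropogenic_items: Sequence[str] = ()
    resample_empty: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        item_sets = set()
        for area, seasons in self.probabilities.items():
            for season, items in seasons.items():
                item_sets.add(frozenset(items))
                for item, p in items.items():
                    if not 0.0 <= p <= 1.0:
                        raise ConfigurationError(
                            f"probability for {item!r} in {area}/{season} "
                            f"is {p}, outside [0, 1]"
                        )
        if len(item_sets) != 1:
            raise ConfigurationError("all areas/seasons must share one item list")
        if self.transects_per_area < 1 or self.scats_per_transect < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.anthro_slope is not None and not self.anthropogenic_items:
            raise ConfigurationError(
                "anthro_slope requires anthropogenic_items to be named"
            )

    @property
    def items(self) -> list[str]:
        first_area = next(iter(self.probabilities.values()))
        return sorted(next(iter(first_area.values())))


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def gen_scat_dataset(
    config: ScatSimConfig,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a scat record table and its truth table.

    Returns ``(records, truth)``: records have one row per scat with the
    standard metadata columns and one 0/1 column per item; truth has one row
    per (area, season, item) with the probability actually used. When
    ``config.anthro_slope`` is set and a covariate table is supplied,
    anthropogenic-item probabilities are shifted on the logit scale by
    slope × (prop_altered − mean prop_altered) per transect.
    """
    rng = spawn_rngs(config.seed, 1)[0]
    items = config.items
    rows = []
    truth_rows = []
    scat_id = 0
    altered_by_transect: dict[str, float] = {}
    if covariates is not None and "prop_altered" in covariates.columns:
        altered_by_transect = dict(
            zip(covariates["buffer"], covariates["prop_altered"])
        )
        altered_center = float(np.mean(list(altered_by_transect.values())))
    for area in sorted(config.probabilities):
        for season in sorted(config.probabilities[area]):
            probs = config.probabilities[area][season]
            base = np.array([probs[i] for i in items])
            for item, p in zip(items, base):
                truth_rows.append(
                    {"area": area, "season": season, "item": item, "probability": p}
                )
            months = _WET if season == "wet" else _DRY
            for t in range(config.transects_per_area):
                transect = f"{area}-T{t + 1:02d}"
                p_vec = base.copy()
                if (
                    config.anthro_slope is not None
                    and transect in altered_by_transect
                ):
                    shift = config.anthro_slope * (
                        altered_by_transect[transect] - altered_center
                    )
                    for j, item in enumerate(items):
                        if item in config.anthropogenic_items:
                            p_vec[j] = 1.0 / (
                                1.0 + np.exp(-(_logit(np.array([base[j]]))[0] + shift))
                            )
                n = config.scats_per_transect
                flags = (rng.random((n, len(items))) < p_vec).astype(int)
                if config.resample_empty:
                    for attempt in range(1000):
                        empty = flags.sum(axis=1) == 0
                        if not empty.any():
                            break
                        flags[empty] = (
                            rng.random((int(empty.sum()), len(items))) < p_vec
                        ).astype(int)
                month_choices = rng.choice(months, size=n)
                for i in range(n):
                    scat_id += 1
                    row = {
                        "scat_id": f"S{scat_id:06d}",
                        "transect": transect,
                        "area": area,
                        "year_month": f"2017-{month_choices[i]:02d}",
                    }
                    row.update(dict(zip(items, flags[i])))
                    rows.append(row)
    records = pd.DataFrame(rows)
    records["is_empty"] = records[items].sum(axis=1) == 0
    return records, pd.DataFrame(truth_rows)


@dataclass
class WhiskerSimConfig:
    """Hierarchical forward model for vibrissa subsample series.

    Per area: the group diet-proportion vector ``diet_proportions[area]``
    (over the named sources, summing to 1) fixes the group-level tissue
    mean via the mixing forward model. Each individual draws a latent mean
    around it (between-individual SD per isotope), then ``n`` subsamples
    around the latent mean (within-individual SD). The study-scale default
    draws subsample counts from round(Normal(16, 7)) clipped to >= 1.
    """

    sources: Sequence[SourceDistribution]
    diet_proportions: Mapping[str, Sequence[float]]
    tdf: TrophicDiscrimination | Mapping[str, TrophicDiscrimination]
    between_sd: tuple[float, float] = (1.0, 1.0)  # (δ13C, δ15N) ‰
    within_sd: tuple[float, float] = (1.0, 1.0)
    individuals_per_area: int = 20
    subsamples_mean: float = 16.0
    subsamples_sd: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.sources)
        for area, p in self.diet_proportions.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (k,):
                raise ConfigurationError(
                    f"area {area!r}: proportion vector length {p.size} != {k} sources"
                )
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ConfigurationError(
                    f"area {area!r}: proportions must be >= 0 and sum to 1"
                )
        if min(self.between_sd) < 0 or min(self.within_sd) < 0:
            raise ConfigurationError("SDs must be >= 0")
        if self.individuals_per_area < 1 or self.subsamples_mean < 1:
            raise ConfigurationError("counts must be >= 1")


def gen_whisker_dataset(
    config: WhiskerSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a whisker subsample table and its per-individual truth.

    Returns ``(whiskers, truth)``. ``whiskers`` is long-form: individual,
    area, sex, subsample, d13c, d15n. ``truth`` holds each individual's
    latent mean and the group forward-model mean plus the proportion vector
    (one row per individual × source).
    """
    rng = spawn_rngs(config.seed, 1)[0]
    names = [s.name for s in config.sources]
    _, mu, var = corrected_source_arrays(config.sources, config.tdf)
    rows = []
    truth_rows = []
    for area in sorted(config.diet_proportions):
        p = np.asarray(config.diet_proportions[area], dtype=float)
        group_mean = p @ mu  # deterministic forward-model mean, (2,)
        for i in range(config.individuals_per_area):
            ind = f"{area}-C{i + 1:03d}"
            sex = "F" if rng.random() < 0.5 else "M"
            latent = group_mean + rng.normal(0.0, config.between_sd, size=2)
            if config.subsamples_sd > 0:
                n_sub = max(
                    1,
                    int(round(rng.normal(config.subsamples_mean, config.subsamples_sd))),
                )
            else:
                n_sub = max(1, int(round(config.subsamples_mean)))
            sub = latent + rng.normal(
                0.0, config.within_sd, size=(n_sub, 2)
            )
            for j in range(n_sub):
                rows.append(
                    {
                        "individual": ind,
                        "area": area,
                        "sex": sex,
                        "subsample": j + 1,
                        "d13c": sub[j, 0],
                        "d15n": sub[j, 1],
                    }
                )
            for k, name in enumerate(names):
                truth_rows.append(
                    {
                        "individual": ind,
                        "area": area,
                        "source": name,
                        "proportion": p[k],
                        "group_mean_d13c": group_mean[0],
                        "group_mean_d15n": group_mean[1],
                        "latent_d13c": latent[0],
                        "latent_d15n": latent[1],
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


@dataclass
class CovariateSimConfig:
    """Ranges and correlation for the four buffer land-use covariates.

    Each covariate is sampled from a uniform over its range via a Gaussian
    copula with the configured pairwise correlation between road density
    and human density (the empirically strongest pair); other pairs are
    independent unless a full correlation matrix is given.
    """

    n_buffers: int = 24
    prop_urban_range: tuple[float, float] = (0.0, 0.98)
    prop_altered_range: tuple[float, float] = (0.0, 0.33)
    road_density_range: tuple[float, float] = (1.0, 15.5)  # km/km²
    human_density_range: tuple[float, float] = (0.1, 11.0)  # 10,000 people/km²
    roads_humans_correlation: float = 0.85
    correlation_matrix: np.ndarray | None = None  # order: urban, altered, roads, humans
    area_labels: Sequence[str] = ("urban", "suburban")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_urban_range", "prop_altered_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} must lie within [0, 1]")
        for name in ("road_density_range", "human_density_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"{name} must be non-negative and ordered")
        if not -1.0 <= self.roads_humans_correlation <= 1.0:
            raise ConfigurationError("correlation must be in [-1, 1]")
        if self.n_buffers < 1:
            raise ConfigurationError("n_buffers must be >= 1")


_COVARIATE_ORDER = ("prop_urban", "prop_altered", "road_density", "human_density")


def gen_covariate_table(config: CovariateSimConfig) -> pd.DataFrame:
    """Generate a buffer covariate table shaped like the study's Table 1."""
    rng = spawn_rngs(config.seed, 1)[0]
    if config.correlation_matrix is not None:
        corr = np.asarray(config.correlation_matrix, dtype=float)
        if corr.shape != (4, 4):
            raise ConfigurationError("correlation_matrix must be 4x4")
    else:
        corr = np.eye(4)
        corr[2, 3] = corr[3, 2] = config.roads_humans_correlation
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(4))
    z = rng.standard_normal((config.n_buffers, 4)) @ chol.T
    u = norm.cdf(z)
    ranges = {
        "prop_urban": config.prop_urban_range,
        "prop_altered": config.prop_altered_range,
        "road_density": config.road_density_range,
        "human_density": config.human_density_range,
    }
    data = {
        name: ranges[name][0] + u[:, j] * (ranges[name][1] - ranges[name][0])
        for j, name in enumerate(_COVARIATE_ORDER)
    }
    areas = [
        config.area_labels[i % len(config.area_labels)]
        for i in range(config.n_buffers)
    ]
    table = pd.DataFrame(
        {
            "buffer": [f"{areas[i]}-T{i // len(config.area_labels) + 1:02d}"
                       for i in range(config.n_buffers)],
            "area": areas,
            **data,
        }
    )
    return table
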