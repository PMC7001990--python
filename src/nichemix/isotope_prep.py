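"""Isotope conversions and corrections for diet reconstruction.

Carries carbon and nitrogen stable-isotope values in per-mil (‰) delta
notation throughout: δ13C relative to VPDB, δ15N relative to atmospheric N2.
Raw isotope ratios appear only in :func:`delta_value`.

The module covers the preparatory steps of a two-isotope diet study:
summarising prey/food source tissues, correcting sources for trophic
discrimination (consumer tissue is systematically enriched relative to its
diet), back-calculating a "human food" source from human hair, pooling
a-priori-combined sources, and the δ13C threshold separating natural from
anthropogenic (C4/corn-based) food chains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataQualityWarning, DegenerateDataError

ISOTOPES = ("d13c", "d15n")

#: SD floor applied when a source is a near-delta distribution (n=1 groups).
SD_FLOOR = 1e-6

AREAS = ("urban", "suburban", "rural")


@dataclass(frozen=True)
class IsotopeValue:
    """A single (δ13C, δ15N) measurement in ‰."""

    d13c: float
    d15n: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d13c) and math.isfinite(self.d15n)):
            raise ConfigurationError("isotope values must be finite")


@dataclass(frozen=True)
class TrophicDiscrimination:
    """Trophic discrimination factors Δ (consumer tissue minus diet), in ‰.

    ``sd_d13c`` / ``sd_d15n`` are the uncertainty (SD) attached to the
    discrimination factors themselves; they are added in quadrature to
    source SDs when correcting sources into consumer-tissue space.
    """

    d13c: float
    d15n: float
    sd_d13c: float = 0.5
    sd_d15n: float = 0.5

    def __post_init__(self) -> None:
        if self.sd_d13c < 0 or self.sd_d15n < 0:
            raise ConfigurationError("TDF SDs must be non-negative")

    def delta(self, isotope: str) -> float:
        return getattr(self, isotope)

    def sd(self, isotope: str) -> float:
        return getattr(self, f"sd_{isotope}")


@dataclass(frozen=True)
class SourceDistribution:
    """Summary statistics of one food source's isotope values (‰)."""

    name: str
    mean_d13c: float
    sd_d13c: float
    mean_d15n: float
    sd_d15n: float
    n: int
    anthropogenic: bool = False
    sd_flagged: bool = False  # True when SD is a placeholder (n = 1 group)

    def __post_init__(self) -> None:
        if self.sd_d13c < 0 or self.sd_d15n < 0:
            raise ConfigurationError(f"source {self.name!r}: SD must be >= 0")
        if self.n < 1:
            raise ConfigurationError(f"source {self.name!r}: n must be >= 1")

    def mean(self, isotope: str) -> float:
        return getattr(self, f"mean_{isotope}")

    def sd(self, isotope: str) -> float:
        return getattr(self, f"sd_{isotope}")


@dataclass
class WhiskerProfile:
    """Ordered δ13C/δ15N subsample series along one individual's vibrissa.

    Vibrissae are metabolically inert keratin, so the segment series is a
    time-averaged record of the individual's assimilated diet. Subsamples
    are treated as exchangeable (no along-whisker ordering is assumed).
    """

    individual: str
    area: str
    sex: str
    d13c: np.ndarray
    d15n: np.ndarray

    def __post_init__(self) -> None:
        self.d13c = np.asarray(self.d13c, dtype=float)
        self.d15n = np.asarray(self.d15n, dtype=float)
        if self.d13c.size < 1 or self.d13c.size != self.d15n.size:
            raise ConfigurationError(
                f"profile {self.individual!r}: need >= 1 paired subsample"
            )
        if self.area not in AREAS:
            raise ConfigurationError(
                f"profile {self.individual!r}: area must be one of {AREAS}, "
                f"got {self.area!r}"
            )

    @property
    def n_subsamples(self) -> int:
        return int(self.d13c.size)

    def values(self, isotope: str) -> np.ndarray:
        return getattr(self, isotope)

    def mean(self) -> IsotopeValue:
        return IsotopeValue(float(self.d13c.mean()), float(self.d15n.mean()))


def delta_value(r_sample: float, r_standard: float) -> float:
    """δ = (R_sample / R_standard − 1) × 1000, in ‰.

    ``r_sample`` and ``r_standard`` are heavy/light isotope ratios
    (13C/12C or 15N/14N) of the sample and the international standard.
    """
    if r_standard <= 0:
        raise ConfigurationError("standard isotope ratio must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def summarize_sources(
    samples: pd.DataFrame,
    *,
    source_col: str = "source",
    anthropogenic: Mapping[str, bool] | None = None,
) -> dict[str, SourceDistribution]:
    """Per-source mean and sample SD (n−1 denominator) of δ13C and δ15N.

    ``samples`` has one row per tissue sample with columns ``source``,
    ``d13c``, ``d15n``. Sources with a single sample get SD = 0 and an
    ``sd_flagged`` marker plus a warning (rather than an error) so that toy
    fixtures run; downstream mixing floors such SDs at ``SD_FLOOR``.
    """
    if samples.empty:
        raise DegenerateDataError("source table is empty")
    missing = {source_col, "d13c", "d15n"} - set(samples.columns)
    if missing:
        raise ConfigurationError(f"source table missing columns: {sorted(missing)}")
    anthropogenic = anthropogenic or {}
    out: dict[str, SourceDistribution] = {}
    for name, grp in samples.groupby(source_col, sort=True):
        n = len(grp)
        flagged = n == 1
        if flagged:
            warnings.warn(
                f"source {name!r} has a single sample; SD reported as 0",
                DataQualityWarning,
                stacklevel=2,
            )
        out[str(name)] = SourceDistribution(
            name=str(name),
            mean_d13c=float(grp["d13c"].mean()),
            sd_d13c=0.0 if flagged else float(grp["d13c"].std(ddof=1)),
            mean_d15n=float(grp["d15n"].mean()),
            sd_d15n=0.0 if flagged else float(grp["d15n"].std(ddof=1)),
            n=n,
            anthropogenic=bool(anthropogenic.get(str(name), False)),
            sd_flagged=flagged,
        )
    return out


def _pool_moments(
    m_a: float, s_a: float, n_a: int, m_b: float, s_b: float, n_b: int
) -> tuple[float, float]:
    """Exact two-group pooling of mean and sample SD.

    Reconstructs the combined group's sum of squares from within-group
    (n−1)s² terms plus the between-group component, then re-normalises with
    the combined n−1 denominator.
    """
    n = n_a + n_b
    mean = (n_a * m_a + n_b * m_b) / n
    ss = (
        (n_a - 1) * s_a**2
        + (n_b - 1) * s_b**2
        + n_a * (m_a - mean) ** 2
        + n_b * (m_b - mean) ** 2
    )
    sd = math.sqrt(ss / (n - 1)) if n > 1 else 0.0
    return mean, sd


def combine_sources(
    a: SourceDistribution,
    b: SourceDistribution,
    *,
    name: str | None = None,
    samples: pd.DataFrame | None = None,
) -> SourceDistribution:
    """Pool two food sources into one (e.g. rabbits + pocket gophers).

    When the raw ``samples`` table is available the pooled group is
    re-summarised from it; otherwise moments are combined exactly
    (weighted mean; within + between variance components).
    """
    if a.anthropogenic != b.anthropogenic:
        raise ConfigurationError(
            f"cannot combine {a.name!r} and {b.name!r}: "
            "anthropogenic flags differ"
        )
    name = name or f"{a.name}-{b.name}"
    if samples is not None:
        sub = samples[samples["source"].isin([a.name, b.name])].copy()
        if sub.empty:
            raise DegenerateDataError(
                f"no raw samples found for {a.name!r} or {b.name!r}"
            )
        sub["source"] = name
        pooled = summarize_sources(sub, anthropogenic={name: a.anthropogenic})
        return pooled[name]
    mc, sc = _pool_moments(a.mean_d13c, a.sd_d13c, a.n, b.mean_d13c, b.sd_d13c, b.n)
    mn, sn = _pool_moments(a.mean_d15n, a.sd_d15n, a.n, b.mean_d15n, b.sd_d15n, b.n)
    return SourceDistribution(
        name=name,
        mean_d13c=mc,
        sd_d13c=sc,
        mean_d15n=mn,
        sd_d15n=sn,
        n=a.n + b.n,
        anthropogenic=a.anthropogenic,
        sd_flagged=a.sd_flagged or b.sd_flagged,
    )


def tdf_correct_source(
    source: SourceDistribution, tdf: TrophicDiscrimination
) -> SourceDistribution:
    """Shift a source from diet space into consumer-tissue space.

    mean′ = mean + Δ per isotope; SD′ = sqrt(SD² + SD_Δ²) — the TDF's own
    uncertainty is added in quadrature, so SD never decreases.
    """
    return replace(
        source,
        mean_d13c=source.mean_d13c + tdf.d13c,
        sd_d13c=math.hypot(source.sd_d13c, tdf.sd_d13c),
        mean_d15n=source.mean_d15n + tdf.d15n,
        sd_d15n=math.hypot(source.sd_d15n, tdf.sd_d15n),
    )


def back_calculate_diet_from_tissue(
    tissue: SourceDistribution, delta_d13c: float, delta_d15n: float
) -> SourceDistribution:
    """Estimate a diet-space source from consumer tissue values.

    Used for the human-food source: human hair reflects the human diet one
    trophic step up, so subtracting hair-specific discrimination factors
    recovers the food itself. SDs are carried through unchanged.
    """
    return replace(
        tissue,
        mean_d13c=tissue.mean_d13c - delta_d13c,
        mean_d15n=tissue.mean_d15n - delta_d15n,
    )


def anthropogenic_threshold(
    natural_sources: Sequence[SourceDistribution],
    tdf: TrophicDiscrimination,
    k_sd: float = 1.0,
) -> float:
    """δ13C cut-off between natural and anthropogenic food chains (‰).

    Takes the natural prey source with the highest mean δ13C, corrects it
    into consumer-tissue space, and adds ``k_sd`` standard deviations of the
    raw source: theoretically the maximum δ13C a consumer of purely natural
    prey can carry. Individuals above it lean on anthropogenic (C4-based)
    subsidies.
    """
    if not natural_sources:
        raise DegenerateDataError("need at least one natural source")
    top = max(natural_sources, key=lambda s: s.mean_d13c)
    return top.mean_d13c + tdf.d13c + k_sd * top.sd_d13c


def classify_consumers(
    profiles: Iterable[WhiskerProfile], threshold: float
) -> tuple[pd.DataFrame, pd.Series]:
    """Label individuals by mean δ13C relative to the threshold.

    Returns ``(per_individual, per_area_fraction)``. Individuals strictly
    above the threshold are "anthropogenic-leaning"; equality classifies as
    "natural-leaning" (the threshold is the maximum natural value).
    """
    if not math.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    profiles = list(profiles)
    if not profiles:
        raise DegenerateDataError("no whisker profiles supplied")
    rows = []
    for prof in profiles:
        mean_c = float(prof.d13c.mean())
        rows.append(
            {
                "individual": prof.individual,
                "area": prof.area,
                "mean_d13c": mean_c,
                "label": (
                    "anthropogenic-leaning"
                    if mean_c > threshold
                    else "natural-leaning"
                ),
            }
        )
    table = pd.DataFrame(rows)
    fractions = (
        (table["label"] == "anthropogenic-leaning")
        .groupby(table["area"])
        .mean()
        .rename("fraction_above_threshold")
    )
    return table, fractions


def profiles_from_table(whiskers: pd.DataFrame) -> list[WhiskerProfile]:
    """Build :class:`WhiskerProfile` objects from a long-form subsample table.

    Expects columns ``individual``, ``area``, ``sex``, ``d13c``, ``d15n``
    (a ``subsample`` index column is allowed and ignored).
    """
    required = {"individual", "area", "sex", "d13c", "d15n"}
    missing = required - set(whiskers.columns)
    if missing:
        raise ConfigurationError(f"whisker table missing columns: {sorted(missing)}")
    profiles = []
    for ind, grp in whiskers.groupby("individual", sort=True):
        profiles.append(
            WhiskerProfile(
                individual=str(ind),
                area=str(grp["area"].iloc[0]),
                sex=str(grp["sex"].iloc[0]),
                d13c=grp["d13c"].to_numpy(dtype=float),
                d15n=grp["d15n"].to_numpy(dtype=float),
            )
        )
    return profiles
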