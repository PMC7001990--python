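"""Occurrence-based diet composition indices from scat records.

A scat record table has one row per scat (presence/absence flags per food
item). From per-group occurrence counts this module computes:

* FO — frequency of occurrence: 100·n_i/N, the percentage of scats
  containing item i (totals may exceed 100% because scats hold >1 item);
* PO — percentage of occurrence: 100·n_i/Σn_i, item i's share of all
  occurrences (totals exactly 100%);
* B — Levins niche breadth: 1/Σp_i² with p_i = n_i/Σn_i, ranging from 1
  (monophagy) to the number of categories (uniform use);
* C — Morisita's index of niche overlap between two groups, with the
  finite-sample (n−1)/(N−1) correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError
from .reference import NINE_CATEGORIES, WET_MONTHS

META_COLUMNS = ("scat_id", "transect", "area", "year_month")


@dataclass(frozen=True)
class FoodItemTaxonomy:
    """Maps raw food items to analysis categories and anthropogenic flags."""

    category: Mapping[str, str]
    anthropogenic: Mapping[str, bool]

    def __post_init__(self) -> None:
        missing = set(self.category) - set(self.anthropogenic)
        if missing:
            raise ConfigurationError(
                f"items missing an anthropogenic flag: {sorted(missing)}"
            )

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "FoodItemTaxonomy":
        required = {"item", "category", "anthropogenic"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigurationError(
                f"taxonomy table missing columns: {sorted(missing)}"
            )
        if table["item"].duplicated().any():
            dupes = table.loc[table["item"].duplicated(), "item"].tolist()
            raise ConfigurationError(f"items mapped more than once: {dupes}")
        return cls(
            category=dict(zip(table["item"], table["category"])),
            anthropogenic={
                item: bool(flag)
                for item, flag in zip(table["item"], table["anthropogenic"])
            },
        )

    def items(self) -> list[str]:
        return list(self.category)

    def categories(self) -> list[str]:
        return sorted(set(self.category.values()))

    def anthropogenic_items(self) -> list[str]:
        return [i for i, flag in self.anthropogenic.items() if flag]


@dataclass(frozen=True)
class SeasonRule:
    """Partition of the 12 calendar months into wet and dry seasons."""

    wet_months: frozenset[int] = WET_MONTHS

    def __post_init__(self) -> None:
        if not self.wet_months <= set(range(1, 13)):
            raise ConfigurationError("wet months must be calendar months 1-12")

    @property
    def dry_months(self) -> frozenset[int]:
        return frozenset(range(1, 13)) - self.wet_months

    def season(self, month: int) -> str:
        if month not in range(1, 13):
            raise ConfigurationError(f"month {month} outside 1-12")
        return "wet" if month in self.wet_months else "dry"


@dataclass
class DietTable:
    """Per-group occurrence counts: n_i per item plus the scat total N.

    ``counts`` holds, per item, the number of scats in which the item was
    present at least once (presence/absence, not fragment multiplicity);
    Σn_i can therefore exceed N.
    """

    group: str
    counts: pd.Series
    n_scats: int

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        if self.n_scats < 1:
            raise ConfigurationError(f"group {self.group!r}: N must be >= 1")
        if (self.counts < 0).any() or (self.counts > self.n_scats).any():
            raise ConfigurationError(
                f"group {self.group!r}: counts must satisfy 0 <= n_i <= N"
            )

    @property
    def total_occurrences(self) -> int:
        return int(self.counts.sum())

    def restrict(self, items: Sequence[str]) -> "DietTable":
        """Counts restricted (and reindexed, filling 0) to ``items``."""
        return DietTable(
            group=self.group,
            counts=self.counts.reindex(items, fill_value=0),
            n_scats=self.n_scats,
        )


def _month_of(year_month: str) -> int:
    try:
        return int(str(year_month).split("-")[1])
    except (IndexError, ValueError):
        raise ConfigurationError(
            f"cannot parse month from year_month value {year_month!r}"
        ) from None


def aggregate_scats(
    records: pd.DataFrame,
    taxonomy: FoodItemTaxonomy,
    season_rule: SeasonRule | None = None,
    by: Sequence[str] = ("area", "season"),
    level: str = "item",
) -> dict[str, DietTable]:
    """Tabulate scat records into per-group occurrence counts.

    ``records`` must carry the metadata columns ``scat_id``, ``transect``,
    ``area``, ``year_month`` plus one 0/1 column per food item. Grouping
    keys may be any of ``area``, ``season``, ``transect``. With
    ``level="category"`` a scat counts toward a category when any member
    item is present.
    """
    season_rule = season_rule or SeasonRule()
    if not set(by) <= {"area", "season", "transect"}:
        raise ConfigurationError(f"unsupported grouping keys: {by}")
    item_cols = [c for c in records.columns if c not in META_COLUMNS]
    unknown = [c for c in item_cols if c not in taxonomy.category]
    if unknown:
        raise ConfigurationError(
            f"items not in taxonomy: {sorted(unknown)}"
        )
    if not item_cols:
        raise ConfigurationError("no food-item columns in scat records")
    df = records.copy()
    flags = df[item_cols].astype(int)
    if ((flags < 0) | (flags > 1)).any().any():
        raise ConfigurationError("item flags must be 0/1 presence markers")
    if "season" in by:
        df["season"] = [
            season_rule.season(_month_of(ym)) for ym in df["year_month"]
        ]
    if level == "category":
        cats = sorted(set(taxonomy.category[c] for c in item_cols))
        presence = pd.DataFrame(
            {
                cat: flags[
                    [c for c in item_cols if taxonomy.category[c] == cat]
                ].max(axis=1)
                for cat in cats
            }
        )
    elif level == "item":
        presence = flags
    else:
        raise ConfigurationError(f"level must be 'item' or 'category', got {level!r}")

    tables: dict[str, DietTable] = {}
    for key, grp_idx in df.groupby(list(by), sort=True).groups.items():
        label = key if isinstance(key, str) else "/".join(str(k) for k in key)
        sub = presence.loc[grp_idx]
        tables[label] = DietTable(
            group=label, counts=sub.sum(axis=0), n_scats=len(sub)
        )
    return tables


def frequency_of_occurrence(table: DietTable) -> pd.Series:
    """FO_i (%) = 100 · n_i / N."""
    if table.n_scats < 1:
        raise DegenerateDataError("FO undefined: no scats in group")
    return (100.0 * table.counts / table.n_scats).rename("FO")


def percent_occurrence(table: DietTable) -> pd.Series:
    """PO_i (%) = 100 · n_i / Σn_i; sums to 100 over items."""
    total = table.total_occurrences
    if total < 1:
        raise DegenerateDataError("PO undefined: all occurrence counts are zero")
    return (100.0 * table.counts / total).rename("PO")


def levins_niche_breadth(
    table: DietTable, categories: Sequence[str] = NINE_CATEGORIES
) -> float:
    """Levins' B = 1/Σp_i² over the given category list.

    B = 1 when the diet is a single category; B = len(categories) when all
    are used in equal frequency. Counts default to the nine standard scat
    analysis categories; pass any category list to override.
    """
    sub = table.restrict(categories)
    total = sub.counts.sum()
    if total == 0:
        raise DegenerateDataError(
            f"group {table.group!r}: all counts zero over {list(categories)}"
        )
    p = sub.counts / total
    return float(1.0 / np.sum(p.to_numpy() ** 2))


def morisita_overlap(
    table_j: DietTable,
    table_k: DietTable,
    items: Sequence[str] | None = None,
    count_basis: str = "scats",
) -> float:
    """Morisita's index of niche overlap C between two diet tables.

    C = 2 Σ p_ij p_ik / [Σ p_ij (n_ij−1)/(N_j−1) + Σ p_ik (n_ik−1)/(N_k−1)]

    with p = n/Σn per group. ``count_basis`` selects the N entering the
    finite-sample correction: ``"scats"`` (the group's scat total, as the
    index is conventionally defined for diet data) or ``"occurrences"``
    (Σn; a dialect for sensitivity checks). C = 0 for disjoint diets; for
    identical finite samples C reaches (and can slightly exceed) 1 — values
    are not clipped.
    """
    if items is None:
        items = sorted(set(table_j.counts.index) | set(table_k.counts.index))
    a, b = table_j.restrict(items), table_k.restrict(items)
    n_j = a.counts.to_numpy(dtype=float)
    n_k = b.counts.to_numpy(dtype=float)
    if count_basis == "scats":
        big_nj, big_nk = a.n_scats, b.n_scats
    elif count_basis == "occurrences":
        big_nj, big_nk = n_j.sum(), n_k.sum()
    else:
        raise ConfigurationError(f"unknown count_basis {count_basis!r}")
    if big_nj < 2 or big_nk < 2:
        raise DegenerateDataError(
            "Morisita's correction requires N >= 2 in both groups"
        )
    if n_j.sum() == 0 or n_k.sum() == 0:
        raise DegenerateDataError("both groups need at least one occurrence")
    p_j = n_j / n_j.sum()
    p_k = n_k / n_k.sum()
    numerator = 2.0 * float(np.dot(p_j, p_k))
    denominator = float(
        np.dot(p_j, (n_j - 1.0) / (big_nj - 1.0))
        + np.dot(p_k, (n_k - 1.0) / (big_nk - 1.0))
    )
    if denominator == 0.0:
        raise DegenerateDataError("Morisita denominator is zero")
    return numerator / denominator


def niche_breadth_ratio(b_a: float, b_b: float) -> float:
    """How many times larger niche breadth ``b_a`` is than ``b_b``."""
    if b_b <= 0:
        raise DegenerateDataError("reference niche breadth must be positive")
    return b_a / b_b


def niche_breadth_reduction_pct(b_small: float, b_large: float) -> float:
    """Percent by which ``b_small`` falls short of ``b_large``: 100·(1 − a/b)."""
    if b_large <= 0:
        raise DegenerateDataError("reference niche breadth must be positive")
    return 100.0 * (1.0 - b_small / b_large)


def diet_summary(
    table: DietTable,
    categories: Sequence[str] = NINE_CATEGORIES,
) -> pd.DataFrame:
    """FO and PO per item plus N and Σn_i, one tidy frame per group."""
    out = pd.DataFrame(
        {
            "n_i": table.counts,
            "FO": frequency_of_occurrence(table),
            "PO": percent_occurrence(table),
        }
    )
    out.insert(0, "group", table.group)
    out.insert(1, "N", table.n_scats)
    out.index.name = "item"
    return out.reset_index()
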