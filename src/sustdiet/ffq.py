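"""FFQ frequency responses -> g/day food-group and nutrient intakes.

The food-frequency questionnaire records, for each food item, an ordinal
frequency category (0 = never/<1 per month ... 8 = 6+ per day).  Each
category carries a servings/day multiplier; multiplied by the item's portion
size this yields g/day.  Nutrients are accumulated linearly through the
composition table; food groups are accumulated through fractional
allocations so that a single item (fruit juice) can contribute part of its
mass to several groups.  Participant-specified 'other foods' extend both the
intake map and the composition table.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import (
    NUTRIENT_COLUMNS,
    load_allocations,
    load_composition,
    load_frequency_mapping,
)

__all__ = [
    "frequency_to_daily_amount",
    "ffq_to_intakes",
    "compute_nutrients",
    "aggregate_food_groups",
    "add_other_foods",
    "validate_allocations",
    "MASS_GROUPS",
]

#: Groups forming a mass-conserving set: one item's fractions over these
#: must not sum above 1.
MASS_GROUPS = frozenset(
    {
        "whole_grains",
        "vegetables",
        "fruits",
        "dairy",
        "red_meat",
        "fish",
        "eggs",
        "poultry",
        "legumes",
        "nuts",
        "unsaturated_oils",
        "saturated_oils",
        "ssb",
    }
)


def frequency_to_daily_amount(
    category: int, portion_g: float, mapping: pd.DataFrame | None = None
) -> float:
    """Convert one frequency category + portion size to g/day.

    Parameters
    ----------
    category : ordinal frequency code present in *mapping*.
    portion_g : portion size in grams (> 0).
    mapping : frequency table indexed by code with a ``multiplier`` column;
        defaults to the bundled EPIC-style table.
    """
    if mapping is None:
        mapping = load_frequency_mapping()
    if portion_g <= 0:
        raise ValueError(f"portion must be positive, got {portion_g}")
    try:
        mult = float(mapping.loc[int(category), "multiplier"])
    except (KeyError, ValueError) as exc:
        raise KeyError(f"unknown frequency category: {category!r}") from exc
    return mult * float(portion_g)


def ffq_to_intakes(
    ffq: Mapping[str, int],
    table: pd.DataFrame | None = None,
    mapping: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Map a full FFQ response (item -> category) to item g/day intakes."""
    if table is None:
        table = load_composition()
    if mapping is None:
        mapping = load_frequency_mapping()
    out: dict[str, float] = {}
    for item, cat in ffq.items():
        if item not in table.index:
            raise KeyError(f"no composition row for item {item!r}")
        out[item] = frequency_to_daily_amount(
            cat, table.loc[item, "portion_g"], mapping
        )
    return out


def compute_nutrients(
    intakes: Mapping[str, float], table: pd.DataFrame | None = None
) -> dict[str, float]:
    """Accumulate nutrient intakes: nutrient = sum_items g/day * per-100g / 100.

    Raises ``KeyError`` naming the first item without a composition row.
    """
    if table is None:
        table = load_composition()
    missing = [it for it in intakes if it not in table.index]
    if missing:
        raise KeyError(f"no composition row for item {missing[0]!r}")
    totals = dict.fromkeys(NUTRIENT_COLUMNS, 0.0)
    for item, grams in intakes.items():
        if grams < 0:
            raise ValueError(f"negative intake for {item!r}")
        row = table.loc[item]
        for nut in NUTRIENT_COLUMNS:
            totals[nut] += float(grams) * float(row[nut]) / 100.0
    return totals


def validate_allocations(allocations: pd.DataFrame) -> None:
    """Check fractions are in [0, 1] and mass-conserving sets sum to <= 1."""
    if (allocations["fraction"] < 0).any() or (allocations["fraction"] > 1).any():
        raise ValueError("allocation fractions must lie in [0, 1]")
    mass = allocations[allocations["group"].isin(MASS_GROUPS)]
    sums = mass.groupby("item")["fraction"].sum()
    bad = sums[sums > 1 + 1e-9]
    if len(bad):
        raise ValueError(
            "mass-conserving allocations exceed 1 for: "
            + ", ".join(f"{i} ({v:.3g})" for i, v in bad.items())
        )


def aggregate_food_groups(
    intakes: Mapping[str, float], allocations: pd.DataFrame | None = None
) -> dict[str, float]:
    """Accumulate g/day food-group intakes through fractional allocations.

    Items with no allocation row (e.g. refined grains in the bundled table)
    simply contribute to no group.  All groups mentioned in the allocation
    table appear in the result, at zero if unconsumed.
    """
    if allocations is None:
        allocations = load_allocations()
    validate_allocations(allocations)
    groups = dict.fromkeys(allocations["group"].unique(), 0.0)
    by_item = allocations.groupby("item")
    for item, grams in intakes.items():
        if grams < 0:
            raise ValueError(f"negative intake for {item!r}")
        if item in by_item.groups:
            for _, row in by_item.get_group(item).iterrows():
                groups[row["group"]] += float(row["fraction"]) * float(grams)
    return groups


def add_other_foods(
    base_intakes: Mapping[str, float],
    extra: Mapping[str, dict],
    table: pd.DataFrame | None = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Merge participant-specified 'other foods' into intakes and the table.

    Parameters
    ----------
    extra : item -> ``{"grams_per_day": float, "composition": {nutrient: per-100g}}``.
        The composition dict must cover every scored nutrient.  A duplicate
        item name is allowed only if its composition matches the existing
        row; its amount is then added to the base amount.

    Returns the merged intake map and the extended composition table.
    """
    if table is None:
        table = load_composition()
    merged = dict(base_intakes)
    table = table.copy()
    for item, entry in extra.items():
        comp = entry.get("composition", {})
        missing = [n for n in NUTRIENT_COLUMNS if n not in comp]
        if missing:
            raise ValueError(
                f"incomplete composition for {item!r}; missing: {', '.join(missing)}"
            )
        grams = float(entry["grams_per_day"])
        if grams < 0:
            raise ValueError(f"negative intake for {item!r}")
        if item in table.index:
            existing = table.loc[item, NUTRIENT_COLUMNS].astype(float)
            new = pd.Series({n: float(comp[n]) for n in NUTRIENT_COLUMNS})
            if not np.allclose(existing.values, new[existing.index].values):
                raise ValueError(
                    f"composition mismatch for duplicate item {item!r}"
                )
        else:
            row = {n: float(comp[n]) for n in NUTRIENT_COLUMNS}
            row["portion_g"] = float(entry.get("portion_g", grams or 1.0))
            table.loc[item] = row
        merged[item] = merged.get(item, 0.0) + grams
    return merged, table
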