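"""Loaders for the bundled data tables.

Every table ships as editable CSV under :mod:`sustdiet.data`:

* ``frequency_multipliers.csv`` — EPIC-style FFQ frequency codes (0-8) and
  their servings/day multipliers.
* ``composition.csv`` — a miniature synthetic food-composition table
  (per-100 g nutrients plus one portion size per item).  It is a desk-scale
  stand-in for a full UK composition database, not an excerpt from one.
* ``allocations.csv`` — fractional item-to-food-group allocations (e.g.
  fruit juice split between total fruit and sugar-sweetened-beverage mass).
* ``wish_rules.csv`` — reconstructed WISH scoring anchors and EAT-Lancet
  reference ranges per food group.
* ``ahei_rules.csv`` — AHEI-2010 component cutoffs (alcohol excluded).
* ``rni_uk.csv`` — UK Reference Nutrient Intakes (adults 19+, by sex).
* ``archetype_profiles.csv`` — generator defaults: mean servings/day per
  dietary archetype.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_frequency_mapping",
    "load_composition",
    "load_allocations",
    "load_wish_rules",
    "load_ahei_rules",
    "load_rni",
    "load_archetype_profiles",
    "NUTRIENT_COLUMNS",
]

#: Nutrient columns of the composition table, in canonical order.  The first
#: ten are the RNI-scored micronutrients/protein; the rest feed AHEI inputs.
NUTRIENT_COLUMNS = [
    "energy_kcal",
    "protein_g",
    "iron_mg",
    "zinc_mg",
    "selenium_ug",
    "folate_ug",
    "b12_ug",
    "calcium_mg",
    "copper_mg",
    "magnesium_mg",
    "iodine_ug",
    "sfa_g",
    "pufa_g",
    "n3_long_g",
    "trans_g",
    "sodium_mg",
    "added_sugar_g",
]


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("sustdiet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kw)


def load_frequency_mapping() -> pd.DataFrame:
    """FFQ frequency codes -> servings/day multipliers, indexed by code."""
    df = _read("frequency_multipliers.csv").set_index("code")
    return df


def load_composition() -> pd.DataFrame:
    """Per-item portion size and per-100 g nutrient amounts, indexed by item."""
    return _read("composition.csv").set_index("item")


def load_allocations() -> pd.DataFrame:
    """Long-format fractional item -> food-group allocations."""
    return _read("allocations.csv")


def load_wish_rules() -> pd.DataFrame:
    """WISH scoring rules (reconstructed anchors), indexed by food group."""
    return _read("wish_rules.csv").set_index("group")


def load_ahei_rules() -> pd.DataFrame:
    """AHEI-2010 component cutoffs, indexed by component."""
    return _read("ahei_rules.csv").set_index("component")


def load_rni() -> pd.DataFrame:
    """UK RNIs per nutrient and sex, indexed by nutrient."""
    return _read("rni_uk.csv").set_index("nutrient")


def load_archetype_profiles() -> pd.DataFrame:
    """Generator mean servings/day per archetype, indexed by item."""
    return _read("archetype_profiles.csv").set_index("item")
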