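"""WISH and modified AHEI-2010 diet-index scoring, adherence, tertiles.

Both indices score each food component on a piecewise-linear 0-10 scale and
sum components with equal weight:

* WISH — 13 EAT-Lancet food groups, total in [0, 130].  Protective groups
  ramp from 0 (no intake) to 10 at/above the reference intake; limited
  groups score 10 at/below the reference cap and fall to 0 at the
  upper anchor; range-peaked groups (dairy) score 10 inside the recommended
  range and decay linearly outside it.
* AHEI-2010 (modified) — 10 components (6 protective, 4 limited); alcohol
  is excluded and treated as a covariate, so the total lies in [0, 100].

The anchor tables ship as editable CSV data and are reconstructed defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import load_ahei_rules, load_wish_rules

__all__ = [
    "ScoringRule",
    "DietScore",
    "score_component",
    "score_components_frame",
    "compute_wish",
    "compute_ahei",
    "ahei_inputs",
    "adherence_gap",
    "tertile_split",
    "wish_rules_from_table",
    "ahei_rules_from_table",
]

# Serving sizes (g) used to express AHEI mass intakes in servings/day.
VEG_SERVING_G = 80.0
FRUIT_SERVING_G = 80.0
NUT_SERVING_G = 28.0
LEGUME_SERVING_G = 100.0
SSB_SERVING_G = 330.0
MEAT_SERVING_G = 85.0
KCAL_PER_G_FAT = 9.0


@dataclass(frozen=True)
class ScoringRule:
    """One component's piecewise-linear 0-10 scoring rule."""

    group: str
    index: str  # "WISH" or "AHEI"
    direction: str  # "increasing" | "decreasing" | "range"
    anchor_0: float
    anchor_10: float
    health_class: str = "neutral"
    environmental_impact: str = "medium"
    ref_min: float | None = None
    ref_opt: float | None = None
    ref_max: float | None = None
    units: str = "g/day"

    def __post_init__(self) -> None:
        if self.direction not in ("increasing", "decreasing", "range"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "increasing" and not self.anchor_10 > self.anchor_0:
            raise ValueError(f"{self.group}: increasing rule needs anchor_10 > anchor_0")
        if self.direction == "decreasing" and not self.anchor_0 > self.anchor_10:
            raise ValueError(f"{self.group}: decreasing rule needs anchor_0 > anchor_10")
        if self.direction == "range":
            if self.ref_min is None or self.ref_max is None:
                raise ValueError(f"{self.group}: range rule needs ref_min/ref_max")
            if not (0 <= self.ref_min <= self.ref_max < self.anchor_0):
                raise ValueError(f"{self.group}: range breakpoints must be ordered")


@dataclass
class DietScore:
    """Component scores (each in [0, 10]) and their equal-weight sum."""

    index: str
    components: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))


def _score_array(x: np.ndarray, rule: ScoringRule) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError(f"{rule.group}: intake must be non-negative")
    if rule.direction == "increasing":
        s = 10.0 * (x - rule.anchor_0) / (rule.anchor_10 - rule.anchor_0)
    elif rule.direction == "decreasing":
        s = 10.0 * (rule.anchor_0 - x) / (rule.anchor_0 - rule.anchor_10)
    else:  # range-peaked
        lo, hi, zero_hi = rule.ref_min, rule.ref_max, rule.anchor_0
        s = np.where(
            x < lo,
            10.0 * x / lo if lo > 0 else 10.0,
            np.where(x <= hi, 10.0, 10.0 * (zero_hi - x) / (zero_hi - hi)),
        )
    return np.clip(s, 0.0, 10.0)


def score_component(intake: float, rule: ScoringRule) -> float:
    """Score a single intake against one rule; result in [0, 10]."""
    return float(_score_array(np.asarray([intake]), rule)[0])


def wish_rules_from_table(table: pd.DataFrame | None = None) -> dict[str, ScoringRule]:
    """Build the 13 WISH :class:`ScoringRule` objects from the rule CSV."""
    if table is None:
        table = load_wish_rules()
    rules = {}
    for group, row in table.iterrows():
        rules[group] = ScoringRule(
            group=group,
            index="WISH",
            direction=row["direction"],
            anchor_0=float(row["anchor_0"]),
            anchor_10=float(row["anchor_10"]),
            health_class=row["health_class"],
            environmental_impact=row["environmental_impact"],
            ref_min=float(row["ref_min"]),
            ref_opt=float(row["ref_opt"]),
            ref_max=float(row["ref_max"]),
            units=row["units"],
        )
    return rules


def ahei_rules_from_table(table: pd.DataFrame | None = None) -> dict[str, ScoringRule]:
    """Build the 10 modified-AHEI rules from the cutoff CSV."""
    if table is None:
        table = load_ahei_rules()
    rules = {}
    for comp, row in table.iterrows():
        rules[comp] = ScoringRule(
            group=comp,
            index="AHEI",
            direction=row["direction"],
            anchor_0=float(row["anchor_0"]),
            anchor_10=float(row["anchor_10"]),
            units=row["units"],
        )
    return rules


def _compute_index(
    intakes: Mapping[str, float], rules: Mapping[str, ScoringRule], index: str
) -> DietScore:
    missing = [g for g in rules if g not in intakes]
    if missing:
        raise KeyError(f"missing {index} component intake: {missing[0]!r}")
    score = DietScore(index=index)
    for group, rule in rules.items():
        score.components[group] = score_component(float(intakes[group]), rule)
    return score


def compute_wish(
    food_groups: Mapping[str, float], rules: Mapping[str, ScoringRule] | None = None
) -> DietScore:
    """Score the 13 WISH components; higher = healthier and more sustainable."""
    if rules is None:
        rules = wish_rules_from_table()
    if len(rules) != 13:
        raise ValueError(f"WISH requires 13 rules, got {len(rules)}")
    return _compute_index(food_groups, rules, "WISH")


def compute_ahei(
    inputs: Mapping[str, float], rules: Mapping[str, ScoringRule] | None = None
) -> DietScore:
    """Score the 10 modified-AHEI components (alcohol excluded)."""
    if rules is None:
        rules = ahei_rules_from_table()
    if len(rules) != 10:
        raise ValueError(f"modified AHEI requires 10 rules, got {len(rules)}")
    return _compute_index(inputs, rules, "AHEI")


def score_components_frame(
    intake_df: pd.DataFrame, rules: Mapping[str, ScoringRule]
) -> pd.DataFrame:
    """Vectorised component scoring: one row per participant, one column per rule."""
    out = {}
    for group, rule in rules.items():
        if group not in intake_df.columns:
            raise KeyError(f"missing component intake column: {group!r}")
        out[group] = _score_array(intake_df[group].to_numpy(dtype=float), rule)
    return pd.DataFrame(out, index=intake_df.index)


def wish_inputs(
    food_groups: Mapping[str, float], nutrients: Mapping[str, float]
) -> dict[str, float]:
    """Assemble the 13 WISH component intakes (g/day).

    Twelve are mass food groups from the fractional allocations; the
    added-sugars component is the added-sugar mass itself (g/day) from the
    nutrient accumulation, so sugary drinks contribute their sugar content
    rather than their beverage mass.
    """
    groups = [
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
    ]
    out = {g: float(food_groups.get(g, 0.0)) for g in groups}
    out["added_sugars"] = float(nutrients.get("added_sugar_g", 0.0))
    return out


def ahei_inputs(
    food_groups: Mapping[str, float], nutrients: Mapping[str, float]
) -> dict[str, float]:
    """Derive the 10 AHEI component inputs from food groups + nutrients.

    Mass groups become servings/day; fat-quality components become % of
    energy (9 kcal/g fat); long-chain n-3 is expressed in mg/day and PUFA
    excludes the long-chain n-3 fraction.
    """
    kcal = float(nutrients.get("energy_kcal", 0.0))
    pufa = max(float(nutrients.get("pufa_g", 0.0)) - float(nutrients.get("n3_long_g", 0.0)), 0.0)

    def pct_energy(grams: float) -> float:
        return 100.0 * grams * KCAL_PER_G_FAT / kcal if kcal > 0 else 0.0

    return {
        "vegetables": float(food_groups.get("vegetables", 0.0)) / VEG_SERVING_G,
        "fruit": float(food_groups.get("fruits", 0.0)) / FRUIT_SERVING_G,
        "whole_grains": float(food_groups.get("whole_grains", 0.0)),
        "nuts_legumes": float(food_groups.get("nuts", 0.0)) / NUT_SERVING_G
        + float(food_groups.get("legumes", 0.0)) / LEGUME_SERVING_G,
        "n3_long": 1000.0 * float(nutrients.get("n3_long_g", 0.0)),
        "pufa_pct_energy": pct_energy(pufa),
        "ssb": float(food_groups.get("ssb", 0.0)) / SSB_SERVING_G,
        "red_processed_meat": float(food_groups.get("red_meat", 0.0)) / MEAT_SERVING_G,
        "trans_pct_energy": pct_energy(float(nutrients.get("trans_g", 0.0))),
        "sodium": float(nutrients.get("sodium_mg", 0.0)),
    }


def adherence_gap(
    intake_df: pd.DataFrame, rules: Mapping[str, ScoringRule] | None = None
) -> pd.DataFrame:
    """Cohort adherence to the reference ranges, one row per food group.

    gap = actual - recommended (the range midpoint when a range is
    recommended); the paired t test compares actual intakes with the
    recommended level; % non-adherent is the share outside [min, max].
    """
    from .stats import paired_t  # local import to avoid a cycle

    if rules is None:
        rules = wish_rules_from_table()
    if len(intake_df) < 2:
        raise ValueError("adherence_gap requires n >= 2 participants")
    rows = []
    for group, rule in rules.items():
        ref = rule.ref_opt if rule.ref_opt is not None else rule.anchor_10
        x = intake_df[group].to_numpy(dtype=float)
        res = paired_t(x, np.full_like(x, ref))
        lo = rule.ref_min if rule.ref_min is not None else ref
        hi = rule.ref_max if rule.ref_max is not None else ref
        rows.append(
            {
                "group": group,
                "recommended": ref,
                "mean_gap": float(np.mean(x) - ref),
                "t": res["t"],
                "df": res["df"],
                "p": res["p"],
                "degenerate": res["degenerate"],
                "pct_non_adherent": 100.0 * float(np.mean((x < lo) | (x > hi))),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def tertile_split(scores) -> np.ndarray:
    """Split scores at the 33.3rd/66.7th percentiles into low/mid/high.

    Ties at a boundary go to the lower tertile.  A degenerate distribution
    (both boundaries equal) yields a single 'low' group with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("tertile_split requires n >= 3")
    q1, q2 = np.quantile(scores, [1.0 / 3.0, 2.0 / 3.0])
    if q1 == q2:
        warnings.warn("degenerate tertile split: boundaries coincide", stacklevel=2)
    labels = np.where(scores <= q1, "low", np.where(scores <= q2, "mid", "high"))
    return labels
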