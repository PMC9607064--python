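"""Nutrient adequacy against UK Reference Nutrient Intakes.

A nutrient is flagged when intake falls strictly below the sex-specific RNI
(intake exactly at the RNI counts as adequate).  The Nutrient Adequacy Ratio
(NAR) is the percentage of the RNI achieved, capped at 100; the Mean
Adequacy Ratio (MAR) is the unweighted mean of the NARs, so MAR = 100 iff
every scored nutrient meets its RNI.  Flags feed per-nutrient 2x2
cluster-by-adequacy contingency tables for chi-squared comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import load_rni

__all__ = [
    "AdequacyResult",
    "rni_for_sex",
    "below_rni_flags",
    "nutrient_adequacy_ratio",
    "mean_adequacy_ratio",
    "assess_adequacy",
    "adequacy_contingency",
    "counts_from_prevalence",
]


@dataclass
class AdequacyResult:
    """Per-nutrient below-RNI flags, NARs (%) and their mean (MAR, %)."""

    flags: dict[str, bool] = field(default_factory=dict)
    nar: dict[str, float] = field(default_factory=dict)

    @property
    def mar(self) -> float:
        return mean_adequacy_ratio(self.nar)


def rni_for_sex(sex: str, rni: pd.DataFrame | None = None) -> pd.Series:
    """The RNI column for one sex ('male' or 'female')."""
    if rni is None:
        rni = load_rni()
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return rni[sex].astype(float)


def below_rni_flags(
    nutrients: Mapping[str, float], sex: str, rni: pd.DataFrame | None = None
) -> dict[str, bool]:
    """Flag each RNI-scored nutrient whose intake is strictly below the RNI."""
    ref = rni_for_sex(sex, rni)
    flags = {}
    for nutrient, target in ref.items():
        if nutrient not in nutrients:
            raise KeyError(f"no intake for RNI nutrient {nutrient!r}")
        flags[nutrient] = bool(float(nutrients[nutrient]) < float(target))
    return flags


def nutrient_adequacy_ratio(intake: float, rni: float) -> float:
    """NAR = 100 * min(intake/RNI, 1), in [0, 100]."""
    if intake < 0:
        raise ValueError(f"negative intake: {intake}")
    if rni <= 0:
        raise ValueError(f"RNI must be positive, got {rni}")
    return 100.0 * min(float(intake) / float(rni), 1.0)


def mean_adequacy_ratio(nar: Mapping[str, float] | Sequence[float]) -> float:
    """Unweighted arithmetic mean of NARs (%)."""
    values = list(nar.values()) if isinstance(nar, Mapping) else list(nar)
    if not values:
        raise ValueError("MAR requires at least one NAR value")
    return float(np.mean([float(v) for v in values]))


def assess_adequacy(
    nutrients: Mapping[str, float], sex: str, rni: pd.DataFrame | None = None
) -> AdequacyResult:
    """Full adequacy assessment (flags, NARs, MAR) for one participant."""
    ref = rni_for_sex(sex, rni)
    result = AdequacyResult()
    for nutrient, target in ref.items():
        if nutrient not in nutrients:
            raise KeyError(f"no intake for RNI nutrient {nutrient!r}")
        intake = float(nutrients[nutrient])
        result.flags[nutrient] = intake < float(target)
        result.nar[nutrient] = nutrient_adequacy_ratio(intake, float(target))
    return result


def adequacy_contingency(labels, flags) -> np.ndarray:
    """2x2 counts (cluster x below/at-or-above RNI) for one nutrient.

    Rows follow the sorted order of the two cluster labels; columns are
    (below RNI, at/above RNI).  Pairs with a missing flag are dropped, so
    the effective n may differ per nutrient.
    """
    labels = pd.Series(list(labels))
    flags = pd.Series(list(flags), index=labels.index)
    keep = flags.notna() & labels.notna()
    labels, flags = labels[keep], flags[keep].astype(bool)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"adequacy_contingency requires exactly 2 clusters, got {len(groups)}")
    table = np.zeros((2, 2), dtype=int)
    for i, g in enumerate(groups):
        in_g = labels == g
        table[i, 0] = int((flags[in_g]).sum())
        table[i, 1] = int((~flags[in_g]).sum())
    return table


def counts_from_prevalence(pct_below_1: float, n1: int, pct_below_2: float, n2: int) -> np.ndarray:
    """Reconstruct 2x2 (cluster x below/adequate) counts from printed prevalences.

    Counts are the prevalence percentages applied to the effective cluster
    sizes and rounded to the nearest integer.
    """
    b1 = int(round(pct_below_1 * n1 / 100.0))
    b2 = int(round(pct_below_2 * n2 / 100.0))
    return np.array([[b1, n1 - b1], [b2, n2 - b2]], dtype=int)
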