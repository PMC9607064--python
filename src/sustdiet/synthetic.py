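"""Synthetic cohort generator.

Emulates the statistical structure of a young-adult UK cohort (N ~ 328)
with three dietary archetypes: an *unsustainable* majority (moderate-to-high
meat, refined grains, low vegetables), a *balanced* sustainable pattern
(high plants, moderate fish and unsaturated oils, moderate meat) and a
*restricted* sustainable pattern (very little red meat, poultry or fish,
with consequent shortfalls in protein, zinc, selenium, iron and folate).

Food intake is drawn at the item level (log-normal servings/day around
archetype profile means), snapped to FFQ frequency categories, and pushed
through the same FFQ -> composition pipeline the analysis uses, so every
downstream quantity (food groups, nutrients, WISH/AHEI scores, MAR) is
internally consistent.  Mood is generated from a latent negative-affect
variable that is linear in the standardized Mean Adequacy Ratio with
standardized slope ``diet_mood_beta``, then emitted on the POMS or PANAS
scale so cross-scale harmonisation is exercised.  R-R interval series are
an additive two-sinusoid model (0.10 Hz and 0.25 Hz) plus white noise with
optional ectopic-beat corruption, so spectral band powers have analytic
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    NUTRIENT_COLUMNS,
    load_allocations,
    load_archetype_profiles,
    load_composition,
    load_frequency_mapping,
    load_rni,
)
from .hrv import RRSeries

__all__ = [
    "CohortConfig",
    "ParticipantRecord",
    "generate_cohort",
    "generate_rr_series",
    "inject_ectopics",
    "generate_task_logs",
    "cohort_frame",
    "write_cohort",
    "ARCHETYPES",
]

ARCHETYPES = ("unsustainable", "balanced", "restricted")

VAGAL_GAIN_DEFAULTS = {"unsustainable": 0.025, "balanced": 0.030, "restricted": 0.026}
FEMALE_FRACTION_DEFAULTS = {"unsustainable": 0.60, "balanced": 0.50, "restricted": 0.75}
ALCOHOL_G_DAY = {"unsustainable": 12.0, "balanced": 6.9, "restricted": 4.3}
EXERCISE_MIN_DAY = {"unsustainable": 16.0, "balanced": 18.7, "restricted": 17.0}

POMS_RANGE = (0.0, 36.0)  # elated-depressed subscale; higher = better mood
PANAS_RANGE = (10.0, 50.0)  # negative affect; higher = worse mood


class ConfigurationError(ValueError):
    """Raised for an invalid :class:`CohortConfig`."""


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_total: int = 328
    archetype_proportions: dict = field(
        default_factory=lambda: {
            "unsustainable": 216 / 328,
            "balanced": 54 / 328,
            "restricted": 57 / 328,
        }
    )
    diet_mood_beta: float = -0.3
    hrv_vagal_gain_by_archetype: dict = field(
        default_factory=lambda: dict(VAGAL_GAIN_DEFAULTS)
    )
    lf_gain: float = 0.025
    mean_rr: float = 0.85
    rr_duration: float = 360.0
    rr_noise_sd: float = 0.02
    ectopic_fraction: float = 0.01
    poms_fraction: float = 0.8
    female_fraction_by_archetype: dict = field(
        default_factory=lambda: dict(FEMALE_FRACTION_DEFAULTS)
    )
    noise_scales: dict = field(
        default_factory=lambda: {
            "bmi": 3.2,
            "height": 0.065,
            "alcohol_sigma": 0.6,
            "exercise_sigma": 0.4,
            "intake_sigma_scale": 0.60,
        }
    )
    include_rr: bool = True
    include_task_logs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ConfigurationError("n_total must be non-negative")
        props = self.archetype_proportions
        if set(props) != set(ARCHETYPES):
            raise ConfigurationError(f"proportions must cover {ARCHETYPES}")
        if any(v < 0 for v in props.values()) or abs(sum(props.values()) - 1.0) > 0.02:
            raise ConfigurationError("archetype proportions must be >= 0 and sum to 1")
        if self.rr_duration <= 0:
            raise ConfigurationError("rr_duration must be positive")
        if any(v < 0 for v in self.noise_scales.values()):
            raise ConfigurationError("noise scales must be non-negative")
        if not 0 <= self.ectopic_fraction < 1:
            raise ConfigurationError("ectopic_fraction must lie in [0, 1)")
        if not 0 <= self.poms_fraction <= 1:
            raise ConfigurationError("poms_fraction must lie in [0, 1]")


@dataclass
class ParticipantRecord:
    """All generated data for one synthetic participant."""

    id: str
    sex: str  # 'male' | 'female'
    height: float  # m
    weight: float  # kg
    exercise: float  # min/day above 3.0 METs
    alcohol: float  # g/day
    kcal: float  # kcal/day (from the composition table)
    ffq: dict  # item -> frequency category code
    food_groups: dict  # group -> g/day
    nutrients: dict  # nutrient -> amount/day
    mood_raw: float
    mood_scale: str  # 'POMS' | 'PANAS'
    rr: RRSeries | None = None
    task_logs: dict | None = None
    archetype: str = ""  # generator truth, hidden from the analysis

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2


def _archetype_counts(n: int, proportions: dict) -> dict:
    """Apportion n over the archetypes.

    Proportions summing exactly to 1 get largest-remainder apportionment
    (counts sum to n).  Proportions quoted as published rounded fractions
    (sum within 2% of 1) are rounded per archetype instead, so the cohort
    size may differ from n by the same rounding.
    """
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        return {a: int(round(n * proportions[a])) for a in ARCHETYPES}
    exact = {a: n * proportions[a] for a in ARCHETYPES}
    base = {a: int(np.floor(v)) for a, v in exact.items()}
    short = n - sum(base.values())
    order = sorted(ARCHETYPES, key=lambda a: exact[a] - base[a], reverse=True)
    for a in order[:short]:
        base[a] += 1
    return base


def generate_rr_series(
    vagal_gain: float,
    lf_gain: float,
    mean_rr: float,
    duration: float,
    noise_sd: float,
    seed: int,
) -> RRSeries:
    """Beat-to-beat R-R series: two sinusoidal modulations plus white noise.

    RR(t) = mean_rr + vagal_gain*sin(2*pi*0.25*t) + lf_gain*sin(2*pi*0.10*t)
    + N(0, noise_sd), sampled at each successive beat time.
    """
    if not 0.3 < mean_rr < 2.0:
        raise ValueError(f"non-physiological mean RR: {mean_rr}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    rr, t = [], 0.0
    while t < duration:
        # modulation is evaluated at the time of the beat terminating the
        # interval (the tachogram convention timestamps each interval at its
        # ending R peak), solved by fixed-point iteration so that
        # interval = m(t + interval) holds to high accuracy
        interval = mean_rr
        for _ in range(4):
            tb = t + interval
            interval = (
                mean_rr
                + vagal_gain * np.sin(2 * np.pi * 0.25 * tb)
                + lf_gain * np.sin(2 * np.pi * 0.10 * tb)
            )
        if noise_sd > 0:
            interval += rng.normal(0.0, noise_sd)
        interval = max(interval, 0.25)
        rr.append(interval)
        t += interval
    return RRSeries(np.asarray(rr))


def inject_ectopics(
    rr: RRSeries, fraction: float, seed: int, magnitude: float = 0.6
) -> RRSeries:
    """Corrupt a fraction of beats with +/- `magnitude` s deviations."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    x = rr.rr.copy()
    k = int(round(fraction * x.size))
    if k == 0:
        return RRSeries(x)
    rng = np.random.default_rng(seed)
    idx = rng.choice(x.size, size=k, replace=False)
    signs = rng.choice([-1.0, 1.0], size=k)
    # keep intervals physically positive: flip a sign that would go <= 0.1 s
    signs[x[idx] - magnitude <= 0.1] = 1.0
    x[idx] = x[idx] + signs * magnitude
    return RRSeries(x)


def generate_task_logs(ability: dict | None = None, seed: int = 0) -> dict:
    """Raw trial logs for serial sevens (28), flanker (72) and word recall.

    ``ability`` overrides per-task accuracy/RT parameters, e.g.
    ``{"serial7_p": 1.0, "serial7_rt_sd": 0.0}`` for a perfect, constant-RT
    participant.
    """
    a = {
        "serial7_p": 0.85,
        "serial7_rt_ms": 1200.0,
        "serial7_rt_sd": 250.0,
        "flanker_p": {"congruent": 0.97, "neutral": 0.96, "incongruent": 0.90},
        "flanker_rt_ms": {"congruent": 450.0, "neutral": 460.0, "incongruent": 520.0},
        "flanker_rt_sd": 80.0,
        "recall_p_immediate": {"concrete": 0.50, "abstract": 0.38},
        "recall_retention": {"concrete": 0.75, "abstract": 0.60},
        "n_serial7": 28,
        "n_flanker": 72,
    }
    if ability:
        a.update(ability)
    rng = np.random.default_rng(seed)

    serial = [
        {
            "trial": i,
            "correct": bool(rng.random() < a["serial7_p"]),
            "rt_ms": float(max(rng.normal(a["serial7_rt_ms"], a["serial7_rt_sd"]), 150.0)),
        }
        for i in range(a["n_serial7"])
    ]

    conditions = ["congruent", "incongruent", "neutral"] * (a["n_flanker"] // 3)
    rng.shuffle(conditions)
    flanker = [
        {
            "trial": i,
            "condition": cond,
            "correct": bool(rng.random() < a["flanker_p"][cond]),
            "rt_ms": float(max(rng.normal(a["flanker_rt_ms"][cond], a["flanker_rt_sd"]), 150.0)),
        }
        for i, cond in enumerate(conditions)
    ]

    words = {
        "abstract": [f"abstract_{i:02d}" for i in range(1, 16)],
        "concrete": [f"concrete_{i:02d}" for i in range(1, 16)],
    }
    immediate, delayed = [], []
    for wtype in ("abstract", "concrete"):
        for w in words[wtype]:
            if rng.random() < a["recall_p_immediate"][wtype]:
                immediate.append(w)
                if rng.random() < a["recall_retention"][wtype]:
                    delayed.append(w)
    return {
        "serial_sevens": serial,
        "flanker": flanker,
        "recall": {"words": words, "immediate": immediate, "delayed": delayed},
    }


def generate_cohort(config: CohortConfig | None = None) -> list[ParticipantRecord]:
    """Draw a full synthetic cohort under the configured study conditions."""
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total
    if n == 0:
        return []

    counts = _archetype_counts(n, cfg.archetype_proportions)
    n = sum(counts.values())  # may differ from n_total by published rounding
    archetype = np.array(
        [a for a in ARCHETYPES for _ in range(counts[a])], dtype=object
    )
    archetype = archetype[rng.permutation(n)]

    female_p = np.array([cfg.female_fraction_by_archetype[a] for a in archetype])
    female = rng.random(n) < female_p
    sex = np.where(female, "female", "male")

    h_sd = cfg.noise_scales["height"]
    height = np.where(
        female, rng.normal(1.64, h_sd, n), rng.normal(1.78, h_sd, n)
    )
    bmi = np.clip(rng.normal(25.6, cfg.noise_scales["bmi"], n), 18.0, 36.5)
    weight = bmi * height**2

    ex_mu = np.array([EXERCISE_MIN_DAY[a] for a in archetype])
    ex_sigma = cfg.noise_scales["exercise_sigma"]
    exercise = np.exp(rng.normal(np.log(ex_mu) - ex_sigma**2 / 2, ex_sigma))
    al_mu = np.array([ALCOHOL_G_DAY[a] for a in archetype])
    al_sigma = cfg.noise_scales["alcohol_sigma"]
    alcohol = np.exp(rng.normal(np.log(al_mu) - al_sigma**2 / 2, al_sigma))

    # --- item-level diet: log-normal servings snapped to FFQ categories
    profiles = load_archetype_profiles()
    comp = load_composition()
    items = [it for it in profiles.index if it in comp.index]
    mu = profiles.loc[items, list(ARCHETYPES)].to_numpy(dtype=float)
    sigma = profiles.loc[items, "sigma"].to_numpy(dtype=float)
    sigma = sigma * cfg.noise_scales["intake_sigma_scale"]
    arch_idx = np.array([ARCHETYPES.index(a) for a in archetype])
    mean_serv = mu[:, arch_idx].T  # n x items
    with np.errstate(divide="ignore"):
        log_mu = np.where(mean_serv > 0, np.log(np.maximum(mean_serv, 1e-12)), -np.inf)
    servings = np.where(
        mean_serv > 0,
        np.exp(rng.normal(0.0, 1.0, (n, len(items))) * sigma + log_mu - sigma**2 / 2),
        0.0,
    )

    freq = load_frequency_mapping()
    multipliers = freq["multiplier"].to_numpy(dtype=float)
    codes = np.abs(servings[:, :, None] - multipliers[None, None, :]).argmin(axis=2)
    snapped = multipliers[codes]
    portions = comp.loc[items, "portion_g"].to_numpy(dtype=float)
    grams = snapped * portions[None, :]  # n x items, g/day

    comp_matrix = comp.loc[items, NUTRIENT_COLUMNS].to_numpy(dtype=float)
    nutrient_mat = grams @ comp_matrix / 100.0  # n x nutrients

    alloc = load_allocations()
    groups = sorted(alloc["group"].unique())
    A = np.zeros((len(items), len(groups)))
    item_pos = {it: i for i, it in enumerate(items)}
    for _, row in alloc.iterrows():
        if row["item"] in item_pos:
            A[item_pos[row["item"]], groups.index(row["group"])] = row["fraction"]
    group_mat = grams @ A  # n x groups

    kcal = nutrient_mat[:, NUTRIENT_COLUMNS.index("energy_kcal")]

    # --- nutrient adequacy -> latent negative affect -> mood scales
    rni = load_rni()
    rni_nutrients = list(rni.index)
    rni_vals = np.where(
        female[:, None],
        rni["female"].to_numpy(dtype=float)[None, :],
        rni["male"].to_numpy(dtype=float)[None, :],
    )
    nut_idx = [NUTRIENT_COLUMNS.index(nm) for nm in rni_nutrients]
    nar = 100.0 * np.clip(nutrient_mat[:, nut_idx] / rni_vals, 0.0, 1.0)
    mar = nar.mean(axis=1)

    beta = cfg.diet_mood_beta
    mar_sd = mar.std(ddof=0)
    z_mar = (mar - mar.mean()) / mar_sd if mar_sd > 0 else np.zeros(n)
    resid_sd = np.sqrt(max(1.0 - beta**2, 0.0))
    latent = beta * z_mar + resid_sd * rng.standard_normal(n)

    use_poms = rng.random(n) < cfg.poms_fraction
    poms = np.rint(np.clip(18.0 - 5.5 * latent, *POMS_RANGE))
    panas = np.rint(np.clip(22.0 + 6.5 * latent, *PANAS_RANGE))
    mood_raw = np.where(use_poms, poms, panas)
    mood_scale = np.where(use_poms, "POMS", "PANAS")

    # --- per-participant RR series and task logs
    child_seeds = rng.integers(0, 2**31 - 1, size=(n, 3))
    vagal_base = np.array([cfg.hrv_vagal_gain_by_archetype[a] for a in archetype])
    vagal = vagal_base * np.exp(rng.normal(0.0, 0.2, n))
    lf = cfg.lf_gain * np.exp(rng.normal(0.0, 0.2, n))
    mean_rr_i = np.clip(rng.normal(cfg.mean_rr, 0.07, n), 0.6, 1.15)

    records: list[ParticipantRecord] = []
    for i in range(n):
        rr = None
        if cfg.include_rr:
            rr = generate_rr_series(
                vagal_gain=float(vagal[i]),
                lf_gain=float(lf[i]),
                mean_rr=float(mean_rr_i[i]),
                duration=cfg.rr_duration,
                noise_sd=cfg.rr_noise_sd,
                seed=int(child_seeds[i, 0]),
            )
            if cfg.ectopic_fraction > 0:
                rr = inject_ectopics(rr, cfg.ectopic_fraction, seed=int(child_seeds[i, 1]))
        logs = (
            generate_task_logs(seed=int(child_seeds[i, 2]))
            if cfg.include_task_logs
            else None
        )
        records.append(
            ParticipantRecord(
                id=f"P{i + 1:04d}",
                sex=str(sex[i]),
                height=float(height[i]),
                weight=float(weight[i]),
                exercise=float(exercise[i]),
                alcohol=float(alcohol[i]),
                kcal=float(kcal[i]),
                ffq={it: int(codes[i, j]) for j, it in enumerate(items)},
                food_groups={g: float(group_mat[i, j]) for j, g in enumerate(groups)},
                nutrients={
                    nm: float(nutrient_mat[i, j]) for j, nm in enumerate(NUTRIENT_COLUMNS)
                },
                mood_raw=float(mood_raw[i]),
                mood_scale=str(mood_scale[i]),
                rr=rr,
                task_logs=logs,
                archetype=str(archetype[i]),
            )
        )
    return records


def cohort_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Analysis-ready per-participant frame (scores computed on the fly).

    Columns: covariates (sex 0/1 female, bmi, kcal, alcohol, exercise),
    mood (raw + scale + harmonised quantile group), WISH component scores
    and totals, modified-AHEI total, MAR, and the generator archetype.
    """
    from .adequacy import assess_adequacy
    from .indices import (
        ahei_inputs,
        ahei_rules_from_table,
        compute_ahei,
        score_components_frame,
        wish_inputs,
        wish_rules_from_table,
    )
    from .stats import harmonise_mood

    if not records:
        return pd.DataFrame()
    wish_rules = wish_rules_from_table()
    ahei_rules = ahei_rules_from_table()
    fg = pd.DataFrame([wish_inputs(r.food_groups, r.nutrients) for r in records])
    comp_scores = score_components_frame(fg, wish_rules)
    rows = []
    for i, r in enumerate(records):
        ahei = compute_ahei(ahei_inputs(r.food_groups, r.nutrients), ahei_rules)
        adequacy = assess_adequacy(r.nutrients, r.sex)
        row = {
            "id": r.id,
            "female": 1.0 if r.sex == "female" else 0.0,
            "bmi": r.bmi,
            "kcal": r.kcal,
            "alcohol": r.alcohol,
            "exercise": r.exercise,
            "mood_raw": r.mood_raw,
            "mood_scale": r.mood_scale,
            "wish_total": float(comp_scores.iloc[i].sum()),
            "ahei_total": ahei.total,
            "mar": adequacy.mar,
            "archetype": r.archetype,
        }
        row.update({f"wish_{g}": float(comp_scores.iloc[i][g]) for g in comp_scores.columns})
        row.update({f"below_rni_{nm}": adequacy.flags[nm] for nm in adequacy.flags})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("id")
    harmonised = harmonise_mood(df["mood_raw"], df["mood_scale"])
    df["mood_group"] = [h.quantile_group for h in harmonised]
    return df


def write_cohort(records: list[ParticipantRecord], outdir: str | Path) -> None:
    """Serialise a cohort: cohort.csv + rr/<id>.txt (ms/beat) + task_logs.json."""
    from .hrv import write_rr_file

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "sex": r.sex,
            "height_m": r.height,
            "weight_kg": r.weight,
            "exercise_min_day": r.exercise,
            "alcohol_g_day": r.alcohol,
            "kcal": r.kcal,
            "mood_raw": r.mood_raw,
            "mood_scale": r.mood_scale,
            "archetype": r.archetype,
        }
        row.update({f"ffq_{item}": code for item, code in r.ffq.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)

    rr_dir = outdir / "rr"
    logs = {}
    for r in records:
        if r.rr is not None:
            rr_dir.mkdir(exist_ok=True)
            write_rr_file(r.rr, rr_dir / f"{r.id}.txt", unit="ms")
        if r.task_logs is not None:
            logs[r.id] = r.task_logs
    if logs:
        (outdir / "task_logs.json").write_text(json.dumps(logs))
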