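"""The statistical battery for the diet-brain analysis.

Contents: cross-scale mood harmonisation by within-scale quantile cuts;
log transform of skewed variables; paired t; Pearson chi-square (no
continuity correction — the convention that reproduces printed 2x2
statistics in this literature); Cook's-distance outlier exclusion (4/N,
applied once); two-step hierarchical regression with standardized
coefficients, 95% CIs and the R-squared-change F test; univariate
repeated-measures ANOVA/ANCOVA with Mauchly's sphericity test and the
Greenhouse-Geisser correction; Benjamini-Hochberg FDR; scoring of raw
cognition trial logs; BMI.

Ordinary model fits go through scipy/statsmodels; what those libraries do
not provide directly (the R-squared-change battery, contrast-transformed
RM-ANCOVA with continuous covariates, the step-up FDR rule) is implemented
here and cross-checked in the test-suite against independent oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "HarmonisedMood",
    "RegressionStepResult",
    "AnovaResult",
    "harmonise_mood",
    "log_transform_if_skewed",
    "paired_t",
    "chi_square",
    "cooks_distance_filter",
    "hierarchical_regression",
    "gg_epsilon",
    "mauchly_test",
    "rm_anova",
    "bh_fdr",
    "score_cognition_logs",
    "compute_bmi",
]

#: Orientation of each mood scale towards *negative affect*: +1 if a higher
#: raw score means more negative affect (PANAS), -1 if a higher raw score
#: means a better mood (POMS elated-depressed).
SCALE_ORIENTATION = {"POMS": -1, "PANAS": +1}


@dataclass
class HarmonisedMood:
    raw: float
    scale: str
    quantile_group: int  # 1 = best mood


@dataclass
class RegressionStepResult:
    step: int
    n: int
    beta_std: "pd.Series"
    ci95: "pd.DataFrame"
    r2: float
    r2_change: float
    f_change: float
    df: tuple[int, int]
    p_change: float
    excluded_ids: list = field(default_factory=list)


@dataclass
class AnovaResult:
    effects: "pd.DataFrame"
    epsilon_gg: dict
    mauchly: dict


# ---------------------------------------------------------------------------
# mood harmonisation


def harmonise_mood(
    raw_scores, scales, q: int = 4, orientation: dict | None = None
) -> list[HarmonisedMood]:
    """Collapse mood scores into within-scale quantile groups.

    Each scale's scores are ranked towards negative affect (POMS reversed)
    and cut into ``q`` near-equal groups; group 1 is the best mood, group
    ``q`` the highest negative affect.  Ties are broken by input order
    (deterministic); a scale with fewer than ``q`` distinct values triggers
    a degenerate-cut warning but still produces balanced groups.
    """
    orientation = dict(SCALE_ORIENTATION if orientation is None else orientation)
    raw = pd.Series(list(raw_scores), dtype=float)
    scale = pd.Series(list(scales))
    if len(raw) != len(scale):
        raise ValueError("raw_scores and scales must have equal length")
    group = pd.Series(0, index=raw.index, dtype=int)
    for sc, idx in scale.groupby(scale).groups.items():
        if sc not in orientation:
            raise KeyError(f"unknown mood scale {sc!r}")
        vals = orientation[sc] * raw[idx]
        n = len(vals)
        if n < q:
            raise ValueError(f"scale {sc!r} has {n} observations, fewer than q={q}")
        if vals.nunique() < q:
            warnings.warn(
                f"scale {sc!r} has fewer than {q} distinct values; quantile cut is degenerate",
                stacklevel=2,
            )
        ranks = vals.rank(method="first").astype(int)  # 1..n, ties by order
        group[idx] = ((ranks - 1) * q) // n + 1
    return [
        HarmonisedMood(raw=float(raw[i]), scale=str(scale[i]), quantile_group=int(group[i]))
        for i in raw.index
    ]


# ---------------------------------------------------------------------------
# elementary tests and transforms


def log_transform_if_skewed(x, skew_threshold: float = 1.0):
    """Natural-log transform applied iff |sample skewness| exceeds the threshold.

    Zeros are offset by half the smallest positive value before the log.
    Returns ``(values, transformed_flag, offset)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.allclose(x, x[0]):
        return x.copy(), False, 0.0
    skew = sps.skew(x, bias=False)
    if not np.isfinite(skew) or abs(skew) <= skew_threshold:
        return x.copy(), False, 0.0
    if (x < 0).any():
        raise ValueError("cannot log-transform negative values")
    offset = 0.0
    if (x == 0).any():
        positive = x[x > 0]
        if positive.size == 0:
            return x.copy(), False, 0.0
        offset = float(positive.min()) / 2.0
    return np.log(x + offset), True, offset


def paired_t(x, y) -> dict:
    """Classical two-sided paired t on x - y, with a zero-variance guard."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired_t requires equal-length samples")
    n = x.size
    if n < 2:
        raise ValueError("paired_t requires n >= 2")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if d.mean() == 0.0 else float(np.sign(d.mean()) * np.inf)
        p = 1.0 if d.mean() == 0.0 else 0.0
        return {"t": t, "df": df, "p": p, "degenerate": True}
    res = sps.ttest_rel(x, y)
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue), "degenerate": False}


def chi_square(table) -> dict:
    """Pearson chi-square on a 2x2 table, without continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("chi_square expects a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi_square undefined with a zero marginal")
    x2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return {"x2": float(x2), "df": int(dof), "p": float(p), "n": int(table.sum())}


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rule; returns a boolean rejection mask."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) * q / m)
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        reject[order[: k + 1]] = True
    return reject


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """BMI = weight (kg) / height (m)^2."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return float(weight_kg) / float(height_m) ** 2


# ---------------------------------------------------------------------------
# regression battery


def _design_matrix(X: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(arr)), arr])) < arr.shape[1] + 1:
        raise ValueError("design matrix is rank deficient (aliased columns)")
    return arr


def cooks_distance_filter(X, y, threshold: float | None = None):
    """Cook's distances from a full-sample OLS fit; exclude D > threshold.

    The default threshold is 4/N.  Returns ``(retained_mask, distances)``;
    exclusion is applied once, with no iterative refitting.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= X.shape[1] + 1:
        raise ValueError("cooks_distance_filter requires N > p + 1")
    arr = _design_matrix(X)
    model = sm.OLS(y, sm.add_constant(arr)).fit()
    if model.mse_resid <= np.finfo(float).tiny:
        distances = np.zeros(n)  # perfect fit: no observation is influential
    else:
        distances = model.get_influence().cooks_distance[0]
    if threshold is None:
        threshold = 4.0 / n
    retained = distances <= threshold
    return retained, distances


def _zscore(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"cannot standardize constant column(s): {bad}")
    return (frame - frame.mean()) / sd


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    step1: list[str],
    step2: list[str],
    cooks_exclude: bool = True,
) -> list[RegressionStepResult]:
    """Two-step OLS with standardized coefficients and the R2-change F test.

    Step 1 enters the covariates; step 2 adds the diet predictor(s).
    Cook's distances from the full (step-2) fit on the raw scale flag
    cases with D > 4/N, which are excluded once before both steps are
    fitted on the z-scored analysed sample.
    """
    cols = [outcome] + list(step1) + list(step2)
    df = data[cols].dropna()
    n0 = len(df)
    if n0 <= len(step1) + len(step2) + 2:
        raise ValueError("too few complete cases for the two-step model")
    excluded: list = []
    if cooks_exclude:
        retained, _ = cooks_distance_filter(df[list(step1) + list(step2)], df[outcome])
        excluded = df.index[~retained].tolist()
        df = df.loc[retained]
    z = _zscore(df)
    n = len(df)

    results = []
    r2_prev, p_prev = 0.0, 0
    for step_num, predictors in ((1, list(step1)), (2, list(step1) + list(step2))):
        X = sm.add_constant(np.asarray(z[predictors], dtype=float))
        fit = sm.OLS(np.asarray(z[outcome], dtype=float), X).fit()
        r2 = float(fit.rsquared)
        q = len(predictors) - p_prev
        df_resid = n - len(predictors) - 1
        if step_num == 1:
            r2_change, f_change = r2, np.nan
            p_change = float(fit.f_pvalue)
            f_change = float(fit.fvalue)
            ddf = (q, df_resid)
        else:
            r2_change = r2 - r2_prev
            f_change = (r2_change / q) / ((1.0 - r2) / df_resid) if df_resid > 0 else np.nan
            p_change = float(sps.f.sf(f_change, q, df_resid))
            ddf = (q, df_resid)
        params = pd.Series(fit.params[1:], index=predictors)
        ci = pd.DataFrame(fit.conf_int()[1:], index=predictors, columns=["lower", "upper"])
        results.append(
            RegressionStepResult(
                step=step_num,
                n=n,
                beta_std=params,
                ci95=ci,
                r2=r2,
                r2_change=float(r2_change),
                f_change=float(f_change),
                df=ddf,
                p_change=p_change,
                excluded_ids=excluded,
            )
        )
        r2_prev, p_prev = r2, len(predictors)
    return results


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with sphericity handling


def gg_epsilon(within_covariance) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-subject covariance."""
    S = np.asarray(within_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ValueError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least two within-subject levels")
    C = np.eye(k) - np.ones((k, k)) / k
    A = C @ S @ C
    lam = np.linalg.eigvalsh(A)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * float(np.sum(lam**2))
    if denom <= 0:
        return 1.0
    eps = float(np.sum(lam)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _epsilon_contrast(S: np.ndarray) -> float:
    """GG epsilon from a covariance already in orthonormal-contrast space."""
    lam = np.clip(np.linalg.eigvalsh(np.asarray(S, dtype=float)), 0.0, None)
    c = S.shape[0]
    denom = c * float(np.sum(lam**2))
    if denom <= 0:
        return 1.0
    return float(np.clip(float(np.sum(lam)) ** 2 / denom, 1.0 / c, 1.0))


def mauchly_test(S_contrast, df_resid: int) -> dict:
    """Mauchly's sphericity test on a contrast-space residual covariance."""
    S = np.asarray(S_contrast, dtype=float)
    c = S.shape[0]
    if c < 2:
        return {"w": 1.0, "x2": 0.0, "df": 0, "p": 1.0}
    sign, logdet = np.linalg.slogdet(S)
    trace = float(np.trace(S))
    if sign <= 0 or trace <= 0:
        return {"w": 0.0, "x2": np.inf, "df": c * (c + 1) // 2 - 1, "p": 0.0}
    log_w = logdet - c * np.log(trace / c)
    f = 1.0 - (2.0 * c**2 + c + 2.0) / (6.0 * c * df_resid)
    x2 = -df_resid * f * log_w
    dof = c * (c + 1) // 2 - 1
    return {"w": float(np.exp(log_w)), "x2": float(x2), "df": dof, "p": float(sps.chi2.sf(x2, dof))}


def _orthonormal_contrasts(levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and (levels-1) orthonormal contrast columns."""
    mean = np.ones((levels, 1)) / np.sqrt(levels)
    # orthonormal complement of the mean vector via QR
    q, _ = np.linalg.qr(np.hstack([mean, np.eye(levels)[:, : levels - 1]]))
    return mean, q[:, 1:levels]


def rm_anova(
    data: pd.DataFrame,
    within: dict[str, list],
    covariates: pd.DataFrame | None = None,
    gg_alpha: float = 0.05,
) -> AnovaResult:
    """Univariate repeated-measures AN(C)OVA on a wide subject-by-cell table.

    Parameters
    ----------
    data : one row per subject; columns are the within-subject cells in the
        order of ``itertools.product(*within.values())``.
    within : factor name -> ordered levels.  All factor-level combinations
        must be present (complete balanced within design).
    covariates : optional continuous between-subject covariates (e.g. a diet
        score entered as a continuous factor, plus sex/BMI/kcal...).  They
        are mean-centred internally so within-subject effects are evaluated
        at the covariate mean.
    gg_alpha : apply the Greenhouse-Geisser df correction to a within block
        when Mauchly's p falls below this level.

    Tests use univariate (contrast-transformed) sums of squares pooled over
    orthonormal contrast columns.
    """
    factors = list(within)
    level_counts = [len(within[f]) for f in factors]
    k = int(np.prod(level_counts))
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != k:
        raise ValueError(
            f"data must have one column per within cell ({k}), got {Y.shape[1]}"
        )
    if np.isnan(Y).any():
        raise ValueError("missing cells are not supported (complete cases only)")
    n = Y.shape[0]

    if covariates is not None:
        C = pd.DataFrame(covariates)
        if len(C) != n:
            raise ValueError("covariates must align with data rows")
        Cc = np.asarray(C, dtype=float)
        Cc = Cc - Cc.mean(axis=0)
        cov_names = list(C.columns)
    else:
        Cc = np.empty((n, 0))
        cov_names = []
    X = np.column_stack([np.ones(n), Cc])
    p = X.shape[1]
    if n <= p:
        raise ValueError("more between-subject parameters than subjects")
    XtX_inv = np.linalg.pinv(X.T @ X)
    coef_names = ["intercept"] + cov_names

    bases = [_orthonormal_contrasts(L) for L in level_counts]
    rows, eps_map, mauchly_map = [], {}, {}

    def run_block(label_prefix: str, M: np.ndarray, is_between: bool) -> None:
        Ye = Y @ M  # n x c
        c = Ye.shape[1]
        B = XtX_inv @ X.T @ Ye
        resid = Ye - X @ B
        sse = float(np.sum(resid**2))
        df_err = c * (n - p)
        S = resid.T @ resid / (n - p)
        if not is_between and c >= 2:
            m = mauchly_test(S, n - p)
            eps = _epsilon_contrast(S)
        else:
            m = {"w": 1.0, "x2": 0.0, "df": 0, "p": 1.0}
            eps = 1.0
        if not is_between:
            eps_map[label_prefix] = eps
            mauchly_map[label_prefix] = m
        gg = (not is_between) and c >= 2 and m["p"] < gg_alpha
        for j, cname in enumerate(coef_names):
            ssh = float(np.sum(B[j, :] ** 2) / XtX_inv[j, j])
            df1, df2 = c, df_err
            F = (ssh / df1) / (sse / df2) if sse > 0 else np.inf
            use_eps = eps if gg else 1.0
            pval = float(sps.f.sf(F, df1 * use_eps, df2 * use_eps))
            if is_between and cname == "intercept":
                continue  # grand-mean test is not a reported effect
            effect = (
                cname
                if is_between
                else (label_prefix if cname == "intercept" else f"{label_prefix} x {cname}")
            )
            rows.append(
                {
                    "effect": effect,
                    "F": F,
                    "df1": df1 * use_eps,
                    "df2": df2 * use_eps,
                    "p": pval,
                    "partial_eta2": ssh / (ssh + sse) if (ssh + sse) > 0 else 0.0,
                    "epsilon_gg": eps,
                    "gg_applied": bool(gg),
                }
            )

    # between-subjects block (subject means)
    M_mean = bases[0][0]
    for mean_f, _ in bases[1:]:
        M_mean = np.kron(M_mean, mean_f)
    run_block("between", M_mean, is_between=True)

    # within-effect blocks: every non-empty subset of within factors
    n_f = len(factors)
    for mask in range(1, 2**n_f):
        subset = [factors[i] for i in range(n_f) if mask >> i & 1]
        M = np.ones((1, 1))
        for i in range(n_f):
            mean_f, contr_f = bases[i]
            M = np.kron(M, contr_f if mask >> i & 1 else mean_f)
        run_block(" x ".join(subset), M, is_between=False)

    return AnovaResult(
        effects=pd.DataFrame(rows).set_index("effect"),
        epsilon_gg=eps_map,
        mauchly=mauchly_map,
    )


# ---------------------------------------------------------------------------
# cognition-log scoring


def score_cognition_logs(task_logs: dict) -> dict:
    """Score raw trial logs into task outcome measures.

    Expected keys (any subset): ``serial_sevens`` (list of trials with
    ``correct`` and ``rt_ms``); ``flanker`` (trials with ``condition`` in
    congruent/incongruent/neutral, ``correct``, ``rt_ms``); ``recall``
    (word lists: ``words`` = {'abstract': [...], 'concrete': [...]},
    ``immediate``/``delayed`` = recalled word lists).
    """
    out: dict[str, float] = {}
    if "serial_sevens" in task_logs:
        trials = task_logs["serial_sevens"]
        _check_trials(trials, "serial_sevens", ("correct", "rt_ms"))
        correct = [bool(t["correct"]) for t in trials]
        out["serial7_pct_correct"] = 100.0 * float(np.mean(correct))
        out["serial7_mean_rt_ms"] = float(np.mean([t["rt_ms"] for t in trials]))
    if "flanker" in task_logs:
        trials = task_logs["flanker"]
        _check_trials(trials, "flanker", ("condition", "correct", "rt_ms"))
        for cond in ("congruent", "incongruent", "neutral"):
            sub = [t for t in trials if t["condition"] == cond]
            if not sub:
                raise ValueError(f"flanker log has no {cond} trials")
            out[f"flanker_{cond}_pct_correct"] = 100.0 * float(
                np.mean([bool(t["correct"]) for t in sub])
            )
            out[f"flanker_{cond}_mean_rt_ms"] = float(np.mean([t["rt_ms"] for t in sub]))
    if "recall" in task_logs:
        log = task_logs["recall"]
        words = {k: {w.lower() for w in log["words"][k]} for k in ("abstract", "concrete")}
        for phase in ("immediate", "delayed"):
            recalled = {w.lower() for w in log.get(phase, [])}
            for wtype in ("abstract", "concrete"):
                out[f"recall_{phase}_{wtype}"] = float(len(recalled & words[wtype]))
    return out


def _check_trials(trials, task: str, keys: tuple) -> None:
    for i, t in enumerate(trials):
        for key in keys:
            if key not in t:
                raise ValueError(f"{task} trial {i} is malformed: missing {key!r}")
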