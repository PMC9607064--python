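"""K-means discovery of dietary sub-patterns within the top WISH tertile.

Clustering operates on the 13 standardized WISH component scores
(Euclidean distance, k-means++ starts, best of `restarts` by within-cluster
sum of squares).  The search runs k = 2..6 and a reproducible default rule
picks the chosen k — the largest k whose marginal gain in variance
explained is at least 10 percentage points and whose smallest cluster holds
at least 10% of the sample — while the full diagnostics table is always
emitted for human review.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ClusterSolution",
    "standardise_components",
    "kmeans_fit",
    "select_k",
    "compare_clusters",
]


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray  # k x n_features, on the standardized scale
    within_ss: float
    variance_explained: float  # between-SS / total-SS
    seed: int
    restarts: int


def standardise_components(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (mean 0, SD 1 with the n-1 denominator).

    Constant columns carry no clustering information and are dropped with a
    warning.
    """
    import warnings

    if len(scores) < 2:
        raise ValueError("standardisation requires n >= 2")
    sd = scores.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warnings.warn(f"dropping constant column(s): {constant}", stacklevel=2)
        scores = scores.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (scores - scores.mean()) / sd


def kmeans_fit(X, k: int, seed: int = 0, restarts: int = 50) -> ClusterSolution:
    """Lloyd's algorithm from k-means++ starts; best of `restarts` by within-SS."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    within = float(km.inertia_)
    ve = 1.0 - within / total_ss if total_ss > 0 else 0.0
    return ClusterSolution(
        k=k,
        assignments=labels,
        centroids=km.cluster_centers_,
        within_ss=within,
        variance_explained=ve,
        seed=seed,
        restarts=restarts,
    )


def select_k(solutions: list[ClusterSolution], min_size_frac: float = 0.10,
             gain_threshold: float = 0.10) -> dict:
    """Reproducible k selection over a scree of candidate solutions.

    Chosen k = the largest candidate whose marginal gain in variance
    explained (over the previous k, with k=1 explaining 0) reaches
    `gain_threshold` AND whose smallest cluster is at least
    `min_size_frac` of the sample.  If no candidate clears the gain
    threshold the rule returns the smallest k with a weak-structure flag.
    Candidates failing only the size constraint are recorded as overridden.
    """
    if len(solutions) < 2:
        raise ValueError("select_k needs at least two candidate solutions")
    solutions = sorted(solutions, key=lambda s: s.k)
    n = len(solutions[0].assignments)
    diag = []
    prev_ve = 0.0
    for sol in solutions:
        sizes = np.bincount(sol.assignments, minlength=sol.k)
        diag.append(
            {
                "k": sol.k,
                "variance_explained": sol.variance_explained,
                "marginal_gain": sol.variance_explained - prev_ve,
                "min_cluster_size": int(sizes.min()),
                "size_ok": bool(sizes.min() >= min_size_frac * n),
            }
        )
        prev_ve = sol.variance_explained
    diagnostics = pd.DataFrame(diag).set_index("k")
    eligible = diagnostics[
        (diagnostics["marginal_gain"] >= gain_threshold) & diagnostics["size_ok"]
    ]
    overridden = diagnostics[
        (diagnostics["marginal_gain"] >= gain_threshold) & ~diagnostics["size_ok"]
    ].index.tolist()
    weak = eligible.empty
    chosen = int(eligible.index.max()) if not eligible.empty else int(diagnostics.index.min())
    return {
        "k": chosen,
        "weak_structure": bool(weak),
        "size_overrides": overridden,
        "diagnostics": diagnostics,
    }


def compare_clusters(
    solution: ClusterSolution,
    continuous: pd.DataFrame | None = None,
    flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster comparisons mirroring a descriptives table.

    Continuous variables get a one-way ANOVA (F, p, eta^2) across the two
    clusters; boolean below-RNI flags get a Pearson chi-square (no
    continuity correction) on the 2x2 cluster-by-flag table.
    """
    from .adequacy import adequacy_contingency
    from .stats import chi_square

    labels = np.asarray(solution.assignments)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("compare_clusters requires exactly 2 clusters")
    for u in uniq:
        if (labels == u).sum() < 2:
            raise ValueError(f"cluster {u} has fewer than 2 members")
    rows = []
    if continuous is not None:
        for col in continuous.columns:
            x = continuous[col].to_numpy(dtype=float)
            groups = [x[labels == u] for u in uniq]
            grand = x.mean()
            ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ss_total = float(((x - grand) ** 2).sum())
            ss_within = ss_total - ss_between
            df1, df2 = len(uniq) - 1, len(x) - len(uniq)
            if ss_within <= 0:
                F, p = (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
            else:
                F = (ss_between / df1) / (ss_within / df2)
                from scipy import stats as sps

                p = float(sps.f.sf(F, df1, df2))
            rows.append(
                {
                    "variable": col,
                    "kind": "continuous",
                    "mean_cluster_0": float(groups[0].mean()),
                    "mean_cluster_1": float(groups[1].mean()),
                    "statistic": float(F),
                    "df1": df1,
                    "df2": df2,
                    "p": p,
                    "eta2": ss_between / ss_total if ss_total > 0 else 0.0,
                }
            )
    if flags is not None:
        for col in flags.columns:
            table = adequacy_contingency(labels, flags[col])
            res = chi_square(table)
            n0, n1 = table.sum(axis=1)
            rows.append(
                {
                    "variable": col,
                    "kind": "flag",
                    "mean_cluster_0": table[0, 0] / n0 if n0 else np.nan,
                    "mean_cluster_1": table[1, 0] / n1 if n1 else np.nan,
                    "statistic": res["x2"],
                    "df1": res["df"],
                    "df2": res["n"],
                    "p": res["p"],
                    "eta2": np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("variable")
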