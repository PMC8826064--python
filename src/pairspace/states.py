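"""Behavioral-state classification and dive-parameter models.

The six per-bin movement metrics are standardized to zero mean and unit
sample variance, the number of clusters is chosen by a majority vote of
four internal validity indices, and k-means partitions the bins. For the
two-cluster solution the slower cluster (lower mean raw swimming speed) is
labelled "resting/milling" and the faster one "travelling", matching the
field interpretation of the cluster centroids.

Whether the adult female's fine-scale dive parameters separate the states
is then asked with binomial (logit) random-intercept models — state as the
response, dive duration / mean depth / maximum depth as candidate
predictors, tag as the grouping factor — ranked by AIC over all non-empty
predictor subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .glmm import Binomial, MixedGLM, MixedGLMResults
from .kinematics import METRIC_COLUMNS

__all__ = [
    "RESTING_MILLING",
    "TRAVELLING",
    "ClusterSolution",
    "DiveModelResult",
    "standardize_metrics",
    "destandardize_metrics",
    "select_cluster_count",
    "cluster_and_label",
    "assign_bin_states",
    "rank_dive_models",
]

RESTING_MILLING = "resting_milling"
TRAVELLING = "travelling"


@dataclass
class ClusterSolution:
    """A fitted k-means partition of the standardized metric space."""

    k: int
    centers: np.ndarray
    labels: np.ndarray
    inertia: float
    seed: int
    index_votes: dict[str, int] = field(default_factory=dict)
    #: cluster index -> state name; empty unless k == 2
    state_of_cluster: dict[int, str] = field(default_factory=dict)


@dataclass
class DiveModelResult:
    """One candidate binomial mixed model of state vs dive parameters."""

    predictor_set: tuple[str, ...]
    aic: float
    coefficients: pd.DataFrame  # name, coef, se, p
    random_effect_variance: float
    flags: list[str]
    results: MixedGLMResults


def standardize_metrics(
    metrics: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center each metric to mean 0 and scale to sample SD 1.

    Returns the standardized table and a scale table (mean, sd per column)
    sufficient to invert the transform. A constant column cannot be scaled
    and raises ``ValueError`` naming it.
    """
    columns = columns or METRIC_COLUMNS
    if len(metrics) < 2:
        raise ValueError("need >= 2 rows to standardize")
    X = metrics[columns].to_numpy(float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    dead = [c for c, s in zip(columns, sd) if s == 0 or not np.isfinite(s)]
    if dead:
        raise ValueError(f"constant column(s) cannot be standardized: {dead}")
    out = metrics.copy()
    out[columns] = (X - mean) / sd
    scale = pd.DataFrame({"column": columns, "mean": mean, "sd": sd})
    return out, scale


def destandardize_metrics(
    standardized: pd.DataFrame, scale: pd.DataFrame
) -> pd.DataFrame:
    """Invert :func:`standardize_metrics`."""
    out = standardized.copy()
    for _, row in scale.iterrows():
        out[row["column"]] = standardized[row["column"]] * row["sd"] + row["mean"]
    return out


def _gap_statistic(
    X: np.ndarray, k_range: list[int], seed: int, n_ref: int = 10
) -> int:
    """Gap statistic with uniform reference over the bounding box; chooses
    the smallest k with gap(k) >= gap(k+1) - s(k+1) (1-SE rule), falling
    back to argmax gap."""
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_wk(data: np.ndarray, k: int, rs: int) -> float:
        km = KMeans(n_clusters=k, n_init=10, random_state=rs, algorithm="lloyd").fit(data)
        return np.log(max(km.inertia_, 1e-300))

    gaps, sks = [], []
    for k in k_range:
        ref = np.array(
            [
                log_wk(rng.uniform(lo, hi, size=X.shape), k, seed + b)
                for b in range(n_ref)
            ]
        )
        gaps.append(ref.mean() - log_wk(X, k, seed))
        sks.append(ref.std(ddof=1) * np.sqrt(1.0 + 1.0 / n_ref))
    for i in range(len(k_range) - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            return k_range[i]
    return k_range[int(np.argmax(gaps))]


def select_cluster_count(
    standardized: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(2, 9),
    seed: int = 0,
    columns: list[str] | None = None,
) -> tuple[int, dict[str, int]]:
    """Choose k by majority vote of four internal validity indices.

    Silhouette and Calinski-Harabasz vote for their maximizing k,
    Davies-Bouldin for its minimizing k, and the gap statistic by the
    1-SE rule. Ties in the vote go to the smallest k; every index's vote is
    returned so disagreement stays visible.
    """
    if isinstance(standardized, pd.DataFrame):
        X = standardized[columns or METRIC_COLUMNS].to_numpy(float)
    else:
        X = np.asarray(standardized, float)
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 points to select a cluster count, got {n}")
    k_range = [k for k in k_range]
    if n <= max(k_range):
        import warnings

        warnings.warn(f"only {n} points: shrinking k range below n")
        k_range = [k for k in k_range if k < n]

    sil, ch, db = {}, {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=25, random_state=seed, algorithm="lloyd").fit(X)
        lab = km.labels_
        sil[k] = silhouette_score(X, lab)
        ch[k] = calinski_harabasz_score(X, lab)
        db[k] = davies_bouldin_score(X, lab)
    votes = {
        "silhouette": max(sorted(sil), key=lambda k: sil[k]),
        "calinski_harabasz": max(sorted(ch), key=lambda k: ch[k]),
        "davies_bouldin": min(sorted(db), key=lambda k: db[k]),
        "gap": _gap_statistic(X, k_range, seed),
    }
    counts: dict[int, int] = {}
    for v in votes.values():
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    k_chosen = min(k for k, c in counts.items() if c == top)
    return k_chosen, votes


def cluster_and_label(
    standardized: pd.DataFrame,
    raw_metrics: pd.DataFrame,
    k: int,
    seed: int = 0,
    columns: list[str] | None = None,
) -> tuple[ClusterSolution, pd.DataFrame]:
    """Run seeded multi-restart k-means and name the two-cluster states.

    For ``k == 2`` the cluster with the lower mean raw swimming speed is
    labelled resting/milling and the other travelling (labels therefore do
    not depend on k-means' arbitrary cluster indexing). For other k the raw
    cluster indices are returned unlabelled.

    Returns the solution and an assignment table aligned with the input
    rows (tag_id, bin_index, cluster, state).
    """
    columns = columns or METRIC_COLUMNS
    if not len(standardized):
        raise ValueError("no bins to cluster")
    X = standardized[columns].to_numpy(float)
    km = KMeans(
        n_clusters=k, n_init=25, random_state=seed, tol=1e-6, algorithm="lloyd"
    ).fit(X)
    solution = ClusterSolution(
        k=k,
        centers=km.cluster_centers_,
        labels=km.labels_.copy(),
        inertia=float(km.inertia_),
        seed=seed,
    )
    assign = pd.DataFrame(
        {
            "tag_id": standardized["tag_id"].to_numpy()
            if "tag_id" in standardized
            else np.repeat("", len(standardized)),
            "bin_index": standardized["bin_index"].to_numpy()
            if "bin_index" in standardized
            else np.arange(len(standardized)),
            "cluster": km.labels_,
        }
    )
    if k == 2:
        speeds = raw_metrics["speed_kmh"].to_numpy(float)
        mean_speed = [speeds[km.labels_ == c].mean() for c in (0, 1)]
        slow = int(np.argmin(mean_speed))
        solution.state_of_cluster = {
            slow: RESTING_MILLING,
            1 - slow: TRAVELLING,
        }
        assign["state"] = [solution.state_of_cluster[c] for c in km.labels_]
    else:
        assign["state"] = None
    return solution, assign


def assign_bin_states(
    metrics: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Merge per-bin state labels onto a metric (or any per-bin) table."""
    return metrics.merge(
        assignments[["tag_id", "bin_index", "state"]],
        on=["tag_id", "bin_index"],
        how="left",
    )


def rank_dive_models(
    dives: pd.DataFrame,
    predictors: tuple[str, ...] = ("duration", "mean_depth", "max_depth"),
) -> list[DiveModelResult]:
    """Rank binomial mixed models of behavioral state on dive parameters.

    ``dives`` needs one row per adult-female deep dive with the candidate
    predictor columns, a ``state`` column (two levels) and ``tag_id``. The
    response is 1 for travelling. Models over every non-empty predictor
    subset are fitted with a random intercept per tag and returned sorted
    by AIC ascending.
    """
    df = dives.dropna(subset=["state"]).copy()
    if df["tag_id"].nunique() < 2:
        raise ValueError("need dives from >= 2 tags")
    y = (df["state"] == TRAVELLING).to_numpy(float)
    results: list[DiveModelResult] = []
    for r in range(1, len(predictors) + 1):
        for subset in combinations(predictors, r):
            X = np.column_stack(
                [np.ones(len(df))] + [df[c].to_numpy(float) for c in subset]
            )
            names = ["intercept", *subset]
            fit = MixedGLM(
                y, X, df["tag_id"].to_numpy(), Binomial(), exog_names=names
            ).fit()
            coef = pd.DataFrame(
                {
                    "name": names,
                    "coef": fit.fe_params,
                    "se": fit.bse[: len(names)],
                    "p": fit.pvalues[: len(names)],
                }
            )
            results.append(
                DiveModelResult(
                    predictor_set=subset,
                    aic=fit.aic,
                    coefficients=coef,
                    random_effect_variance=fit.random_effect_var,
                    flags=list(fit.flags),
                    results=fit,
                )
            )
    results.sort(key=lambda r: r.aic)
    return results


def dive_models_table(results: list[DiveModelResult]) -> pd.DataFrame:
    """Flatten ranked dive models into one row per coefficient."""
    rows = []
    for res in results:
        for _, c in res.coefficients.iterrows():
            rows.append(
                {
                    "predictor_set": "+".join(res.predictor_set),
                    "aic": res.aic,
                    "term": c["name"],
                    "coef": c["coef"],
                    "se": c["se"],
                    "p": c["p"],
                }
            )
    return pd.DataFrame(rows)
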