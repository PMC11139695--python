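"""Trend scores: cluster-level summaries of ordinal questionnaire variables.

Each response category of a variable carries an integer weight (points
increasing with consumption frequency / intensity).  For a cluster, the
trend score of a variable is

    score = sum_i  w_i * p_i

where w_i is the weight of category i and p_i the within-cluster
proportion of responses in category i.  The score is algebraically the
mean mapped weight of the cluster's participants, bounded by the extreme
weights, and equals a weight exactly only for a degenerate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .schema import VariableDef

PROPORTION_TOL = 1e-12


class EmptyClusterError(ValueError):
    pass


@dataclass(frozen=True)
class WeightVector:
    variable_id: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = self.weights
        if len(w) == 0 or w[0] != 1:
            raise ValueError("weights must start at 1")
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValueError("weights must be strictly increasing")


@dataclass(frozen=True)
class ProportionVector:
    variable_id: str
    cluster: object
    proportions: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if self.n == 0:
            raise EmptyClusterError(
                f"cluster {self.cluster!r} is empty for {self.variable_id!r}"
            )
        if (p < -PROPORTION_TOL).any():
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > PROPORTION_TOL:
            raise ValueError(f"proportions sum to {p.sum()}, expected 1")


def map_weight(variable: VariableDef, label: str) -> int:
    """Points for one response label of one variable."""
    return variable.weight(label)


def trend_score(weights: WeightVector, proportions: ProportionVector) -> float:
    """The weighted category-proportion sum for one (cluster, variable)."""
    if weights.variable_id != proportions.variable_id:
        raise ValueError("weight and proportion vectors describe different "
                         "variables")
    w = np.asarray(weights.weights, dtype=float)
    p = np.asarray(proportions.proportions, dtype=float)
    if len(w) != len(p):
        raise ValueError("weight/proportion length mismatch")
    return float(w @ p)


@dataclass
class TrendTable:
    """Cluster-by-variable trend scores with per-variable diagnostics.

    ``scores``: DataFrame indexed by variable id, one column per cluster.
    ``p_values``: per-variable cross-cluster one-way ANOVA p on the
    participant-level mapped weights.  ``max_cluster``: per variable, the
    cluster(s) attaining the maximal score (ties kept).
    """

    scores: pd.DataFrame
    p_values: pd.Series
    max_cluster: pd.Series
    categories: pd.Series
    cluster_sizes: pd.Series

    def to_csv(self, path) -> None:
        out = self.scores.round(3).copy()
        out["p_value"] = self.p_values
        out["max_cluster"] = [";".join(map(str, m)) for m in self.max_cluster]
        out["category"] = self.categories
        out.to_csv(path, index_label="variable")


def participant_weights(cohort: Cohort) -> pd.DataFrame:
    """Per-participant mapped weights, one column per variable.

    Independent of the proportion bookkeeping: the column mean over a
    cluster equals that cluster's trend score.
    """
    out = {}
    for var in cohort.schema:
        codes = cohort.data[var.id].cat.codes.to_numpy()
        weights = np.asarray(var.weights, dtype=float)
        vals = np.where(codes >= 0, weights[np.clip(codes, 0, None)], np.nan)
        out[var.id] = vals
    return pd.DataFrame(out, index=cohort.data.index)


def trend_table(cohort: Cohort, labels) -> TrendTable:
    """Trend scores for every (cluster, variable) plus cross-cluster tests.

    ``labels`` is an array-like of cluster labels aligned with the cohort.
    Raises :class:`EmptyClusterError` if any declared cluster is empty and
    errors if any participant is unassigned.
    """
    labels = pd.Series(np.asarray(labels), index=cohort.data.index)
    if labels.isna().any():
        raise ValueError("every participant must carry a cluster label")
    clusters = sorted(pd.unique(labels))
    sizes = labels.value_counts()
    for c in clusters:
        if sizes.get(c, 0) == 0:
            raise EmptyClusterError(f"cluster {c!r} is empty")

    rows, pvals, argmax, cats = {}, {}, {}, {}
    for var in cohort.schema:
        w = WeightVector(var.id, tuple(float(x) for x in var.weights))
        col = cohort.data[var.id]
        scores = {}
        groups = []
        for c in clusters:
            sub = col[labels == c]
            counts = sub.value_counts().reindex(var.scale_labels).fillna(0)
            n = int(counts.sum())
            pi = ProportionVector(var.id, c,
                                  tuple(counts.to_numpy() / n), n)
            scores[c] = trend_score(w, pi)
            weights_arr = np.asarray(var.weights, dtype=float)
            groups.append(np.repeat(weights_arr, counts.to_numpy().astype(int)))
        rows[var.id] = scores
        pooled = np.concatenate(groups)
        if len(groups) < 2 or np.ptp(pooled) == 0:
            pvals[var.id] = np.nan  # single cluster / constant: undefined
        else:
            pvals[var.id] = float(stats.f_oneway(*groups).pvalue)
        smax = max(scores.values())
        argmax[var.id] = tuple(c for c in clusters
                               if np.isclose(scores[c], smax))
        cats[var.id] = var.category

    scores_df = pd.DataFrame.from_dict(rows, orient="index")[clusters]
    scores_df = scores_df.loc[cohort.schema.variable_ids]
    return TrendTable(
        scores=scores_df,
        p_values=pd.Series(pvals).loc[scores_df.index],
        max_cluster=pd.Series(argmax).loc[scores_df.index],
        categories=pd.Series(cats).loc[scores_df.index],
        cluster_sizes=sizes.loc[clusters],
    )


def rank_clusters(table: TrendTable) -> pd.DataFrame:
    """Per-cluster summary of where it attains the maximal trend score.

    Returns a DataFrame indexed by cluster with, per variable category, the
    count of variables on which the cluster holds the (possibly shared)
    maximum, plus a ``summary`` column like ``"29/58 food_item"``.
    """
    clusters = list(table.scores.columns)
    categories = sorted(table.categories.unique())
    totals = table.categories.value_counts()
    counts = pd.DataFrame(0, index=clusters, columns=categories)
    for var, winners in table.max_cluster.items():
        cat = table.categories[var]
        for c in winners:
            counts.loc[c, cat] += 1
    counts["summary"] = [
        "; ".join(f"{counts.loc[c, cat]}/{totals[cat]} {cat}"
                  for cat in categories)
        for c in clusters
    ]
    return counts
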