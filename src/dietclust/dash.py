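"""DASH-style diet-quality score and cluster-wise comparisons.

The score covers 8 dietary components: five favorable (fruits,
vegetables, nuts/legumes, low-fat dairy, whole grains) and three
restricted (sodium, sweetened beverages, red/processed meats).  Each
component is scored 1-5 by cohort quintile of intake — ascending for
favorable components, reversed (quintile q -> 6-q) for restricted ones —
and the total, the sum of the 8 sub-scores, ranges 8-40.  Component
intakes are numeric inputs (g/day or servings/day); they are not derived
from the ordinal frequency questionnaire.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

FAVORABLE = ("fruits", "vegetables", "nuts_legumes", "low_fat_dairy",
             "whole_grains")
RESTRICTED = ("sodium", "sweetened_beverages", "red_processed_meats")
COMPONENTS = FAVORABLE + RESTRICTED


def _rank_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """1..n_bins bins from average ranks; boundary ties fall to the lower
    bin; an all-identical vector maps everyone to the midpoint bin."""
    n = len(values)
    if np.ptp(values) == 0:
        warnings.warn("all component values identical; assigning the "
                      "midpoint sub-score", stacklevel=3)
        return np.full(n, (n_bins + 1) // 2, dtype=int)
    ranks = stats.rankdata(values, method="average")
    bins = np.ceil(n_bins * ranks / n).astype(int)
    return np.clip(bins, 1, n_bins)


def dash_subscore(values, direction: str = "favorable") -> np.ndarray:
    """Quintile sub-scores (1..5) for one component across the cohort.

    ``direction='favorable'``: higher intake, higher score;
    ``'restricted'``: reversed (s -> 6-s).
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("component intakes must not be missing")
    if direction not in ("favorable", "restricted"):
        raise ValueError(f"unknown direction {direction!r}")
    if len(np.unique(values)) < 5:
        warnings.warn("fewer than 5 distinct values; quintiles are coarse",
                      stacklevel=2)
    sub = _rank_bins(values, 5)
    if direction == "restricted":
        sub = 6 - sub
    return sub


def dash_total(sub_scores) -> np.ndarray:
    """Total DASH score per participant from an (n, 8) sub-score array."""
    sub = np.asarray(sub_scores)
    if sub.ndim != 2 or sub.shape[1] != 8:
        raise ValueError(f"expected 8 sub-scores per participant, got shape "
                         f"{sub.shape}")
    if sub.min() < 1 or sub.max() > 5:
        raise ValueError("sub-scores must lie in 1..5")
    return sub.sum(axis=1)


def quartile_groups(totals) -> np.ndarray:
    """Cohort-relative quartile labels 1..4 (1 = lowest DASH quartile)."""
    return _rank_bins(np.asarray(totals, dtype=float), 4)


def dash_score(components: pd.DataFrame) -> pd.DataFrame:
    """Per-participant DASH scoring from a component-intake table.

    ``components`` must carry the 8 canonical columns.  Returns sub-scores,
    the total (8..40), and the cohort quartile (Q1..Q4).
    """
    missing = [c for c in COMPONENTS if c not in components.columns]
    if missing:
        raise ValueError(f"missing DASH components: {missing}")
    out = pd.DataFrame(index=components.index)
    for comp in COMPONENTS:
        direction = "favorable" if comp in FAVORABLE else "restricted"
        out[f"sub_{comp}"] = dash_subscore(components[comp].to_numpy(),
                                           direction)
    sub_cols = [f"sub_{c}" for c in COMPONENTS]
    out["total"] = dash_total(out[sub_cols].to_numpy())
    out["quartile"] = [f"Q{q}" for q in quartile_groups(out["total"])]
    return out


def dash_by_cluster(totals, labels, reference=None) -> dict:
    """Cluster-wise DASH comparison.

    Returns the K x 4 quartile composition (counts and %), per-cluster
    mean/SD totals, and, against the designated reference cluster
    (default: lowest mean score), a chi-square test of quartile
    composition and a two-sample t-test of mean totals per other cluster.
    Degenerate compositions (any cluster with < 2 participants) skip the
    tests with a warning.
    """
    totals = pd.Series(np.asarray(totals, dtype=float))
    labels = pd.Series(np.asarray(labels))
    quart = pd.Series(quartile_groups(totals), index=totals.index)
    clusters = sorted(pd.unique(labels))

    comp = pd.crosstab(labels, quart).reindex(
        index=clusters, columns=[1, 2, 3, 4], fill_value=0)
    comp.columns = [f"Q{q}" for q in comp.columns]
    comp_pct = comp.div(comp.sum(axis=1), axis=0) * 100.0
    means = totals.groupby(labels).agg(["mean", "std", "count"])

    if reference is None:
        reference = means["mean"].idxmin()

    tests = {}
    if (means["count"] < 2).any():
        warnings.warn("some cluster has fewer than 2 participants; "
                      "composition tests skipped", stacklevel=2)
    else:
        ref_tot = totals[labels == reference]
        for c in clusters:
            if c == reference:
                continue
            sub = comp.loc[[reference, c]].to_numpy()
            keep = sub.sum(axis=0) > 0
            chi_p = float(stats.chi2_contingency(sub[:, keep])[1])
            t_p = float(stats.ttest_ind(totals[labels == c], ref_tot).pvalue)
            tests[c] = {"composition_chi2_p": chi_p, "mean_t_p": t_p}

    return {"composition": comp, "composition_pct": comp_pct,
            "means": means, "reference": reference, "tests": tests}
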