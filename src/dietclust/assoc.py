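"""Cluster-hypertension association: contingency tables, crude odds
ratios, adjusted logistic models, and descriptive cluster comparisons.

Odds ratios contrast each dietary-pattern cluster against a reference
cluster (by default the largest cluster, ties broken by prevalence — the
pattern most plausibly aversive).  Per-contrast confidence intervals are
Wald intervals on the log-odds scale; the model-level p-value is the
likelihood-ratio test of the model with versus without the cluster
indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

Z_95 = float(stats.norm.ppf(0.975))  # 1.959964...


class SeparationError(RuntimeError):
    """A logistic fit failed to produce finite estimates."""


@dataclass
class ContingencyTable2xK:
    """Cases / non-cases per cluster with a flagged reference."""

    clusters: list
    cases: np.ndarray
    non_cases: np.ndarray
    reference: object

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases, dtype=int)
        self.non_cases = np.asarray(self.non_cases, dtype=int)
        if (self.cases < 0).any() or (self.non_cases < 0).any():
            raise ValueError("counts must be non-negative")
        if self.reference not in self.clusters:
            raise ValueError(f"reference {self.reference!r} not a cluster")

    @property
    def sizes(self) -> np.ndarray:
        return self.cases + self.non_cases

    @property
    def prevalence_pct(self) -> pd.Series:
        return pd.Series(100.0 * self.cases / self.sizes, index=self.clusters,
                         name="prevalence_pct")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cases": self.cases, "non_cases": self.non_cases,
             "n": self.sizes, "prevalence_pct": self.prevalence_pct,
             "reference": [c == self.reference for c in self.clusters]},
            index=pd.Index(self.clusters, name="cluster"),
        )


@dataclass(frozen=True)
class ModelSpec:
    """A named covariate set for the adjusted logistic models."""

    name: str
    covariates: tuple[str, ...] = ()

    @property
    def continuous(self) -> tuple[str, ...]:
        return tuple(c for c in self.covariates if c in CONTINUOUS_COVARIATES)

    @property
    def categorical(self) -> tuple[str, ...]:
        return tuple(c for c in self.covariates
                     if c not in CONTINUOUS_COVARIATES)


CONTINUOUS_COVARIATES = {"age", "bmi", "salt_intake"}

#: The staged adjustment sets: crude; + age, BMI; + smoking, education,
#: physical activity; + dyslipidemia, diabetes; + salt intake.
MODEL_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec("Model 1", ()),
    ModelSpec("Model 2", ("age", "bmi")),
    ModelSpec("Model 3", ("age", "bmi", "smoking", "education", "pa_category")),
    ModelSpec("Model 4", ("age", "bmi", "smoking", "education", "pa_category",
                          "dyslipidemia", "diabetes")),
    ModelSpec("Model 5", ("age", "bmi", "smoking", "education", "pa_category",
                          "dyslipidemia", "diabetes", "salt_intake")),
)


def model_specs(names: "list[str] | None" = None,
                drop: tuple[str, ...] = ()) -> list[ModelSpec]:
    """The standard staged models, optionally filtered by name and with
    covariates dropped (e.g. ``drop=('age',)`` for exact-age-matched runs)."""
    specs = [s for s in MODEL_SPECS if names is None or s.name in names]
    if drop:
        specs = [ModelSpec(s.name,
                           tuple(c for c in s.covariates if c not in drop))
                 for s in specs]
    return specs


@dataclass
class ORResult:
    model: str
    contrast: object              # cluster compared to the reference
    reference: object
    odds_ratio: float
    ci_low: float
    ci_high: float
    lr_p: float                   # model-level likelihood-ratio p

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence interval does not bracket the OR")
        if min(self.odds_ratio, self.ci_low, self.ci_high) <= 0:
            raise ValueError("odds ratios and bounds must be positive")


def or_results_frame(results: list[ORResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"model": r.model, "cluster": r.contrast, "reference": r.reference,
          "OR": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
          "lr_p": r.lr_p} for r in results]
    )


# ---------------------------------------------------------------------------
# Contingency and crude ORs
# ---------------------------------------------------------------------------

def default_reference(sizes: pd.Series, prevalence: pd.Series):
    """Reference cluster rule: largest n, ties broken by prevalence."""
    order = sorted(sizes.index,
                   key=lambda c: (sizes[c], prevalence[c]), reverse=True)
    return order[0]


def contingency_by_cluster(outcome, labels, reference=None,
                           ) -> ContingencyTable2xK:
    """2xK table of a binary outcome by cluster.

    ``outcome`` and ``labels`` are aligned array-likes; the outcome must be
    binary with no missing values and every participant must be labeled.
    """
    outcome = pd.Series(np.asarray(outcome))
    labels = pd.Series(np.asarray(labels))
    if outcome.isna().any():
        raise ValueError("outcome contains missing values")
    if labels.isna().any():
        raise ValueError("every participant must carry a cluster label")
    vals = set(pd.unique(outcome.astype(int)))
    if not vals <= {0, 1}:
        raise ValueError(f"outcome must be binary 0/1, saw {sorted(vals)}")
    outcome = outcome.astype(int)
    clusters = sorted(pd.unique(labels))
    cases = np.array([int(outcome[labels == c].sum()) for c in clusters])
    sizes = np.array([int((labels == c).sum()) for c in clusters])
    non_cases = sizes - cases
    size_s = pd.Series(sizes, index=clusters)
    prev_s = pd.Series(np.divide(cases, sizes, out=np.zeros(len(sizes)),
                                 where=sizes > 0), index=clusters)
    if reference is None:
        reference = default_reference(size_s, prev_s)
    return ContingencyTable2xK(clusters=clusters, cases=cases,
                               non_cases=non_cases, reference=reference)


def crude_or(table: ContingencyTable2xK,
             continuity_correction: bool = False) -> list[ORResult]:
    """Cross-product odds ratios vs the reference with Wald 95% CIs.

    OR = (a*d)/(b*c) for each non-reference cluster's 2x2 sub-table;
    CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  A zero cell is
    an error unless ``continuity_correction`` adds 0.5 to all four cells.
    The model-level p is the G-test (likelihood-ratio chi-square) of the
    full 2xK table with K-1 degrees of freedom.
    """
    ref_idx = table.clusters.index(table.reference)
    d, c0 = table.cases[ref_idx], table.non_cases[ref_idx]
    lr_p = likelihood_ratio_p(table)
    results = []
    for i, cl in enumerate(table.clusters):
        if i == ref_idx:
            continue
        a, b = table.cases[i], table.non_cases[i]
        cells = np.array([a, b, d, c0], dtype=float)
        if (cells == 0).any():
            if not continuity_correction:
                raise ValueError(
                    f"zero cell in the 2x2 sub-table for cluster {cl!r}; "
                    "enable continuity_correction to add 0.5 to all cells"
                )
            cells = cells + 0.5
        a_, b_, d_, c_ = cells
        or_ = (a_ * c_) / (b_ * d_)
        se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
        results.append(ORResult(
            model="crude", contrast=cl, reference=table.reference,
            odds_ratio=float(or_),
            ci_low=float(or_ * np.exp(-Z_95 * se)),
            ci_high=float(or_ * np.exp(Z_95 * se)),
            lr_p=lr_p,
        ))
    return results


def likelihood_ratio_p(table: ContingencyTable2xK) -> float:
    """G-test p for outcome-cluster association in the 2xK table.

    G^2 = 2 * sum O * ln(O/E) over all cells, df = K-1.  Identical to the
    deviance difference of the cluster-only logistic model versus the
    intercept-only model.
    """
    obs = np.vstack([table.cases, table.non_cases]).astype(float)
    row = obs.sum(axis=1, keepdims=True)
    colsum = obs.sum(axis=0, keepdims=True)
    expected = row * colsum / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g2 = 2.0 * terms.sum()
    df = len(table.clusters) - 1
    return float(stats.chi2.sf(g2, df))


# ---------------------------------------------------------------------------
# Adjusted logistic models
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, labels: pd.Series, reference,
            spec: ModelSpec) -> tuple[pd.DataFrame, list]:
    """Design matrix: intercept + cluster indicators + covariates."""
    clusters = sorted(pd.unique(labels))
    contrasts = [c for c in clusters if c != reference]
    X = pd.DataFrame(index=labels.index)
    X["const"] = 1.0
    for c in contrasts:
        X[f"cluster[{c}]"] = (labels == c).astype(float)
    for cov in spec.covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} missing from the data")
        ser = df[cov]
        if cov in CONTINUOUS_COVARIATES:
            X[cov] = pd.to_numeric(ser, errors="raise").astype(float)
        elif ser.dtype == bool or str(ser.dtype) == "boolean" or \
                set(pd.unique(ser.dropna())) <= {0, 1, True, False}:
            X[cov] = ser.astype(float)
        else:  # categorical: indicator set, first level as baseline
            dummies = pd.get_dummies(ser.astype(str), prefix=cov,
                                     drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in {bad}")
    return X, contrasts


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> sm.Logit:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X.to_numpy())
            res = model.fit(disp=0, maxiter=200, method="newton")
    except Exception as exc:  # singular Hessian etc.
        raise SeparationError(
            f"logistic fit failed on design {list(X.columns)}: {exc}"
        ) from exc
    bse = np.asarray(res.bse)
    if not np.isfinite(res.params).all() or not np.isfinite(bse).all() or \
            np.abs(res.params).max() > 30 or bse.max() > 100:
        idx = int(np.argmax(np.where(np.isfinite(res.params),
                                     np.abs(res.params), np.inf)))
        raise SeparationError(
            f"non-finite or diverging estimate for {X.columns[idx]!r}; "
            "likely quasi-complete separation"
        )
    return res


def fit_models(df: pd.DataFrame, labels, specs=None, reference=None,
               outcome: str = "incident_hypertension") -> list[ORResult]:
    """Adjusted logistic models: cluster ORs with Wald CIs and LR p-values.

    ``df`` holds the outcome column and covariates; ``labels`` the cluster
    assignment (array-like or :class:`~dietclust.cluster.ClusterAssignment`).
    For each model spec the cluster-effect p is the likelihood-ratio test
    against the same model with the cluster indicators removed.
    """
    from .cluster import ClusterAssignment  # cycle guard

    if isinstance(labels, ClusterAssignment):
        labels = labels.labels
    labels = pd.Series(np.asarray(labels), index=df.index)
    specs = list(specs) if specs is not None else list(MODEL_SPECS)
    y = pd.to_numeric(df[outcome], errors="raise").astype(int).to_numpy()
    if reference is None:
        table = contingency_by_cluster(y, labels.to_numpy())
        reference = table.reference

    results: list[ORResult] = []
    for spec in specs:
        X, contrasts = _design(df, labels, reference, spec)
        res_full = _fit_logit(y, X)
        null_cols = [c for c in X.columns if not c.startswith("cluster[")]
        res_null = _fit_logit(y, X[null_cols])
        lr_stat = 2.0 * (res_full.llf - res_null.llf)
        lr_p = float(stats.chi2.sf(max(lr_stat, 0.0), len(contrasts)))
        for j, cl in enumerate(contrasts):
            col = 1 + j  # const first, cluster indicators follow
            beta, se = float(res_full.params[col]), float(res_full.bse[col])
            results.append(ORResult(
                model=spec.name, contrast=cl, reference=reference,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - Z_95 * se)),
                ci_high=float(np.exp(beta + Z_95 * se)),
                lr_p=lr_p,
            ))
    return results


# ---------------------------------------------------------------------------
# Descriptive comparisons
# ---------------------------------------------------------------------------

@dataclass
class DescriptiveResult:
    variable: str
    kind: str                     # 'continuous' or 'categorical'
    p_value: float                # nan if undefined (constant variable)
    statistic: float
    normality_p: float | None = None   # Kolmogorov-Smirnov screen


def descriptive_compare(df: pd.DataFrame, labels, variable: str,
                        kind: str | None = None) -> DescriptiveResult:
    """Cross-cluster test for one variable.

    One-way ANOVA for continuous variables, Pearson chi-square for
    categorical ones.  Continuous variables also carry a
    Kolmogorov-Smirnov normality screen (pooled values standardized by
    the sample moments, tested against the standard normal) as a side
    diagnostic.  A constant variable yields an undefined (NaN) p-value.
    """
    labels = pd.Series(np.asarray(labels), index=df.index)
    ser = df[variable]
    if kind is None:
        kind = ("continuous"
                if pd.api.types.is_numeric_dtype(ser) and ser.nunique() > 5
                else "categorical")
    clusters = sorted(pd.unique(labels))
    if kind == "continuous":
        x = pd.to_numeric(ser, errors="raise")
        groups = [x[labels == c].dropna().to_numpy() for c in clusters]
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            return DescriptiveResult(variable, kind, np.nan, np.nan)
        stat, p = stats.f_oneway(*groups)
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        ks = stats.kstest((pooled - mu) / sd, "norm")
        return DescriptiveResult(variable, kind, float(p), float(stat),
                                 normality_p=float(ks.pvalue))
    ct = pd.crosstab(ser, labels)
    if ct.shape[0] < 2:
        return DescriptiveResult(variable, kind, np.nan, np.nan)
    stat, p, _, _ = stats.chi2_contingency(ct.to_numpy())
    return DescriptiveResult(variable, kind, float(p), float(stat))
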