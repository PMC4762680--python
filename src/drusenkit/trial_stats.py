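"""The two-arm trial statistical battery over subject tables.

The analyses mirror a classical randomized-trial report on drusen
remodeling: baseline arm comparisons (pooled-variance Student t on
log-transformed drusen characteristics, Pearson chi-square for categorical
covariates), within-arm paired t-tests between baseline and final visits,
linear regression of each remodeling outcome on arm adjusted for age and
gender, and covariate screens (Pearson correlation with age, t-tests for
gender and smoking, one-way ANOVA across genotypes). Twelve planned
comparisons (3 characteristics × 4 fields) motivate a Bonferroni
significance threshold of 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "StatConfig",
    "StatResult",
    "log_transform",
    "two_sample_t_summary",
    "two_sample_t",
    "chi_square_test",
    "paired_t",
    "adjusted_regression",
    "pearson_corr",
    "oneway_anova",
    "run_trial_analysis",
]

METRICS = ("number", "diameter", "area")
FIELDS = ("inner", "middle", "outer", "all")


@dataclass(frozen=True)
class StatConfig:
    """Constants of the statistical battery.

    ``log_c`` is the constant of the variance-stabilizing ``log(Y+c)``
    transform applied to drusen characteristics (c=1 keeps zero-drusen
    cells finite). ``bonferroni_threshold`` is the significance level after
    correcting for ``n_comparisons`` planned tests; the exact
    ``alpha / n_comparisons`` value is also reported.
    """

    log_c: float = 1.0
    bonferroni_threshold: float = 0.005
    n_comparisons: int = 12
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.log_c <= 0:
            raise ValueError("log constant c must be positive")
        if not 0 < self.bonferroni_threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def exact_bonferroni(self) -> float:
        return self.alpha / self.n_comparisons


@dataclass(frozen=True)
class StatResult:
    """One test's outcome: statistic, df, p, estimate and 95% CI."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    significant: bool | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if None not in (self.ci_low, self.ci_high, self.estimate):
            if not self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12:
                raise ValueError("estimate must lie inside its CI")

    def flagged(self, threshold: float) -> "StatResult":
        return StatResult(
            self.statistic, self.df, self.p, self.estimate, self.ci_low,
            self.ci_high, bool(self.p < threshold), self.method,
        )


def log_transform(values, c: float = 1.0) -> np.ndarray:
    """Elementwise ``ln(Y + c)`` for non-negative drusen characteristics."""
    v = np.asarray(values, dtype=float)
    if c <= 0:
        raise ValueError("c must be positive")
    if np.any(v < 0):
        raise ValueError("drusen characteristics must be non-negative")
    return np.log(v + c)


def two_sample_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> StatResult:
    """Pooled-variance Student t-test from group summaries.

    The classical equal-variance form: df = n1 + n2 − 2, two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    diff = mean1 - mean2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if diff == 0:
            return StatResult(0.0, df, 1.0, 0.0, 0.0, 0.0, method="pooled t")
        raise ValueError("zero variance in both groups with unequal means")
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return StatResult(
        float(t), df, float(p), float(diff),
        float(diff - tcrit * se), float(diff + tcrit * se), method="pooled t",
    )


def two_sample_t(values1, values2) -> StatResult:
    """Pooled-variance Student t-test on two raw samples."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("each group needs n >= 2")
    return two_sample_t_summary(
        float(v1.mean()), float(v1.std(ddof=1)), len(v1),
        float(v2.mean()), float(v2.std(ddof=1)), len(v2),
    )


def chi_square_test(table) -> StatResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    x2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return StatResult(float(x2), int(df), float(p), method="Pearson chi-square")


def paired_t(baseline, final, c: float = 1.0) -> StatResult:
    """Paired t-test on log-transformed baseline/final pairs.

    One-sample t on the differences ``log(final+c) − log(baseline+c)``,
    df = n − 1.
    """
    b = log_transform(baseline, c)
    f = log_transform(final, c)
    if b.shape != f.shape:
        raise ValueError("baseline and final must have equal length")
    n = len(b)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = f - b
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd <= 1e-12 * max(1.0, abs(mean)):  # constant differences up to rounding
        if abs(mean) <= 1e-12:
            return StatResult(0.0, df, 1.0, 0.0, 0.0, 0.0, method="paired t (log scale)")
        raise ValueError("zero-variance nonzero-mean differences: t undefined")
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return StatResult(
        float(t), df, float(p), float(mean),
        float(mean - tcrit * se), float(mean + tcrit * se),
        method="paired t (log scale)",
    )


def adjusted_regression(outcome, arm, age, gender) -> StatResult:
    """OLS of a remodeling outcome on arm, adjusted for age and gender.

    ``arm`` and ``gender`` may be 0/1 indicators or the string labels used
    in cohort tables ('treated'/'placebo', 'female'/'male'); reference
    levels are placebo and male. Returns the arm coefficient — the adjusted
    between-group difference — with its t-based 95% CI and p-value.
    """
    y = np.asarray(outcome, dtype=float)
    arm_i = _indicator(arm, "treated")
    gender_i = _indicator(gender, "female")
    age = np.asarray(age, dtype=float)
    n = len(y)
    if n <= 4:
        raise ValueError("need n > 4 observations")
    x = np.column_stack([arm_i, age, gender_i])
    x = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = np.array(["intercept", "arm", "age", "gender"])
        sds = x.std(axis=0)
        degenerate = names[1:][sds[1:] == 0]
        raise ValueError(
            "design matrix is rank deficient; collinear/constant columns: "
            + (", ".join(degenerate) if len(degenerate) else "see design")
        )
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int()
    return StatResult(
        float(fit.tvalues[1]), float(fit.df_resid), float(fit.pvalues[1]),
        float(fit.params[1]), float(ci[1, 0]), float(ci[1, 1]),
        method="OLS adjusted for age and gender",
    )


def _indicator(values, positive_label: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "ifb":
        return arr.astype(float)
    return (arr == positive_label).astype(float)


def pearson_corr(x, y) -> StatResult:
    """Pearson product-moment correlation with a t-based two-sided p.

    ``t = r·sqrt((n−2)/(1−r²))`` on n−2 df; the 95% CI uses the Fisher z
    transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    n = len(x)
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zse = 1 / np.sqrt(n - 3) if n > 3 else np.inf
    zcrit = stats.norm.ppf(0.975)
    if abs(r) < 1:
        t = r * np.sqrt((n - 2) / (1 - r * r))
    else:
        t = np.inf * np.sign(r)
    return StatResult(
        float(t), n - 2, float(p), float(r),
        float(np.tanh(z - zcrit * zse)), float(np.tanh(z + zcrit * zse)),
        method="Pearson correlation",
    )


def oneway_anova(values, groups) -> StatResult:
    """One-way ANOVA across group labels (e.g. 3 genotype levels).

    F = MS_between / MS_within on (k−1, n−k) df, upper-tail p.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    n = len(values)
    k = len(samples)
    if n <= k:
        raise ValueError("need more observations than groups")
    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return StatResult(0.0, (dfb, dfw), 1.0, method="one-way ANOVA")
        raise ValueError("zero within-group variance with unequal means")
    f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    return StatResult(float(f), (dfb, dfw), float(p), method="one-way ANOVA")


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def _cell_cols(prefix: str) -> list[tuple[str, str, str]]:
    return [(m, s, f"{prefix}_{m}_{s}") for m in METRICS for s in FIELDS]


def _summaries(v: np.ndarray) -> dict[str, float]:
    return {
        "median": float(np.median(v)),
        "p5": float(np.percentile(v, 5)),
        "p95": float(np.percentile(v, 95)),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
    }


def run_trial_analysis(cohort: pd.DataFrame, config: StatConfig | None = None) -> dict:
    """Run the full battery and emit the four report tables.

    Returns a dict with DataFrames ``baseline`` (arm comparisons at
    baseline), ``paired`` (within-arm baseline-vs-final paired t),
    ``adjusted`` (arm effect on each remodeling cell, age/gender adjusted,
    flagged at the Bonferroni threshold; None for single-arm cohorts) and
    ``covariates`` (age correlation, gender/smoking t, genotype ANOVA per
    cell), plus an ``errors`` list of analyses that could not run.

    Missing genotypes (NaN) are dropped per-analysis.
    """
    if cohort is None or len(cohort) == 0:
        raise ValueError("cohort is empty")
    config = config or StatConfig()
    errors: list[str] = []
    arms = [a for a in ("treated", "placebo") if (cohort["arm"] == a).any()]
    two_arms = len(arms) == 2

    # Table-1 analogue: baseline comparisons between arms
    baseline_rows = []
    if two_arms:
        g1 = cohort[cohort["arm"] == arms[0]]
        g2 = cohort[cohort["arm"] == arms[1]]
        try:
            res = two_sample_t(g1["age"], g2["age"])
            baseline_rows.append(
                {"characteristic": "age", "metric": "", "field": "", "test": res.method,
                 "statistic": res.statistic, "p": res.p}
            )
        except ValueError as exc:
            errors.append(f"baseline age: {exc}")
        for cov in ("gender", "smoking", "cfh", "arms2"):
            sub = cohort.dropna(subset=[cov])
            tab = pd.crosstab(sub["arm"], sub[cov])
            try:
                res = chi_square_test(tab.values)
                baseline_rows.append(
                    {"characteristic": cov, "metric": "", "field": "", "test": res.method,
                     "statistic": res.statistic, "p": res.p}
                )
            except ValueError as exc:
                errors.append(f"baseline {cov}: {exc}")
        for m, s, col in _cell_cols("baseline"):
            try:
                res = two_sample_t(
                    log_transform(g1[col], config.log_c),
                    log_transform(g2[col], config.log_c),
                )
                baseline_rows.append(
                    {"characteristic": "drusen", "metric": m, "field": s,
                     "test": "pooled t (log scale)", "statistic": res.statistic, "p": res.p}
                )
            except ValueError as exc:
                errors.append(f"baseline {col}: {exc}")
    else:
        errors.append("baseline comparisons skipped: single-arm cohort")
    baseline_tbl = pd.DataFrame(baseline_rows)

    # Table-2 analogue: paired baseline-vs-final per arm
    paired_rows = []
    for arm in arms:
        g = cohort[cohort["arm"] == arm]
        for m, s, col in _cell_cols("baseline"):
            fcol = f"final_{m}_{s}"
            try:
                base_v = np.clip(np.asarray(g[col], dtype=float), 0, None)
                fin_v = np.clip(np.asarray(g[fcol], dtype=float), 0, None)
                res = paired_t(base_v, fin_v, config.log_c)
                paired_rows.append(
                    {"arm": arm, "metric": m, "field": s, "n": len(g),
                     "baseline_median": float(np.median(base_v)),
                     "final_median": float(np.median(fin_v)),
                     "statistic": res.statistic, "p": res.p}
                )
            except ValueError as exc:
                errors.append(f"paired {arm} {col}: {exc}")
    paired_tbl = pd.DataFrame(paired_rows)

    # Table-3 analogue: adjusted arm differences on remodeling
    adjusted_tbl = None
    if two_arms:
        adj_rows = []
        for m, s, col in _cell_cols("delta"):
            try:
                res = adjusted_regression(
                    cohort[col], cohort["arm"], cohort["age"], cohort["gender"]
                ).flagged(config.bonferroni_threshold)
                d1 = cohort.loc[cohort["arm"] == "treated", col]
                d0 = cohort.loc[cohort["arm"] == "placebo", col]
                adj_rows.append(
                    {"metric": m, "field": s,
                     "treated_mean": float(d1.mean()), "treated_sd": float(d1.std(ddof=1)),
                     "placebo_mean": float(d0.mean()), "placebo_sd": float(d0.std(ddof=1)),
                     "difference": res.estimate, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p": res.p,
                     "significant": res.significant,
                     "significant_exact_bonferroni": bool(res.p < config.exact_bonferroni)}
                )
            except ValueError as exc:
                errors.append(f"adjusted {col}: {exc}")
        adjusted_tbl = pd.DataFrame(adj_rows)
    else:
        errors.append("adjusted arm comparisons skipped: single-arm cohort (no arm contrast)")

    # Table-4 analogue: covariate screens on remodeling
    cov_rows = []
    for m, s, col in _cell_cols("delta"):
        delta = np.asarray(cohort[col], dtype=float)
        row = {"metric": m, "field": s}
        try:
            res = pearson_corr(cohort["age"], delta)
            row.update(age_r=res.estimate, age_p=res.p)
        except ValueError as exc:
            errors.append(f"covariate age {col}: {exc}")
        for cov, pos in (("gender", "female"), ("smoking", "ever")):
            try:
                a = delta[cohort[cov] == pos]
                b = delta[cohort[cov] != pos]
                res = two_sample_t(a, b)
                row[f"{cov}_p"] = res.p
            except ValueError as exc:
                errors.append(f"covariate {cov} {col}: {exc}")
        for cov in ("cfh", "arms2"):
            try:
                ok = cohort[cov].notna()
                res = oneway_anova(delta[ok.values], cohort.loc[ok, cov])
                row[f"{cov}_p"] = res.p
            except ValueError as exc:
                errors.append(f"covariate {cov} {col}: {exc}")
        cov_rows.append(row)
    covariates_tbl = pd.DataFrame(cov_rows)

    return {
        "baseline": baseline_tbl,
        "paired": paired_tbl,
        "adjusted": adjusted_tbl,
        "covariates": covariates_tbl,
        "errors": errors,
        "config": config,
    }
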