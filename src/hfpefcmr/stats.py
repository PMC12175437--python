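"""Cohort statistics: group comparisons, discrimination and reliability.

Implements the analysis chain applied to the subject-level cohort table:
visit averaging, one-way ANOVA with Tukey-Kramer post-hoc pairs, Pearson
chi-squared for categorical rows, Pearson correlation (with optional
natural-log transform for skewed biomarkers), univariable and
age/sex/BMI-adjusted logistic regression for HFpEF membership with Wald
confidence intervals, empirical ROC curves with DeLong AUC confidence
intervals and Youden-optimal operating points, two-way random-effects
absolute-agreement ICC(2,1) reliability with Cicchetti interpretation
bands, and a sensitivity re-analysis excluding subjects with a history of
atrial arrhythmia.

Standard procedures are delegated to scipy / statsmodels / pingouin; the
ROC machinery (DeLong variance, Youden tie-breaking) is implemented here.
All tests are two-sided at the 0.05 level by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "GroupComparison",
    "LogisticResult",
    "ROCResult",
    "ICCResult",
    "SensitivityResult",
    "average_across_visits",
    "one_way_anova",
    "tukey_hsd",
    "chi_squared",
    "pearson_corr",
    "fit_logistic",
    "roc_analysis",
    "icc2",
    "cicchetti_band",
    "sensitivity_excluding_arrhythmia",
    "cohort_summary",
    "compare_groups",
    "pooled_mean",
]

_Z975 = sps.norm.ppf(0.975)


class AnovaResult(NamedTuple):
    f: float
    p: float


@dataclass
class GroupComparison:
    """ANOVA plus Tukey post-hoc summary for one variable."""

    variable: str
    group_names: list[str]
    means: list[float]
    sds: list[float]
    ns: list[int]
    f: float
    anova_p: float
    tukey_p: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class LogisticResult:
    """One predictor's logistic-regression odds ratio for HFpEF."""

    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    adjusted: bool
    covariates: list[str]
    coef: float
    se: float
    n: int
    separated: bool = False
    converged: bool = True


@dataclass
class ROCResult:
    """Empirical ROC with the Youden-optimal operating point."""

    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


@dataclass
class ICCResult:
    """Two-way random absolute-agreement single-measure ICC(2,1)."""

    icc2: float
    ci95: tuple[float, float]
    cicchetti_band: str


@dataclass
class SensitivityResult:
    """Re-analysis on the arrhythmia-free subset."""

    n_excluded: int
    n_remaining: int
    result: object


# ---------------------------------------------------------------- averaging


def average_across_visits(
    table: pd.DataFrame,
    subject_col: str = "subject_id",
    visit_col: str = "visit_day",
) -> pd.DataFrame:
    """Collapse a subject-visit table to one record per subject.

    Numeric variables are averaged over the available visits (a single
    visit passes through unchanged, a missing visit value is skipped so
    the remaining one carries); non-numeric columns take their first
    value, which is constant per subject by construction.
    """
    if visit_col not in table.columns:
        return table.copy()
    value_cols = [c for c in table.columns if c not in (subject_col, visit_col)]
    numeric = [c for c in value_cols if pd.api.types.is_numeric_dtype(table[c])]
    other = [c for c in value_cols if c not in numeric]
    agg = {c: "mean" for c in numeric} | {c: "first" for c in other}
    out = table.groupby(subject_col, sort=True).agg(agg).reset_index()
    return out[[subject_col] + value_cols]


# ------------------------------------------------------------- comparisons


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least two observations")
    return arrs


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Classical one-way ANOVA F test.

    Between/within mean squares on (k-1, N-k) degrees of freedom. The
    degenerate zero-within-variance case is resolved explicitly: unequal
    means give p = 0, all-equal means give F = 0, p = 1.
    """
    arrs = _check_groups(groups)
    grand = np.concatenate(arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    ssb = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrs)
    if ssw == 0.0:
        return AnovaResult(f=np.inf, p=0.0) if ssb > 0 else AnovaResult(f=0.0, p=1.0)
    f, p = sps.f_oneway(*arrs)
    return AnovaResult(f=float(f), p=float(p))


def tukey_hsd(
    groups: Sequence[np.ndarray], names: Sequence[str] | None = None
) -> dict[tuple[str, str], float]:
    """Tukey-Kramer pairwise adjusted p-values.

    Studentized-range test on all group pairs; unequal sizes use the
    Tukey-Kramer standard error sqrt(MSW/2 * (1/n_i + 1/n_j)).
    """
    arrs = _check_groups(groups)
    if names is None:
        names = [f"group{i}" for i in range(len(arrs))]
    res = sps.tukey_hsd(*arrs)
    out: dict[tuple[str, str], float] = {}
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            out[(names[i], names[j])] = float(res.pvalue[i, j])
    return out


def chi_squared(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared test on a category-by-group count table.

    No continuity correction (the convention for tables larger than 2x2);
    zero-margin rows/columns and zero expected counts are rejected.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero-margin row or column: test undefined")
    res = sps.chi2_contingency(tab, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValueError("zero expected count: test undefined")
    return float(res.statistic), float(res.pvalue)


def pearson_corr(
    x: np.ndarray,
    y: np.ndarray,
    log_x: bool = False,
    log_y: bool = False,
) -> tuple[float, float]:
    """Pearson product-moment correlation with optional natural-log
    transforms for right-skewed variables; two-sided p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive x")
        x = np.log(x)
    if log_y:
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive y")
        y = np.log(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------- logistic


def fit_logistic(
    outcome: np.ndarray,
    predictor: np.ndarray,
    covariates: pd.DataFrame | None = None,
    log_predictor: bool = False,
    predictor_name: str = "predictor",
) -> LogisticResult:
    """Maximum-likelihood logistic regression of a binary outcome on one
    predictor, optionally adjusted for covariates.

    Reports the per-unit odds ratio exp(beta) with a Wald 95% CI and
    two-sided p-value. Complete or quasi-complete separation is detected
    (non-finite or explosive coefficient / standard error) and flagged
    with a warning instead of silently reporting an inflated OR.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must include both classes")
    x = np.asarray(predictor, dtype=float)
    if log_predictor:
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive predictor")
        x = np.log(x)
    X = pd.DataFrame({predictor_name: x})
    cov_names: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
            cov_names.append(c)
    X = sm.add_constant(X, prepend=True)
    separated = False
    failed = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # singular Hessians at the MLE are the numerical face of
            # (quasi-)complete separation at these sample sizes
            failed = True
    if failed:
        warnings.warn(
            f"complete separation for {predictor_name}: odds ratio not "
            "estimable",
            stacklevel=2,
        )
        return LogisticResult(
            predictor=predictor_name, odds_ratio=np.nan, ci_low=np.nan,
            ci_high=np.nan, p=np.nan, adjusted=bool(cov_names),
            covariates=cov_names, coef=np.nan, se=np.nan, n=y.size,
            separated=True, converged=False,
        )
    if any("separation" in str(w.message).lower() for w in caught):
        separated = True
    # perfect prediction without a numerical failure is separation too
    if np.max(np.abs(y - np.asarray(fit.predict(X)))) < 1e-4:
        separated = True
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit for {predictor_name} did not converge")
    beta = float(fit.params[predictor_name])
    se = float(fit.bse[predictor_name])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 50 or se > 500:
        separated = True
    if separated:
        warnings.warn(
            f"quasi-complete separation suspected for {predictor_name} "
            f"(coef {beta:.3g}, SE {se:.3g}); estimates unreliable",
            stacklevel=2,
        )
    return LogisticResult(
        predictor=predictor_name,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        p=float(fit.pvalues[predictor_name]),
        adjusted=bool(cov_names),
        covariates=cov_names,
        coef=beta,
        se=se,
        n=int(y.size),
        separated=separated,
        converged=True,
    )


# --------------------------------------------------------------------- ROC


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong variance-based 95% CI for an empirical AUC."""
    # placement values: fraction of the other class each score beats
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    m, n = pos.size, neg.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    return (
        float(np.clip(auc - _Z975 * se, 0.0, 1.0)),
        float(np.clip(auc + _Z975 * se, 0.0, 1.0)),
    )


def roc_analysis(values: np.ndarray, outcome: np.ndarray) -> ROCResult:
    """Empirical ROC analysis of one continuous marker.

    Higher values are taken to indicate the positive class; negate a
    marker with the opposite polarity before calling. The AUC is the
    Mann-Whitney concordance probability (equivalently the trapezoidal
    area under the empirical curve) with a DeLong 95% CI. The operating
    threshold maximizes Youden's J = sensitivity + specificity - 1 over
    midpoints between adjacent observed values; ties break toward higher
    specificity. A subject is called positive when its value is at or
    above the threshold.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size != y.size:
        raise ValueError("values and outcome must have equal length")
    if set(np.unique(y)) - {0.0, 1.0} or y.min() == y.max():
        raise ValueError("outcome must be binary with both classes present")
    pos, neg = x[y == 1], x[y == 0]
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    ci = _delong_ci(pos, neg, auc)
    uniq = np.unique(x)
    if uniq.size == 1:
        warnings.warn("constant marker: ROC degenerate, AUC 0.5", stacklevel=2)
        thresholds = np.array([uniq[0]])
    else:
        mid = 0.5 * (uniq[:-1] + uniq[1:])
        thresholds = np.concatenate(([uniq[0] - 1.0], mid, [uniq[-1] + 1.0]))
    best = None
    for c in thresholds:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, thr, sens, spec = best
    pred = x >= thr
    tp = float(np.sum(pred & (y == 1)))
    fp = float(np.sum(pred & (y == 0)))
    tn = float(np.sum(~pred & (y == 0)))
    fn = float(np.sum(~pred & (y == 1)))
    ppv = tp / (tp + fp) if tp + fp > 0 else np.nan
    npv = tn / (tn + fn) if tn + fn > 0 else np.nan
    return ROCResult(
        auc=auc,
        auc_ci=ci,
        threshold=float(thr),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=(tp + tn) / x.size,
    )


# --------------------------------------------------------------------- ICC


def cicchetti_band(icc: float) -> str:
    """Cicchetti interpretation: <0.40 poor, 0.40-0.59 fair,
    0.60-0.74 good, >=0.75 excellent."""
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def icc2(day1: np.ndarray, day8: np.ndarray) -> ICCResult:
    """Test-retest reliability as ICC(2,1): two-way random effects,
    absolute agreement, single measurement, with the standard F-based
    95% CI. A systematic day effect counts against agreement, unlike the
    consistency form ICC(3,1)."""
    import pingouin as pg

    a = np.asarray(day1, dtype=float)
    b = np.asarray(day8, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need complete pairs with n >= 3")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero total variance: ICC undefined")
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(a.size), 2),
            "visit": np.repeat(["day1", "day8"], a.size),
            "value": np.concatenate([a, b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = pg.intraclass_corr(
            data=long, targets="subject", raters="visit", ratings="value"
        ).set_index("Type")
    # absolute-agreement single-measure row; label varies across versions
    label = "ICC(A,1)" if "ICC(A,1)" in tab.index else "ICC2"
    row = tab.loc[label]
    ci_col = "CI95" if "CI95" in tab.columns else "CI95%"
    icc = float(row["ICC"])
    lo, hi = (float(v) for v in row[ci_col])
    if not np.isfinite(lo) or not np.isfinite(hi):
        lo, hi = icc, icc  # degenerate (e.g. exact agreement)
    return ICCResult(icc2=icc, ci95=(lo, hi), cicchetti_band=cicchetti_band(icc))


# -------------------------------------------------------------- sensitivity


def sensitivity_excluding_arrhythmia(
    table: pd.DataFrame,
    analysis: Callable[[pd.DataFrame], object],
    flag_col: str = "arrhythmia_history",
    group_col: str = "group",
) -> SensitivityResult:
    """Rerun an analysis on the subset without atrial-arrhythmia history.

    Fails loudly, naming the group, if the exclusion empties any cohort
    group (the subset analyses would silently change structure otherwise).
    """
    if flag_col not in table.columns:
        raise ValueError(f"missing arrhythmia flag column {flag_col!r}")
    flagged = table[flag_col].astype(bool)
    subset = table.loc[~flagged]
    for g in table[group_col].unique():
        if (subset[group_col] == g).sum() == 0:
            raise ValueError(f"sensitivity exclusion removed the entire group {g!r}")
    n_subjects = table["subject_id"].nunique() if "subject_id" in table else len(table)
    n_kept = subset["subject_id"].nunique() if "subject_id" in subset else len(subset)
    return SensitivityResult(
        n_excluded=int(n_subjects - n_kept),
        n_remaining=int(n_kept),
        result=analysis(subset),
    )


# ------------------------------------------------------------------ summary


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Size-weighted overall mean from per-group means."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    return float((means * ns).sum() / ns.sum())


def compare_groups(
    values_by_group: dict[str, np.ndarray], variable: str = ""
) -> GroupComparison:
    """ANOVA plus Tukey pairs for one variable, keyed by group name."""
    names = list(values_by_group)
    arrs = [np.asarray(values_by_group[g], dtype=float) for g in names]
    f, p = one_way_anova(arrs)
    tk = tukey_hsd(arrs, names) if np.isfinite(f) else {}
    return GroupComparison(
        variable=variable,
        group_names=names,
        means=[float(a.mean()) for a in arrs],
        sds=[float(a.std(ddof=1)) for a in arrs],
        ns=[int(a.size) for a in arrs],
        f=f,
        anova_p=p,
        tukey_p=tk,
    )


def cohort_summary(
    table: pd.DataFrame,
    continuous: Sequence[str],
    categorical: Sequence[str] = (),
    group_col: str = "group",
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group summary table with hypothesis tests per row.

    Continuous rows report mean and SD per group plus the one-way ANOVA
    p-value; categorical (0/1) rows report count and percent per group
    plus the Pearson chi-squared p-value. The ``overall`` columns pool all
    groups, so the overall mean equals the size-weighted mean of the
    group means.
    """
    groups = list(group_order) if group_order else sorted(table[group_col].unique())
    rows = []
    for var in continuous:
        sub = table.dropna(subset=[var])
        by = [sub.loc[sub[group_col] == g, var].to_numpy(dtype=float) for g in groups]
        f, p = one_way_anova(by)
        row = {"variable": var, "kind": "continuous", "n": int(sub.shape[0]),
               "overall_mean": float(sub[var].mean()), "overall_sd": float(sub[var].std(ddof=1)),
               "p_value": p}
        for g, a in zip(groups, by):
            row[f"{g}_mean"] = float(a.mean())
            row[f"{g}_sd"] = float(a.std(ddof=1))
            row[f"{g}_n"] = int(a.size)
        rows.append(row)
    for var in categorical:
        sub = table.dropna(subset=[var])
        counts = np.array(
            [
                [
                    int((sub.loc[sub[group_col] == g, var] == 1).sum()),
                    int((sub.loc[sub[group_col] == g, var] != 1).sum()),
                ]
                for g in groups
            ]
        ).T
        try:
            _, p = chi_squared(counts)
        except ValueError:
            p = np.nan
        row = {"variable": var, "kind": "categorical", "n": int(sub.shape[0]),
               "overall_count": int(counts[0].sum()),
               "overall_pct": 100.0 * counts[0].sum() / counts.sum(),
               "p_value": p}
        for i, g in enumerate(groups):
            n_g = counts[:, i].sum()
            row[f"{g}_count"] = int(counts[0, i])
            row[f"{g}_pct"] = 100.0 * counts[0, i] / n_g if n_g else np.nan
            row[f"{g}_n"] = int(n_g)
        rows.append(row)
    return pd.DataFrame(rows)
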