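"""Cohort-level statistics: summaries, group tests, survival, logistic model.

Conventions follow common clinical-reporting practice: medians with
interquartile ranges (type-7 linear-interpolation quantiles), Fisher's exact
test for categorical contrasts, Mann-Whitney U for continuous ones,
Kaplan-Meier product-limit curves with Greenwood variance and log-log 95%
confidence intervals, and a maximum-likelihood logistic model with Wald
intervals and listwise deletion of records with missing covariates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lesionkinetics.volumetry import ValidationError

__all__ = [
    "MLNM_LEVELS",
    "KMCurve",
    "LogisticFit",
    "median_iqr",
    "mann_whitney",
    "fisher_exact_2x2",
    "km_fit",
    "logistic_progression",
    "location_distribution",
    "symptom_onset_rate",
]

#: Mesenteric-metastasis location categories relative to the superior
#: mesenteric artery (Deguelte levels).
MLNM_LEVELS = ("I", "II", "III_down", "III_up", "IV")

_Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# descriptive statistics and group tests


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and interquartile bounds (median, Q1, Q3).

    Missing values (NaN/None) are dropped first; quantiles use linear
    interpolation between order statistics (numpy's default, type 7).
    """
    arr = np.asarray(pd.Series(list(values), dtype=float).dropna(), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValidationError("median_iqr requires at least one finite value")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U statistic (for group A) and two-sided p-value.

    Uses the exact null distribution when both groups have at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("mann_whitney requires both groups non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Sums hypergeometric probabilities of tables at most as probable as the
    observed one (the standard two-sided convention).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValidationError("fisher_exact_2x2 requires integer counts")
        if np.any(arr < 0):
            raise ValidationError("fisher_exact_2x2 requires non-negative counts")
        arr = arr.astype(int)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival step function with Greenwood 95% bands.

    Arrays are aligned on the distinct event times (censoring-only times do
    not create steps but do reduce the risk set). The curve is
    right-continuous; ``survival_at(t)`` evaluates it at any t >= 0.
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): survival probability just after time t."""
        if t < 0:
            raise ValidationError(f"time must be non-negative, got {t!r}")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.event_times,
                "n_at_risk": self.n_at_risk,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def km_fit(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier estimate from right-censored time-to-event data.

    Parameters
    ----------
    times
        Follow-up times in months, non-negative.
    events
        True where the endpoint occurred, False where censored.

    Returns
    -------
    KMCurve
        Steps at distinct event times; Greenwood variance on the survival
        scale and 95% confidence bands via the log(-log) transform.
    """
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=bool)
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValidationError("times must be finite and non-negative")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])

    n = t.size
    surv = []
    var_sum = 0.0  # running sum of d / (n (n - d))
    n_at_risk = []
    greenwood = []
    ci_low = []
    ci_high = []
    s = 1.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            var_sum += d / (at_risk * (at_risk - d))
        else:
            var_sum = math.inf
        gv = s * s * var_sum if math.isfinite(var_sum) else (0.0 if s == 0.0 else math.inf)
        lo, hi = _loglog_ci(s, var_sum)
        n_at_risk.append(at_risk)
        surv.append(s)
        greenwood.append(gv)
        ci_low.append(lo)
        ci_high.append(hi)

    return KMCurve(
        event_times=event_times,
        n_at_risk=np.asarray(n_at_risk, dtype=int),
        survival=np.asarray(surv, dtype=float),
        greenwood_var=np.asarray(greenwood, dtype=float),
        ci_low=np.asarray(ci_low, dtype=float),
        ci_high=np.asarray(ci_high, dtype=float),
    )


def _loglog_ci(s: float, var_sum: float) -> tuple[float, float]:
    # CI on the log(-log S) scale: S^exp(+/- z * se), se = sqrt(var_sum)/|ln S|
    if s <= 0.0:
        return 0.0, 0.0
    if s >= 1.0 or not math.isfinite(var_sum):
        return (s, s) if s >= 1.0 else (0.0, 1.0)
    se = math.sqrt(var_sum) / abs(math.log(s))
    return s ** math.exp(_Z95 * se), s ** math.exp(-_Z95 * se)


# ---------------------------------------------------------------------------
# logistic progression model


@dataclass(frozen=True)
class LogisticFit:
    """Logistic model summary: odds ratios, Wald 95% CIs, p-values.

    ``identifiable`` flags per-term convergence; separated terms are
    reported with a degenerate odds ratio and a (0, inf) interval instead of
    raising. ``n_excluded`` maps a reason to the number of records dropped
    by listwise deletion.
    """

    terms: tuple[str, ...]
    odds_ratios: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    identifiable: dict[str, bool]
    n_used: int
    n_excluded: dict[str, int] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_excluded_total(self) -> int:
        return sum(self.n_excluded.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term in self.terms:
            rows.append(
                {
                    "term": term,
                    "odds_ratio": self.odds_ratios[term],
                    "ci_low": self.ci_low[term],
                    "ci_high": self.ci_high[term],
                    "p_value": self.p_values[term],
                    "identifiable": self.identifiable[term],
                }
            )
        return pd.DataFrame(rows)


_SEPARATION_SE = 50.0  # |coef| SE beyond this is treated as non-identifiable


def logistic_progression(
    patients: pd.DataFrame,
    growth: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "u5hiaa", "ki67", "grade"),
) -> LogisticFit:
    """Logistic model of volumetric progression on clinical covariates.

    The outcome is the ``progressed`` flag from the growth table. Covariates
    are age (years), sex (female vs male reference), urinary 5-HIAA, Ki-67
    index, and grade (categorical, grade 1 reference). Records with any
    missing covariate or no growth estimate are removed first (listwise
    deletion) and counted in ``n_excluded``.

    Complete or quasi-complete separation is detected per term (exploding
    Wald standard error) and reported as non-identifiable rather than
    raising.
    """
    df = patients.merge(
        growth[["patient_id", "progressed"]], on="patient_id", how="left"
    )
    n_total = len(df)

    no_outcome = df["progressed"].isna()
    df = df.loc[~no_outcome].copy()

    design = pd.DataFrame(index=df.index)
    design["const"] = 1.0
    if "age" in covariates:
        design["age"] = pd.to_numeric(df["age"], errors="coerce")
    if "sex" in covariates:
        sex = df["sex"].astype("string").str.lower()
        design["sex_female"] = sex.map({"female": 1.0, "male": 0.0})
    if "u5hiaa" in covariates:
        design["u5hiaa"] = pd.to_numeric(df["u5hiaa"], errors="coerce")
    if "ki67" in covariates:
        design["ki67"] = pd.to_numeric(df["ki67"], errors="coerce")
    if "grade" in covariates:
        grade = pd.to_numeric(df["grade"], errors="coerce")
        design["grade_2"] = np.where(grade.isna(), np.nan, (grade == 2).astype(float))
        design["grade_3"] = np.where(grade.isna(), np.nan, (grade == 3).astype(float))

    complete = design.notna().all(axis=1)
    n_missing = int((~complete).sum())
    design = design.loc[complete]
    y = df.loc[complete, "progressed"].astype(float)

    n_excluded = {}
    if int(no_outcome.sum()):
        n_excluded["no growth estimate"] = int(no_outcome.sum())
    if n_missing:
        n_excluded["missing covariate"] = n_missing
    assert len(design) + sum(n_excluded.values()) == n_total

    # drop constant dummy columns (e.g. no grade-3 patients) as structurally
    # non-identifiable rather than letting the optimizer chase them
    terms = tuple(c for c in design.columns if c != "const")
    absent = {c for c in terms if design[c].nunique() <= 1}
    fit_cols = ["const"] + [c for c in terms if c not in absent]

    result = _fit_logit(y, design[fit_cols])

    odds_ratios: dict[str, float] = {}
    ci_low: dict[str, float] = {}
    ci_high: dict[str, float] = {}
    p_values: dict[str, float] = {}
    identifiable: dict[str, bool] = {}
    all_terms = ("const",) + terms
    for term in all_terms:
        if result is None or term in absent or term not in fit_cols:
            # outcome constant, column absent, or fit failed outright
            direction = 0.0
            if result is None and len(y) and term == "const":
                direction = math.inf if y.mean() > 0.5 else 0.0
            odds_ratios[term] = direction
            ci_low[term] = 0.0
            ci_high[term] = math.inf
            p_values[term] = math.nan
            identifiable[term] = False
            continue
        coef = float(result.params[term])
        se = float(result.bse[term])
        if not math.isfinite(se) or se > _SEPARATION_SE:
            odds_ratios[term] = 0.0 if coef < 0 else math.inf
            ci_low[term] = 0.0
            ci_high[term] = math.inf
            p_values[term] = float(result.pvalues[term])
            identifiable[term] = False
        else:
            odds_ratios[term] = math.exp(coef)
            ci_low[term] = math.exp(coef - _Z95 * se)
            ci_high[term] = math.exp(coef + _Z95 * se)
            p_values[term] = float(result.pvalues[term])
            identifiable[term] = True

    return LogisticFit(
        terms=all_terms,
        odds_ratios=odds_ratios,
        ci_low=ci_low,
        ci_high=ci_high,
        p_values=p_values,
        identifiable=identifiable,
        n_used=int(len(design)),
        n_excluded=n_excluded,
        converged=result is not None,
    )


def _fit_logit(y: pd.Series, X: pd.DataFrame):
    import statsmodels.api as sm

    if y.nunique() < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(np.asarray(y), X.astype(float))
            return model.fit(disp=0, method="bfgs", maxiter=500)
        except Exception:
            return None


# ---------------------------------------------------------------------------
# report counts


def location_distribution(patients: pd.DataFrame) -> pd.DataFrame:
    """Counts and integer percentages of MLNM location per symptom group.

    Returns one row per Deguelte level with count and percent columns for
    the asymptomatic and symptomatic-at-diagnosis groups. Percentages are
    count / group size rounded half-up to integers; an empty group reports
    blank (NA) percentages.
    """
    known = patients["mlnm_level"].dropna()
    bad = sorted(set(known) - set(MLNM_LEVELS))
    if bad:
        raise ValidationError(f"unknown mlnm_level labels: {bad}")

    rows = []
    groups = {
        "asymptomatic": patients.loc[~patients["symptomatic_at_dx"].astype(bool)],
        "symptomatic": patients.loc[patients["symptomatic_at_dx"].astype(bool)],
    }
    for level in MLNM_LEVELS:
        row: dict[str, object] = {"mlnm_level": level}
        for name, grp in groups.items():
            n = len(grp)
            count = int((grp["mlnm_level"] == level).sum())
            row[f"{name}_n"] = count
            row[f"{name}_pct"] = _round_half_up(100.0 * count / n) if n else pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


def symptom_onset_rate(patients: pd.DataFrame) -> tuple[int, int, int]:
    """(events, n, percent) of symptom-driven surgery among patients
    asymptomatic at diagnosis. Percent is rounded half-up to an integer."""
    asym = patients.loc[~patients["symptomatic_at_dx"].astype(bool)]
    n = len(asym)
    if n == 0:
        raise ValidationError("no asymptomatic patients in cohort")
    events = int(asym["symptom_surgery_event"].astype(bool).sum())
    return events, n, _round_half_up(100.0 * events / n)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))
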