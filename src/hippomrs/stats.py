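"""Group, trend, reliability and correlation statistics for the cohort.

Conventions follow the clinical-neuroimaging defaults the analysis relies
on: pooled-variance (Student) two-sample t tests with df = n1 + n2 - 2,
Pearson chi-square on 2x2 tables without continuity correction, a
linear-in-week contrast inside a one-way ANOVA for "p for trend",
covariate adjustment by an ordinary linear model, and the two-way
mixed-effects consistency ICC for test-retest reliability.  Alpha is 0.05
two-sided throughout and no multiplicity correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "UndefinedTestError",
    "CollinearityError",
    "response_classification",
    "response_group",
    "t_test_from_summary",
    "chi_square_2x2",
    "trend_anova",
    "glm_adjusted_difference",
    "icc_test_retest",
    "pearson_diff_correlation",
    "COVARIATES",
]

#: Covariates corrected for in the adjusted models.
COVARIATES = ["age", "gender", "age_onset", "duration"]


class UndefinedTestError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# treatment-response classification


def response_classification(hdrs_week0: float, hdrs_weekn: float) -> str:
    """Categorise the HDRS reduction r = (week0 - weekN) / week0.

    r < 0.25 -> "non-responder"; 0.25 <= r < 0.5 -> "partial responder";
    r >= 0.5 -> "complete responder" (boundaries inclusive upward).
    """
    if hdrs_week0 <= 0:
        raise UndefinedTestError("baseline HDRS must be positive to define a reduction")
    r = (hdrs_week0 - hdrs_weekn) / hdrs_week0
    if r >= 0.5:
        return "complete responder"
    if r >= 0.25:
        return "partial responder"
    return "non-responder"


def response_group(hdrs_week0: float, hdrs_week6: float) -> str:
    """Final RD / n-RD split: n-RD iff the week-6 reduction is >= 50 %."""
    if hdrs_week0 <= 0:
        raise UndefinedTestError("baseline HDRS must be positive to define a reduction")
    r = (hdrs_week0 - hdrs_week6) / hdrs_week0
    return "n-RD" if r >= 0.5 else "RD"


# ---------------------------------------------------------------------------
# elementary group tests


def t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample Student t from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise UndefinedTestError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise UndefinedTestError("SDs must be non-negative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if mean1 == mean2:
            return TestResult(0.0, df, 1.0, "pooled t")
        return TestResult(np.inf if mean1 > mean2 else -np.inf, df, 0.0, "pooled t")
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p), "pooled t")


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table (no continuity correction), with
    the table laid out row-wise as [[a, b], [c, d]]."""
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0) or counts.sum() == 0:
        raise UndefinedTestError("counts must be non-negative with a positive total")
    n = counts.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise UndefinedTestError("chi-square undefined: a margin is zero")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = sps.chi2.sf(chi2, 1)
    return TestResult(float(chi2), 1, float(p), "chi-square (2x2)")


# ---------------------------------------------------------------------------
# trend over treatment weeks


def trend_anova(records: pd.DataFrame, metabolite: str) -> TestResult:
    """Linear-in-week contrast within a one-way across-week ANOVA.

    ``records`` holds one group's visits (columns ``week`` and the
    metabolite); returns the contrast's t statistic and two-sided p
    ("p for trend").  Weeks need >= 2 observations each and >= 3 distinct
    weeks overall.
    """
    df = records[["week", metabolite]].dropna()
    weeks = np.sort(df["week"].unique())
    if len(weeks) < 3:
        raise UndefinedTestError("trend test needs at least 3 weeks")
    groups = [df.loc[df["week"] == w, metabolite].to_numpy(dtype=float) for w in weeks]
    ns = np.array([len(g) for g in groups])
    if np.any(ns < 2):
        raise UndefinedTestError("each week needs at least 2 observations")
    means = np.array([g.mean() for g in groups])
    n_total = int(ns.sum())
    dfe = n_total - len(weeks)
    sse = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    mse = sse / dfe
    contrast = weeks - weeks.mean()
    l_value = float(contrast @ means)
    var_l = mse * float((contrast**2 / ns).sum())
    if var_l == 0:
        p = 1.0 if l_value == 0 else 0.0
        stat = 0.0 if l_value == 0 else np.inf
        return TestResult(stat, dfe, p, "trend contrast")
    t = l_value / np.sqrt(var_l)
    p = 2.0 * sps.t.sf(abs(t), dfe)
    return TestResult(float(t), dfe, float(p), "trend contrast")


# ---------------------------------------------------------------------------
# covariate-adjusted group difference


def glm_adjusted_difference(
    records: pd.DataFrame,
    response: str,
    group_col: str = "group",
    covariates=COVARIATES,
) -> TestResult:
    """Group effect on ``response`` adjusted for covariates via OLS.

    Returns the group indicator's t and p from the linear model
    ``response ~ group + covariates``.
    """
    import statsmodels.api as sm

    cols = [response, group_col, *covariates]
    df = records[cols].dropna().copy()
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise UndefinedTestError("adjusted comparison requires exactly 2 groups")
    df["_group"] = (df[group_col] == levels[1]).astype(float)
    x = df[["_group", *covariates]].to_numpy(dtype=float)
    for j, name in enumerate(["_group", *covariates]):
        if np.ptp(x[:, j]) == 0:
            raise CollinearityError(f"column {name!r} has zero variance")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    fit = sm.OLS(df[response].to_numpy(dtype=float), design).fit()
    return TestResult(
        float(fit.tvalues[1]),
        float(fit.df_resid),
        float(fit.pvalues[1]),
        f"GLM-adjusted {levels[1]} vs {levels[0]}",
    )


# ---------------------------------------------------------------------------
# test-retest reliability


def icc_test_retest(week0: np.ndarray, week1: np.ndarray) -> float:
    """Two-way mixed-effects, single-measure, consistency ICC — ICC(3,1).

    From the two-way ANOVA decomposition with subjects as rows and the two
    sessions as columns: ``(MS_subjects - MS_error) / (MS_subjects +
    (k-1) MS_error)`` with k = 2 sessions.  Values > 0.7 indicate good
    reliability.
    """
    x = np.column_stack([np.asarray(week0, float), np.asarray(week1, float)])
    n, k = x.shape
    if n < 3:
        raise UndefinedTestError("ICC needs at least 3 paired subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        warnings.warn("zero between-subject variance: ICC set to 0", UserWarning)
        return 0.0
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


# ---------------------------------------------------------------------------
# correlations of differentiated scores


def pearson_diff_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise UndefinedTestError("Pearson correlation needs n >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedTestError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
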