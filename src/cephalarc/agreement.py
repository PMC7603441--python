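"""Continuous-outcome validation statistics.

Implements the agreement and regression toolkit used to validate the arcial
construction: Bland–Altman limits of agreement (the study convention of
mean ± 2·sd, not 1.96·sd), two-way mixed average-measures consistency ICC —
ICC(3,k) in the Shrout–Fleiss taxonomy — the Ryan–Joiner normal-scores
normality test, quartile summaries under the Minitab-style (n+1)p convention,
Spearman correlation with a Fisher-z interval, and simple OLS with the
published predictive equation for mandibular body length from anterior
cranial base length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

#: Published predictive equation Go-Me = intercept + slope * |SN| (mm).
STUDY_GOME_INTERCEPT = 22.65
STUDY_GOME_SLOPE = 0.5426


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_raters: int
    model: str = "two-way mixed, average measures, consistency (ICC(3,k))"


@dataclass(frozen=True)
class RJResult:
    statistic: float
    n: int
    reject_at_05: bool
    critical_value_05: float


@dataclass(frozen=True)
class GapSummary:
    mean: float
    q1: float
    q3: float
    median: float
    n: int
    normality: Optional[RJResult]


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    slope: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def bland_altman(first: Sequence[float], second: Sequence[float],
                 loa_multiplier: float = 2.0) -> BlandAltmanResult:
    """Agreement between paired measurements via differences first - second.

    Limits of agreement default to mean ± 2·sd (sample sd, n-1 denominator),
    matching the reporting convention of the validation study; pass 1.96 for
    the asymptotic normal convention.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D series of equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean, sd, mean - loa_multiplier * sd,
                             mean + loa_multiplier * sd, int(a.size))


def icc_two_way_mixed_average(data: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(3,k): two-way mixed model, average measures, consistency.

    Classical ANOVA decomposition: with between-subject mean square MS_S and
    residual (subject x rater interaction) mean square MS_E,

        ICC(3,k) = (MS_S - MS_E) / MS_S = 1 - 1/F,   F = MS_S / MS_E,

    with the confidence interval from the F distribution on (n-1) and
    (n-1)(k-1) degrees of freedom.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be an n_subjects x k_raters matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_rater
    df_s, df_e = n - 1, (n - 1) * (k - 1)
    ms_s = ss_subj / df_s
    ms_e = max(ss_err, 0.0) / df_e  # ss_err can be -eps from cancellation
    # degenerate design: no real between-subject variance (tolerance relative
    # to the magnitude of the data so rounding dust does not masquerade as
    # signal)
    if ms_s <= 1e-15 * (float(np.mean(x * x)) + 1.0):
        raise ValueError("zero between-subject variance: ICC undefined")
    if ms_e == 0.0:
        return ICCResult(1.0, 1.0, 1.0, n, k)
    f = ms_s / ms_e
    icc = 1.0 - 1.0 / f
    fl = f / stats.f.ppf(1 - alpha / 2, df_s, df_e)
    fu = f * stats.f.ppf(1 - alpha / 2, df_e, df_s)
    return ICCResult(float(icc), float(1 - 1 / fl), float(1 - 1 / fu), n, k)


def normal_scores(n: int) -> np.ndarray:
    """Blom-style normal scores Phi^{-1}((i - 3/8)/(n + 1/4)), i = 1..n."""
    i = np.arange(1, n + 1)
    return stats.norm.ppf((i - 0.375) / (n + 0.25))


def ryan_joiner_critical_value(n: int, alpha: float = 0.05) -> float:
    """Critical-value approximation polynomials in 1/sqrt(n), 1/n, 1/n^2."""
    rn = 1.0 / math.sqrt(n)
    coeffs = {
        0.10: (1.0071, -0.1371, -0.3682, 0.7780),
        0.05: (1.0063, -0.1288, -0.6118, 1.3505),
        0.01: (0.9963, -0.0211, -1.4106, 3.1791),
    }
    if alpha not in coeffs:
        raise ValueError(f"no critical-value approximation for alpha={alpha}")
    c0, c1, c2, c3 = coeffs[alpha]
    return c0 + c1 * rn + c2 * rn ** 2 + c3 * rn ** 4


def ryan_joiner(x: Sequence[float], alpha: float = 0.05,
                critical_value: Optional[float] = None) -> RJResult:
    """Normality test: correlation of the sorted sample with normal scores.

    A statistic below the critical value rejects normality at ``alpha``.
    ``critical_value`` overrides the shipped approximation (e.g. with a
    Monte-Carlo table).
    """
    v = np.sort(np.asarray(x, dtype=float))
    n = v.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if v[0] == v[-1]:
        raise ValueError("constant series: normality test undefined")
    b = normal_scores(n)
    r = float(np.corrcoef(v, b)[0, 1])
    cv = ryan_joiner_critical_value(n, alpha) if critical_value is None else critical_value
    return RJResult(statistic=r, n=int(n), reject_at_05=r < cv, critical_value_05=cv)


def quartiles(x: Sequence[float]) -> tuple[float, float, float]:
    """(q1, median, q3) under the (n+1)p order-statistic convention."""
    v = np.asarray(x, dtype=float)
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="weibull")
    return float(q1), float(med), float(q3)


def gap_summary(gaps: Sequence[float]) -> GapSummary:
    """Mean plus IQR summary of Euclidean gaps (the study reports both)."""
    v = np.asarray(gaps, dtype=float)
    if v.size == 0:
        raise ValueError("empty gap series")
    q1, med, q3 = quartiles(v)
    rj = None
    if v.size >= 4 and v.min() != v.max():
        rj = ryan_joiner(v)
    return GapSummary(mean=float(v.mean()), q1=q1, q3=q3, median=med,
                      n=int(v.size), normality=rj)


def spearman_with_ci(x: Sequence[float], y: Sequence[float],
                     alpha: float = 0.05) -> CorrelationResult:
    """Spearman rank correlation with a Fisher-z interval.

    rho is the Pearson correlation of average ranks.  The interval uses the
    rank-correlation standard error 1.03/sqrt(n-3) on the z scale; the p-value
    comes from the t approximation t = rho sqrt((n-2)/(1-rho^2)).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D series of equal length")
    n = a.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    if np.all(ra == ra[0]) or np.all(rb == rb[0]):
        raise ValueError("all-tied input: correlation undefined")
    rho = float(np.corrcoef(ra, rb)[0, 1])
    z = math.atanh(min(max(rho, -1 + 1e-15), 1 - 1e-15))
    se = 1.03 / math.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    lo, hi = math.tanh(z - zc * se), math.tanh(z + zc * se)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
        p = 2 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, ci_low=lo, ci_high=hi, p=p, n=int(n))


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple least-squares line y = intercept + slope * x."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need equal-length 1-D series with n >= 3")
    if np.ptp(a) == 0.0:
        raise ValueError("zero variance in x: slope undefined")
    res = stats.linregress(a, b)
    return RegressionResult(intercept=float(res.intercept), slope=float(res.slope),
                            n=int(a.size))


def predict_gome_from_sn(sn_mm: float,
                         intercept: float = STUDY_GOME_INTERCEPT,
                         slope: float = STUDY_GOME_SLOPE) -> float:
    """Predicted mandibular body length Go-Me (mm) from |SN| (mm)."""
    if sn_mm < 0:
        raise ValueError("SN length must be non-negative")
    return intercept + slope * sn_mm


def agreement_table(columns: dict[str, tuple[Sequence[float], Sequence[float]]]) -> str:
    """TSV agreement table (rows mean/sd/2sd/ICC) across named measurements.

    Each value is a (first, second) pair of repeat-measurement series; the ICC
    row treats them as two raters.
    """
    names = list(columns)
    rows: dict[str, list[str]] = {"Mean": [], "sd": [], "2sd": [], "ICC": []}
    for name in names:
        first, second = columns[name]
        ba = bland_altman(first, second)
        icc = icc_two_way_mixed_average(np.column_stack([first, second]))
        rows["Mean"].append(f"{ba.mean_diff:.2f}")
        rows["sd"].append(f"{ba.sd:.2f}")
        rows["2sd"].append(f"{2 * ba.sd:.2f}")
        rows["ICC"].append(f"{icc.icc:.3f}")
    out = ["\t".join(["measure"] + names)]
    for label in ("Mean", "sd", "2sd", "ICC"):
        out.append("\t".join([label] + rows[label]))
    return "\n".join(out) + "\n"
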