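"""Method-comparison statistics: two-way random-effects ICC and Bland-Altman.

Agreement between two ways of measuring the same per-subject quantity
(e.g. diary-derived vs algorithm-derived adherent step count) is
quantified by the intraclass correlation coefficient from a two-way
random-effects ANOVA — by default ICC(2,1), single measures, absolute
agreement — and visual bias/limits-of-agreement statistics in the
Bland-Altman style.  ICC > 0.9 is read as excellent agreement, 0.75–0.9
good, 0.5–0.75 moderate, < 0.5 poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AgreementResult:
    """ICC with its F test, Bland-Altman bias/limits, and the verbal grade.

    ``icc`` is None when total variance is zero (agreement undefined, see
    ``undefined``).  ``bias`` is mean(method_b − method_a); with the
    conventional ordering (a=algorithm, b=diary) a positive bias means the
    diary reports more adherence than the algorithm.
    """

    icc: float | None
    f_statistic: float | None
    p_value: float | None
    df1: int
    df2: int
    bias: float
    loa_low: float
    loa_high: float
    interpretation: str | None
    undefined: bool = False


def _anova_mean_squares(x: np.ndarray):
    """Two-way (subjects x methods) ANOVA mean squares for a complete table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way_random(
    method_a, method_b, *, average_measures: bool = False
) -> AgreementResult:
    """ICC (two-way random effects, absolute agreement) between two methods.

    Default is single measures, ICC(2,1):

        (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

    with ``average_measures=True`` the average-measures form ICC(2,k).
    Significance is the F test MS_R/MS_E on (n−1, (n−1)(k−1)) df.
    Requires n >= 3 paired subjects.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("method_a and method_b must be equal-length 1-D vectors")
    if a.size < 3:
        raise ValueError("ICC needs at least 3 paired subjects")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values must be removed before pairing")
    x = np.column_stack([a, b])
    n, k = x.shape
    ba = bland_altman(a, b)

    msr, msc, mse = _anova_mean_squares(x)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if np.isclose(msr, 0.0) and np.isclose(mse, 0.0) and np.isclose(msc, 0.0):
        return AgreementResult(
            icc=None, f_statistic=None, p_value=None, df1=df1, df2=df2,
            bias=ba["bias"], loa_low=ba["loa_low"], loa_high=ba["loa_high"],
            interpretation=None, undefined=True,
        )
    if average_measures:
        denom = msr + (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else None
    if mse == 0:
        f = np.inf
        p = 0.0
    else:
        f = msr / mse
        p = float(stats.f.sf(f, df1, df2))
    return AgreementResult(
        icc=None if icc is None else float(icc),
        f_statistic=float(f),
        p_value=p,
        df1=df1,
        df2=df2,
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        interpretation=None if icc is None else interpret_icc(float(icc)),
        undefined=icc is None,
    )


def bland_altman(method_a, method_b) -> dict:
    """Bias and 95% limits of agreement for differences method_b − method_a.

    LoA = bias ± 1.96 x sample SD (ddof=1) of the differences.  Also
    returns the per-pair means and differences for plotting.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("Bland-Altman needs two equal-length vectors, n >= 2")
    diffs = b - a
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "means": (a + b) / 2.0,
        "differences": diffs,
    }


def interpret_icc(icc: float) -> str:
    """Verbal grade: >0.9 excellent, 0.75–0.9 good, 0.5–0.75 moderate, else poor."""
    if icc > 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"
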