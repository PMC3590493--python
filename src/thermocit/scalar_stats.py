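"""Scalar inference on FTCVs: t-tests, normality screening, Bonferroni.

These are the study's "initial" (non-functional) analyses: an
independent-samples t-test comparing baseline temperatures between
groups, Shapiro-Wilk normality screening of the FTCV scores per cell,
directional paired t-tests of RE vs IR FTCVs within each group, and a
Bonferroni correction across the two directional tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError

TAILS = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    tail: str
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tail not in TAILS:
            raise ValidationError(f"tail must be one of {TAILS}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value outside [0, 1]")
        if self.adjusted_p is not None and not 0.0 <= self.adjusted_p <= 1.0:
            raise ValidationError("adjusted_p outside [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValidationError("df must be >= 1")

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "tail": self.tail,
            "adjusted_p": self.adjusted_p,
        }
        d.update(self.extra)
        return d


def _t_pvalue(t: float, df: float, tail: str) -> float:
    if tail == "greater":
        return float(stats.t.sf(t, df))
    if tail == "less":
        return float(stats.t.cdf(t, df))
    return float(2.0 * stats.t.sf(abs(t), df))


def paired_t_directional(x, y, tail: str = "greater") -> TestResult:
    """Paired t-test on d = x - y with a directional (or two-sided) p.

    t = mean(d) / (sd(d) / sqrt(n)), df = n - 1, unbiased sd.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tail not in TAILS:
        raise ValidationError(f"tail must be one of {TAILS}")
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    return TestResult(
        statistic=t,
        df=df,
        p_value=_t_pvalue(t, df, tail),
        tail=tail,
        extra={"mean_diff": float(d.mean()), "sd_diff": float(sd), "n": n},
    )


def independent_t(x, y, tail: str = "two_sided") -> TestResult:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2, no Welch correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 2 or len(y) < 2:
        raise ValidationError("both samples must be 1-D with at least 2 values")
    return t_from_summary(
        len(x), float(x.mean()), float(x.std(ddof=1)),
        len(y), float(y.mean()), float(y.std(ddof=1)),
        tail=tail,
    )


def t_from_summary(n1: int, m1: float, s1: float, n2: int, m2: float, s2: float,
                   tail: str = "two_sided") -> TestResult:
    """Pooled-variance t-test from per-group summary statistics."""
    if tail not in TAILS:
        raise ValidationError(f"tail must be one of {TAILS}")
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 observations")
    if s1 < 0 or s2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    if sp2 == 0.0:
        raise DegenerateInputError("pooled variance is zero")
    t = float((m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    return TestResult(
        statistic=t,
        df=df,
        p_value=_t_pvalue(t, df, tail),
        tail=tail,
        extra={"mean1": m1, "sd1": s1, "n1": n1, "mean2": m2, "sd2": s2, "n2": n2},
    )


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk test of normality (W statistic), for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not (3 <= len(x) <= 5000):
        raise ValidationError("Shapiro-Wilk requires a 1-D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("sample has zero variance")
    w, p = stats.shapiro(x)
    return TestResult(statistic=float(w), df=None, p_value=float(p), tail="two_sided",
                      extra={"n": len(x)})


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must lie in [0, 1]")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValidationError("m must be an integer >= 1")
    return min(1.0, m * p)
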