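"""Agreement and association statistics for 2x2 tables.

Everything here operates on counts: per-item prediction-vs-truth
confusion matrices (accuracy, Cohen's kappa, McNemar) and
correct/incorrect-by-group strata (Pearson chi-square), plus the Wald
confidence-interval margin for a proportion and the matching sample-size
formula.

Conventions chosen to match the monitoring study's reporting:

* McNemar uses the plain discordant-cell statistic (b - c)^2 / (b + c)
  with **no** continuity correction; a corrected variant is available
  behind a flag.
* Pearson chi-square on the 2x2 strata uses no Yates correction;
  a corrected variant is available behind a flag.
* p-values come from the upper tail of the chi-square distribution with
  one degree of freedom.
* The CI is the Wald (normal-approximation) interval; Wilson is
  available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as sps


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Paired 2x2 counts, ground truth on rows, prediction on columns.

    ``a`` = truth true & predicted true (TP), ``b`` = truth true &
    predicted false (FN), ``c`` = truth false & predicted true (FP),
    ``d`` = truth false & predicted false (TN).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class Strata2x2:
    """Correct/incorrect counts for two strata (e.g. scrubs vs casual)."""

    correct_a: int
    correct_b: int
    incorrect_a: int
    incorrect_b: int

    def __post_init__(self) -> None:
        for f in ("correct_a", "correct_b", "incorrect_a", "incorrect_b"):
            v = getattr(self, f)
            if int(v) != v or v < 0:
                raise ValueError(f"count {f} must be a non-negative integer, got {v}")
            object.__setattr__(self, f, int(v))

    @property
    def n(self) -> int:
        return self.correct_a + self.correct_b + self.incorrect_a + self.incorrect_b


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value; ``degenerate`` marks the
    b + c = 0 McNemar edge case where the statistic is undefined."""

    statistic: float
    pvalue: float
    degenerate: bool = False


def accuracy(cm: ConfusionMatrix2x2) -> float:
    """(a + d) / n — the proportion of agreeing pairs."""
    if cm.n == 0:
        raise ValueError("accuracy undefined for an empty table")
    return (cm.a + cm.d) / cm.n


def cohen_kappa(cm: ConfusionMatrix2x2) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Returns NaN when the expected agreement p_e equals 1 (both marginals
    fully concentrated), where kappa is undefined.
    """
    n = cm.n
    if n == 0:
        raise ValueError("kappa undefined for an empty table")
    po = (cm.a + cm.d) / n
    pe = ((cm.a + cm.b) * (cm.a + cm.c) + (cm.c + cm.d) * (cm.b + cm.d)) / n**2
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def chi2_survival(x: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-square distribution.

    One minus the CDF at *x* — the p-value attached to every chi-square
    shaped statistic in this module.
    """
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return float(sps.chi2.sf(x, df))


def mcnemar(cm: ConfusionMatrix2x2, correction: bool = False) -> TestResult:
    """Marginal-homogeneity test on the discordant cells.

    statistic = (b - c)^2 / (b + c); with ``correction`` the numerator
    becomes (|b - c| - 1)^2 (Edwards continuity correction, off by
    default).  When b + c = 0 there are no discordant pairs and the
    result is flagged degenerate with statistic 0, p = 1.
    """
    if cm.n == 0:
        raise ValueError("mcnemar undefined for an empty table")
    disc = cm.b + cm.c
    if disc == 0:
        return TestResult(0.0, 1.0, degenerate=True)
    num = (abs(cm.b - cm.c) - 1) ** 2 if correction else (cm.b - cm.c) ** 2
    stat = num / disc
    return TestResult(float(stat), chi2_survival(stat, 1))


def pearson_chi2(strata: Strata2x2, correction: bool = False) -> TestResult:
    """Pearson chi-square of independence on the 2x2 strata table.

    statistic = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)] with
    a, b = correct counts and c, d = incorrect counts of the two groups.
    No Yates correction by default.
    """
    a, b = strata.correct_a, strata.correct_b
    c, d = strata.incorrect_a, strata.incorrect_b
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined with a zero marginal")
    n = strata.n
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return TestResult(float(stat), chi2_survival(stat, 1))


def wald_ci_margin(p: float, n: int, confidence: float = 0.95) -> float:
    """Half-width of the Wald interval for a proportion: z * sqrt(p(1-p)/n)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    return float(z * math.sqrt(p * (1.0 - p) / n))


def wilson_ci_margin(p: float, n: int, confidence: float = 0.95) -> float:
    """Half-width of the Wilson score interval (alternative to Wald)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    denom = 1.0 + z * z / n
    half = (z / denom) * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    return half


def required_sample_size(p: float, half_width: float, confidence: float = 0.95) -> int:
    """Smallest n for which the Wald margin at *p* is <= *half_width*.

    ceil(z^2 p (1 - p) / half_width^2), with a floor of 1.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    return max(1, math.ceil(z * z * p * (1.0 - p) / (half_width * half_width)))


def format_pvalue(p: float) -> str:
    """Report to three decimals, '<0.001' below that."""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"
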