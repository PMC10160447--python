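"""Mendelian goodness-of-fit tests for two-class phenotype counts.

A single fully penetrant dominant locus predicts a 3:1 yellow:green
segregation in an F2 and 1:1 in a backcross to the recessive parent.
The fit is assessed with the Pearson chi-squared statistic on the two
observed classes (df = 1, no continuity correction) against the
chi-squared upper tail; the conventional 5% critical value is 3.84.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class SegregationCount:
    n_yellow: int
    n_green: int

    def __post_init__(self):
        if self.n_yellow < 0 or self.n_green < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one plant required")

    @property
    def total(self) -> int:
        return self.n_yellow + self.n_green


@dataclass
class SegregationTestResult:
    counts: SegregationCount
    ratio: tuple[float, float]  # hypothesized yellow:green
    expected: tuple[float, float]
    chi2: float
    df: int
    p: float

    @property
    def fits(self) -> bool:
        """True when the hypothesized ratio is not rejected at alpha=0.05."""
        return self.p > ALPHA


def chi2_upper_tail(x: float, df: int = 1) -> float:
    """P(X >= x) for X ~ chi-squared(df); for df=1 this equals 2*(1-Phi(sqrt(x)))."""
    if x < 0:
        raise ValueError("chi-squared statistic must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(x, df))


def chi_square_gof(counts: SegregationCount, ratio: tuple[float, float] = (3, 1)) -> SegregationTestResult:
    """Pearson chi-squared test of a yellow:green segregation ratio."""
    ry, rg = ratio
    if ry <= 0 or rg <= 0:
        raise ValueError("ratio components must be > 0")
    total = counts.total
    ey = total * ry / (ry + rg)
    eg = total * rg / (ry + rg)
    chi2 = (counts.n_yellow - ey) ** 2 / ey + (counts.n_green - eg) ** 2 / eg
    return SegregationTestResult(counts, (ry, rg), (ey, eg), float(chi2), 1, chi2_upper_tail(chi2, 1))
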