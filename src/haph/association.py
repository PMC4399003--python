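"""Case-control association and screening statistics for carrier/status data.

All statistics operate on a 2x2 contingency table of carrier status
(dominant model: one or two alternate alleles) against disease status
(affected / unaffected by mean pulmonary artery pressure thresholds):

    ==============  =========  ============
                    carrier    non-carrier
    affected        a          b
    unaffected      c          d
    ==============  =========  ============

Conventions chosen to match standard screening-study practice:

* Pearson chi-square without continuity correction by default (Yates
  available via a flag);
* relative risk and odds ratio with Wald 95% confidence intervals on the
  log scale (z = 1.96);
* predictive values from sensitivity/specificity via Bayes' rule under an
  assumed pre-test prevalence;
* exact Wilcoxon rank-sum by convolution over mid-ranks for small
  samples, normal approximation with tie correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class ConfigError(ValueError):
    """Invalid analysis configuration (e.g. inverted PAP thresholds)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-by-status counts: a/b affected, c/d unaffected."""

    a: int  # affected carriers
    b: int  # affected non-carriers
    c: int  # unaffected carriers
    d: int  # unaffected non-carriers

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.n < 1:
            raise ValueError("table must contain at least one subject")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def sensitivity(self) -> float:
        """Fraction of affected animals that carry the variant."""
        return self.a / (self.a + self.b)

    @property
    def specificity(self) -> float:
        """Fraction of unaffected animals that do not carry it."""
        return self.d / (self.c + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class GenotypeCounts3:
    """Per-status genotype counts (hom-ref, het, hom-alt)."""

    affected: tuple[int, int, int]
    unaffected: tuple[int, int, int]

    def __post_init__(self) -> None:
        for row in (self.affected, self.unaffected):
            if len(row) != 3 or any(v < 0 for v in row):
                raise ValueError("each row needs 3 non-negative counts")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    df: int = 1
    note: str = ""

    @property
    def defined(self) -> bool:
        return not math.isnan(self.statistic)


@dataclass(frozen=True)
class ScreeningEstimate:
    """Point estimate with 95% bounds; NaN bounds mean 'undefined'."""

    point: float
    lower: float
    upper: float
    scale: str  # "ratio" or "probability"
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.lower) or math.isnan(self.upper)):
            if not (self.lower <= self.point <= self.upper):
                raise ValueError("interval must bracket the point estimate")


def classify_status(
    pap: float,
    affected_min: float = 50.0,
    unaffected_max: float = 39.0,
    affected_inclusive: bool = False,
    unaffected_inclusive: bool = False,
) -> str:
    """Classify an animal by mean PAP (mm Hg) into a case-control status.

    With the defaults, PAP strictly above 50 is affected and strictly
    below 39 is unaffected; the zone in between is indeterminate and is
    excluded from case-control analyses.  Herds phenotyped with different
    cut-offs (e.g. affected at >=45 in younger animals) are handled by the
    threshold and inclusivity arguments.
    """
    if unaffected_max > affected_min:
        raise ConfigError(
            f"unaffected_max ({unaffected_max}) must not exceed "
            f"affected_min ({affected_min})"
        )
    if pap > affected_min or (affected_inclusive and pap == affected_min):
        return "affected"
    if pap < unaffected_max or (unaffected_inclusive and pap == unaffected_max):
        return "unaffected"
    return "indeterminate"


def chi2_2x2(table: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Pearson chi-square (1 df) on a 2x2 table.

    No continuity correction by default.  With ``yates=True``, n/2 is
    subtracted from \\|ad - bc\\| (floored at zero) before squaring.  A zero
    margin leaves the statistic undefined (NaN).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return TestResult(math.nan, math.nan, 1, note="zero margin")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / math.prod(margins)
    return TestResult(stat, float(stats.chi2.sf(stat, 1)), 1)


def armitage_trend(
    counts: GenotypeCounts3, weights: Sequence[float] = (0.0, 1.0, 2.0)
) -> TestResult:
    """Cochran-Armitage trend test across genotype dose categories.

    The statistic is the squared trend z-score referred to a 1-df
    chi-square.  With weights (0, 1, 1) it reduces to the uncorrected
    Pearson chi-square on the carrier-collapsed 2x2 table.
    """
    w = np.asarray(weights, dtype=float)
    r = np.asarray(counts.affected, dtype=float)
    s = np.asarray(counts.unaffected, dtype=float)
    n_i = r + s
    N = n_i.sum()
    R = r.sum()
    if N < 1 or R == 0 or R == N:
        return TestResult(math.nan, math.nan, 1, note="one status group empty")
    if np.count_nonzero(n_i) < 2:
        return TestResult(math.nan, math.nan, 1, note="all subjects in one genotype")
    num = N * float(w @ r) - R * float(w @ n_i)
    var = R * (N - R) * (N * float((w * w) @ n_i) - float(w @ n_i) ** 2)
    if var <= 0:
        return TestResult(math.nan, math.nan, 1, note="degenerate weights")
    stat = num * num * N / var
    return TestResult(stat, float(stats.chi2.sf(stat, 1)), 1)


def _exact_ranksum_pvalue(ranks2: np.ndarray, n_a: int, w2_obs: int) -> float:
    """Two-sided exact p for the rank-sum statistic by convolution.

    ``ranks2`` are mid-ranks doubled (hence integral).  Counts the number
    of size-``n_a`` subsets whose doubled rank sum is at least as far from
    the null mean as the observed one.
    """
    total = int(ranks2.sum())
    # dp[k][s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n_a + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n_a, 0, -1):  # descending k: each rank used once
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n_a]
    n_subsets = counts.sum()
    mu2 = n_a * (total / len(ranks2))  # doubled null mean = n_a * (N+1)
    dev = abs(w2_obs - mu2)
    sums = np.arange(total + 1)
    extreme = counts[np.abs(sums - mu2) >= dev - 1e-9].sum()
    return float(min(1.0, extreme / n_subsets))


def rank_sum(
    values_a: Sequence[float],
    values_b: Sequence[float],
    mode: str = "auto",
    exact_limit: int = 20,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test on two samples (e.g. PAP values).

    Mid-ranks handle ties.  ``mode`` is ``exact`` (subset convolution over
    the permutation null), ``normal_approx`` (z with tie-corrected
    variance, no continuity correction), or ``auto`` (exact when
    n_a + n_b <= ``exact_limit``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = float(ranks[: a.size].sum())
    n_a, n = a.size, combined.size
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n <= exact_limit)
    if use_exact:
        ranks2 = np.rint(2 * ranks).astype(int)
        p = _exact_ranksum_pvalue(ranks2, n_a, int(round(2 * w)))
        return TestResult(w, p, df=0, note="exact")
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n_a * (n - n_a) / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(w, 1.0, df=0, note="all values tied")
    z = (w - mu) / math.sqrt(var)
    return TestResult(w, float(2 * stats.norm.sf(abs(z))), df=0, note="normal_approx")


def relative_risk(
    table: ContingencyTable2x2, continuity: bool = False
) -> ScreeningEstimate:
    """Risk of disease in carriers relative to non-carriers, Wald 95% CI.

    RR = (a/(a+c)) / (b/(b+d)); the CI is exp(ln RR +- 1.96 * SE) with
    SE^2 = 1/a - 1/(a+c) + 1/b - 1/(b+d).  A zero ``a`` or ``b`` cell
    leaves the CI undefined unless ``continuity`` adds 0.5 to each cell.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if a + c == 0 or b + d == 0:
        raise ValueError("carrier and non-carrier groups must be non-empty")
    note = ""
    if continuity and (a == 0 or b == 0):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        note = "0.5 continuity correction applied"
    risk_carrier = a / (a + c)
    risk_noncarrier = b / (b + d)
    if risk_noncarrier == 0:
        return ScreeningEstimate(math.inf, math.nan, math.nan, "ratio", "zero denominator risk")
    rr = risk_carrier / risk_noncarrier
    if a == 0:
        return ScreeningEstimate(0.0, math.nan, math.nan, "ratio", "zero numerator risk")
    se = math.sqrt(1 / a - 1 / (a + c) + 1 / b - 1 / (b + d))
    lo = math.exp(math.log(rr) - Z_95 * se)
    hi = math.exp(math.log(rr) + Z_95 * se)
    return ScreeningEstimate(rr, lo, hi, "ratio", note)


def odds_ratio(
    table: ContingencyTable2x2, haldane: bool = False
) -> ScreeningEstimate:
    """Cross-product odds ratio with Woolf (Wald, log-scale) 95% CI.

    OR = ad/bc; SE^2 = 1/a + 1/b + 1/c + 1/d.  With a zero cell the
    estimate/CI are undefined unless ``haldane`` applies the
    Haldane-Anscombe 0.5 correction to every cell.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    note = ""
    if 0.0 in (a, b, c, d):
        if not haldane:
            point = math.inf if b * c == 0 and a * d > 0 else 0.0
            return ScreeningEstimate(point, math.nan, math.nan, "ratio", "zero cell")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        note = "Haldane-Anscombe 0.5 correction applied"
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - Z_95 * se)
    hi = math.exp(math.log(orr) + Z_95 * se)
    return ScreeningEstimate(orr, lo, hi, "ratio", note)


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Positive and negative predictive values under an assumed prevalence.

    PPV = se*p / (se*p + (1-sp)(1-p)); NPV = sp(1-p) / (sp(1-p) + (1-se)p).
    Returns probabilities in [0, 1]; a zero denominator yields NaN.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    ppv_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    npv_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    ppv = sensitivity * prevalence / ppv_den if ppv_den > 0 else math.nan
    npv = specificity * (1 - prevalence) / npv_den if npv_den > 0 else math.nan
    return ppv, npv


def pool_tables(tables: Sequence[ContingencyTable2x2]) -> ContingencyTable2x2:
    """Cell-wise pooling of per-herd tables for a joint analysis."""
    if not tables:
        raise ValueError("need at least one table")
    return ContingencyTable2x2(
        a=sum(t.a for t in tables),
        b=sum(t.b for t in tables),
        c=sum(t.c for t in tables),
        d=sum(t.d for t in tables),
    )
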