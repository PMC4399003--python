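"""Gene-set expression enrichment by three-category chi-square.

The procedure asks whether a hypoxia-response gene set is enriched for
differential expression between affected carrier animals and unaffected
controls, against an empirical genome-wide background:

1. keep gene-set genes whose group-mean log2 expression exceeds a
   reliable-signal floor (default 7 log2 units) in either group;
2. call each kept gene ``up`` / ``down`` / ``neither`` by an uncorrected
   two-sample t-test (default Welch) at ``p_threshold`` combined with a
   linear fold-change threshold (default 1.25) computed from anti-logged
   group means;
3. estimate the background up/down rates as the fraction of *all*
   floor-passing genes on the array called up/down by the same criteria;
4. compare observed (up, down, neither) counts in the gene set with the
   expected counts from the background rates by a Pearson chi-square with
   2 degrees of freedom.

``expected_mode`` controls whether expected counts are used as raw
proportions (statistically standard) or rounded to whole genes, the
convention some screening reports use; both are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionTable, GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentConfig:
    expression_floor: float = 7.0  # log2 units
    p_threshold: float = 0.05
    fc_threshold: float = 1.25  # linear fold change
    expected_mode: str = "rounded_counts"  # or "raw_proportions"
    welch: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.expression_floor):
            raise ValueError("expression_floor must be finite")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")
        if self.expected_mode not in ("rounded_counts", "raw_proportions"):
            raise ValueError(f"unknown expected_mode {self.expected_mode!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    n_expressed: int
    observed: tuple[int, int, int]  # up, down, neither
    expected: tuple[float, float, float]
    statistic: float
    pvalue: float
    df: int = 2
    mode: str = "rounded_counts"
    note: str = ""


def _group_arrays(
    expr: ExpressionTable, groups: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    cols_a = [s for s in expr.samples if groups.get(s) == "affected"]
    cols_u = [s for s in expr.samples if groups.get(s) == "unaffected"]
    if len(cols_a) < 2 or len(cols_u) < 2:
        raise ValueError("need >=2 samples per group for a t-test")
    return (
        expr.df[cols_a].to_numpy(dtype=float),
        expr.df[cols_u].to_numpy(dtype=float),
    )


def expressed_subset(
    expr: ExpressionTable,
    genes: GeneSet,
    groups: Mapping[str, str],
    floor: float = 7.0,
) -> GeneSet:
    """Gene-set genes whose mean log2 expression strictly exceeds the
    floor in the affected group or in the unaffected group."""
    a, u = _group_arrays(expr, groups)
    mean_a = a.mean(axis=1)
    mean_u = u.mean(axis=1)
    by_gene = {
        g: (mean_a[i], mean_u[i]) for i, g in enumerate(expr.genes)
    }
    kept = []
    n_absent = 0
    for g in genes:
        if g not in by_gene:
            n_absent += 1
            continue
        ma, mu = by_gene[g]
        if ma > floor or mu > floor:
            kept.append(g)
    if n_absent:
        logger.warning("%d gene-set symbols absent from expression table", n_absent)
    return GeneSet(symbols=tuple(kept), name=f"{genes.name}_expressed")


def _directions(
    a: np.ndarray, u: np.ndarray, cfg: EnrichmentConfig
) -> np.ndarray:
    """Vectorised up/down/neither calls for rows of two group arrays."""
    mean_a = a.mean(axis=1)
    mean_u = u.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, u, axis=1, equal_var=not cfg.welch)
    p = np.asarray(p, dtype=float)
    delta = mean_a - mean_u
    # zero variance in both groups: identical means -> no evidence (p NaN);
    # differing constant groups -> treat as maximal evidence
    both_const = (a.std(axis=1) == 0) & (u.std(axis=1) == 0)
    p = np.where(both_const & (delta != 0), 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    log2_fc = math.log2(cfg.fc_threshold)
    up = (p < cfg.p_threshold) & (delta > log2_fc)
    down = (p < cfg.p_threshold) & (-delta > log2_fc)
    out = np.full(a.shape[0], "neither", dtype=object)
    out[up] = "up"
    out[down] = "down"
    return out


def call_direction(
    expr: ExpressionTable,
    gene: str,
    groups: Mapping[str, str],
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> str:
    """Differential call for one gene: ``up``, ``down`` or ``neither``.

    ``up`` requires two-sided t-test p below ``p_threshold`` *and* a
    linear fold change 2^(mean_affected - mean_unaffected) strictly above
    ``fc_threshold``; ``down`` is symmetric with the reciprocal.
    """
    if gene not in expr.df.index:
        raise KeyError(gene)
    a, u = _group_arrays(expr, groups)
    i = expr.genes.index(gene)
    return str(_directions(a[i : i + 1], u[i : i + 1], cfg)[0])


def call_directions(
    expr: ExpressionTable,
    genes: Sequence[str],
    groups: Mapping[str, str],
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> dict[str, str]:
    a, u = _group_arrays(expr, groups)
    idx = {g: i for i, g in enumerate(expr.genes)}
    rows = [idx[g] for g in genes]
    calls = _directions(a[rows], u[rows], cfg)
    return dict(zip(genes, (str(c) for c in calls)))


def background_rates(
    expr: ExpressionTable,
    groups: Mapping[str, str],
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> tuple[float, float]:
    """Genome-wide up/down call rates among floor-passing genes."""
    a, u = _group_arrays(expr, groups)
    passing = (a.mean(axis=1) > cfg.expression_floor) | (
        u.mean(axis=1) > cfg.expression_floor
    )
    n = int(passing.sum())
    if n == 0:
        raise ValueError("no genes pass the expression floor")
    calls = _directions(a[passing], u[passing], cfg)
    p_up = float((calls == "up").sum()) / n
    p_down = float((calls == "down").sum()) / n
    return p_up, p_down


def enrichment_chi2(
    observed: tuple[int, int, int],
    n: int,
    rates: tuple[float, float],
    mode: str = "rounded_counts",
) -> EnrichmentResult:
    """Three-category Pearson chi-square of observed vs expected calls.

    ``observed`` is (up, down, neither) and must sum to ``n``.  Expected
    counts are (n*p_up, n*p_down, remainder); in ``rounded_counts`` mode
    the up/down expectations are rounded to the nearest whole gene with
    the ``neither`` category absorbing the difference.
    """
    if sum(observed) != n:
        raise ValueError("observed counts must sum to n")
    p_up, p_down = rates
    if not (0 <= p_up <= 1 and 0 <= p_down <= 1 and p_up + p_down <= 1):
        raise ValueError("rates must be proportions summing to <= 1")
    if mode == "rounded_counts":
        e_up = float(round(n * p_up))
        e_down = float(round(n * p_down))
    elif mode == "raw_proportions":
        e_up = n * p_up
        e_down = n * p_down
    else:
        raise ValueError(f"unknown mode {mode!r}")
    e_neither = n - e_up - e_down
    expected = (e_up, e_down, e_neither)
    if any(e <= 0 for e in expected):
        return EnrichmentResult(
            n_expressed=n,
            observed=observed,
            expected=expected,
            statistic=math.nan,
            pvalue=math.nan,
            mode=mode,
            note="zero expected count; statistic undefined",
        )
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return EnrichmentResult(
        n_expressed=n,
        observed=observed,
        expected=expected,
        statistic=stat,
        pvalue=float(stats.chi2.sf(stat, 2)),
        mode=mode,
    )


def run_enrichment(
    expr: ExpressionTable,
    gene_set: GeneSet,
    groups: Mapping[str, str],
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> tuple[EnrichmentResult, dict[str, str]]:
    """Full enrichment procedure; returns the result and per-gene calls."""
    expressed = expressed_subset(expr, gene_set, groups, cfg.expression_floor)
    if len(expressed) == 0:
        raise ValueError("no gene-set genes pass the expression floor")
    calls = call_directions(expr, list(expressed), groups, cfg)
    observed = (
        sum(c == "up" for c in calls.values()),
        sum(c == "down" for c in calls.values()),
        sum(c == "neither" for c in calls.values()),
    )
    rates = background_rates(expr, groups, cfg)
    result = enrichment_chi2(observed, len(expressed), rates, cfg.expected_mode)
    return result, calls
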