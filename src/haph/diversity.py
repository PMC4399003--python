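"""Microsatellite diversity scoring and diverse-subset selection.

Before sequencing an extreme-phenotype subset, the most genetically
diverse animals within each phenotype group are chosen to reduce the
chance that shared variants merely reflect relatedness.  Diversity is
scored from a panel of microsatellite markers: the pairwise distance
between two animals is the number of alleles that differ between them,
i.e. per marker 2 minus the multiset overlap of the two unordered allele
pairs, summed over markers (range 0..2M for M markers).

Subset selection maximises the total within-subset pairwise distance,
exhaustively when the number of candidate subsets is within a budget and
by a greedy max-min heuristic otherwise.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .io_formats import MicrosatellitePanel, PhenotypeTable, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_SUBSET_BUDGET = 10**6


@dataclass
class DistanceMatrix:
    """Symmetric allele-difference counts with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray  # (n, n) int

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diagonal(self.values).any():
            raise ValueError("distance matrix diagonal must be zero")

    def between(self, s1: str, s2: str) -> int:
        i, j = self.sample_ids.index(s1), self.sample_ids.index(s2)
        return int(self.values[i, j])


@dataclass
class SelectionResult:
    sample_ids: list[str]
    total_distance: int
    method: str  # "exhaustive" or "greedy_maxmin"


def _marker_distance(pair1: np.ndarray, pair2: np.ndarray) -> int:
    """2 minus multiset overlap of two unordered allele pairs."""
    overlap = sum((Counter(pair1) & Counter(pair2)).values())
    return 2 - overlap


def pairwise_distance(panel: MicrosatellitePanel) -> DistanceMatrix:
    """Allele-difference distance between every pair of animals.

    Markers with a missing allele in either animal contribute 0 to that
    pair (logged), keeping the matrix complete.
    """
    n = len(panel.sample_ids)
    m = len(panel.marker_names)
    values = np.zeros((n, n), dtype=int)
    n_skipped = 0
    for i, j in combinations(range(n), 2):
        total = 0
        for k in range(m):
            a, b = panel.alleles[i, k], panel.alleles[j, k]
            if "" in a or "" in b:
                n_skipped += 1
                continue
            total += _marker_distance(a, b)
        values[i, j] = values[j, i] = total
    if n_skipped:
        logger.warning(
            "%d marker comparisons skipped due to missing alleles", n_skipped
        )
    return DistanceMatrix(sample_ids=list(panel.sample_ids), values=values)


def _subset_score(values: np.ndarray, idx: tuple[int, ...]) -> int:
    sub = values[np.ix_(idx, idx)]
    return int(sub.sum()) // 2


def select_diverse_subset(
    dist: DistanceMatrix,
    phenotypes: PhenotypeTable,
    k: int,
    group: str,
    budget: int = DEFAULT_SUBSET_BUDGET,
) -> SelectionResult:
    """Pick the k most diverse animals within one phenotype group.

    Objective: maximise the sum of within-subset pairwise distances.  All
    C(n, k) subsets are enumerated when that count is within ``budget``;
    otherwise a greedy max-min heuristic seeds with the farthest pair and
    repeatedly adds the animal maximising its minimum distance to the
    chosen set.  Ties break lexicographically by sample id, making the
    result deterministic.
    """
    members = sorted(phenotypes.samples_with_status(group))
    missing = [s for s in members if s not in dist.sample_ids]
    if missing:
        raise SchemaError(f"samples missing from distance matrix: {missing}")
    n = len(members)
    if k > n:
        raise ValueError(f"k={k} exceeds group size {n}")
    idx_of = {s: dist.sample_ids.index(s) for s in members}
    # restrict to the group, in sorted-id order so ties break lexicographically
    sub = dist.values[np.ix_([idx_of[s] for s in members], [idx_of[s] for s in members])]

    if comb(n, k) <= budget:
        best: tuple[int, ...] | None = None
        best_score = -1
        for cand in combinations(range(n), k):
            score = _subset_score(sub, cand)
            if score > best_score:  # strict: first (lexicographic) subset wins ties
                best, best_score = cand, score
        assert best is not None
        return SelectionResult(
            sample_ids=[members[i] for i in best],
            total_distance=best_score,
            method="exhaustive",
        )

    logger.info("C(%d,%d) exceeds budget %d; using greedy max-min", n, k, budget)
    pairs = [(i, j) for i, j in combinations(range(n), 2)]
    i0, j0 = max(pairs, key=lambda p: (sub[p[0], p[1]], -p[0], -p[1]))
    chosen = [i0, j0]
    remaining = [i for i in range(n) if i not in chosen]
    while len(chosen) < k:
        nxt = max(remaining, key=lambda i: (min(sub[i, c] for c in chosen), -i))
        chosen.append(nxt)
        remaining.remove(nxt)
    chosen.sort()
    return SelectionResult(
        sample_ids=[members[i] for i in chosen],
        total_distance=_subset_score(sub, tuple(chosen)),
        method="greedy_maxmin",
    )


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(
        dist.values, index=dist.sample_ids, columns=dist.sample_ids
    ).to_csv(path, sep="\t", index_label="sample_id")
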