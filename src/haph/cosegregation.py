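"""Autosomal-dominant co-segregation filtering of exome genotype matrices.

Given affected/unaffected extreme-phenotype groups, a variant co-segregates
under a dominant model when enough affected animals carry at least one
alternate allele while (almost) no unaffected animal does.  A filter stage
is the pair of thresholds (min carriers among affected, max carriers among
unaffected); a cascade evaluates several stages — e.g. (5,0), (4,1), (4,0)
for a five-versus-five design — each independently on the class-filtered
variant list, and reports per-stage variant and distinct-gene counts.

Variants in the same gene whose carrier sets are bit-identical across all
samples are collapsed into a single cis-haplotype unit: with no observed
recombinant, the genotype data cannot distinguish them and they segregate
as one dominant allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, VariantRecord

logger = logging.getLogger(__name__)

#: Consequence classes retained by default: protein-changing point
#: variants and short coding indels.
DEFAULT_VARIANT_CLASSES = frozenset(
    {
        "nonsynonymous SNV",
        "stopgain",
        "stoploss",
        "frameshift insertion",
        "frameshift deletion",
        "nonframeshift insertion",
        "nonframeshift deletion",
    }
)

MISSING_POLICIES = ("as_noncarrier", "as_fail", "exclude_sample")


@dataclass(frozen=True)
class FilterConfig:
    """One co-segregation stage for an n_affected vs n_unaffected design."""

    min_affected_carriers: int
    max_unaffected_carriers: int
    n_affected: int
    n_unaffected: int
    variant_classes: frozenset[str] = DEFAULT_VARIANT_CLASSES
    missing_policy: str = "as_noncarrier"
    keep_unannotated: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.min_affected_carriers <= self.n_affected:
            raise ValueError("min_affected_carriers out of range")
        if not 0 <= self.max_unaffected_carriers <= self.n_unaffected:
            raise ValueError("max_unaffected_carriers out of range")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")

    @property
    def label(self) -> str:
        return f"({self.min_affected_carriers},{self.max_unaffected_carriers})"


@dataclass
class HaplotypeUnit:
    """Variants in one gene sharing a bit-identical carrier set."""

    members: list[VariantRecord]
    carrier_mask: np.ndarray
    gene: str

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class StageResult:
    config: FilterConfig
    passing: list[VariantRecord]
    units: list[HaplotypeUnit]

    @property
    def n_variants(self) -> int:
        return len(self.passing)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.passing:
            seen.setdefault(rec.gene or rec.variant_id)
        return list(seen)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class FilterReport:
    """Per-stage outcome of the cascade, plus the input bookkeeping."""

    stages: list[StageResult]
    n_input_variants: int
    n_class_filtered: int

    def summary(self) -> list[dict]:
        return [
            {
                "stage": s.config.label,
                "min_affected_carriers": s.config.min_affected_carriers,
                "max_unaffected_carriers": s.config.max_unaffected_carriers,
                "n_variants": s.n_variants,
                "n_genes": s.n_genes,
                "n_haplotype_units": len(s.units),
            }
            for s in self.stages
        ]


def carrier_vector(
    record: VariantRecord, missing_policy: str = "as_noncarrier"
) -> np.ndarray:
    """Dominant-model carrier flags: het or hom-alt means carrier.

    Missing genotypes map to non-carrier under ``as_noncarrier``; the
    other policies act at the filtering step (see :func:`dominant_filter`)
    and map to non-carrier here.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    g = record.genotypes
    return (g == HET) | (g == HOM_ALT)


def class_filter(
    records: Sequence[VariantRecord],
    classes: frozenset[str] | set[str] = DEFAULT_VARIANT_CLASSES,
    keep_unannotated: bool = False,
) -> list[VariantRecord]:
    """Keep variants whose consequence class is in the allowed set.

    Records with no class annotation are dropped (with a warning) unless
    ``keep_unannotated`` is set.
    """
    kept: list[VariantRecord] = []
    n_unannotated = 0
    for rec in records:
        if not rec.var_class:
            n_unannotated += 1
            if keep_unannotated:
                kept.append(rec)
            continue
        if rec.var_class in classes:
            kept.append(rec)
    if n_unannotated:
        action = "kept" if keep_unannotated else "dropped"
        logger.warning("%d unannotated variants %s", n_unannotated, action)
    return kept


def _status_masks(
    samples: Sequence[str], status: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    aff = np.zeros(len(samples), dtype=bool)
    unaff = np.zeros(len(samples), dtype=bool)
    for i, sid in enumerate(samples):
        st = status.get(sid)
        if st == "affected":
            aff[i] = True
        elif st == "unaffected":
            unaff[i] = True
        elif st is None:
            raise ValueError(f"sample {sid!r} has no status assignment")
        else:
            raise ValueError(
                f"sample {sid!r} has status {st!r}; indeterminate samples "
                "must be excluded before filtering"
            )
    return aff, unaff


def dominant_filter(
    matrix: GenotypeMatrix,
    status: Mapping[str, str],
    cfg: FilterConfig,
    pre_mask: np.ndarray | None = None,
) -> list[VariantRecord]:
    """Variants co-segregating with disease under the dominant model.

    A variant passes iff carriers among affected >= ``min_affected_carriers``
    and carriers among unaffected <= ``max_unaffected_carriers``.

    ``pre_mask`` is an optional (n_variants, n_samples) boolean array of
    genotype-quality failures (True = mask the call); masked calls are
    treated as missing, emulating upstream GQ-based genotype removal.

    Missing-call policies: ``as_noncarrier`` counts missing as hom-ref on
    both sides; ``as_fail`` fails any variant with a missing call in a
    statused sample; ``exclude_sample`` drops the call from both counts
    (equivalent counting to as_noncarrier, reported distinctly).
    """
    aff, unaff = _status_masks(matrix.samples, status)
    passing: list[VariantRecord] = []
    for vi, rec in enumerate(matrix.records):
        g = rec.genotypes
        if pre_mask is not None:
            g = np.where(pre_mask[vi], MISSING, g)
        missing = g == MISSING
        if cfg.missing_policy == "as_fail" and bool(missing[aff | unaff].any()):
            continue
        carrier = (g == HET) | (g == HOM_ALT)
        n_aff_carriers = int((carrier & aff).sum())
        n_unaff_carriers = int((carrier & unaff).sum())
        if (
            n_aff_carriers >= cfg.min_affected_carriers
            and n_unaff_carriers <= cfg.max_unaffected_carriers
        ):
            passing.append(rec)
    return passing


def collapse_cis(
    records: Sequence[VariantRecord], missing_policy: str = "as_noncarrier"
) -> list[HaplotypeUnit]:
    """Merge same-gene variants with bit-identical carrier sets.

    Variants with no observed recombinant carry no independent signal and
    are reported as one haplotype unit (e.g. a double variant in perfect
    linkage).  Singleton variants become single-member units.  The
    operation is idempotent.
    """
    groups: dict[tuple[str, bytes], HaplotypeUnit] = {}
    for rec in records:
        mask = carrier_vector(rec, missing_policy)
        key = (rec.gene or rec.variant_id, mask.tobytes())
        if key in groups:
            groups[key].members.append(rec)
        else:
            groups[key] = HaplotypeUnit(members=[rec], carrier_mask=mask, gene=key[0])
    return list(groups.values())


def run_cascade(
    matrix: GenotypeMatrix,
    status: Mapping[str, str],
    stages: Sequence[FilterConfig],
    pre_mask: np.ndarray | None = None,
) -> FilterReport:
    """Evaluate each filter stage independently on the class-filtered set.

    The class filter (and the optional quality pre-mask) of the first
    stage applies to all stages; stage thresholds then act independently,
    so a report row exists for every requested (min_affected,
    max_unaffected) pair and nesting between stages can be read off
    directly.
    """
    if not stages:
        raise ValueError("need at least one filter stage")
    records = matrix.records
    if pre_mask is not None:
        from dataclasses import replace as _replace

        records = [
            _replace(r, genotypes=np.where(pre_mask[i], MISSING, r.genotypes))
            for i, r in enumerate(records)
        ]
    first = stages[0]
    filtered = class_filter(records, first.variant_classes, first.keep_unannotated)
    sub = GenotypeMatrix(samples=matrix.samples, records=filtered)
    results = []
    for cfg in stages:
        passing = dominant_filter(sub, status, cfg)
        units = collapse_cis(passing, cfg.missing_policy)
        results.append(StageResult(config=cfg, passing=passing, units=units))
    return FilterReport(
        stages=results,
        n_input_variants=len(matrix.records),
        n_class_filtered=len(filtered),
    )


def default_stages(
    n_affected: int = 5, n_unaffected: int = 5, **kwargs
) -> list[FilterConfig]:
    """The (all, none), (n-1, 1), (n-1, 0) cascade for an extreme design."""
    mk = lambda lo, hi: FilterConfig(
        min_affected_carriers=lo,
        max_unaffected_carriers=hi,
        n_affected=n_affected,
        n_unaffected=n_unaffected,
        **kwargs,
    )
    return [mk(n_affected, 0), mk(n_affected - 1, 1), mk(n_affected - 1, 0)]
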