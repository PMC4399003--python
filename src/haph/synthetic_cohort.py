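"""Synthetic cohort generator for extreme-phenotype dominant-model studies.

The generator emulates the statistical structure of a high-altitude herd
segregating a dominant causal haplotype with incomplete penetrance:

* each animal carries the causal haplotype with probability
  ``carrier_freq`` (the population carrier frequency, ~0.41 in lowland
  Angus herds);
* carriers become affected (high mean PAP) with probability
  ``penetrance``; non-carriers become affected with the phenocopy
  probability (HAPH has non-genetic contributors, so this defaults to a
  small non-zero rate);
* animals are accepted by rejection sampling until the requested
  affected/unaffected case-control counts are filled;
* mean PAP is drawn from status-specific normal distributions truncated
  below at 15 mm Hg (extreme-affected 94.2 +- 5.3 mm Hg, unaffected
  30.8 +- 0.8 mm Hg by default);
* the causal haplotype is emitted as two heterozygous variant records in
  one gene with identical carrier sets (a perfect-linkage cis pair);
* background variants carry no phenotype association: per-variant
  population carrier frequencies are uniform over a configurable range
  and carrier states are drawn independently of status;
* ten microsatellite markers with uniform allele draws support the
  diversity-selection stage.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cosegregation import FilterConfig, class_filter, dominant_filter
from .io_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    ExpressionTable,
    GeneSet,
    GenotypeMatrix,
    MicrosatellitePanel,
    PhenotypeTable,
    VariantRecord,
)

PAP_TRUNCATION_MMHG = 15.0


class ConfigError(ValueError):
    """Simulation configuration that cannot produce the requested cohort."""


@dataclass(frozen=True)
class CohortSimConfig:
    """Generative parameters of a simulated high-altitude herd.

    Defaults reflect the first study herd: 20 affected vs 21 unaffected
    animals, a carrier frequency of 0.41, penetrance 0.75 at altitude and
    a 5% phenocopy rate, with extreme-group PAP distributions
    94.2 +- 5.3 / 30.8 +- 0.8 mm Hg.
    """

    n_affected: int = 20
    n_unaffected: int = 21
    penetrance: float = 0.75
    phenocopy: float = 0.05
    carrier_freq: float = 0.41
    background_variants: int = 500
    background_alt_freq_range: tuple[float, float] = (0.05, 0.5)
    synonymous_fraction: float = 0.3
    pap_affected_mean: float = 94.2
    pap_affected_sd: float = 5.3
    pap_unaffected_mean: float = 30.8
    pap_unaffected_sd: float = 0.8
    n_microsat_markers: int = 10
    n_alleles_per_marker: int = 8
    hardy_weinberg_genotypes: bool = False
    herd: str = "sim_herd"
    altitude_ft: float = 8000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigError("penetrance must lie in [0, 1]")
        if not 0.0 <= self.phenocopy <= 1.0:
            raise ConfigError("phenocopy must lie in [0, 1]")
        if not 0.0 < self.carrier_freq < 1.0:
            raise ConfigError("carrier_freq must lie in (0, 1)")
        if self.pap_affected_sd <= 0 or self.pap_unaffected_sd <= 0:
            raise ConfigError("PAP standard deviations must be positive")
        if self.n_affected < 1 or self.n_unaffected < 1:
            raise ConfigError("group sizes must be >= 1")
        lo, hi = self.background_alt_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("background_alt_freq_range must be ordered in [0,1]")
        p_affected = (
            self.carrier_freq * self.penetrance
            + (1 - self.carrier_freq) * self.phenocopy
        )
        if p_affected == 0.0 and self.n_affected > 0:
            raise ConfigError(
                "no animal can become affected (penetrance and phenocopy both 0)"
            )
        if p_affected == 1.0 and self.n_unaffected > 0:
            raise ConfigError("no animal can remain unaffected")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a simulated cohort, for evaluation only."""

    causal_gene: str
    causal_variant_ids: tuple[str, str]
    carrier_sample_ids: tuple[str, ...]


@dataclass
class SimulatedCohort:
    config: CohortSimConfig
    matrix: GenotypeMatrix
    phenotypes: PhenotypeTable
    microsatellites: MicrosatellitePanel
    truth: CohortTruth

    @property
    def status(self) -> dict[str, str]:
        return dict(
            zip(self.phenotypes.df["sample_id"], self.phenotypes.df["status"])
        )


# the cis pair emulated: two exon-12 substitutions in one HIF2a-like gene
_CAUSAL_GENE = "EPAS1"
_CAUSAL_VARIANTS = (
    ("11", 28662654, "G", "A", "c.G1816A:p.A606T"),
    ("11", 28662666, "G", "A", "c.G1828A:p.G610S"),
)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    while True:
        x = rng.normal(mean, sd)
        if x >= PAP_TRUNCATION_MMHG:
            return float(x)


def _draw_individuals(cfg: CohortSimConfig, rng: np.random.Generator):
    """Rejection-sample carrier/status pairs until both quotas are full."""
    need = {"affected": cfg.n_affected, "unaffected": cfg.n_unaffected}
    out: list[tuple[bool, str]] = []
    guard = 0
    max_draws = 10_000 * (cfg.n_affected + cfg.n_unaffected) + 10_000
    while need["affected"] > 0 or need["unaffected"] > 0:
        guard += 1
        if guard > max_draws:
            raise ConfigError(
                "rejection sampling failed to fill the requested groups; "
                "penetrance/phenocopy/carrier_freq make a group vanishingly rare"
            )
        carrier = rng.random() < cfg.carrier_freq
        p_aff = cfg.penetrance if carrier else cfg.phenocopy
        status = "affected" if rng.random() < p_aff else "unaffected"
        if need[status] > 0:
            need[status] -= 1
            out.append((carrier, status))
    return out


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Generate one cohort: genotypes, phenotypes, microsatellites, truth."""
    rng = np.random.default_rng(config.seed)
    individuals = _draw_individuals(config, rng)
    n = len(individuals)
    width = max(3, len(str(n)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    carriers = np.array([c for c, _ in individuals], dtype=bool)
    statuses = [s for _, s in individuals]

    pap = np.array(
        [
            _truncated_normal(
                rng,
                config.pap_affected_mean if s == "affected" else config.pap_unaffected_mean,
                config.pap_affected_sd if s == "affected" else config.pap_unaffected_sd,
            )
            for s in statuses
        ]
    )
    phenotypes = PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "herd": config.herd,
                "altitude_ft": config.altitude_ft,
                "mean_pap": np.round(pap, 1),
                "status": statuses,
            }
        )
    )

    # causal cis pair: identical carrier sets by construction
    if config.hardy_weinberg_genotypes:
        # P(hom-alt | carrier) under HWE with carrier freq = q(2-q)
        q = 1.0 - np.sqrt(1.0 - config.carrier_freq)
        p_hom = q * q / config.carrier_freq
        hom = rng.random(n) < p_hom
        causal_gt = np.where(carriers, np.where(hom, HOM_ALT, HET), HOM_REF)
    else:
        causal_gt = np.where(carriers, HET, HOM_REF)
    causal_gt = causal_gt.astype(np.int8)
    records = [
        VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            genotypes=causal_gt.copy(),
            gene=_CAUSAL_GENE,
            var_class="nonsynonymous SNV",
            annotation=ann,
        )
        for chrom, pos, ref, alt, ann in _CAUSAL_VARIANTS
    ]

    # background variants: carrier state independent of phenotype
    lo, hi = config.background_alt_freq_range
    freqs = rng.uniform(lo, hi, size=config.background_variants)
    for j in range(config.background_variants):
        gt = np.where(rng.random(n) < freqs[j], HET, HOM_REF).astype(np.int8)
        var_class = (
            "synonymous SNV"
            if rng.random() < config.synonymous_fraction
            else "nonsynonymous SNV"
        )
        records.append(
            VariantRecord(
                chrom=str(1 + j % 29),
                pos=100_000 + 1_000 * j,
                ref="C",
                alt="T",
                genotypes=gt,
                gene=f"BG{j:04d}",
                var_class=var_class,
                annotation="",
            )
        )
    matrix = GenotypeMatrix(samples=sample_ids, records=records)

    # microsatellites: uniform allele labels, independent across markers
    labels = np.array(
        [str(150 + 2 * k) for k in range(config.n_alleles_per_marker)], dtype=object
    )
    draws = rng.integers(
        0, config.n_alleles_per_marker, size=(n, config.n_microsat_markers, 2)
    )
    panel = MicrosatellitePanel(
        sample_ids=sample_ids,
        marker_names=[f"marker{k + 1}" for k in range(config.n_microsat_markers)],
        alleles=labels[draws],
    )

    truth = CohortTruth(
        causal_gene=_CAUSAL_GENE,
        causal_variant_ids=tuple(r.variant_id for r in records[:2]),
        carrier_sample_ids=tuple(
            sid for sid, c in zip(sample_ids, carriers) if c
        ),
    )
    return SimulatedCohort(
        config=config,
        matrix=matrix,
        phenotypes=phenotypes,
        microsatellites=panel,
        truth=truth,
    )


def simulate_expression(
    cohort: SimulatedCohort,
    gene_set: GeneSet,
    upshift: float = 2.0,
    n_background_genes: int = 1000,
    noise_sd: float = 0.3,
    seed: int = 0,
    baseline: float = 9.0,
    below_floor_fraction: float = 0.1,
    below_floor_level: float = 5.0,
) -> ExpressionTable:
    """log2 expression with gene-set genes shifted up in affected carriers.

    Background genes are Normal(baseline, noise_sd) in everyone; gene-set
    genes gain ``upshift`` log2 units in affected carrier animals only.  A
    ``below_floor_fraction`` of all genes is re-based below the reliable-
    signal floor (and left unshifted) to exercise the expression-floor
    filter downstream.
    """
    if upshift < 0:
        raise ValueError("upshift must be >= 0")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    rng = np.random.default_rng(seed)
    samples = cohort.phenotypes.sample_ids
    status = cohort.status
    carrier_set = set(cohort.truth.carrier_sample_ids)
    shifted_samples = np.array(
        [status[s] == "affected" and s in carrier_set for s in samples]
    )
    genes = list(gene_set) + [f"BGENE{j:05d}" for j in range(n_background_genes)]
    n_genes, n_samples = len(genes), len(samples)
    below = rng.random(n_genes) < below_floor_fraction
    base = np.where(below, below_floor_level, baseline)
    vals = rng.normal(0.0, noise_sd, size=(n_genes, n_samples)) + base[:, None]
    in_set = np.array([g in set(gene_set.symbols) for g in genes])
    shift_rows = in_set & ~below
    vals[np.ix_(shift_rows, shifted_samples)] += upshift
    return ExpressionTable(pd.DataFrame(vals, index=genes, columns=samples))


@dataclass(frozen=True)
class PowerResult:
    survival_probability: float
    mean_false_genes: float
    n_background_variants: int
    reps: int


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds derived from one root seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def power_of_design(
    config: CohortSimConfig,
    filter_cfg: FilterConfig,
    reps: int,
    seed: int = 0,
) -> PowerResult:
    """How often the planted haplotype survives one filter stage.

    Runs ``reps`` independent cohort simulations sized to the filter
    design, applies the consequence-class filter and the dominant
    co-segregation stage, and reports (i) the fraction of replicates in
    which the causal gene passes and (ii) the mean number of passing
    non-causal genes per replicate.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = replace(
        config,
        n_affected=filter_cfg.n_affected,
        n_unaffected=filter_cfg.n_unaffected,
    )
    seeds = child_seeds(seed, reps)
    n_survive = 0
    n_false = 0
    for s in seeds:
        cohort = simulate_cohort(replace(cfg, seed=s))
        filtered = class_filter(
            cohort.matrix.records,
            filter_cfg.variant_classes,
            filter_cfg.keep_unannotated,
        )
        sub = GenotypeMatrix(samples=cohort.matrix.samples, records=filtered)
        passing = dominant_filter(sub, cohort.status, filter_cfg)
        genes = {r.gene for r in passing}
        if cohort.truth.causal_gene in genes:
            n_survive += 1
        n_false += len(genes - {cohort.truth.causal_gene})
    return PowerResult(
        survival_probability=n_survive / reps,
        mean_false_genes=n_false / reps,
        n_background_variants=config.background_variants,
        reps=reps,
    )
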