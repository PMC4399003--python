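"""End-to-end orchestration: simulate -> diversity -> filter -> assoc -> enrich.

One structured config (YAML) drives every stage; a single root seed is
split deterministically per stage, so identical config+seed reproduces
identical artifacts and an identical JSON run report.  Every intermediate
is persisted in the formats the io module reads, so any stage can be
re-run standalone from its persisted inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, Field

from . import association as assoc_mod
from . import cosegregation as coseg
from . import diversity as div_mod
from . import enrichment as enr_mod
from . import io_formats as io
from . import synthetic_cohort as sim_mod

logger = logging.getLogger(__name__)


class ClassifyConfig(BaseModel):
    affected_min: float = 50.0
    unaffected_max: float = 39.0
    affected_inclusive: bool = False
    unaffected_inclusive: bool = False


class DiversityConfig(BaseModel):
    k: int = 5
    budget: int = div_mod.DEFAULT_SUBSET_BUDGET


class FilterStageSpec(BaseModel):
    min_affected_carriers: int
    max_unaffected_carriers: int


class AssocConfig(BaseModel):
    prevalence: float = 0.5
    # optional pre-tabulated per-herd counts [a, b, c, d]; when given, the
    # association stage runs on these instead of the genotype matrix
    tables: Optional[list[list[int]]] = None


class EnrichStageConfig(BaseModel):
    upshift: float = 2.0
    n_background_genes: int = 1000
    noise_sd: float = 0.3
    gene_set_size: int = 171
    expression_floor: float = 7.0
    p_threshold: float = 0.05
    fc_threshold: float = 1.25
    expected_mode: str = "rounded_counts"


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "haph_run"
    stages: list[str] = Field(
        default_factory=lambda: ["simulate", "diversity", "filter", "assoc", "enrich"]
    )
    simulate: dict[str, Any] = Field(default_factory=dict)
    classify: ClassifyConfig = ClassifyConfig()
    diversity: DiversityConfig = DiversityConfig()
    filter_stages: Optional[list[FilterStageSpec]] = None
    assoc: AssocConfig = AssocConfig()
    enrich: EnrichStageConfig = EnrichStageConfig()
    # optional real inputs; when absent the simulate stage provides them
    vcf: Optional[str] = None
    phenotypes: Optional[str] = None
    microsatellites: Optional[str] = None
    expression: Optional[str] = None
    gene_set: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


class StageCounts(BaseModel):
    stage: str
    min_affected_carriers: int
    max_unaffected_carriers: int
    n_variants: int
    n_genes: int
    n_haplotype_units: int


class FilterSection(BaseModel):
    n_input_variants: int
    n_class_filtered: int
    n_affected: int
    n_unaffected: int
    stages: list[StageCounts]
    final_stage_genes: list[str]


class GeneAssociation(BaseModel):
    gene: str
    table: list[int]  # a, b, c, d
    chi2: Optional[float]
    chi2_p: Optional[float]
    relative_risk: Optional[float]
    rr_ci: Optional[list[float]]
    odds_ratio: Optional[float]
    or_ci: Optional[list[float]]
    ppv: Optional[float]
    npv: Optional[float]


class AssocSection(BaseModel):
    prevalence: float
    per_gene: list[GeneAssociation]
    pooled: Optional[GeneAssociation] = None


class EnrichSection(BaseModel):
    n_expressed: int
    observed: list[int]
    expected: list[float]
    statistic: Optional[float]
    pvalue: Optional[float]
    df: int
    mode: str
    background_rates: list[float]


class DiversitySection(BaseModel):
    affected_selected: list[str]
    unaffected_selected: list[str]
    method: str


class RunReport(BaseModel):
    """Aggregated machine-readable outcome of one pipeline run."""

    seed: int
    stages_run: list[str]
    artifact_digests: dict[str, str] = Field(default_factory=dict)
    diversity: Optional[DiversitySection] = None
    filter: Optional[FilterSection] = None
    association: Optional[AssocSection] = None
    enrichment: Optional[EnrichSection] = None
    truth: Optional[dict[str, Any]] = None


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _estimate_or_none(est) -> tuple[Optional[float], Optional[list[float]]]:
    import math

    point = None if est.point != est.point else float(est.point)
    if math.isnan(est.lower) or math.isnan(est.upper):
        return point, None
    return point, [float(est.lower), float(est.upper)]


def _gene_association(
    gene: str, table: assoc_mod.ContingencyTable2x2, prevalence: float
) -> GeneAssociation:
    chi = assoc_mod.chi2_2x2(table)
    rr_point = rr_ci = or_point = or_ci = None
    ppv = npv = None
    try:
        rr_point, rr_ci = _estimate_or_none(assoc_mod.relative_risk(table))
    except ValueError:
        pass
    or_point, or_ci = _estimate_or_none(assoc_mod.odds_ratio(table))
    if table.a + table.b > 0 and table.c + table.d > 0:
        ppv, npv = assoc_mod.predictive_values(
            table.sensitivity, table.specificity, prevalence
        )
    return GeneAssociation(
        gene=gene,
        table=[table.a, table.b, table.c, table.d],
        chi2=None if chi.statistic != chi.statistic else chi.statistic,
        chi2_p=None if chi.pvalue != chi.pvalue else chi.pvalue,
        relative_risk=rr_point,
        rr_ci=rr_ci,
        odds_ratio=or_point,
        or_ci=or_ci,
        ppv=ppv,
        npv=npv,
    )


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the configured stages in order and persist all artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = sim_mod.child_seeds(cfg.seed, 4)  # simulate, expression, spare, spare
    report = RunReport(seed=cfg.seed, stages_run=[])
    digests = report.artifact_digests

    cohort = None
    failure_marker = out / "FAILED"
    if failure_marker.exists():
        failure_marker.unlink()

    def fail(stage: str, exc: Exception):
        failure_marker.write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- inputs: simulate or load -------------------------------------
    if "simulate" in cfg.stages:
        try:
            sim_cfg = sim_mod.CohortSimConfig(**{**cfg.simulate, "seed": seeds[0]})
            cohort = sim_mod.simulate_cohort(sim_cfg)
            io.write_vcf(cohort.matrix, out / "cohort.vcf")
            io.write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv")
            io.write_microsatellites(cohort.microsatellites, out / "microsatellites.tsv")
            (out / "truth.json").write_text(
                json.dumps(asdict(cohort.truth), indent=2) + "\n"
            )
            report.truth = asdict(cohort.truth)
            for name in ("cohort.vcf", "phenotypes.tsv", "microsatellites.tsv"):
                digests[name] = _digest(out / name)
            matrix, phenotypes, panel = (
                cohort.matrix,
                cohort.phenotypes,
                cohort.microsatellites,
            )
            report.stages_run.append("simulate")
        except Exception as exc:  # pragma: no cover - defensive
            fail("simulate", exc)
    else:
        if cfg.vcf is None or cfg.phenotypes is None:
            if cfg.assoc.tables is None:
                raise ValueError(
                    "without the simulate stage, provide vcf+phenotypes paths "
                    "or pre-tabulated assoc tables"
                )
            matrix = phenotypes = panel = None
        else:
            matrix = io.read_vcf(cfg.vcf)
            phenotypes = io.read_phenotypes(cfg.phenotypes)
            panel = (
                io.read_microsatellites(cfg.microsatellites)
                if cfg.microsatellites
                else None
            )

    # ---- status assignment --------------------------------------------
    status: dict[str, str] = {}
    if phenotypes is not None:
        cc = cfg.classify
        df = phenotypes.df
        assigned = [
            s
            if isinstance(s, str) and s in ("affected", "unaffected", "indeterminate")
            else assoc_mod.classify_status(
                pap,
                cc.affected_min,
                cc.unaffected_max,
                cc.affected_inclusive,
                cc.unaffected_inclusive,
            )
            for s, pap in zip(df["status"], df["mean_pap"])
        ]
        phenotypes.df["status"] = assigned
        status = dict(zip(df["sample_id"], assigned))

    # ---- diversity selection ------------------------------------------
    selected: list[str] | None = None
    if "diversity" in cfg.stages and panel is not None:
        try:
            dist = div_mod.pairwise_distance(panel)
            div_mod.write_distance_matrix(dist, out / "distance_matrix.tsv")
            digests["distance_matrix.tsv"] = _digest(out / "distance_matrix.tsv")
            sel_a = div_mod.select_diverse_subset(
                dist, phenotypes, cfg.diversity.k, "affected", cfg.diversity.budget
            )
            sel_u = div_mod.select_diverse_subset(
                dist, phenotypes, cfg.diversity.k, "unaffected", cfg.diversity.budget
            )
            selected = sel_a.sample_ids + sel_u.sample_ids
            (out / "selected_samples.txt").write_text(
                "".join(f"{s}\n" for s in selected)
            )
            report.diversity = DiversitySection(
                affected_selected=sel_a.sample_ids,
                unaffected_selected=sel_u.sample_ids,
                method=sel_a.method,
            )
            report.stages_run.append("diversity")
        except Exception as exc:
            fail("diversity", exc)

    # ---- co-segregation filter ----------------------------------------
    filter_report = None
    if "filter" in cfg.stages and matrix is not None:
        try:
            subset_ids = selected or [
                s for s in matrix.samples if status.get(s) in ("affected", "unaffected")
            ]
            sub = matrix.subset_samples(subset_ids)
            n_aff = sum(status[s] == "affected" for s in subset_ids)
            n_unaff = sum(status[s] == "unaffected" for s in subset_ids)
            if cfg.filter_stages:
                stages = [
                    coseg.FilterConfig(
                        min_affected_carriers=s.min_affected_carriers,
                        max_unaffected_carriers=s.max_unaffected_carriers,
                        n_affected=n_aff,
                        n_unaffected=n_unaff,
                    )
                    for s in cfg.filter_stages
                ]
            else:
                stages = coseg.default_stages(n_aff, n_unaff)
            filter_report = coseg.run_cascade(
                sub, {s: status[s] for s in subset_ids}, stages
            )
            final = filter_report.stages[-1]
            report.filter = FilterSection(
                n_input_variants=filter_report.n_input_variants,
                n_class_filtered=filter_report.n_class_filtered,
                n_affected=n_aff,
                n_unaffected=n_unaff,
                stages=[StageCounts(**row) for row in filter_report.summary()],
                final_stage_genes=final.genes,
            )
            _write_filter_tsv(filter_report, out / "filter_report.tsv")
            (out / "filter_summary.json").write_text(
                json.dumps(filter_report.summary(), indent=2) + "\n"
            )
            digests["filter_report.tsv"] = _digest(out / "filter_report.tsv")
            report.stages_run.append("filter")
        except Exception as exc:
            fail("filter", exc)

    # ---- association on the full cohort -------------------------------
    if "assoc" in cfg.stages:
        try:
            per_gene: list[GeneAssociation] = []
            pooled = None
            if cfg.assoc.tables is not None:
                tables = [
                    assoc_mod.ContingencyTable2x2(*row) for row in cfg.assoc.tables
                ]
                per_gene = [
                    _gene_association(f"herd{i + 1}", t, cfg.assoc.prevalence)
                    for i, t in enumerate(tables)
                ]
                if len(tables) > 1:
                    pooled = _gene_association(
                        "pooled",
                        assoc_mod.pool_tables(tables),
                        cfg.assoc.prevalence,
                    )
            elif matrix is not None:
                genes = (
                    report.filter.final_stage_genes
                    if report.filter is not None
                    else sorted({r.gene for r in matrix.records if r.gene})
                )
                for gene in genes:
                    recs = [r for r in matrix.records if r.gene == gene]
                    units = coseg.collapse_cis(recs)
                    unit = max(units, key=lambda u: u.n_members)
                    carriers = {
                        s
                        for s, c in zip(matrix.samples, unit.carrier_mask)
                        if c
                    }
                    a = b = c_ = d = 0
                    for s in matrix.samples:
                        st = status.get(s)
                        if st == "affected":
                            a, b = (a + 1, b) if s in carriers else (a, b + 1)
                        elif st == "unaffected":
                            c_, d = (c_ + 1, d) if s in carriers else (c_, d + 1)
                    table = assoc_mod.ContingencyTable2x2(a, b, c_, d)
                    per_gene.append(
                        _gene_association(gene, table, cfg.assoc.prevalence)
                    )
                per_gene.sort(key=lambda g: (g.chi2_p is None, g.chi2_p, g.gene))
            report.association = AssocSection(
                prevalence=cfg.assoc.prevalence, per_gene=per_gene, pooled=pooled
            )
            report.stages_run.append("assoc")
        except Exception as exc:
            fail("assoc", exc)

    # ---- expression enrichment ----------------------------------------
    if "enrich" in cfg.stages:
        try:
            ec = cfg.enrich
            e_cfg = enr_mod.EnrichmentConfig(
                expression_floor=ec.expression_floor,
                p_threshold=ec.p_threshold,
                fc_threshold=ec.fc_threshold,
                expected_mode=ec.expected_mode,
            )
            if cfg.expression is not None:
                expr = io.read_expression(cfg.expression)
                gene_set = io.read_gene_set(cfg.gene_set)
                groups = status
            elif cohort is not None:
                if cfg.gene_set is not None:
                    gene_set = io.read_gene_set(cfg.gene_set)
                else:
                    gene_set = io.GeneSet(
                        symbols=tuple(
                            f"HIF_TARGET{j:03d}" for j in range(ec.gene_set_size)
                        ),
                        name="synthetic_hypoxia_up",
                    )
                expr = sim_mod.simulate_expression(
                    cohort,
                    gene_set,
                    upshift=ec.upshift,
                    n_background_genes=ec.n_background_genes,
                    noise_sd=ec.noise_sd,
                    seed=seeds[1],
                )
                io.write_expression(expr, out / "expression.tsv")
                io.write_gene_set(gene_set, out / "gene_set.txt")
                digests["expression.tsv"] = _digest(out / "expression.tsv")
                groups = cohort.status
            else:
                raise ValueError("enrich stage needs an expression source")
            result, calls = enr_mod.run_enrichment(expr, gene_set, groups, e_cfg)
            rates = enr_mod.background_rates(expr, groups, e_cfg)
            report.enrichment = EnrichSection(
                n_expressed=result.n_expressed,
                observed=list(result.observed),
                expected=list(result.expected),
                statistic=None if result.statistic != result.statistic else result.statistic,
                pvalue=None if result.pvalue != result.pvalue else result.pvalue,
                df=result.df,
                mode=result.mode,
                background_rates=list(rates),
            )
            _write_calls_tsv(calls, out / "gene_calls.tsv")
            report.stages_run.append("enrich")
        except Exception as exc:
            fail("enrich", exc)

    (out / "run_report.json").write_text(
        report.model_dump_json(indent=2) + "\n"
    )
    logger.info(
        "pipeline done: stages=%s artifacts=%s", report.stages_run, sorted(digests)
    )
    return report


def _write_filter_tsv(filter_report, path: Path) -> None:
    rows = ["stage\tvariant_id\tgene\tannotation"]
    for stage in filter_report.stages:
        for rec in stage.passing:
            rows.append(
                f"{stage.config.label}\t{rec.variant_id}\t{rec.gene}\t{rec.annotation}"
            )
    path.write_text("\n".join(rows) + "\n")


def _write_calls_tsv(calls: dict[str, str], path: Path) -> None:
    rows = ["gene\tcall"] + [f"{g}\t{c}" for g, c in calls.items()]
    path.write_text("\n".join(rows) + "\n")


def emit_paper_tables(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Render the run report as flat TSV tables.

    Writes a stage-count table (cascade overview), a passing-gene table
    and a statistics table; each re-parses into the same numbers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    stage_path = out / "stage_counts.tsv"
    lines = ["stage\tmin_affected_carriers\tmax_unaffected_carriers\tn_variants\tn_genes\tn_haplotype_units"]
    if report.filter is not None:
        for s in report.filter.stages:
            lines.append(
                f"{s.stage}\t{s.min_affected_carriers}\t{s.max_unaffected_carriers}"
                f"\t{s.n_variants}\t{s.n_genes}\t{s.n_haplotype_units}"
            )
    stage_path.write_text("\n".join(lines) + "\n")
    paths["stage_counts"] = stage_path

    gene_path = out / "passing_genes.tsv"
    lines = ["gene"]
    if report.filter is not None:
        lines += report.filter.final_stage_genes
    gene_path.write_text("\n".join(lines) + "\n")
    paths["passing_genes"] = gene_path

    stat_path = out / "statistics.tsv"
    lines = ["gene\ta\tb\tc\td\tchi2\tchi2_p\trelative_risk\todds_ratio\tppv\tnpv"]
    if report.association is not None:
        entries = list(report.association.per_gene)
        if report.association.pooled is not None:
            entries.append(report.association.pooled)
        for g in entries:
            a, b, c, d = g.table
            fmt = lambda v: "" if v is None else repr(float(v))
            lines.append(
                f"{g.gene}\t{a}\t{b}\t{c}\t{d}\t{fmt(g.chi2)}\t{fmt(g.chi2_p)}"
                f"\t{fmt(g.relative_risk)}\t{fmt(g.odds_ratio)}\t{fmt(g.ppv)}\t{fmt(g.npv)}"
            )
    stat_path.write_text("\n".join(lines) + "\n")
    paths["statistics"] = stat_path
    return paths
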