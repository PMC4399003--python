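"""Readers and writers for every external format the pipeline touches.

The pipeline exchanges data through a small set of plain-text formats:

* a minimal VCF v4.2 dialect (``CHROM POS ID REF ALT QUAL FILTER INFO
  FORMAT`` + per-sample ``GT``; the ``INFO`` keys ``GENE``, ``CLASS`` and
  ``ANN`` carry the gene symbol, consequence class and free-text
  annotation);
* tab-separated phenotype tables (``sample_id``, ``herd``, ``altitude_ft``,
  ``mean_pap``, optional ``status``);
* tab-separated microsatellite tables (``sample_id`` plus two allele
  columns per marker, ``marker1_a``, ``marker1_b``, ...);
* tab-separated log2 expression matrices (genes in rows, samples in
  columns);
* plain-text gene-set lists (one symbol per line, ``#`` comments).

Genotypes are stored as small integer codes with explicit missingness;
phased and unphased calls are treated identically and multi-allelic
records are split into biallelic records on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Genotype codes (dominant-model semantics live in cosegregation, not here).
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


class VCFParseError(ValueError):
    """Raised for malformed VCF input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class SchemaError(ValueError):
    """Raised when a tabular input is missing required structure."""


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample genotype codes.

    ``genotypes`` holds one code per sample (HOM_REF/HET/HOM_ALT/MISSING)
    in the sample order of the owning :class:`GenotypeMatrix`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    gene: str = ""
    var_class: str = ""
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError("VariantRecord holds exactly one alternate allele")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class GenotypeMatrix:
    """Variants x samples; the substrate of the co-segregation filter."""

    samples: list[str]
    records: list[VariantRecord]

    def __post_init__(self) -> None:
        n = len(self.samples)
        for rec in self.records:
            if len(rec.genotypes) != n:
                raise ValueError(
                    f"{rec.variant_id}: {len(rec.genotypes)} genotypes for "
                    f"{n} samples"
                )

    def __len__(self) -> int:
        return len(self.records)

    def genotype_array(self) -> np.ndarray:
        """(n_variants, n_samples) int8 array of genotype codes."""
        if not self.records:
            return np.empty((0, len(self.samples)), dtype=np.int8)
        return np.vstack([rec.genotypes for rec in self.records])

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = []
        for sid in sample_ids:
            try:
                idx.append(self.samples.index(sid))
            except ValueError:
                raise KeyError(f"sample {sid!r} not present in matrix") from None
        take = np.asarray(idx, dtype=int)
        recs = [replace(r, genotypes=r.genotypes[take]) for r in self.records]
        return GenotypeMatrix(samples=list(sample_ids), records=recs)


@dataclass(frozen=True)
class GeneSet:
    """Ordered, de-duplicated collection of gene symbols."""

    symbols: tuple[str, ...]
    name: str = ""

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: object) -> bool:
        return symbol in set(self.symbols)


@dataclass
class PhenotypeTable:
    """Per-animal phenotype rows, backed by a DataFrame.

    Columns: ``sample_id``, ``mean_pap`` (mm Hg, required), ``herd``,
    ``altitude_ft`` and ``status`` (optional).  ``status`` values are
    ``affected`` / ``unaffected`` / ``indeterminate`` or NA when not yet
    assigned.
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "mean_pap")
    OPTIONAL = ("herd", "altitude_ft", "status")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise SchemaError(f"phenotype table missing column {col!r}")
        if self.df["sample_id"].duplicated().any():
            dupes = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"]
            raise SchemaError(f"duplicated sample_id(s): {sorted(set(dupes))}")
        pap = pd.to_numeric(self.df["mean_pap"], errors="coerce")
        if pap.isna().any():
            bad = self.df.loc[pap.isna(), "sample_id"].tolist()
            raise ValueError(f"non-numeric mean_pap for samples {bad}")
        if (pap <= 0).any():
            raise ValueError("mean_pap must be positive")
        self.df = self.df.assign(mean_pap=pap).reset_index(drop=True)
        if "status" not in self.df.columns:
            self.df["status"] = pd.NA

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def status_of(self, sample_id: str) -> str | None:
        row = self.df.loc[self.df["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        val = row["status"].iloc[0]
        return None if pd.isna(val) else str(val)

    def samples_with_status(self, status: str) -> list[str]:
        mask = self.df["status"] == status
        return self.df.loc[mask, "sample_id"].tolist()


@dataclass
class MicrosatellitePanel:
    """Two alleles per marker per animal; missing alleles are empty strings."""

    sample_ids: list[str]
    marker_names: list[str]
    # shape (n_samples, n_markers, 2), dtype object (allele labels as str)
    alleles: np.ndarray

    def __post_init__(self) -> None:
        expect = (len(self.sample_ids), len(self.marker_names), 2)
        if self.alleles.shape != expect:
            raise SchemaError(
                f"allele array shape {self.alleles.shape} != {expect}"
            )

    def profile(self, sample_id: str) -> np.ndarray:
        return self.alleles[self.sample_ids.index(sample_id)]


@dataclass
class ExpressionTable:
    """log2 expression values, genes in rows and samples in columns."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dupes = self.df.index[self.df.index.duplicated()].tolist()
            raise SchemaError(f"duplicated gene symbols: {sorted(set(dupes))}")
        vals = self.df.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals) | np.isnan(vals)):
            raise ValueError("expression values must be finite or NaN")

    @property
    def genes(self) -> list[str]:
        return self.df.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.df.columns.tolist()


# ---------------------------------------------------------------------------
# VCF


def _parse_info(info: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if info in (".", ""):
        return out
    for item in info.split(";"):
        if "=" in item:
            key, val = item.split("=", 1)
            out[key] = val
        else:
            out[item] = ""
    return out


def _split_gt(gt_field: str, alt_index: int, line_number: int) -> int:
    """Map one GT subfield onto a genotype code for the given alt allele."""
    gt = gt_field.split(":", 1)[0]
    alleles = re.split(r"[/|]", gt)
    if not 1 <= len(alleles) <= 2:
        raise VCFParseError(f"cannot parse GT {gt!r}", line_number)
    if any(a == "." for a in alleles):
        return MISSING
    try:
        counts = sum(int(a) == alt_index for a in alleles)
    except ValueError:
        raise VCFParseError(f"non-numeric allele in GT {gt!r}", line_number)
    if len(alleles) == 1:  # haploid call: carrier iff the allele matches
        return HOM_ALT if counts == 1 else HOM_REF
    return (HOM_REF, HET, HOM_ALT)[counts]


def read_vcf(path: str | Path, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a minimal VCF v4.2 into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into one biallelic record per ALT
    allele; ``./.`` (and any partially missing call) becomes MISSING.
    Phase separators are ignored.  Records are returned in file order.
    """
    samples: list[str] | None = None
    records: list[VariantRecord] = []
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10 or cols[8] != "FORMAT":
                    raise VCFParseError(
                        "header must contain FORMAT and >=1 sample column",
                        lineno,
                    )
                samples = cols[9:]
                continue
            if samples is None:
                raise VCFParseError("record before #CHROM header", lineno)
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise VCFParseError(
                    f"expected {9 + len(samples)} columns, got {len(cols)}",
                    lineno,
                )
            chrom, pos_s, _id, ref, alt_field, _qual, _filt, info_s, fmt = cols[:9]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VCFParseError(f"non-integer POS {pos_s!r}", lineno)
            if "GT" not in fmt.split(":"):
                raise VCFParseError("FORMAT lacks GT", lineno)
            if fmt.split(":")[0] != "GT":
                raise VCFParseError("GT must be the first FORMAT key", lineno)
            info = _parse_info(info_s)
            alts = alt_field.split(",")
            for alt_index, alt in enumerate(alts, start=1):
                gts = np.array(
                    [_split_gt(c, alt_index, lineno) for c in cols[9:]],
                    dtype=np.int8,
                )
                records.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        genotypes=gts,
                        gene=info.get("GENE", ""),
                        var_class=info.get("CLASS", ""),
                        annotation=info.get("ANN", ""),
                    )
                )
    if samples is None:
        raise VCFParseError("no #CHROM header found in file")
    matrix = GenotypeMatrix(samples=samples, records=records)
    if sample_subset is not None:
        matrix = matrix.subset_samples(sample_subset)
    return matrix


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix in the minimal VCF dialect read by :func:`read_vcf`.

    Round-trip guarantee: re-reading a written file reproduces CHROM, POS,
    REF, ALT, GT and the GENE/CLASS/ANN annotations exactly.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    for rec in matrix.records:
        info_items = []
        if rec.gene:
            info_items.append(f"GENE={rec.gene}")
        if rec.var_class:
            info_items.append(f"CLASS={rec.var_class}")
        if rec.annotation:
            info_items.append(f"ANN={rec.annotation}")
        info = ";".join(info_items) if info_items else "."
        gts = "\t".join(_GT_STRINGS[int(g)] for g in rec.genotypes)
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a tab-separated phenotype table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "herd": str, "status": str})
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    df = table.df.copy()
    cols = [c for c in ("sample_id", "herd", "altitude_ft", "mean_pap", "status") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Microsatellites

_MARKER_COL = re.compile(r"^(?P<marker>.+)_(?P<slot>[ab])$")


def read_microsatellites(path: str | Path) -> MicrosatellitePanel:
    """Read a microsatellite TSV with columns ``sample_id, m1_a, m1_b, ...``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise SchemaError("microsatellite table missing column 'sample_id'")
    markers: list[str] = []
    for col in df.columns:
        m = _MARKER_COL.match(col)
        if m and m.group("slot") == "a":
            marker = m.group("marker")
            if f"{marker}_b" not in df.columns:
                raise SchemaError(f"marker {marker!r} has _a column but no _b")
            markers.append(marker)
    if not markers:
        raise SchemaError("no marker columns (expected pairs like marker1_a/_b)")
    sample_ids = df["sample_id"].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise SchemaError("duplicated sample_id in microsatellite table")
    alleles = np.empty((len(sample_ids), len(markers), 2), dtype=object)
    for j, marker in enumerate(markers):
        alleles[:, j, 0] = df[f"{marker}_a"].to_numpy()
        alleles[:, j, 1] = df[f"{marker}_b"].to_numpy()
    n_missing = int((alleles == "").sum())
    if n_missing:
        logger.warning("microsatellite table has %d missing allele slots", n_missing)
    return MicrosatellitePanel(sample_ids=sample_ids, marker_names=markers, alleles=alleles)


def write_microsatellites(panel: MicrosatellitePanel, path: str | Path) -> None:
    data: dict[str, list[str]] = {"sample_id": panel.sample_ids}
    for j, marker in enumerate(panel.marker_names):
        data[f"{marker}_a"] = list(panel.alleles[:, j, 0])
        data[f"{marker}_b"] = list(panel.alleles[:, j, 1])
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a log2 expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionTable(df)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    out = table.df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets


def read_gene_set(path: str | Path, name: str = "") -> GeneSet:
    """Read a plain-text gene list: one symbol per line, ``#`` comments.

    Duplicates collapse to the first occurrence; an empty file yields an
    empty set with a warning rather than an error.
    """
    seen: dict[str, None] = {}
    with open(path, "r", newline=None) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                seen.setdefault(line)
    if not seen:
        logger.warning("gene set file %s contains no symbols", path)
    return GeneSet(symbols=tuple(seen), name=name or Path(path).stem)


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
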