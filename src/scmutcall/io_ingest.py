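"""Input/output and count collation.

Reads every external format the caller consumes (cell-metadata TSV, allele
count TSV, candidate-locus and SNP-mask VCF, BED6/GFF3 gene annotation,
FASTA reference, barcoded BAM) and collates per-cell allele counts into the
sparse matrix the rest of the pipeline operates on.

Coordinates are 1-based inclusive (VCF convention) throughout.
Mitochondrial contig aliases ("chrM", "chrMT", "M") are normalized to "MT";
mitochondrial loci are processed exactly like autosomal ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")
_MT_ALIASES = {"MT", "CHRM", "CHRMT", "M"}

COUNT_COLUMNS = ["cell_id", "chrom", "pos", "ref", "alt", "ref_count", "var_count"]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input violating a semantic invariant."""


def normalize_chrom(chrom: str) -> str:
    """Map mitochondrial contig aliases to the canonical 'MT' label."""
    return "MT" if chrom.upper() in _MT_ALIASES else chrom


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class GenomicLocus(NamedTuple):
    """A single-nucleotide substitution site, 1-based."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    @classmethod
    def make(cls, chrom: str, pos: int, ref_base: str, alt_base: str) -> "GenomicLocus":
        chrom = normalize_chrom(str(chrom))
        pos = int(pos)
        ref_base, alt_base = ref_base.upper(), alt_base.upper()
        if pos < 1:
            raise ValidationError(f"locus position must be >= 1, got {pos}")
        if ref_base not in _VALID_BASES or alt_base not in _VALID_BASES:
            raise ValidationError(
                f"substitutions only: ref/alt must be single A/C/G/T, got {ref_base}>{alt_base}"
            )
        if ref_base == alt_base:
            raise ValidationError(f"ref and alt identical at {chrom}:{pos}")
        return cls(chrom, pos, ref_base, alt_base)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.pos}{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class CellRecord:
    """One cell: barcode identity plus its patient and classification."""

    cell_id: str
    patient_id: str
    lineage: str
    subtype: str
    clonotype_id: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.lineage or not self.subtype:
            raise ValidationError(f"cell {self.cell_id}: lineage and subtype must be non-empty")


@dataclass(frozen=True)
class GeneInterval:
    """A gene/exon span with transcriptional strand, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    feature: str = "exon"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"interval {self.name}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"interval {self.name}: strand must be + or -")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class MaskSet:
    """Site and annotation masks used by the filter cascade.

    ``known_snp_sites`` holds (chrom, pos, alt) triples of population
    polymorphisms; ``genes`` is the strand-aware gene annotation;
    ``deg_genes_by_cluster`` maps cluster label to its top differentially
    expressed genes (used only by lineage tracing).
    """

    known_snp_sites: set[tuple[str, int, str]] = field(default_factory=set)
    genes: list[GeneInterval] = field(default_factory=list)
    deg_genes_by_cluster: dict[str, list[str]] | None = None

    def genes_at(self, chrom: str, pos: int) -> list[GeneInterval]:
        return [g for g in self.genes if g.contains(chrom, pos)]

    def is_known_snp(self, locus: GenomicLocus) -> bool:
        return (locus.chrom, locus.pos, locus.alt_base) in self.known_snp_sites


class AlleleCountMatrix:
    """Sparse (cell x locus) reference/variant read counts.

    Backed by a long-format table; zero-count pairs are never stored.
    Lookup by locus is the hot path for the enrichment tests, so a
    per-locus dict index is built once at construction.
    """

    def __init__(self, entries: Iterable[tuple[str, GenomicLocus, int, int]]):
        by_locus: dict[GenomicLocus, dict[str, tuple[int, int]]] = {}
        for cell_id, locus, ref_count, var_count in entries:
            ref_count, var_count = int(ref_count), int(var_count)
            if ref_count < 0 or var_count < 0:
                raise ValidationError(f"negative count at {cell_id} / {locus}")
            if ref_count == 0 and var_count == 0:
                continue
            cellmap = by_locus.setdefault(locus, {})
            if cell_id in cellmap:
                raise ValidationError(
                    f"duplicate (cell, locus) entry: {cell_id} / {locus}"
                )
            cellmap[cell_id] = (ref_count, var_count)
        self._by_locus = by_locus
        self._cells = sorted({c for m in by_locus.values() for c in m})

    # -- accessors ---------------------------------------------------------

    @property
    def loci(self) -> list[GenomicLocus]:
        return sorted(self._by_locus)

    @property
    def cells(self) -> list[str]:
        return self._cells

    @property
    def n_entries(self) -> int:
        return sum(len(m) for m in self._by_locus.values())

    def counts_at(self, locus: GenomicLocus) -> Mapping[str, tuple[int, int]]:
        """All stored (ref, var) counts at one locus, keyed by cell."""
        return self._by_locus.get(locus, {})

    def get(self, cell_id: str, locus: GenomicLocus) -> tuple[int, int]:
        return self._by_locus.get(locus, {}).get(cell_id, (0, 0))

    def subset_cells(self, keep: set[str]) -> "AlleleCountMatrix":
        return AlleleCountMatrix(
            (c, loc, r, v)
            for loc, m in self._by_locus.items()
            for c, (r, v) in m.items()
            if c in keep
        )

    def validate_cells(self, cells: Sequence[CellRecord]) -> None:
        """Every cell in the matrix must resolve to a metadata record."""
        known = {c.cell_id for c in cells}
        missing = [c for c in self._cells if c not in known]
        if missing:
            raise ValidationError(
                f"{len(missing)} matrix cell(s) absent from metadata, e.g. {missing[:5]}"
            )

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, loc.chrom, loc.pos, loc.ref_base, loc.alt_base, r, v)
            for loc in self.loci
            for c, (r, v) in sorted(self._by_locus[loc].items())
        ]
        return pd.DataFrame(rows, columns=COUNT_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleCountMatrix":
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"count table missing column(s): {missing}")
        return cls(
            (
                str(row.cell_id),
                GenomicLocus.make(row.chrom, row.pos, row.ref, row.alt),
                row.ref_count,
                row.var_count,
            )
            for row in df.itertuples(index=False)
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AlleleCountMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class Candidate:
    """A candidate locus with its carrier cells, scoped to one patient."""

    locus: GenomicLocus
    patient_id: str
    carrier_cells: frozenset[str]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_REQUIRED_CELL_COLUMNS = ["cell_id", "patient_id", "lineage", "subtype"]


def read_cell_metadata(path: str | Path) -> list[CellRecord]:
    """Read the cell-metadata TSV into CellRecords.

    Required columns: cell_id, patient_id, lineage, subtype.  Optional:
    clonotype_id, region.  Duplicate cell ids are rejected; a clonotype on
    a cell outside a T/NK lineage is suspicious (clonotypes come from TCR
    sequencing) and triggers a warning, not a failure.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell metadata missing required column(s): {missing}")
    dupes = df.cell_id[df.cell_id.duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate cell_id(s): {dupes[:10]}")

    records = []
    n_warned = 0
    for row in df.itertuples(index=False):
        clonotype = getattr(row, "clonotype_id", None)
        if pd.isna(clonotype):
            clonotype = None
        region = getattr(row, "region", None)
        if pd.isna(region):
            region = None
        rec = CellRecord(
            cell_id=str(row.cell_id),
            patient_id=str(row.patient_id),
            lineage=str(row.lineage),
            subtype=str(row.subtype),
            clonotype_id=clonotype,
            region=region,
        )
        if rec.clonotype_id is not None and "T" not in rec.lineage.upper():
            n_warned += 1
        records.append(rec)
    if n_warned:
        logger.warning(
            "%d cell(s) carry a clonotype_id outside a T/NK lineage", n_warned
        )
    logger.info("read %d cell records from %s", len(records), path)
    return records


def read_loci_vcf(path: str | Path) -> list[GenomicLocus]:
    """Read candidate loci from a VCF; only CHROM/POS/REF/ALT are consumed.

    Indels and multi-allelic records are split/skipped: every biallelic
    SNV ALT becomes one locus.
    """
    from cyvcf2 import VCF

    loci = []
    for rec in VCF(str(path)):
        if len(rec.REF) != 1 or rec.REF not in _VALID_BASES:
            continue
        for alt in rec.ALT:
            if len(alt) == 1 and alt in _VALID_BASES:
                loci.append(GenomicLocus.make(rec.CHROM, rec.POS, rec.REF, alt))
    logger.info("read %d SNV loci from %s", len(loci), path)
    return loci


def read_snp_mask_vcf(path: str | Path) -> set[tuple[str, int, str]]:
    """Known-polymorphism mask as (chrom, pos, alt) triples."""
    return {(l.chrom, l.pos, l.alt_base) for l in read_loci_vcf(path)}


def read_bed(path: str | Path, feature: str = "exon") -> list[GeneInterval]:
    """Read a BED6 gene annotation (strand in column 6).

    BED is 0-based half-open; intervals are converted to 1-based
    inclusive.  Intervals are treated as ``feature`` spans (default
    "exon": single-exon gene models).
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            intervals.append(
                GeneInterval(
                    chrom=normalize_chrom(chrom),
                    start=int(start) + 1,
                    end=int(end),
                    strand=strand,
                    name=name,
                    feature=feature,
                )
            )
    return intervals


def read_gff3(path: str | Path, features: tuple[str, ...] = ("gene", "exon")) -> list[GeneInterval]:
    """Read gene/exon intervals from GFF3 (1-based inclusive already)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"malformed GFF3 line in {path}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            if ftype not in features:
                continue
            name = ""
            for kv in attrs.split(";"):
                k, _, v = kv.partition("=")
                if k.strip() in ("Name", "gene_name", "ID", "gene_id") and not name:
                    name = v.strip()
            intervals.append(
                GeneInterval(
                    chrom=normalize_chrom(chrom),
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    name=name,
                    feature=ftype,
                )
            )
    return intervals


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) reference FASTA into contig -> uppercase sequence."""
    from Bio import SeqIO

    return {
        normalize_chrom(rec.id): str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def read_deg_lists(path: str | Path, top_n: int = 100) -> dict[str, list[str]]:
    """Read per-cluster differentially-expressed-gene lists.

    TSV with columns cluster, gene, rank; the ``top_n`` lowest-ranked
    genes per cluster are kept.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cluster": str, "gene": str})
    missing = [c for c in ("cluster", "gene", "rank") if c not in df.columns]
    if missing:
        raise FormatError(f"DEG table missing column(s): {missing}")
    out: dict[str, list[str]] = {}
    for cluster, sub in df.groupby("cluster"):
        out[str(cluster)] = sub.sort_values("rank").gene.head(top_n).tolist()
    return out


# ---------------------------------------------------------------------------
# Count collation
# ---------------------------------------------------------------------------

def collate_counts(
    counts: str | Path | pd.DataFrame,
    cells: Sequence[CellRecord] | None = None,
) -> AlleleCountMatrix:
    """Collate a per-cell allele-count table into the sparse matrix.

    Duplicate (cell, locus) rows are a validation error -- never silently
    summed.  If ``cells`` is given, every cell in the table must resolve
    to a metadata record.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.read_csv(counts, sep="\t")
    matrix = AlleleCountMatrix.from_frame(df)
    if cells is not None:
        matrix.validate_cells(cells)
    logger.info(
        "collated %d entries over %d loci and %d cells",
        matrix.n_entries, len(matrix.loci), len(matrix.cells),
    )
    return matrix


def collate_counts_bam(
    bam_path: str | Path,
    loci: Sequence[GenomicLocus],
    *,
    min_base_quality: int = 20,
    min_mapping_quality: int = 30,
    cell_barcode_tag: str = "CB",
    cells: Sequence[CellRecord] | None = None,
) -> AlleleCountMatrix:
    """Per-cell pileup of a barcoded BAM at the supplied candidate loci.

    Reads must carry the cell barcode in ``cell_barcode_tag`` (CB by
    default); bases below ``min_base_quality`` and reads below
    ``min_mapping_quality`` (or marked duplicate/secondary/QC-fail) are
    ignored.  Bases other than ref or alt at a locus are discarded.
    """
    import pysam

    entries: dict[tuple[str, GenomicLocus], list[int]] = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        contig_map = {normalize_chrom(c): c for c in bam.references}
        for locus in loci:
            contig = contig_map.get(locus.chrom)
            if contig is None:
                continue
            for col in bam.pileup(
                contig,
                locus.pos - 1,
                locus.pos,
                truncate=True,
                min_base_quality=min_base_quality,
                min_mapping_quality=min_mapping_quality,
                ignore_overlaps=False,
            ):
                for read in col.pileups:
                    if read.is_del or read.is_refskip or read.query_position is None:
                        continue
                    aln = read.alignment
                    if aln.is_duplicate or aln.is_secondary or aln.is_qcfail:
                        continue
                    if not aln.has_tag(cell_barcode_tag):
                        continue
                    base = aln.query_sequence[read.query_position].upper()
                    barcode = aln.get_tag(cell_barcode_tag)
                    counts = entries.setdefault((barcode, locus), [0, 0])
                    if base == locus.ref_base:
                        counts[0] += 1
                    elif base == locus.alt_base:
                        counts[1] += 1
    matrix = AlleleCountMatrix(
        (cell, locus, r, v) for (cell, locus), (r, v) in entries.items()
    )
    if cells is not None:
        matrix.validate_cells(cells)
    return matrix


def enumerate_candidates(
    matrix: AlleleCountMatrix,
    cells: Sequence[CellRecord] | None = None,
) -> list[Candidate]:
    """Enumerate candidate loci: any locus where >=1 cell has a variant read.

    A cell carries the candidate iff its variant count is >= 1.  With cell
    metadata, candidates are scoped per patient (loci are patient-specific
    throughout the cascade); without it, a single pseudo-patient is used.
    """
    if not matrix.loci:
        raise ValidationError("empty allele-count matrix")
    patient_of = {c.cell_id: c.patient_id for c in cells} if cells is not None else None
    out = []
    for locus in matrix.loci:
        carriers_by_patient: dict[str, set[str]] = {}
        for cell_id, (_r, v) in matrix.counts_at(locus).items():
            if v >= 1:
                if patient_of is None:
                    pid = "all"
                elif cell_id in patient_of:
                    pid = patient_of[cell_id]
                else:
                    raise ValidationError(f"cell {cell_id} absent from metadata")
                carriers_by_patient.setdefault(pid, set()).add(cell_id)
        for pid in sorted(carriers_by_patient):
            out.append(
                Candidate(locus=locus, patient_id=pid,
                          carrier_cells=frozenset(carriers_by_patient[pid]))
            )
    return out
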