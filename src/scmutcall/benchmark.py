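"""Benchmarking calls against orthogonal DNA evidence and TCR clonotypes.

Transcriptome-derived calls are validated two ways.  Against bulk DNA
(exome) data from the same tumor, each call is classified as a true
positive (also called by the DNA pipeline), a pileup-only true positive
(variant reads present in the tumor DNA with none in the matched normal,
but no DNA-pipeline call -- typically low DNA coverage or mtDNA), a false
positive (adequate DNA depth showing essentially no variant support), or
indeterminate (DNA depth too low to adjudicate); DNA-pipeline calls the
transcriptome missed despite adequate single-cell coverage are false
negatives.  Within CD8+ T cells, where mutations acquired after thymic
egress must be confined to one expanded TCR clonotype, the fraction of
calls restricted to a single clonotype is an orthogonal precision proxy
that needs no DNA at all.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import PipelineConfig
from .enrichment import MutationCall
from .io_ingest import (
    AlleleCountMatrix,
    CellRecord,
    GenomicLocus,
    MaskSet,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("TP", "TP_pileup_only", "FP", "FN", "indeterminate")

_DNA_COLUMNS = ["chrom", "pos", "ref", "alt", "tumor_var", "tumor_ref",
                "normal_var", "orthogonal_call"]


@dataclass(frozen=True)
class DnaRecord:
    tumor_var_reads: int
    tumor_ref_reads: int
    normal_var_reads: int
    orthogonal_call: bool

    def __post_init__(self) -> None:
        if min(self.tumor_var_reads, self.tumor_ref_reads, self.normal_var_reads) < 0:
            raise ValidationError("negative DNA read count")


class DnaEvidence:
    """Per-locus orthogonal DNA read support, keyed by GenomicLocus."""

    def __init__(self, records: dict[GenomicLocus, DnaRecord]):
        self._records = dict(records)

    def get(self, locus: GenomicLocus) -> DnaRecord | None:
        return self._records.get(locus)

    @property
    def loci(self) -> list[GenomicLocus]:
        return sorted(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (l.chrom, l.pos, l.ref_base, l.alt_base, r.tumor_var_reads,
             r.tumor_ref_reads, r.normal_var_reads, r.orthogonal_call)
            for l, r in sorted(self._records.items())
        ]
        return pd.DataFrame(rows, columns=_DNA_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DnaEvidence":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _DNA_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"DNA evidence table missing column(s): {missing}")
        records = {}
        for row in df.itertuples(index=False):
            locus = GenomicLocus.make(row.chrom, row.pos, row.ref, row.alt)
            records[locus] = DnaRecord(
                tumor_var_reads=int(row.tumor_var),
                tumor_ref_reads=int(row.tumor_ref),
                normal_var_reads=int(row.normal_var),
                orthogonal_call=bool(row.orthogonal_call),
            )
        return cls(records)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _adequate_scrna_coverage(
    locus: GenomicLocus,
    matrix: AlleleCountMatrix,
    cells: Sequence[CellRecord],
    dna_lineage: str,
    cfg: PipelineConfig,
) -> bool:
    """Would the transcriptome have had a chance to call this DNA mutation?

    Interpreted as coverage: >= ``min_variant_cells`` cells of the
    DNA-assayed lineage with any read at the locus, and >=
    ``min_reference_cells`` cells with the reference base outside it.
    """
    lineage_of = {c.cell_id: c.lineage for c in cells}
    counts = matrix.counts_at(locus)
    n_lineage_covered = sum(
        1 for cell, (r, v) in counts.items()
        if r + v >= 1 and lineage_of.get(cell) == dna_lineage
    )
    n_ref_outside = sum(
        1 for cell, (r, _v) in counts.items()
        if r >= 1 and lineage_of.get(cell) not in (None, dna_lineage)
    )
    return (n_lineage_covered >= cfg.min_variant_cells
            and n_ref_outside >= cfg.min_reference_cells)


def classify_calls(
    scrna_calls: Sequence[MutationCall],
    dna: DnaEvidence,
    matrix: AlleleCountMatrix,
    cells: Sequence[CellRecord],
    config: PipelineConfig | None = None,
    dna_lineage: str = "tumor",
) -> dict[GenomicLocus, str]:
    """Classify every scRNA call and every DNA-only call.

    scRNA calls: TP when the DNA pipeline also called the locus;
    TP_pileup_only when the tumor DNA pileup supports the variant
    (>= ``pileup_min_var_reads`` variant reads, zero matched-normal
    variant reads) without a DNA-pipeline call; FP when the DNA pileup
    has fewer than ``fp_max_var_reads`` variant reads and more than
    ``fp_min_ref_reads`` reference reads; indeterminate otherwise,
    including loci absent from the DNA table.  DNA-pipeline calls not
    called from scRNA are FN when the single-cell data had adequate
    coverage (see ``_adequate_scrna_coverage``) and are otherwise
    ignored.
    """
    cfg = config or PipelineConfig()
    categories: dict[GenomicLocus, str] = {}
    scrna_loci = set()
    for call in scrna_calls:
        locus = call.locus
        scrna_loci.add(locus)
        rec = dna.get(locus)
        if rec is None:
            logger.warning("%s absent from DNA table; indeterminate", locus)
            categories[locus] = "indeterminate"
        elif rec.orthogonal_call:
            categories[locus] = "TP"
        elif (rec.tumor_var_reads >= cfg.pileup_min_var_reads
              and rec.normal_var_reads == 0):
            categories[locus] = "TP_pileup_only"
        elif (rec.tumor_var_reads < cfg.fp_max_var_reads
              and rec.tumor_ref_reads > cfg.fp_min_ref_reads):
            categories[locus] = "FP"
        else:
            categories[locus] = "indeterminate"

    for locus in dna.loci:
        if locus in scrna_loci or not dna.get(locus).orthogonal_call:
            continue
        if _adequate_scrna_coverage(locus, matrix, cells, dna_lineage, cfg):
            categories[locus] = "FN"
        # DNA calls without adequate scRNA coverage are not counted at all

    return categories


def precision_sensitivity(
    counts: dict[str, int],
) -> tuple[float | None, float | None]:
    """Precision and sensitivity from category counts.

    precision = (TP + TP_pileup_only) / (TP + TP_pileup_only + FP);
    sensitivity = TP / (TP + FN).  Indeterminate calls are excluded from
    both.  A zero denominator yields None (undefined), never 0.
    """
    tp = counts.get("TP", 0)
    tpp = counts.get("TP_pileup_only", 0)
    fp = counts.get("FP", 0)
    fn = counts.get("FN", 0)
    precision = (tp + tpp) / (tp + tpp + fp) if (tp + tpp + fp) else None
    sensitivity = tp / (tp + fn) if (tp + fn) else None
    return precision, sensitivity


@dataclass
class BenchmarkReport:
    counts: dict[str, int]
    precision: float | None
    sensitivity: float | None
    counts_exonic: dict[str, int]
    precision_exonic: float | None
    sensitivity_exonic: float | None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def benchmark_report(
    scrna_calls: Sequence[MutationCall],
    dna: DnaEvidence,
    matrix: AlleleCountMatrix,
    cells: Sequence[CellRecord],
    config: PipelineConfig | None = None,
    dna_lineage: str = "tumor",
    masks: MaskSet | None = None,
) -> tuple[BenchmarkReport, pd.DataFrame]:
    """Full DNA benchmark: category counts, precision/sensitivity, and the
    exonic-only restriction of both.

    Exonic status comes from the call annotation; for DNA-only loci it is
    resolved against ``masks`` gene intervals when provided, otherwise
    those loci are excluded from the exonic subset.
    """
    categories = classify_calls(scrna_calls, dna, matrix, cells, config, dna_lineage)
    exonic_of: dict[GenomicLocus, bool] = {}
    for call in scrna_calls:
        exonic_of[call.locus] = call.annotated.exonic_class == "exonic"
    for locus in categories:
        if locus not in exonic_of and masks is not None:
            exonic_of[locus] = any(
                g.feature == "exon" for g in masks.genes_at(locus.chrom, locus.pos)
            )

    counts = {c: 0 for c in CATEGORIES}
    counts_exonic = {c: 0 for c in CATEGORIES}
    rows = []
    for locus in sorted(categories):
        cat = categories[locus]
        counts[cat] += 1
        exonic = exonic_of.get(locus, False)
        if exonic:
            counts_exonic[cat] += 1
        rows.append((locus.chrom, locus.pos, locus.ref_base, locus.alt_base,
                     cat, exonic))
    precision, sensitivity = precision_sensitivity(counts)
    precision_ex, sensitivity_ex = precision_sensitivity(counts_exonic)
    report = BenchmarkReport(
        counts=counts,
        precision=precision,
        sensitivity=sensitivity,
        counts_exonic=counts_exonic,
        precision_exonic=precision_ex,
        sensitivity_exonic=sensitivity_ex,
    )
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "category", "exonic"]
    )
    return report, table


# ---------------------------------------------------------------------------
# Clonotype benchmark
# ---------------------------------------------------------------------------

def clonotype_restriction(
    calls: Sequence[MutationCall],
    cells: Sequence[CellRecord],
) -> float:
    """Fraction of calls whose variant cells all share one TCR clonotype.

    ``calls`` should come from the clonotype-grouped pipeline run on
    clonotyped CD8+ cells with thresholds identical to the lineage
    pipeline.  A mutation acquired after clonal expansion is confined to
    one clonotype; pre-thymic mutations may span several.
    """
    clonotype_of = {
        c.cell_id: c.clonotype_id for c in cells if c.clonotype_id is not None
    }
    if not clonotype_of:
        raise ValidationError("no clonotyped cells supplied")
    if not calls:
        raise ValidationError("no calls to evaluate for clonotype restriction")
    n_restricted = 0
    for call in calls:
        clonotypes = {
            clonotype_of[c] for c in call.carrier_cells if c in clonotype_of
        }
        if len(clonotypes) == 1:
            n_restricted += 1
    return n_restricted / len(calls)
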