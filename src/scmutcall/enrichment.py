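"""Lineage/clonotype enrichment tests and the final filter cascade.

A real somatic mutation arises in one cell and is inherited by that
cell's clonal descendants, so its carriers should concentrate in a single
cell lineage (or, within CD8+ T cells, a single TCR clonotype).  Each
candidate is therefore scored with a one-sided Fisher's exact test of
variant versus reference cells in its most-mutated group against all
other groups, plus a prevalence-ratio enrichment factor.  Fixed
thresholds on these statistics, a known-SNP mask, cross-patient
uniqueness, minimum cell support, a transcribed-strand bias filter over
trinucleotide substitution classes, and a proximity-cluster filter then
yield the final calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binomtest, fisher_exact

from .candidate_filter import AnnotatedCandidate, revcomp
from .config import PipelineConfig
from .io_ingest import (
    AlleleCountMatrix,
    CellRecord,
    MaskSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

Table2x2 = tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class EnrichmentStats:
    """2x2 enrichment of variant cells in the top group vs all others."""

    grouping: str  # 'lineage' or 'clonotype'
    top_group: str
    var_cells_top: int
    ref_cells_top: int
    var_cells_other: int
    ref_cells_other: int
    fisher_p: float
    enrichment_factor: float
    tied_top: bool = False

    @property
    def table(self) -> Table2x2:
        return (
            (self.var_cells_top, self.ref_cells_top),
            (self.var_cells_other, self.ref_cells_other),
        )


@dataclass
class MutationCall:
    """An annotated candidate with enrichment statistics and filter flags.

    ``filters`` maps criterion name -> passed; a call is PASS iff every
    flag is True.  ``stats`` is the enrichment used for thresholding
    (lineage in the standard pipeline, clonotype in the TCR benchmark);
    ``clonotype_stats`` carries the secondary clonotype enrichment where
    clonotype annotations exist.
    """

    annotated: AnnotatedCandidate
    stats: EnrichmentStats
    clonotype_stats: EnrichmentStats | None = None
    filters: dict[str, bool] = field(default_factory=dict)

    @property
    def locus(self):
        return self.annotated.locus

    @property
    def patient_id(self) -> str:
        return self.annotated.patient_id

    @property
    def carrier_cells(self) -> frozenset[str]:
        return self.annotated.carrier_cells

    @property
    def passed(self) -> bool:
        return all(self.filters.values())


# ---------------------------------------------------------------------------
# 2x2 construction and Fisher test
# ---------------------------------------------------------------------------

def group_counts(
    candidate: AnnotatedCandidate,
    matrix: AlleleCountMatrix,
    cells: Sequence[CellRecord],
    grouping: str = "lineage",
) -> tuple[str, Table2x2, bool]:
    """Build the (top group vs rest) x (variant vs reference cells) table.

    Variant cells are the accepted carriers; reference cells are cells
    with >=1 reference read that are not variant cells (this includes
    carriers whose call the binomial filter suppressed).  For clonotype
    grouping the universe is restricted to clonotyped cells of the
    candidate's patient.  The top group maximizes the variant-cell count;
    ties break lexicographically and are flagged.
    """
    if grouping not in ("lineage", "clonotype"):
        raise ValueError(f"unknown grouping {grouping!r}")
    pid = candidate.patient_id
    if grouping == "lineage":
        group_of = {c.cell_id: c.lineage for c in cells if c.patient_id == pid}
    else:
        group_of = {
            c.cell_id: c.clonotype_id
            for c in cells
            if c.patient_id == pid and c.clonotype_id is not None
        }
        if not group_of:
            raise ValidationError(
                f"clonotype grouping requested but patient {pid} has no "
                "clonotype annotations"
            )

    counts = matrix.counts_at(candidate.locus)
    variant_cells = {c for c in candidate.carrier_cells if c in group_of}
    var_by_group: dict[str, int] = {}
    ref_by_group: dict[str, int] = {}
    for cell_id, (r, _v) in counts.items():
        grp = group_of.get(cell_id)
        if grp is None:
            continue
        if cell_id in variant_cells:
            var_by_group[grp] = var_by_group.get(grp, 0) + 1
        elif r >= 1:
            ref_by_group[grp] = ref_by_group.get(grp, 0) + 1

    if not var_by_group:
        raise ValidationError(f"{candidate.locus}: no variant cells in grouping universe")
    best = max(var_by_group.values())
    top_candidates = sorted(g for g, n in var_by_group.items() if n == best)
    top = top_candidates[0]
    tied = len(top_candidates) > 1

    a = var_by_group.get(top, 0)
    b = ref_by_group.get(top, 0)
    c = sum(n for g, n in var_by_group.items() if g != top)
    d = sum(n for g, n in ref_by_group.items() if g != top)
    return top, ((a, b), (c, d)), tied


def fisher_enrichment(table: Table2x2) -> tuple[float, float]:
    """One-sided Fisher p and prevalence-ratio enrichment factor.

    p is the exact hypergeometric tail toward greater variant prevalence
    in the top row.  The enrichment factor is
    (var_top / top row total) / (var_other / other row total); it is +inf
    when the top group has variants but no other group does, and 0 for an
    all-zero table (p = 1 by convention).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell count in 2x2 table")
    if a + b + c + d == 0:
        return 1.0, 0.0
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    if a == 0:
        factor = 0.0
    elif c == 0:
        factor = math.inf
    elif c + d == 0:
        factor = math.inf
    else:
        factor = (a / (a + b)) / (c / (c + d))
    return float(p), factor


def compute_enrichment(
    candidate: AnnotatedCandidate,
    matrix: AlleleCountMatrix,
    cells: Sequence[CellRecord],
    grouping: str = "lineage",
) -> EnrichmentStats:
    top, table, tied = group_counts(candidate, matrix, cells, grouping)
    p, factor = fisher_enrichment(table)
    (a, b), (c, d) = table
    return EnrichmentStats(
        grouping=grouping, top_group=top,
        var_cells_top=a, ref_cells_top=b,
        var_cells_other=c, ref_cells_other=d,
        fisher_p=p, enrichment_factor=factor, tied_top=tied,
    )


# ---------------------------------------------------------------------------
# Final filter cascade
# ---------------------------------------------------------------------------

def apply_final_thresholds(
    calls: Sequence[MutationCall],
    masks: MaskSet,
    all_patients_calls: Sequence[MutationCall] | None = None,
    config: PipelineConfig | None = None,
) -> list[MutationCall]:
    """Apply the fixed final-filter thresholds; record per-criterion flags.

    Criteria: enrichment significance (Fisher p below ``fisher_alpha``
    with factor >= ``min_enrichment_factor``); absence from the known-SNP
    mask; no sharing of the same chrom/pos/alt between patients; and
    adequate support (>= ``min_variant_cells`` variant cells in the top
    group, >= ``min_reference_cells`` reference cells outside it).
    Returns the surviving calls; every input call keeps its flags.
    """
    cfg = config or PipelineConfig()
    if not masks.known_snp_sites:
        logger.warning("known-SNP mask is empty; SNP criterion passes vacuously")

    pool = all_patients_calls if all_patients_calls is not None else calls
    patients_by_site: dict[tuple, set[str]] = {}
    for call in pool:
        loc = call.locus
        patients_by_site.setdefault(
            (loc.chrom, loc.pos, loc.alt_base), set()
        ).add(call.patient_id)

    kept = []
    for call in calls:
        s = call.stats
        loc = call.locus
        call.filters["fisher"] = s.fisher_p < cfg.fisher_alpha
        call.filters["enrichment_factor"] = (
            s.enrichment_factor >= cfg.min_enrichment_factor
        )
        call.filters["known_snp"] = not masks.is_known_snp(loc)
        call.filters["patient_unique"] = (
            len(patients_by_site[(loc.chrom, loc.pos, loc.alt_base)]) == 1
        )
        call.filters["min_variant_cells"] = s.var_cells_top >= cfg.min_variant_cells
        call.filters["min_reference_cells"] = (
            s.ref_cells_other >= cfg.min_reference_cells
        )
        if call.passed:
            kept.append(call)
    logger.info("final thresholds: %d -> %d calls", len(calls), len(kept))
    return kept


def substitution_class(call: MutationCall) -> tuple[str, str | None]:
    """Canonical (substitution, trinucleotide context) class and strand label.

    The class is pyrimidine-normalized (purine-reference events are
    reverse-complemented), the convention of mutational-signature
    accounting, so the same chemical event in genes on opposite strands
    lands in one class.  The strand label marks which transcribed strand
    the pyrimidine representation sits on; it is None for sites without a
    strand assignment (intergenic or genes on both strands).
    """
    ann = call.annotated
    ref, alt, ctx = ann.locus.ref_base, ann.locus.alt_base, ann.tri_context
    flipped = ref in "AG"
    if flipped:
        ctx = revcomp(ctx)
        ref = revcomp(ref)
        alt = revcomp(alt)
    key = f"{ctx}>{alt}"
    if ann.gene_strand is None:
        return key, None
    strand = ann.gene_strand if not flipped else ("-" if ann.gene_strand == "+" else "+")
    return key, strand


def strand_bias_filter(
    calls: Sequence[MutationCall],
    min_class_size: int = 10,
    alpha: float = 0.005,
) -> list[MutationCall]:
    """Remove whole substitution classes with biased transcribed strands.

    Classes are (substitution, trinucleotide context) pairs pooled across
    the dataset.  For each class with >= ``min_class_size``
    strand-assignable members, a two-sided exact binomial test compares
    its strand counts to 1:1; all members of a failing class are removed,
    including strand-unassignable ones (erring toward specificity).
    Smaller classes are untested.
    """
    members: dict[str, list[MutationCall]] = {}
    strand_counts: dict[str, list[int]] = {}
    for call in calls:
        key, strand = substitution_class(call)
        members.setdefault(key, []).append(call)
        counts = strand_counts.setdefault(key, [0, 0])
        if strand == "+":
            counts[0] += 1
        elif strand == "-":
            counts[1] += 1

    failing = set()
    for key, (n_plus, n_minus) in strand_counts.items():
        n = n_plus + n_minus
        if n < min_class_size:
            continue
        p = binomtest(n_plus, n, 0.5, alternative="two-sided").pvalue
        if p < alpha:
            failing.add(key)
            logger.info(
                "strand-bias: class %s removed (%d+/%d-, p=%.3g)",
                key, n_plus, n_minus, p,
            )

    kept = []
    for call in calls:
        key, _ = substitution_class(call)
        call.filters["strand_bias"] = key not in failing
        if call.filters["strand_bias"]:
            kept.append(call)
    return kept


def proximity_filter(
    calls: Sequence[MutationCall], proximity_bp: int = 4
) -> list[MutationCall]:
    """Remove calls clustered within ``proximity_bp`` bases in one patient.

    Clustering is transitive: every member of a proximity cluster is
    removed, both ends included.  The rule is per patient and per
    chromosome.
    """
    by_group: dict[tuple[str, str], list[MutationCall]] = {}
    for call in calls:
        by_group.setdefault((call.patient_id, call.locus.chrom), []).append(call)

    removed = set()
    for group in by_group.values():
        group.sort(key=lambda c: c.locus.pos)
        cluster = [group[0]]
        for call in group[1:]:
            if call.locus.pos - cluster[-1].locus.pos <= proximity_bp:
                cluster.append(call)
            else:
                if len(cluster) > 1:
                    removed.update(id(c) for c in cluster)
                cluster = [call]
        if len(cluster) > 1:
            removed.update(id(c) for c in cluster)

    kept = []
    for call in calls:
        call.filters["proximity"] = id(call) not in removed
        if call.filters["proximity"]:
            kept.append(call)
    logger.info("proximity filter: %d -> %d calls", len(calls), len(kept))
    return kept


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def calls_to_frame(calls: Iterable[MutationCall]) -> pd.DataFrame:
    """Flatten calls (with stats, annotations and flags) to a table."""
    rows = []
    for call in calls:
        ann, s = call.annotated, call.stats
        row = {
            "chrom": ann.locus.chrom,
            "pos": ann.locus.pos,
            "ref": ann.locus.ref_base,
            "alt": ann.locus.alt_base,
            "patient_id": ann.patient_id,
            "gene": ann.gene or "",
            "exonic_class": ann.exonic_class,
            "tri_context": ann.tri_context,
            "gene_strand": ann.gene_strand or "",
            "transcribed_strand_context": ann.transcribed_strand_context or "",
            "grouping": s.grouping,
            "top_group": s.top_group,
            "var_cells_top": s.var_cells_top,
            "ref_cells_top": s.ref_cells_top,
            "var_cells_other": s.var_cells_other,
            "ref_cells_other": s.ref_cells_other,
            "fisher_p": s.fisher_p,
            "enrichment_factor": s.enrichment_factor,
            "tied_top": s.tied_top,
            "n_carriers": len(ann.carrier_cells),
            "carrier_cells": ";".join(sorted(ann.carrier_cells)),
            "pass": call.passed,
        }
        for name, ok in sorted(call.filters.items()):
            row[f"filter_{name}"] = ok
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["patient_id", "chrom", "pos", "alt"], kind="mergesort"
        ).reset_index(drop=True)
    return df


def write_calls_tsv(calls: Iterable[MutationCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_calls_vcf(calls: Sequence[MutationCall], path: str | Path) -> None:
    """Minimal VCF of PASS calls with enrichment statistics in INFO."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "scmutcall")
    for chrom in sorted({c.locus.chrom for c in calls}):
        header.contigs.add(chrom)
    header.info.add("PATIENT", 1, "String", "Patient the call is scoped to")
    header.info.add("TOPGROUP", 1, "String", "Most-mutated lineage/clonotype")
    header.info.add("FISHERP", 1, "Float", "One-sided Fisher enrichment p")
    header.info.add("EF", 1, "Float", "Enrichment factor (prevalence ratio)")
    header.info.add("VCT", 1, "Integer", "Variant cells in top group")
    header.info.add("RCO", 1, "Integer", "Reference cells outside top group")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        ordered = sorted(
            calls, key=lambda c: (c.locus.chrom, c.locus.pos, c.locus.alt_base)
        )
        for call in ordered:
            loc, s = call.locus, call.stats
            rec = vcf.new_record(
                contig=loc.chrom,
                start=loc.pos - 1,
                stop=loc.pos,
                alleles=(loc.ref_base, loc.alt_base),
            )
            rec.info["PATIENT"] = call.patient_id
            rec.info["TOPGROUP"] = s.top_group
            rec.info["FISHERP"] = s.fisher_p
            ef = s.enrichment_factor
            rec.info["EF"] = float(ef if math.isfinite(ef) else 1e38)
            rec.info["VCT"] = s.var_cells_top
            rec.info["RCO"] = s.ref_cells_other
            vcf.write(rec)
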