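"""First-stage candidate filters and annotation.

Somatic mutations are acquired after embryonic lineage commitment, so a
true mutation cannot be shared across the major cell lineages; and a
variant seen in exactly one cell cannot be distinguished from artifact.
These two facts drive the first filter pass.  A per-cell one-sided
binomial test then discards calls in cells whose reference reads
significantly outnumber their variant reads -- the autosomal expectation
for a heterozygous somatic mutation is roughly balanced allele counts, so
a strong reference excess implies mapping artifact or high-depth noise
rather than a real variant (a two-sided test would also discard cells
with bursty monoallelic variant expression, which are biologically real).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import binom

from .io_ingest import (
    AlleleCountMatrix,
    Candidate,
    CellRecord,
    GenomicLocus,
    MaskSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnnotatedCandidate:
    """A surviving candidate with gene and trinucleotide context.

    ``tri_context`` is the 3-mer around the site in reference orientation
    (middle base = ref).  ``transcribed_strand_context`` is that 3-mer
    read off the transcribed strand: the reverse complement when the
    overlapping gene is on '-', absent for intergenic sites or sites
    under genes on both strands.
    """

    locus: GenomicLocus
    patient_id: str
    carrier_cells: frozenset[str]
    tri_context: str
    gene: str | None = None
    exonic_class: str = "intergenic"
    gene_strand: str | None = None
    transcribed_strand_context: str | None = None

    def __post_init__(self) -> None:
        if not self.carrier_cells:
            raise ValidationError(f"{self.locus}: carrier set must be non-empty")
        if len(self.tri_context) != 3 or self.tri_context[1] != self.locus.ref_base:
            raise ValidationError(
                f"{self.locus}: tri_context {self.tri_context!r} middle base "
                f"must equal ref {self.locus.ref_base}"
            )


def _lineage_of(cells: Sequence[CellRecord]) -> dict[str, str]:
    return {c.cell_id: c.lineage for c in cells}


def remove_singlets(
    candidates: Sequence[Candidate], min_carrier_cells: int = 2
) -> list[Candidate]:
    """Drop candidates carried by fewer than ``min_carrier_cells`` cells."""
    kept = [c for c in candidates if len(c.carrier_cells) >= min_carrier_cells]
    logger.info("singlet filter: %d -> %d candidates", len(candidates), len(kept))
    return kept


def remove_cross_lineage_shared(
    candidates: Sequence[Candidate], cells: Sequence[CellRecord]
) -> list[Candidate]:
    """Drop candidates whose carriers span more than one major lineage.

    Sharing between subtypes of the same lineage is fine -- the rule is
    lineage-level only.
    """
    lineage_of = _lineage_of(cells)
    kept = []
    for cand in candidates:
        lineages = set()
        for cell_id in cand.carrier_cells:
            if cell_id not in lineage_of:
                raise ValidationError(
                    f"carrier cell {cell_id} has no lineage in metadata"
                )
            lineages.add(lineage_of[cell_id])
        if len(lineages) == 1:
            kept.append(cand)
    logger.info("cross-lineage filter: %d -> %d candidates", len(candidates), len(kept))
    return kept


def binomial_reference_excess_p(ref_count: int, var_count: int) -> float:
    """One-sided P(X <= var | n = ref+var, p = 1/2).

    Small p means the cell shows significantly more reference than
    variant reads than a balanced heterozygous site would produce.
    """
    n = ref_count + var_count
    if n == 0:
        return 1.0
    return float(binom.cdf(var_count, n, 0.5))


def binomial_allelic_filter(
    matrix: AlleleCountMatrix,
    candidates: Sequence[Candidate],
    alpha: float = 0.05,
    min_carrier_cells: int = 2,
) -> list[Candidate]:
    """Ignore per-cell calls with significant reference excess.

    For each carrier, the call is ignored when p < ``alpha``; candidates
    whose carrier set drops below ``min_carrier_cells`` are dropped.
    Cells whose call is ignored keep their reference reads and therefore
    still contribute to reference-cell counts downstream.
    """
    kept = []
    n_suppressed = 0
    for cand in candidates:
        counts = matrix.counts_at(cand.locus)
        surviving = set()
        for cell_id in cand.carrier_cells:
            r, v = counts.get(cell_id, (0, 0))
            if binomial_reference_excess_p(r, v) < alpha:
                n_suppressed += 1
            else:
                surviving.add(cell_id)
        if len(surviving) >= min_carrier_cells:
            kept.append(
                Candidate(cand.locus, cand.patient_id, frozenset(surviving))
            )
    logger.info(
        "binomial allelic filter: %d -> %d candidates (%d cell calls suppressed)",
        len(candidates), len(kept), n_suppressed,
    )
    return kept


def annotate(
    candidates: Sequence[Candidate],
    reference: Mapping[str, str],
    masks: MaskSet,
) -> list[AnnotatedCandidate]:
    """Attach trinucleotide context and gene annotation to candidates.

    ``reference`` maps contig -> sequence and must cover each locus with
    one flanking base on each side.  Gene and exonic class come from
    interval overlap: "exonic" iff an exon-typed interval covers the
    site, "intronic" when only a gene body does, else "intergenic".  A
    site under genes on both strands gets no strand assignment.
    """
    out = []
    for cand in candidates:
        locus = cand.locus
        seq = reference.get(locus.chrom)
        if seq is None:
            raise ValidationError(f"contig {locus.chrom} absent from reference")
        if not (2 <= locus.pos <= len(seq) - 1):
            raise ValidationError(
                f"{locus}: needs one flanking base within the reference "
                f"(contig length {len(seq)})"
            )
        tri = seq[locus.pos - 2 : locus.pos + 1].upper()

        overlapping = masks.genes_at(locus.chrom, locus.pos)
        gene = None
        strand = None
        exonic_class = "intergenic"
        if overlapping:
            gene = min(g.name for g in overlapping)
            strands = {g.strand for g in overlapping}
            strand = strands.pop() if len(strands) == 1 else None
            features = {g.feature for g in overlapping}
            exonic_class = "exonic" if "exon" in features else "intronic"

        ts_context = None
        if strand is not None:
            ts_context = tri if strand == "+" else revcomp(tri)

        out.append(
            AnnotatedCandidate(
                locus=locus,
                patient_id=cand.patient_id,
                carrier_cells=cand.carrier_cells,
                tri_context=tri,
                gene=gene,
                exonic_class=exonic_class,
                gene_strand=strand,
                transcribed_strand_context=ts_context,
            )
        )
    return out
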