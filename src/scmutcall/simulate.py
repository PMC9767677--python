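"""Synthetic scRNA-seq allele-count datasets with full truth labels.

The generator emulates the data regime the caller is built for: several
broad cell lineages per patient; a clonally structured tumor (a small
clone tree whose mutations are inherited down the branches); myeloid
clones from clonal hematopoiesis; expanded CD8+ TCR clonotypes carrying
post-thymic mutations; expression-dependent per-cell coverage with
dropout and allelic dropout; per-base sequencing error; and three
artifact classes -- cross-lineage site errors, strand-asymmetric
trinucleotide-context classes, and singlet errors.  Loci live on a small
generated genome (a few hundred kb over five contigs including MT) with
a strand-annotated gene set, so annotation and strand logic run
hermetically.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .benchmark import DnaEvidence, DnaRecord
from .io_ingest import (
    AlleleCountMatrix,
    CellRecord,
    GeneInterval,
    GenomicLocus,
    MaskSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_PYRIMIDINE_ALTS = {"C": "AGT", "T": "ACG"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageSpec:
    name: str
    n_cells: int
    subtypes: tuple[str, ...]


@dataclass(frozen=True)
class CloneSpec:
    """A tumor clone-tree node: cells assigned here carry the mutations of
    this clone and of every ancestor."""

    name: str
    fraction: float  # fraction of tumor cells assigned directly to this clone
    n_mutations: int
    parent: str | None = None


@dataclass(frozen=True)
class StrandArtifactClass:
    """A strand-asymmetric artifact class.

    ``context`` is the pyrimidine-oriented trinucleotide (middle base C
    or T) and ``alt`` the substituted base; members are placed in genes
    whose transcribed strand is '+' with probability ``plus_fraction``.
    """

    context: str
    alt: str
    n_mutations: int
    plus_fraction: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a single patient with 1,200 cells over 7 broad
    lineages, 60 clonally structured true mutations (35 tumor across a
    3-clone tree, 10 clonal-hematopoiesis myeloid, 15 post-thymic T-cell
    tied to expanded clonotypes), droplet-scale coverage (Poisson depth 8
    on expressed loci, UMI-consensus error 2e-5, allelic dropout 0.15),
    and modest artifact contamination.
    """

    seed: int = 0
    n_patients: int = 1
    lineages: tuple[LineageSpec, ...] = (
        LineageSpec("tumor", 300, ("tumor_1", "tumor_2")),
        LineageSpec("myeloid", 250, ("mono_CD14", "mono_CD16", "macro_C1QA")),
        LineageSpec("T/NK", 300, ("CD8_eff", "CD8_mem", "CD4", "NK")),
        LineageSpec("B/plasma", 100, ("B", "plasma")),
        LineageSpec("endothelial", 100, ("endo",)),
        LineageSpec("epithelial", 100, ("epi_PT",)),
        LineageSpec("fibroblast", 50, ("fibro",)),
    )
    tumor_lineage: str = "tumor"
    myeloid_lineage: str = "myeloid"
    t_lineage: str = "T/NK"
    clonotype_subtypes: tuple[str, ...] = ("CD8_eff", "CD8_mem")
    # clonal structure
    tumor_clones: tuple[CloneSpec, ...] = (
        CloneSpec("trunk", 0.2, 20, None),
        CloneSpec("subA", 0.4, 8, "trunk"),
        CloneSpec("subB", 0.4, 7, "trunk"),
    )
    ch_clones: tuple[tuple[str, int, int], ...] = (  # (name, n_cells, n_mutations)
        ("ch1", 40, 5),
        ("ch2", 30, 5),
    )
    # CH clone cells are drawn preferentially from one myeloid subtype
    # (clone k prefers subtype k mod n): differentiation makes clone
    # representation uneven across monocyte/macrophage states, which is
    # what gives the subtype tree its signal.
    ch_subtype_bias: float = 6.0
    t_clonotype_sizes: tuple[int, ...] = (40, 25, 15, 4)
    t_clonotype_mutations: tuple[int, ...] = (6, 5, 4, 0)
    n_prethymic_shared: int = 0  # mutations shared between clonotypes 1 and 4
    # genome
    n_genes: int = 350
    gene_length: int = 300
    intergenic_length: int = 100
    n_mt_genes: int = 2
    # expression and noise
    expr_log_mu: float = -0.8
    expr_log_sigma: float = 0.7
    min_expr_rate_mutated: float = 0.6
    mean_depth: float = 8.0
    dropout: float = 0.1
    allelic_dropout: float = 0.15
    error_rate: float = 2e-5
    # artifacts
    n_cross_lineage_artifacts: int = 10
    cross_lineage_n_lineages: int = 3
    cross_lineage_cells_per_lineage: int = 3
    strand_artifact_classes: tuple[StrandArtifactClass, ...] = (
        StrandArtifactClass("GCA", "G", 12, 0.95),
        StrandArtifactClass("GTA", "G", 12, 0.95),
    )
    truth_context_class: tuple[str, str] | None = None  # (context, alt)
    truth_context_class_n: int = 0
    n_singlet_errors: int = 20
    artifact_carriers: int = 10
    # masks / sharing
    n_masked_snp_sites: int = 2
    n_shared_across_patients: int = 0
    # DNA evidence
    wes_depth: int = 60
    n_dna_only_calls: int = 3
    # DEG lists
    deg_genes_per_cluster: int = 100
    deg_overlap_truth_genes: int = 2

    def __post_init__(self) -> None:
        for rate in (self.dropout, self.allelic_dropout, self.error_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValidationError("rates must lie in [0, 1]")
        if len(self.t_clonotype_sizes) != len(self.t_clonotype_mutations):
            raise ValidationError("clonotype sizes and mutation counts mismatch")
        total_loci = self.total_planned_loci()
        if total_loci > self.n_genes:
            raise ValidationError(
                f"planned loci ({total_loci}) exceed gene pool ({self.n_genes}); "
                "increase n_genes"
            )

    def total_planned_loci(self) -> int:
        per_patient = (
            sum(c.n_mutations for c in self.tumor_clones)
            + sum(n for _, _, n in self.ch_clones)
            + sum(self.t_clonotype_mutations)
            + self.n_prethymic_shared
            + self.n_cross_lineage_artifacts
            + sum(c.n_mutations for c in self.strand_artifact_classes)
            + self.truth_context_class_n
            + self.n_singlet_errors
            + self.n_masked_snp_sites
            + self.n_dna_only_calls
        )
        return per_patient * self.n_patients + self.n_shared_across_patients


TRUE_SOMATIC_KINDS = ("tumor_clone", "ch_clone", "t_clonotype", "t_prethymic")


@dataclass(frozen=True)
class TruthMutation:
    locus: GenomicLocus
    patient_id: str
    kind: str
    gene: str
    tri_context: str
    gene_strand: str
    lineage: str | None = None
    clone: str | None = None
    clonotype_ids: tuple[str, ...] = ()
    strand_class: str | None = None
    dna_ccf: float | None = None  # cancer-cell fraction for DNA evidence


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset.

    ``carriers`` maps (locus, patient) to the cells seeded with the
    event; ``detectable`` flags the true somatic mutations expected to
    survive the full threshold set given the counts actually emitted
    (computed with independent exact arithmetic, not the pipeline code).
    """

    mutations: list[TruthMutation]
    carriers: dict[tuple[GenomicLocus, str], frozenset[str]]
    detectable: dict[tuple[GenomicLocus, str], bool] = field(default_factory=dict)
    cell_clone: dict[str, str] = field(default_factory=dict)

    def detectable_set(self) -> set[tuple[GenomicLocus, str]]:
        """Keys of true somatic mutations expected in the final calls."""
        return {
            (m.locus, m.patient_id)
            for m in self.mutations
            if m.kind in TRUE_SOMATIC_KINDS
            and self.detectable.get((m.locus, m.patient_id), False)
        }

    def by_kind(self, *kinds: str) -> list[TruthMutation]:
        return [m for m in self.mutations if m.kind in kinds]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mutations": [
                {
                    **dataclasses.asdict(m),
                    "locus": list(m.locus),
                    "detectable": self.detectable.get((m.locus, m.patient_id)),
                    "carriers": sorted(self.carriers[(m.locus, m.patient_id)]),
                }
                for m in self.mutations
            ],
            "cell_clone": self.cell_clone,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimResult:
    config: SimConfig
    cells: list[CellRecord]
    matrix: AlleleCountMatrix
    masks: MaskSet
    dna: DnaEvidence
    truth: SimTruth
    reference: dict[str, str]

    def write(self, outdir: str | Path) -> None:
        """Emit every format the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.to_tsv(outdir / "counts.tsv")
        _write_cells_tsv(self.cells, outdir / "cells.tsv")
        _write_fasta(self.reference, outdir / "genome.fa")
        _write_bed(self.masks.genes, outdir / "genes.bed")
        _write_snp_vcf(sorted(self.masks.known_snp_sites), outdir / "snp_mask.vcf")
        self.dna.to_tsv(outdir / "dna_evidence.tsv")
        if self.masks.deg_genes_by_cluster:
            _write_deg_tsv(self.masks.deg_genes_by_cluster, outdir / "deg.tsv")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# Genome and cells
# ---------------------------------------------------------------------------

def _build_genome(cfg: SimConfig, rng: np.random.Generator):
    """Random contigs with evenly spaced single-exon genes on both strands."""
    n_auto = cfg.n_genes - cfg.n_mt_genes
    per_contig = math.ceil(n_auto / 4)
    slot = cfg.gene_length + cfg.intergenic_length
    genes: list[GeneInterval] = []
    reference: dict[str, str] = {}
    gi = 0
    for ci in range(4):
        n_here = min(per_contig, n_auto - ci * per_contig)
        if n_here <= 0:
            break
        contig = f"chr{ci + 1}"
        length = cfg.intergenic_length + n_here * slot
        reference[contig] = "".join(rng.choice(_BASES, size=length))
        for k in range(n_here):
            start = cfg.intergenic_length + k * slot + 1
            genes.append(GeneInterval(
                chrom=contig, start=start, end=start + cfg.gene_length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                name=f"GENE{gi:04d}", feature="exon",
            ))
            gi += 1
    if cfg.n_mt_genes:
        length = cfg.intergenic_length + cfg.n_mt_genes * slot
        reference["MT"] = "".join(rng.choice(_BASES, size=length))
        for k in range(cfg.n_mt_genes):
            start = cfg.intergenic_length + k * slot + 1
            genes.append(GeneInterval(
                chrom="MT", start=start, end=start + cfg.gene_length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                name=f"GENE{gi:04d}", feature="exon",
            ))
            gi += 1
    return reference, genes


def _make_cells(cfg: SimConfig, pid: str) -> list[CellRecord]:
    cells = []
    i = 0
    for lin in cfg.lineages:
        for k in range(lin.n_cells):
            cells.append(CellRecord(
                cell_id=f"{pid}_c{i:04d}",
                patient_id=pid,
                lineage=lin.name,
                subtype=lin.subtypes[k % len(lin.subtypes)],
            ))
            i += 1
    return cells


# ---------------------------------------------------------------------------
# Locus planning
# ---------------------------------------------------------------------------

class _GenePool:
    """Deterministic allocator of one locus per unused gene."""

    def __init__(self, genes: Sequence[GeneInterval], reference: dict[str, str],
                 rng: np.random.Generator):
        self.reference = reference
        self.rng = rng
        order = rng.permutation(len(genes))
        self.free = [genes[i] for i in order]

    def take(self, strand: str | None = None) -> GeneInterval:
        for i, g in enumerate(self.free):
            if strand is None or g.strand == strand:
                return self.free.pop(i)
        raise ValidationError("gene pool exhausted (infeasible config)")

    def take_with_context(self, context: str, strand: str) -> tuple[GeneInterval, int]:
        """A gene of the given strand whose reference sequence contains
        ``context`` away from the gene edges; returns (gene, middle pos)."""
        for i, g in enumerate(self.free):
            if g.strand != strand:
                continue
            seq = self.reference[g.chrom][g.start + 9 : g.end - 10]
            hit = seq.find(context)
            if hit >= 0:
                self.free.pop(i)
                return g, g.start + 10 + hit + 1  # 1-based middle base
        raise ValidationError(
            f"no free {strand}-strand gene contains context {context}"
        )

    def site_in(self, gene: GeneInterval) -> tuple[int, str]:
        """A central position and its reference base."""
        pos = (gene.start + gene.end) // 2
        base = self.reference[gene.chrom][pos - 1]
        return pos, base


def _random_alt(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


# ---------------------------------------------------------------------------
# Independent detectability arithmetic (exact, no scipy)
# ---------------------------------------------------------------------------

def _binom_cdf_exact(k: int, n: int) -> float:
    """P(X <= k) for X ~ Binomial(n, 1/2), by direct summation."""
    if n == 0:
        return 1.0
    total = sum(math.comb(n, i) for i in range(0, k + 1))
    return total / 2 ** n


def _hypergeom_tail_exact(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table's hypergeometric null, exact fractions."""
    n_top = a + b
    k_var = a + c
    n_tot = a + b + c + d
    if n_tot == 0:
        return 1.0
    num = sum(
        math.comb(n_top, k) * math.comb(n_tot - n_top, k_var - k)
        for k in range(a, min(n_top, k_var) + 1)
    )
    return num / math.comb(n_tot, k_var)


def _expected_detectable(
    locus: GenomicLocus,
    origin_lineage: str,
    matrix_entries: dict[str, tuple[int, int]],
    lineage_of: dict[str, str],
    carriers: frozenset[str],
) -> bool:
    """Would this mutation survive the full threshold set, given the
    emitted counts?  Exact arithmetic, independent of the pipeline code.

    Requires: >=2 then >=5 carrier cells (after the reference-excess
    rule) confined to the origin lineage, >=20 reference cells outside
    it, one-sided hypergeometric tail < 1e-4 and prevalence ratio >= 5.
    """
    kept = set()
    extra_lineages = set()
    for cell, (r, v) in matrix_entries.items():
        if v >= 1:
            lin = lineage_of[cell]
            if lin != origin_lineage:
                extra_lineages.add(lin)
            elif _binom_cdf_exact(v, r + v) >= 0.05:
                kept.add(cell)
    if extra_lineages:
        return False  # cross-lineage sharing (error reads) kills the call
    a = len(kept)
    if a < 5:
        return False
    b = sum(
        1 for cell, (r, v) in matrix_entries.items()
        if cell not in kept and r >= 1 and lineage_of[cell] == origin_lineage
    )
    c = 0
    d = sum(
        1 for cell, (r, v) in matrix_entries.items()
        if r >= 1 and v == 0 and lineage_of[cell] != origin_lineage
    )
    if d < 20:
        return False
    if _hypergeom_tail_exact(a, b, c, d) >= 1e-4:
        return False
    return True  # c == 0 makes the prevalence ratio +inf >= 5


# ---------------------------------------------------------------------------
# Count emission
# ---------------------------------------------------------------------------

def _emit_locus(
    rng: np.random.Generator,
    cfg: SimConfig,
    n_cells: int,
    carrier_idx: np.ndarray,
    expr_rate: float,
    forced: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (ref, var) read vectors at one locus.

    Expression is Bernoulli(expr_rate * (1 - dropout)); expressed cells
    draw Poisson depth; carriers split reads ~Binomial(depth, 1/2) with
    allelic dropout forcing monoallelic output; non-carriers draw variant
    reads at the error rate.  ``forced`` carriers (injected artifacts)
    instead get balanced counts with at least one variant read so they
    survive to the filter stage under test.
    """
    p = expr_rate * (1.0 - cfg.dropout)
    expressed = rng.random(n_cells) < p
    depth = rng.poisson(cfg.mean_depth, n_cells)
    covered = expressed & (depth > 0)

    carrier = np.zeros(n_cells, dtype=bool)
    carrier[carrier_idx] = True

    var = np.zeros(n_cells, dtype=np.int64)
    ref = np.zeros(n_cells, dtype=np.int64)

    if forced:
        # artifact injection: counts independent of expression model
        k = len(carrier_idx)
        ref[carrier_idx] = rng.poisson(3.0, k)
        var[carrier_idx] = rng.poisson(2.5, k) + 1
        noncar = covered & ~carrier
        v_err = rng.binomial(depth[noncar], cfg.error_rate)
        var[noncar] = v_err
        ref[noncar] = depth[noncar] - v_err
        return ref, var

    is_car = carrier & covered
    u = rng.random(n_cells)
    mono_ref = is_car & (u < cfg.allelic_dropout / 2)
    mono_var = is_car & (u >= cfg.allelic_dropout / 2) & (u < cfg.allelic_dropout)
    biallelic = is_car & (u >= cfg.allelic_dropout)
    var[biallelic] = rng.binomial(depth[biallelic], 0.5)
    var[mono_var] = depth[mono_var]
    # mono_ref carriers emit reference only
    ref[is_car] = depth[is_car] - var[is_car]
    ref[mono_ref] = depth[mono_ref]

    noncar = covered & ~carrier
    v_err = rng.binomial(depth[noncar], cfg.error_rate)
    var[noncar] = v_err
    ref[noncar] = depth[noncar] - v_err
    return ref, var


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------

@dataclass
class _PlannedLocus:
    locus: GenomicLocus
    patient_id: str
    kind: str
    gene: GeneInterval
    carriers: frozenset[str]
    origin_lineage: str | None
    clone: str | None = None
    clonotype_ids: tuple[str, ...] = ()
    strand_class: str | None = None
    dna_ccf: float | None = None
    expr_rate: float = 0.5
    forced: bool = False


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate one fully labeled dataset under ``config``.

    Returns cell metadata, the sparse allele-count matrix, masks (gene
    annotation, SNP sites, DEG lists), a DNA-evidence table consistent
    with the tumor clone fractions, and the truth labels with expected
    detectability per true mutation.  Byte-identical under the same
    config (the seed included).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    reference, genes = _build_genome(cfg, rng)
    pool = _GenePool(genes, reference, rng)

    # gene expression rates; boosted for mutation-hosting genes at planning
    base_rates = np.clip(
        rng.lognormal(cfg.expr_log_mu, cfg.expr_log_sigma, cfg.n_genes), 0.02, 0.95
    )
    expr_rate = {g.name: float(r) for g, r in zip(genes, base_rates)}

    all_cells: list[CellRecord] = []
    planned: list[_PlannedLocus] = []
    cell_clone: dict[str, str] = {}
    snp_sites: set[tuple[str, int, str]] = set()

    def plan_site(pid, kind, carriers, origin_lineage, *, gene=None, strand=None,
                  context=None, alt=None, clone=None, clonotype_ids=(),
                  strand_class=None, dna_ccf=None, forced=False, boost=True):
        if context is not None:
            gene, pos = pool.take_with_context(context, strand)
            ref_base = context[1]
        else:
            gene = gene or pool.take(strand)
            pos, ref_base = pool.site_in(gene)
        if boost:
            expr_rate[gene.name] = max(
                expr_rate[gene.name], cfg.min_expr_rate_mutated
            )
        alt_base = alt or _random_alt(ref_base, rng)
        locus = GenomicLocus.make(gene.chrom, pos, ref_base, alt_base)
        tri = reference[gene.chrom][pos - 2 : pos + 1]
        planned.append(_PlannedLocus(
            locus=locus, patient_id=pid, kind=kind, gene=gene,
            carriers=frozenset(carriers), origin_lineage=origin_lineage,
            clone=clone, clonotype_ids=tuple(clonotype_ids),
            strand_class=strand_class, dna_ccf=dna_ccf,
            expr_rate=expr_rate[gene.name], forced=forced,
        ))
        return locus, tri

    shared_sites: list[tuple[GeneInterval, int, str, str]] = []

    for p in range(cfg.n_patients):
        pid = f"P{p + 1}"
        cells = _make_cells(cfg, pid)
        all_cells.extend(cells)
        by_lineage: dict[str, list[CellRecord]] = {}
        for c in cells:
            by_lineage.setdefault(c.lineage, []).append(c)

        # --- tumor clone tree -------------------------------------------
        tumor_cells = by_lineage.get(cfg.tumor_lineage, [])
        clone_names = [cl.name for cl in cfg.tumor_clones]
        fractions = np.array([cl.fraction for cl in cfg.tumor_clones])
        fractions = fractions / fractions.sum() if fractions.sum() else fractions
        assignment = rng.choice(
            len(clone_names), size=len(tumor_cells), p=fractions
        )
        clone_cells: dict[str, set[str]] = {n: set() for n in clone_names}
        for cell, ci in zip(tumor_cells, assignment):
            clone_cells[clone_names[ci]].add(cell.cell_id)
            cell_clone[cell.cell_id] = clone_names[ci]
        parent_of = {cl.name: cl.parent for cl in cfg.tumor_clones}

        def clade_cells(name: str) -> set[str]:
            out = set(clone_cells[name])
            for child, par in parent_of.items():
                if par == name:
                    out |= clade_cells(child)
            return out

        n_tumor = max(len(tumor_cells), 1)
        for cl in cfg.tumor_clones:
            carriers = clade_cells(cl.name)
            ccf = len(carriers) / n_tumor
            for _ in range(cl.n_mutations):
                plan_site(pid, "tumor_clone", carriers, cfg.tumor_lineage,
                          clone=cl.name, dna_ccf=ccf)

        # --- clonal hematopoiesis ---------------------------------------
        myeloid_cells = by_lineage.get(cfg.myeloid_lineage, [])
        myeloid_subtypes = sorted({c.subtype for c in myeloid_cells})
        taken: set[str] = set()
        for k, (name, n_cells_clone, n_muts) in enumerate(cfg.ch_clones):
            avail = [c for c in myeloid_cells if c.cell_id not in taken]
            preferred = (
                myeloid_subtypes[k % len(myeloid_subtypes)]
                if myeloid_subtypes else None
            )
            w = np.array([
                cfg.ch_subtype_bias if c.subtype == preferred else 1.0
                for c in avail
            ])
            idx = rng.choice(
                len(avail), size=min(n_cells_clone, len(avail)),
                replace=False, p=w / w.sum(),
            )
            chosen = {avail[i].cell_id for i in idx}
            taken |= chosen
            for cid in chosen:
                cell_clone[cid] = name
            for _ in range(n_muts):
                plan_site(pid, "ch_clone", chosen, cfg.myeloid_lineage,
                          clone=name)

        # --- T clonotypes -----------------------------------------------
        cd8 = [
            c for c in by_lineage.get(cfg.t_lineage, [])
            if c.subtype in cfg.clonotype_subtypes
        ]
        clonotype_of: dict[str, str] = {}
        idx = 0
        clonotype_members: list[set[str]] = []
        for k, size in enumerate(cfg.t_clonotype_sizes):
            members = {c.cell_id for c in cd8[idx: idx + size]}
            if len(members) < size:
                raise ValidationError("not enough CD8 cells for clonotype sizes")
            for cid in members:
                clonotype_of[cid] = f"{pid}_ct{k + 1}"
            clonotype_members.append(members)
            idx += size
        for j, c in enumerate(cd8[idx:]):
            clonotype_of[c.cell_id] = f"{pid}_sg{j + 1}"  # singleton clonotypes
        for k, (members, n_muts) in enumerate(
            zip(clonotype_members, cfg.t_clonotype_mutations)
        ):
            for _ in range(n_muts):
                plan_site(pid, "t_clonotype", members, cfg.t_lineage,
                          clonotype_ids=(f"{pid}_ct{k + 1}",))
        for _ in range(cfg.n_prethymic_shared):
            members = clonotype_members[0] | clonotype_members[-1]
            plan_site(
                pid, "t_prethymic", members, cfg.t_lineage,
                clonotype_ids=(f"{pid}_ct1",
                               f"{pid}_ct{len(cfg.t_clonotype_sizes)}"),
            )

        # annotate clonotypes onto the cell records
        for i, c in enumerate(all_cells):
            if c.patient_id == pid and c.cell_id in clonotype_of:
                all_cells[i] = dataclasses.replace(
                    c, clonotype_id=clonotype_of[c.cell_id]
                )

        # --- masked SNP-like sites (clonal but in the mask) -------------
        lineage_cycle = [s.name for s in cfg.lineages]
        for k in range(cfg.n_masked_snp_sites):
            lin = lineage_cycle[k % len(lineage_cycle)]
            members = {
                c.cell_id
                for c in rng.choice(by_lineage[lin],
                                    size=min(cfg.artifact_carriers,
                                             len(by_lineage[lin])),
                                    replace=False)
            }
            locus, _ = plan_site(pid, "masked_snp", members, lin, forced=True)
            snp_sites.add((locus.chrom, locus.pos, locus.alt_base))

        # --- shared-across-patients sites -------------------------------
        for k in range(cfg.n_shared_across_patients):
            if p == 0:
                gene = pool.take()
                pos, ref_base = pool.site_in(gene)
                alt_base = _random_alt(ref_base, rng)
                expr_rate[gene.name] = max(
                    expr_rate[gene.name], cfg.min_expr_rate_mutated
                )
                shared_sites.append((gene, pos, ref_base, alt_base))
            gene, pos, ref_base, alt_base = shared_sites[k]
            lin = cfg.tumor_lineage
            members = {
                c.cell_id
                for c in rng.choice(by_lineage[lin], size=cfg.artifact_carriers,
                                    replace=False)
            }
            planned.append(_PlannedLocus(
                locus=GenomicLocus.make(gene.chrom, pos, ref_base, alt_base),
                patient_id=pid, kind="shared_across_patients", gene=gene,
                carriers=frozenset(members), origin_lineage=lin,
                expr_rate=expr_rate[gene.name], forced=True,
            ))

        # --- DNA-only calls (missed by the transcriptome) ----------------
        for _ in range(cfg.n_dna_only_calls):
            plan_site(pid, "dna_only", set(), cfg.tumor_lineage,
                      dna_ccf=1.0, boost=True)

    # --- injected artifacts (separate op, shared rng stream) -------------
    artifact_plans = _plan_artifacts(cfg, all_cells, pool, expr_rate, rng)
    planned.extend(artifact_plans)

    # --- emission ---------------------------------------------------------
    cells_by_patient: dict[str, list[CellRecord]] = {}
    for c in all_cells:
        cells_by_patient.setdefault(c.patient_id, []).append(c)

    entries = []
    emitted: dict[tuple[GenomicLocus, str], dict[str, tuple[int, int]]] = {}
    for plan in sorted(planned, key=lambda q: (q.patient_id, q.locus)):
        cells = cells_by_patient[plan.patient_id]
        ids = [c.cell_id for c in cells]
        index_of = {cid: i for i, cid in enumerate(ids)}
        carrier_idx = np.array(
            sorted(index_of[c] for c in plan.carriers), dtype=np.int64
        )
        ref, var = _emit_locus(
            rng, cfg, len(cells), carrier_idx,
            expr_rate[plan.gene.name], plan.forced,
        )
        locus_entries = {}
        for i in np.nonzero(ref + var > 0)[0]:
            entries.append((ids[i], plan.locus, int(ref[i]), int(var[i])))
            locus_entries[ids[i]] = (int(ref[i]), int(var[i]))
        emitted[(plan.locus, plan.patient_id)] = locus_entries

    matrix = AlleleCountMatrix(entries)

    # --- truth, detectability, DNA evidence -------------------------------
    truth_mutations = []
    carriers_map = {}
    detectable = {}
    dna_records: dict[GenomicLocus, DnaRecord] = {}
    lineage_of_all = {c.cell_id: c.lineage for c in all_cells}
    for plan in planned:
        key = (plan.locus, plan.patient_id)
        tri = reference[plan.locus.chrom][plan.locus.pos - 2: plan.locus.pos + 1]
        truth_mutations.append(TruthMutation(
            locus=plan.locus, patient_id=plan.patient_id, kind=plan.kind,
            gene=plan.gene.name, tri_context=tri, gene_strand=plan.gene.strand,
            lineage=plan.origin_lineage, clone=plan.clone,
            clonotype_ids=plan.clonotype_ids, strand_class=plan.strand_class,
            dna_ccf=plan.dna_ccf,
        ))
        carriers_map[key] = plan.carriers
        if plan.kind in TRUE_SOMATIC_KINDS:
            pid_lineages = {
                c.cell_id: c.lineage
                for c in cells_by_patient[plan.patient_id]
            }
            detectable[key] = _expected_detectable(
                plan.locus, plan.origin_lineage, emitted[key],
                pid_lineages, plan.carriers,
            )
        if plan.dna_ccf is not None:
            v = int(rng.binomial(cfg.wes_depth, plan.dna_ccf / 2))
            dna_records[plan.locus] = DnaRecord(
                tumor_var_reads=v,
                tumor_ref_reads=cfg.wes_depth - v,
                normal_var_reads=0,
                orthogonal_call=v >= 4,
            )

    # extra benign SNP-mask entries (never simulated as counts)
    for _ in range(5):
        gene = pool.take()
        pos, ref_base = pool.site_in(gene)
        snp_sites.add((gene.chrom, pos, _random_alt(ref_base, rng)))

    deg_lists = _make_deg_lists(cfg, all_cells, planned, genes, rng)
    masks = MaskSet(known_snp_sites=snp_sites, genes=genes,
                    deg_genes_by_cluster=deg_lists)
    truth = SimTruth(
        mutations=truth_mutations, carriers=carriers_map,
        detectable=detectable, cell_clone=cell_clone,
    )
    logger.info(
        "simulated %d cells, %d loci (%d true somatic, %d expected detectable)",
        len(all_cells), len(planned),
        len(truth.by_kind(*TRUE_SOMATIC_KINDS)), len(truth.detectable_set()),
    )
    return SimResult(
        config=cfg, cells=all_cells, matrix=matrix, masks=masks,
        dna=DnaEvidence(dna_records), truth=truth, reference=reference,
    )


def _plan_artifacts(
    cfg: SimConfig,
    all_cells: Sequence[CellRecord],
    pool: _GenePool,
    expr_rate: dict[str, float],
    rng: np.random.Generator,
) -> list[_PlannedLocus]:
    """Plan the injected artifact loci (all labeled in the truth).

    Cross-lineage site errors span >=2 lineages; strand-class artifacts
    reproduce the transcribed-strand-asymmetric context failure mode at
    the configured ratio; singlet errors touch one cell.  The balanced
    ``truth_context_class`` plants clone-like true-context mutations on
    both strands to give the strand filter a class it must retain.
    """
    plans: list[_PlannedLocus] = []
    by_patient_lineage: dict[tuple[str, str], list[str]] = {}
    for c in all_cells:
        by_patient_lineage.setdefault((c.patient_id, c.lineage), []).append(c.cell_id)
    patients = sorted({c.patient_id for c in all_cells})
    lineage_names = [s.name for s in cfg.lineages]

    def pick_cells(pid, lineage, k):
        cells = by_patient_lineage[(pid, lineage)]
        return set(rng.choice(cells, size=min(k, len(cells)), replace=False))

    def add(pid, kind, carriers, origin, *, context=None, strand=None,
            alt=None, strand_class=None):
        if context is not None:
            gene, pos = pool.take_with_context(context, strand)
            ref_base = context[1]
        else:
            gene = pool.take()
            pos, ref_base = pool.site_in(gene)
        expr_rate[gene.name] = max(expr_rate[gene.name], cfg.min_expr_rate_mutated)
        alt_base = alt or _random_alt(ref_base, rng)
        plans.append(_PlannedLocus(
            locus=GenomicLocus.make(gene.chrom, pos, ref_base, alt_base),
            patient_id=pid, kind=kind, gene=gene,
            carriers=frozenset(carriers), origin_lineage=origin,
            strand_class=strand_class,
            expr_rate=expr_rate[gene.name], forced=True,
        ))

    for i in range(cfg.n_cross_lineage_artifacts * len(patients)):
        pid = patients[i % len(patients)]
        start = int(rng.integers(0, len(lineage_names)))
        chosen = [
            lineage_names[(start + j) % len(lineage_names)]
            for j in range(cfg.cross_lineage_n_lineages)
        ]
        carriers = set()
        for lin in chosen:
            carriers |= pick_cells(pid, lin, cfg.cross_lineage_cells_per_lineage)
        add(pid, "cross_lineage_artifact", carriers, None)

    for cls in cfg.strand_artifact_classes:
        if cls.context[1] not in "CT" or cls.alt == cls.context[1]:
            raise ValidationError(
                f"strand class context must be pyrimidine-centered, alt != ref: {cls}"
            )
        for i in range(cls.n_mutations * len(patients)):
            pid = patients[i % len(patients)]
            strand = "+" if rng.random() < cls.plus_fraction else "-"
            lin = lineage_names[int(rng.integers(0, len(lineage_names)))]
            carriers = pick_cells(pid, lin, cfg.artifact_carriers)
            add(pid, "strand_artifact", carriers, lin,
                context=cls.context, strand=strand, alt=cls.alt,
                strand_class=f"{cls.context}>{cls.alt}")

    if cfg.truth_context_class is not None and cfg.truth_context_class_n:
        context, alt = cfg.truth_context_class
        for i in range(cfg.truth_context_class_n):
            pid = patients[i % len(patients)]
            strand = "+" if i % 2 == 0 else "-"
            lin = lineage_names[int(rng.integers(0, len(lineage_names)))]
            carriers = pick_cells(pid, lin, cfg.artifact_carriers)
            add(pid, "context_class_truth", carriers, lin,
                context=context, strand=strand, alt=alt,
                strand_class=f"{context}>{alt}")

    for i in range(cfg.n_singlet_errors * len(patients)):
        pid = patients[i % len(patients)]
        lin = lineage_names[int(rng.integers(0, len(lineage_names)))]
        carriers = pick_cells(pid, lin, 1)
        add(pid, "singlet_error", carriers, lin)

    return plans


def inject_artifacts(
    matrix: AlleleCountMatrix,
    config: SimConfig,
    *,
    cells: Sequence[CellRecord],
    genes: Sequence[GeneInterval],
    reference: dict[str, str],
    seed: int | None = None,
) -> tuple[AlleleCountMatrix, list[TruthMutation]]:
    """Add labeled artifact loci to an existing matrix.

    A zero-artifact config returns the matrix unchanged with an empty
    label list.  Artifact loci are drawn from genes not already carrying
    counts in ``matrix``.
    """
    cfg = config
    if (cfg.n_cross_lineage_artifacts == 0
            and not cfg.strand_artifact_classes
            and cfg.truth_context_class_n == 0
            and cfg.n_singlet_errors == 0):
        return matrix, []

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    used_chrom_pos = {(l.chrom, l.pos) for l in matrix.loci}
    free_genes = [
        g for g in genes
        if not any(g.contains(ch, pos) for ch, pos in used_chrom_pos)
    ]
    pool = _GenePool(free_genes, reference, rng)
    expr_rate = {g.name: cfg.min_expr_rate_mutated for g in free_genes}
    plans = _plan_artifacts(cfg, cells, pool, expr_rate, rng)

    cells_by_patient: dict[str, list[CellRecord]] = {}
    for c in cells:
        cells_by_patient.setdefault(c.patient_id, []).append(c)

    entries = [
        (c, loc, r, v)
        for loc in matrix.loci
        for c, (r, v) in matrix.counts_at(loc).items()
    ]
    for plan in sorted(plans, key=lambda q: (q.patient_id, q.locus)):
        pcells = cells_by_patient[plan.patient_id]
        ids = [c.cell_id for c in pcells]
        index_of = {cid: i for i, cid in enumerate(ids)}
        carrier_idx = np.array(
            sorted(index_of[c] for c in plan.carriers), dtype=np.int64
        )
        ref, var = _emit_locus(
            rng, cfg, len(pcells), carrier_idx, plan.expr_rate, True
        )
        for i in np.nonzero(ref + var > 0)[0]:
            entries.append((ids[i], plan.locus, int(ref[i]), int(var[i])))

    labels = [
        TruthMutation(
            locus=p.locus, patient_id=p.patient_id, kind=p.kind,
            gene=p.gene.name,
            tri_context=reference[p.locus.chrom][p.locus.pos - 2: p.locus.pos + 1],
            gene_strand=p.gene.strand, lineage=p.origin_lineage,
            strand_class=p.strand_class,
        )
        for p in plans
    ]
    return AlleleCountMatrix(entries), labels


def _make_deg_lists(cfg, cells, planned, genes, rng) -> dict[str, list[str]]:
    """Per-subtype top-DEG gene lists; a couple of mutation-hosting genes
    are planted in the first list to exercise the tracing exclusion."""
    subtypes = sorted({c.subtype for c in cells})
    mutated_genes = [p.gene.name for p in planned if p.kind in TRUE_SOMATIC_KINDS]
    unmutated = [g.name for g in genes if g.name not in set(mutated_genes)]
    lists: dict[str, list[str]] = {}
    for si, s in enumerate(subtypes):
        start = (si * cfg.deg_genes_per_cluster) % max(len(unmutated), 1)
        chosen = [
            unmutated[(start + j) % len(unmutated)]
            for j in range(min(cfg.deg_genes_per_cluster, len(unmutated)))
        ]
        lists[s] = chosen
    planted = sorted(set(mutated_genes))[: cfg.deg_overlap_truth_genes]
    if planted and subtypes:
        head = lists[subtypes[0]]
        lists[subtypes[0]] = planted + head[: len(head) - len(planted)]
    return lists


# ---------------------------------------------------------------------------
# Preset configurations (study conditions for the standard checks)
# ---------------------------------------------------------------------------

def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard noisy, artifact-bearing study conditions."""
    return dataclasses.replace(SimConfig(seed=seed), **overrides)


def noise_free_config(seed: int = 0, **overrides) -> SimConfig:
    """Error-free, dropout-free conditions: every true mutation should be
    detected and nothing else (pipeline-closure regime)."""
    base = dict(
        seed=seed,
        dropout=0.0,
        allelic_dropout=0.0,
        error_rate=0.0,
        min_expr_rate_mutated=0.75,
        mean_depth=10.0,
        n_cross_lineage_artifacts=0,
        strand_artifact_classes=(),
        n_singlet_errors=0,
        n_masked_snp_sites=0,
        n_dna_only_calls=0,
    )
    base.update(overrides)
    return SimConfig(**base)


def artifact_config(seed: int = 0, **overrides) -> SimConfig:
    """Noise-free truth plus heavy artifact injection: 100 cross-lineage
    site errors, a 42-member strand class at ~20:1 asymmetry, a balanced
    19-member true context class, and 30 singlet errors."""
    base = dict(
        seed=seed,
        dropout=0.0,
        allelic_dropout=0.0,
        error_rate=0.0,
        min_expr_rate_mutated=0.75,
        mean_depth=10.0,
        n_cross_lineage_artifacts=100,
        strand_artifact_classes=(
            StrandArtifactClass("GCA", "G", 42, 20.0 / 21.0),
        ),
        truth_context_class=("TCT", "T"),
        truth_context_class_n=19,
        n_singlet_errors=30,
        n_masked_snp_sites=0,
        n_dna_only_calls=0,
        n_genes=400,
    )
    base.update(overrides)
    return SimConfig(**base)


def clonotype_config(seed: int = 0, n_prethymic_shared: int = 0, **overrides) -> SimConfig:
    """Noise-free conditions for the TCR-clonotype benchmark: all T-cell
    mutations are acquired after clonal expansion unless
    ``n_prethymic_shared`` plants mutations spanning two clonotypes."""
    return noise_free_config(
        seed=seed, n_prethymic_shared=n_prethymic_shared, **overrides
    )


# ---------------------------------------------------------------------------
# Writers for the emitted formats
# ---------------------------------------------------------------------------

def _write_cells_tsv(cells: Sequence[CellRecord], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "cell_id": c.cell_id, "patient_id": c.patient_id,
                "lineage": c.lineage, "subtype": c.subtype,
                "clonotype_id": c.clonotype_id or "",
                "region": c.region or "",
            }
            for c in cells
        ]
    ).to_csv(path, sep="\t", index=False)


def _write_fasta(reference: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")


def _write_bed(genes: Sequence[GeneInterval], path: Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.name}\t0\t{g.strand}\n"
            )


def _write_snp_vcf(sites: Sequence[tuple[str, int, str]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({s[0] for s in sites}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, alt in sorted(sites):
            ref = next(b for b in "ACGT" if b != alt)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def _write_deg_tsv(deg: dict[str, list[str]], path: Path) -> None:
    import pandas as pd

    rows = [
        {"cluster": cluster, "gene": gene, "rank": i + 1}
        for cluster in sorted(deg)
        for i, gene in enumerate(deg[cluster])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
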