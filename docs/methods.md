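# Methods

## Problem and model

Droplet scRNA-seq reads carry the cell's expressed genome, so somatic
mutations can in principle be read off the transcriptome — but naive
per-cell variant calling at transcriptome scale produces overwhelmingly
artifactual calls. `scmutcall` implements a calling cascade whose
specificity comes entirely from population-level structure rather than
read-level heuristics:

1. **Candidate enumeration.** Any locus at which at least one cell has a
   variant-supporting read is a candidate; a cell *carries* a candidate
   iff its variant count is ≥ 1. (An external high-sensitivity pileup
   caller would serve the same role; a count threshold keeps the core
   dependency-free, and an optional barcoded-BAM adapter produces the
   same count table by per-cell pileup.)
2. **Singlet removal.** Candidates carried by a single cell are
   uninterpretable and dropped (per patient: candidates are
   patient-scoped throughout).
3. **Cross-lineage removal.** Somatic mutations are acquired after
   embryonic lineage commitment, so carriers spanning more than one
   major lineage (T/NK, B/plasma, myeloid, endothelial, epithelial,
   fibroblast, tumor) indicate a site-specific artifact. Sharing between
   subtypes of one lineage is allowed.
4. **Per-cell allelic binomial filter.** For a heterozygous autosomal
   site, reads split ~Binomial(n, ½) between alleles. For each carrier
   with `ref` and `var` reads, the one-sided tail
   P(X ≤ var | n = ref+var, p = ½) < 0.05 flags significant reference
   excess (mapping artifact / high-depth noise) and the cell's call is
   ignored. The test is one-sided deliberately: monoallelic bursts of
   the variant allele are biologically real and must not be discarded.
   Ignored cells keep their reference reads and count toward the
   reference population downstream.
5. **Enrichment statistics.** Per candidate, cells are tabulated as
   (top group vs all others) × (variant vs reference), where groups are
   major lineages (or TCR clonotypes, for the CD8⁺ benchmark), the top
   group is the one with most variant cells (ties broken
   lexicographically and flagged), variant cells are the accepted
   carriers, and reference cells are cells with ≥ 1 reference read that
   are not variant cells. A one-sided Fisher exact test gives the
   enrichment p; the enrichment factor is the prevalence ratio
   (var_top / row total) / (var_other / row total), defined as +∞ when
   no other group carries the variant (maximal enrichment, passes the
   ratio threshold) and 0 for an all-zero table (p = 1).
6. **Final thresholds** (fixed, uncorrected — the operating point is
   defined by raw cutoffs, and multiple-testing correction would move
   it): Fisher p < 1e-4 **and** factor ≥ 5; absence from the known-SNP
   mask; the same chrom/pos/alt called in two patients fails in both;
   ≥ 5 variant cells in the top group and ≥ 20 reference cells outside
   it.
7. **Transcribed-strand bias filter.** True mutational processes leave
   (substitution, trinucleotide-context) classes roughly balanced
   between transcribed strands; library-prep/RNA-editing artifacts do
   not. Classes are pyrimidine-normalized 3-mer substitutions pooled
   across the dataset; the strand label is the transcribed strand of
   the host gene (absent for intergenic sites or genes on both
   strands). For each class with ≥ 10 strand-assignable members, a
   two-sided exact binomial test against 1:1 at p < 0.005 removes the
   whole class, including its strand-unassignable members — erring
   toward specificity. Smaller classes are untested.
8. **Proximity filter.** Within a patient, calls on one chromosome
   within 4 bp of each other (transitively) are removed as clustered
   alignment artifacts.

Candidate counts are non-increasing through every stage, and steps 2–3
commute.

## Benchmarks

**DNA evidence.** Each final call is classified against a per-locus
exome table (tumor variant/reference reads, matched-normal variant
reads, whether the DNA pipeline called it): *TP* — called by both; *TP
pileup-only* — ≥ 2 tumor variant reads with zero normal variant reads
but no DNA-pipeline call (typically low DNA coverage or mtDNA); *FP* —
< 5 variant and > 20 reference reads in the exome; *indeterminate* —
anything else, including loci absent from the table. Where a locus
meets both the pileup-support and FP depth conditions, pileup support
takes precedence: positive evidence of the mutation in DNA should not
count against precision. DNA-pipeline calls missed by the transcriptome
are *FN* when the single-cell data had adequate coverage, interpreted
as ≥ 5 cells of the DNA-assayed lineage with any read at the locus and
≥ 20 reference cells outside it (the coverage reading of an ambiguous
condition; a literal "5 cells with the variant" would make every such
site callable). Then

    precision  = (TP + TP_pileup_only) / (TP + TP_pileup_only + FP)
    sensitivity = TP / (TP + FN)

with indeterminate calls excluded from both and zero denominators
reported as undefined, never 0.

**TCR clonotypes.** Mutations in expanded CD8⁺ T cells acquired after
thymic egress must be confined to one clonotype. The pipeline is re-run
on clonotyped cells with clonotype grouping and otherwise identical
thresholds; the reported fraction is (# calls whose variant cells share
one clonotype) / (# calls).

## Burden and lineage tracing

Per (patient, lineage) with ≥ 100 cells, the burden profile is the
proportion of cells carrying exactly 1, 2, 3 and > 3 final calls
(proportions plus the zero-mutation fraction sum to 1). For lineage
tracing, calls are reduced to a binary mutation × subtype matrix
(present iff ≥ 1 carrier cell of that subtype — configurable);
mutations in any cluster's top-100 DEG list are excluded first, because
their detection tracks expression rather than ancestry, and all-zero
rows are dropped. Distances between subtypes are asymmetric-binary
(Jaccard): |symmetric difference| / |union| over mutations, double
absences ignored, 0 on empty unions. The tree is Saitou–Nei neighbor
joining with Q-criterion ties broken by lexicographic leaf-pair order
(degenerate inputs are deterministic) and negative branch lengths
clamped to 0 and counted. Bootstrap supports resample mutation rows
with replacement (default 100 replicates, explicit index draws from a
seeded generator, so results are platform- and row-order-invariant);
an internal edge's support is the number of replicates containing the
same bipartition.

## Synthetic data

The simulator emulates the regime the caller targets: per patient,
1,200 cells over 7 lineages; a tumor whose cells are assigned to a
3-clone tree (trunk 20 mutations, two subclones of 8 and 7 at 40% each)
with mutations inherited down the branches; two myeloid
clonal-hematopoiesis clones (40 and 30 cells, 5 mutations each) drawn
with a 6:1 preference for one monocyte/macrophage subtype each (clone
representation across differentiation states is what gives the subtype
tree signal); and expanded CD8⁺ TCR clonotypes of 40/25/15/4 cells
carrying 6/5/4/0 post-thymic mutations, remaining CD8 cells in
singleton clonotypes. Optional pre-thymic mutations span the largest
and smallest expanded clonotypes.

Counts: each gene has an expression rate (log-normal, clipped to
[0.02, 0.95]; mutation-hosting genes floored at 0.6 so the events are
observable); a cell expresses a locus with probability
rate × (1 − dropout), draws Poisson(8) total reads, and splits them
Binomial(depth, ½) if a carrier — with allelic dropout 0.15 forcing
monoallelic output — or draws variant reads at the per-base error rate
2e-5 (UMI-consensus scale) otherwise. Loci live on a generated ~140 kb
genome (4 contigs + MT) of 300-bp single-exon genes on both strands,
one locus per gene (so proximity clustering never triggers on truth).
Injected artifacts are emitted with forced balanced counts so they
reach the filter stage under test: cross-lineage site errors (3
lineages × 3 cells), strand-class artifacts (pyrimidine-context loci
found in genes of the sampled strand at the configured +/− ratio, 10
carriers in one lineage), singlet errors, SNP-mask-listed clonal sites,
and cross-patient shared sites. DNA evidence draws tumor variant reads
Binomial(60, ccf/2) per tumor mutation with a clean matched normal,
plus configurable DNA-only calls for the FN path.

Each true somatic mutation gets an *expected-detectability* flag
computed from the emitted counts with independent exact arithmetic
(`math.comb` fractions, not the pipeline's scipy calls): carriers
surviving the reference-excess rule ≥ 5 and confined to the origin
lineage, reference cells outside ≥ 20, exact hypergeometric tail
< 1e-4, prevalence ratio ≥ 5. The flag is the full threshold check
rather than the bare cell counts because a broadly expressed mutation
with exactly 5 carriers can meet the cell counts yet fail the Fisher
threshold; the closure property (noise-free calls = detectable truth,
exactly) needs the flag to mean "expected to pass".

What the generator does **not** model: read-level data (FASTQ),
realistic transcriptome-wide expression covariance, doublets, ambient
RNA, copy-number-driven allelic imbalance, indels. Passing tests
therefore demonstrate the logic and statistics of the cascade, not
performance on real droplet data, where candidate counts are orders of
magnitude larger and error structure is richer.

## Numerical and design choices

- Coordinates are 1-based inclusive (VCF convention); "chrM"/"chrMT"/"M"
  normalize to "MT" and mitochondrial loci are treated like autosomal.
- Fisher p via `scipy.stats.fisher_exact(alternative="greater")`;
  binomial tails via `scipy.stats.binom.cdf` / `binomtest`. Tests check
  both against exact-fraction enumeration (|Δp| < 1e-9).
- Gene/exonic annotation is interval overlap against user-supplied
  BED6/GFF3 (a locus is exonic iff an exon-typed interval covers it);
  no functional-consequence prediction. BED intervals default to
  feature "exon" (single-exon gene models).
- BAM adapter defaults: base quality ≥ 20, mapping quality ≥ 30, CB
  barcode tag (all configurable; duplicates/secondary/QC-fail reads
  skipped).
- Neighbor joining is implemented in-package because the deterministic
  tie rule and clamp accounting are part of the contract; a library NJ
  is used only as an independent cross-check in tests.
- Problem sizes in tests and the acceptance script (1,200 cells,
  ~60–250 loci, 100 bootstrap replicates) are the simulator's standard
  study conditions; the whole suite runs in well under a minute of
  compute per scenario.

## Known limitations

- Initial candidate enumeration from counts (≥ 1 variant read) is more
  permissive than a pileup caller; with non-negligible per-cell error
  rates it inflates carrier sets, and a single error read in another
  lineage removes a true mutation via the cross-lineage rule. At
  UMI-consensus error scales this loss is a few percent of true
  mutations (visible as sensitivity < 1 under the default noisy
  conditions).
- Class-level strand-bias removal deletes true mutations that happen to
  share a context class with an artifact process — a deliberate trade
  of sensitivity for specificity.
- The enrichment-factor denominator, FN coverage condition and
  pileup-support threshold (≥ 2 tumor variant reads, clean normal) are
  interpretations of ambiguous prose definitions; each is configurable
  and recorded in the output.
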