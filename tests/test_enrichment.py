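"""Fisher enrichment, final thresholds, strand-bias and proximity filters."""

import math

import numpy as np
import pandas as pd
import pytest

import scmutcall as sm
from scmutcall.enrichment import substitution_class
from conftest import exact_fisher_greater


def _counts(rows):
    return sm.collate_counts(pd.DataFrame(
        rows, columns=["cell_id", "chrom", "pos", "ref", "alt",
                       "ref_count", "var_count"]))


def _annotated(pos=100, carriers=("c1", "c2"), patient="P1", chrom="chr1",
               ref="C", alt="T", tri="ACG", gene=None, strand=None):
    ts = None if strand is None else (tri if strand == "+" else
                                      tri.translate(str.maketrans("ACGT", "TGCA"))[::-1])
    return sm.AnnotatedCandidate(
        locus=sm.GenomicLocus(chrom, pos, ref, alt),
        patient_id=patient,
        carrier_cells=frozenset(carriers),
        tri_context=tri[0] + ref + tri[2],
        gene=gene, gene_strand=strand,
        transcribed_strand_context=ts,
        exonic_class="exonic" if gene else "intergenic",
    )


def _call(stats=None, **kw):
    stats = stats or sm.EnrichmentStats(
        "lineage", "tumor", 10, 5, 0, 100, 1e-9, math.inf)
    return sm.MutationCall(annotated=_annotated(**kw), stats=stats)


def _stats(a, b, c, d, p, ef):
    return sm.EnrichmentStats("lineage", "tumor", a, b, c, d, p, ef)


class TestGroupCounts:
    def test_all_carriers_one_lineage(self):
        cells = [sm.CellRecord(f"t{i}", "P1", "T/NK", "CD8" if i < 5 else "CD4")
                 for i in range(8)] + [
                sm.CellRecord(f"m{i}", "P1", "myeloid", "mono") for i in range(4)]
        rows = ([(f"t{i}", "chr1", 100, "C", "T", 2, 3) for i in range(6)]
                + [(f"t{i}", "chr1", 100, "C", "T", 5, 0) for i in range(6, 8)]
                + [(f"m{i}", "chr1", 100, "C", "T", 4, 0) for i in range(4)])
        cand = _annotated(carriers=[f"t{i}" for i in range(6)])
        top, table, tied = sm.group_counts(cand, _counts(rows), cells)
        assert top == "T/NK" and not tied
        assert table == ((6, 2), (0, 4))

    def test_tie_broken_lexicographically_and_flagged(self):
        cells = ([sm.CellRecord(f"a{i}", "P1", "B/plasma", "B") for i in range(3)]
                 + [sm.CellRecord(f"b{i}", "P1", "myeloid", "mono") for i in range(3)])
        rows = ([(f"a{i}", "chr1", 100, "C", "T", 0, 2) for i in range(3)]
                + [(f"b{i}", "chr1", 100, "C", "T", 0, 2) for i in range(3)])
        cand = _annotated(carriers=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)])
        top, table, tied = sm.group_counts(cand, _counts(rows), cells)
        assert top == "B/plasma" and tied

    def test_clonotype_grouping_without_annotations_rejected(self):
        cells = [sm.CellRecord("c1", "P1", "T/NK", "CD8")]
        cand = _annotated(carriers=["c1"])
        with pytest.raises(sm.ValidationError, match="clonotype"):
            sm.group_counts(cand, _counts([("c1", "chr1", 100, "C", "T", 0, 2)]),
                            cells, grouping="clonotype")

    def test_suppressed_carriers_count_as_reference(self):
        """A cell whose call the binomial filter ignored still has reference
        reads, so it lands in the reference column of the 2x2 table."""
        cells = [sm.CellRecord("c1", "P1", "tumor", "t"),
                 sm.CellRecord("c2", "P1", "tumor", "t"),
                 sm.CellRecord("c3", "P1", "tumor", "t")]
        rows = [("c1", "chr1", 100, "C", "T", 1, 2),
                ("c2", "chr1", 100, "C", "T", 2, 2),
                ("c3", "chr1", 100, "C", "T", 30, 1)]  # suppressed upstream
        cand = _annotated(carriers=["c1", "c2"])  # c3 not an accepted carrier
        _top, table, _ = sm.group_counts(cand, _counts(rows), cells)
        assert table == ((2, 1), (0, 0))


class TestFisherEnrichment:
    def test_exclusive_top_group(self):
        p, factor = sm.fisher_enrichment(((5, 15), (0, 50)))
        assert p == pytest.approx(float(exact_fisher_greater(5, 15, 0, 50)), abs=1e-12)
        assert factor == math.inf

    def test_identical_proportions_not_enriched(self):
        p, factor = sm.fisher_enrichment(((2, 2), (2, 2)))
        assert factor == 1.0
        assert p > 0.05

    def test_prevalence_ratio_arithmetic(self):
        _p, factor = sm.fisher_enrichment(((10, 20), (1, 200)))
        assert factor == pytest.approx((10 / 30) / (1 / 201), rel=1e-12)
        assert factor == pytest.approx(67.0, abs=0.05)

    def test_all_zero_table_degenerate(self):
        assert sm.fisher_enrichment(((0, 0), (0, 0))) == (1.0, 0.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 101, size=4)
            p, _ = sm.fisher_enrichment(((int(a), int(b)), (int(c), int(d))))
            assert abs(p - float(exact_fisher_greater(int(a), int(b), int(c), int(d)))) < 1e-9


class TestFinalThresholds:
    def _masks(self, snps=()):
        return sm.MaskSet(known_snp_sites=set(snps))

    def test_boundary_pass(self):
        call = _call(stats=_stats(5, 10, 1, 25, 2e-5, 6.0))
        kept = sm.apply_final_thresholds([call], self._masks())
        assert kept == [call] and call.passed

    def test_each_criterion_fails_independently(self):
        cases = {
            "fisher": _stats(5, 10, 1, 25, 2e-4, 6.0),
            "enrichment_factor": _stats(5, 10, 5, 25, 2e-5, 4.9),
            "min_variant_cells": _stats(4, 10, 0, 25, 2e-5, math.inf),
            "min_reference_cells": _stats(5, 10, 0, 19, 2e-5, math.inf),
        }
        for criterion, stats in cases.items():
            call = _call(stats=stats)
            kept = sm.apply_final_thresholds([call], self._masks())
            assert kept == [] and call.filters[criterion] is False, criterion

    def test_known_snp_masked(self):
        call = _call()
        kept = sm.apply_final_thresholds(
            [call], self._masks({("chr1", 100, "T")}))
        assert kept == [] and call.filters["known_snp"] is False

    def test_shared_between_patients_both_fail(self):
        c1 = _call(patient="P1")
        c2 = _call(patient="P2")
        c3 = _call(patient="P2", pos=999)
        kept = sm.apply_final_thresholds([c1, c2, c3], self._masks())
        assert kept == [c3]
        assert not c1.filters["patient_unique"]
        assert not c2.filters["patient_unique"]


class TestStrandBias:
    def _class_calls(self, n_plus, n_minus, n_none=0, tri="GCA", alt="G", pos0=1000):
        calls = []
        strands = ["+"] * n_plus + ["-"] * n_minus + [None] * n_none
        for i, s in enumerate(strands):
            calls.append(_call(
                pos=pos0 + 10 * i, ref=tri[1], alt=alt, tri=tri,
                gene=None if s is None else f"G{i}", strand=s))
        return calls

    def test_biased_class_removed_including_unassignable(self):
        calls = self._class_calls(40, 2, n_none=1)
        kept = sm.strand_bias_filter(calls)
        assert kept == []
        assert all(c.filters["strand_bias"] is False for c in calls)

    def test_balanced_class_retained(self):
        calls = self._class_calls(10, 9)
        assert sm.strand_bias_filter(calls) == calls

    def test_small_class_untested(self):
        calls = self._class_calls(3, 0)
        assert sm.strand_bias_filter(calls) == calls

    def test_purine_reference_normalized_into_same_class(self):
        # T>C at reference context TGC in a + gene is the reverse complement
        # of GCA with C>G in a - gene: same canonical class, flipped strand.
        plus = _call(ref="C", alt="G", tri="GCA", gene="G1", strand="-")
        flipped = _call(pos=500, ref="G", alt="C", tri="TGC", gene="G2", strand="+")
        k1, s1 = substitution_class(plus)
        k2, s2 = substitution_class(flipped)
        assert k1 == k2 == "GCA>G"
        assert s1 == s2 == "-"


class TestProximity:
    def _at(self, pos, patient="P1"):
        return _call(pos=pos, patient=patient)

    def test_within_four_bases_both_removed(self):
        calls = [self._at(100), self._at(103)]
        assert sm.proximity_filter(calls) == []

    def test_distance_five_retained(self):
        calls = [self._at(100), self._at(105)]
        assert sm.proximity_filter(calls) == calls

    def test_rule_is_per_patient(self):
        calls = [self._at(100, "PA"), self._at(102, "PB")]
        assert sm.proximity_filter(calls) == calls

    def test_transitive_cluster_fully_removed(self):
        calls = [self._at(100), self._at(104), self._at(108), self._at(200)]
        kept = sm.proximity_filter(calls)
        assert [c.locus.pos for c in kept] == [200]


class TestPipelineMonotonicity:
    def test_candidate_count_non_increasing(self, default_result):
        a = default_result.attrition
        stages = ["candidates", "after_singlet_filter", "after_cross_lineage_filter",
                  "after_binomial_filter", "after_final_thresholds",
                  "after_strand_bias_filter", "after_proximity_filter"]
        values = [a[s] for s in stages]
        assert values == sorted(values, reverse=True)

    def test_no_pass_call_spans_lineages(self, default_sim, default_result):
        lineage_of = {c.cell_id: c.lineage for c in default_sim.cells}
        for call in default_result.passed:
            assert len({lineage_of[c] for c in call.carrier_cells}) == 1


def test_calls_tsv_round_trip(tmp_path, default_result):
    path = tmp_path / "calls.tsv"
    sm.write_calls_tsv(default_result.passed, path)
    df = pd.read_csv(path, sep="\t")
    assert len(df) == len(default_result.passed)
    assert df["pass"].all()


def test_calls_vcf_written_and_readable(tmp_path, default_result):
    path = tmp_path / "calls.vcf"
    sm.write_calls_vcf(default_result.passed, path)
    loci = sm.read_loci_vcf(path)
    assert {(l.chrom, l.pos) for l in loci} == {
        (c.locus.chrom, c.locus.pos) for c in default_result.passed}
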