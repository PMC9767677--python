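"""Simulator contracts: determinism, truth labeling, noise model."""

import dataclasses
import math

import numpy as np
import pytest

import scmutcall as sm
from scmutcall.simulate import TRUE_SOMATIC_KINDS


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = sm.default_config(seed=21)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sm.simulate_dataset(cfg).write(d1)
        sm.simulate_dataset(cfg).write(d2)
        for name in ("counts.tsv", "cells.tsv", "genome.fa", "genes.bed",
                     "snp_mask.vcf", "dna_evidence.tsv", "deg.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seeds_differ(self):
        m1 = sm.simulate_dataset(sm.default_config(seed=1)).matrix
        m2 = sm.simulate_dataset(sm.default_config(seed=2)).matrix
        assert m1.loci != m2.loci or any(
            dict(m1.counts_at(l)) != dict(m2.counts_at(l)) for l in m1.loci)


class TestTruthStructure:
    def test_planned_mutation_counts(self, noise_free_sim):
        truth = noise_free_sim.truth
        assert len(truth.by_kind("tumor_clone")) == 35
        assert len(truth.by_kind("ch_clone")) == 10
        assert len(truth.by_kind("t_clonotype")) == 15

    def test_carriers_respect_clonal_structure(self, noise_free_sim):
        truth = noise_free_sim.truth
        lineage_of = {c.cell_id: c.lineage for c in noise_free_sim.cells}
        clonotype_of = {c.cell_id: c.clonotype_id for c in noise_free_sim.cells}
        for m in truth.by_kind(*TRUE_SOMATIC_KINDS):
            carriers = truth.carriers[(m.locus, m.patient_id)]
            assert {lineage_of[c] for c in carriers} == {m.lineage}
            if m.kind == "t_clonotype":
                assert {clonotype_of[c] for c in carriers} == set(m.clonotype_ids)

    def test_trunk_mutations_carried_by_all_tumor_cells(self, noise_free_sim):
        truth = noise_free_sim.truth
        n_tumor = sum(1 for c in noise_free_sim.cells if c.lineage == "tumor")
        trunk = [m for m in truth.by_kind("tumor_clone") if m.clone == "trunk"]
        assert trunk
        for m in trunk:
            assert len(truth.carriers[(m.locus, m.patient_id)]) == n_tumor
            assert m.dna_ccf == 1.0

    def test_noise_free_detectable_have_five_variant_carriers(self, noise_free_sim):
        """With zero error/dropout and generous depth, each detectable truth
        mutation shows >= 5 carrier cells with variant reads."""
        sim = noise_free_sim
        for key in sim.truth.detectable_set():
            locus, _pid = key
            carriers_with_var = sum(
                1 for cell, (_r, v) in sim.matrix.counts_at(locus).items()
                if v >= 1 and cell in sim.truth.carriers[key])
            assert carriers_with_var >= 5

    def test_variant_reads_trace_to_truth_or_error(self, noise_free_sim):
        """Error rate 0: every emitted variant read sits in a truth carrier."""
        sim = noise_free_sim
        by_key = sim.truth.carriers
        for m in sim.truth.mutations:
            carriers = by_key[(m.locus, m.patient_id)]
            for cell, (_r, v) in sim.matrix.counts_at(m.locus).items():
                if v >= 1:
                    assert cell in carriers

    def test_dna_evidence_consistent_with_clone_fractions(self, default_sim):
        truth = default_sim.truth
        for m in truth.by_kind("tumor_clone"):
            rec = default_sim.dna.get(m.locus)
            assert rec is not None
            total = rec.tumor_var_reads + rec.tumor_ref_reads
            assert total == default_sim.config.wes_depth
            assert rec.normal_var_reads == 0
            # VAF ~ Binomial(depth, ccf/2): allow generous sampling slack
            vaf = rec.tumor_var_reads / total
            assert abs(vaf - m.dna_ccf / 2) < 0.25


class TestArtifactInjection:
    def test_cross_lineage_artifacts_span_lineages(self, artifact_sim):
        lineage_of = {c.cell_id: c.lineage for c in artifact_sim.cells}
        arts = artifact_sim.truth.by_kind("cross_lineage_artifact")
        assert len(arts) == 100
        for m in arts:
            carriers = artifact_sim.truth.carriers[(m.locus, m.patient_id)]
            assert len({lineage_of[c] for c in carriers}) >= 2

    def test_artifacts_never_in_detectable_truth(self, artifact_sim):
        det = artifact_sim.truth.detectable_set()
        for m in artifact_sim.truth.by_kind(
                "cross_lineage_artifact", "strand_artifact", "singlet_error"):
            assert (m.locus, m.patient_id) not in det

    def test_strand_class_asymmetry_near_configured_ratio(self, artifact_sim):
        arts = artifact_sim.truth.by_kind("strand_artifact")
        assert len(arts) == 42
        n_plus = sum(1 for m in arts if m.gene_strand == "+")
        # Binomial(42, 20/21): expect ~40 on the plus strand
        assert n_plus >= 35

    def test_singlet_errors_have_one_carrier(self, artifact_sim):
        for m in artifact_sim.truth.by_kind("singlet_error"):
            assert len(artifact_sim.truth.carriers[(m.locus, m.patient_id)]) == 1

    def test_zero_artifact_config_is_identity(self, noise_free_sim):
        sim = noise_free_sim
        matrix, labels = sm.inject_artifacts(
            sim.matrix, sim.config, cells=sim.cells, genes=sim.masks.genes,
            reference=sim.reference)
        assert labels == []
        assert matrix is sim.matrix

    def test_inject_artifacts_adds_labeled_loci(self, noise_free_sim):
        sim = noise_free_sim
        cfg = dataclasses.replace(sim.config, n_cross_lineage_artifacts=5,
                                  n_singlet_errors=3)
        matrix, labels = sm.inject_artifacts(
            sim.matrix, cfg, cells=sim.cells, genes=sim.masks.genes,
            reference=sim.reference, seed=99)
        assert len(labels) == 8
        new_loci = set(matrix.loci) - set(sim.matrix.loci)
        assert new_loci == {m.locus for m in labels}
        # original entries untouched
        for locus in sim.matrix.loci:
            assert dict(matrix.counts_at(locus)) == dict(sim.matrix.counts_at(locus))


class TestConfigValidation:
    def test_infeasible_locus_pool_rejected(self):
        with pytest.raises(sm.ValidationError, match="gene pool|exceed"):
            sm.SimConfig(seed=0, n_genes=10)

    def test_invalid_rates_rejected(self):
        with pytest.raises(sm.ValidationError):
            sm.SimConfig(seed=0, error_rate=1.5)

    def test_masked_snp_sites_fail_only_the_snp_criterion(self):
        sim = sm.simulate_dataset(sm.noise_free_config(seed=13, n_masked_snp_sites=2))
        res = sm.call_mutations(sim.matrix, sim.cells, sim.masks, sim.reference)
        masked = {m.locus for m in sim.truth.by_kind("masked_snp")}
        assert len(masked) == 2
        called = {c.locus for c in res.passed}
        assert not (masked & called)
        scored = {c.locus: c for c in res.scored}
        for locus in masked:
            assert scored[locus].filters["known_snp"] is False

    def test_shared_locus_present_in_both_patients(self):
        sim = sm.simulate_dataset(
            sm.noise_free_config(seed=17, n_patients=2,
                                 n_shared_across_patients=1))
        shared = sim.truth.by_kind("shared_across_patients")
        assert len(shared) == 2  # one record per patient, same site
        assert len({m.locus for m in shared}) == 1
        locus = shared[0].locus
        patients = {c.patient_id for c in sim.cells}
        cells_with_var = {
            cell for cell, (_r, v) in sim.matrix.counts_at(locus).items()
            if v >= 1}
        patient_of = {c.cell_id: c.patient_id for c in sim.cells}
        assert {patient_of[c] for c in cells_with_var} == patients
        # and the cross-patient filter removes it from both
        res = sm.call_mutations(sim.matrix, sim.cells, sim.masks, sim.reference)
        assert locus not in {c.locus for c in res.passed}
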