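"""Pipeline configuration.

Every tunable threshold of the calling cascade lives here, with the
published operating point as the default.  Thresholds are applied raw --
no multiple-testing correction anywhere -- because the method's operating
point is defined by fixed cutoffs, and correcting would move it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds for the somatic-mutation calling cascade.

    Attributes
    ----------
    min_carrier_cells:
        Minimum number of cells carrying a variant for a candidate to be
        interpretable; singlets (one carrier) are discarded.
    binomial_alpha:
        One-sided per-cell binomial significance: a carrier whose reference
        reads significantly outnumber its variant reads at this level has
        its call ignored (allele-imbalance artifact guard).
    fisher_alpha:
        One-sided Fisher significance required for enrichment of the
        variant in its top lineage/clonotype.
    min_enrichment_factor:
        Minimum prevalence ratio of the variant in the top group versus
        all other groups.
    min_variant_cells:
        Minimum variant-carrying cells in the top group.
    min_reference_cells:
        Minimum reference-only cells outside the top group ("reference
        population").
    strand_bias_alpha:
        Two-sided exact binomial significance for transcribed-strand
        asymmetry of a (substitution, trinucleotide-context) class; a
        failing class is removed wholesale.
    strand_min_class_size:
        Classes with fewer strand-assignable members than this are left
        untested.
    proximity_bp:
        Calls within this many bases of each other in one patient are
        removed as clustered artifacts.
    min_base_quality / min_mapping_quality / cell_barcode_tag:
        BAM-adapter pileup filters.
    fp_max_var_reads / fp_min_ref_reads:
        DNA-benchmark false-positive condition: fewer than ``fp_max_var_reads``
        variant reads and more than ``fp_min_ref_reads`` reference reads in
        the exome pileup.
    pileup_min_var_reads:
        Minimum tumor variant reads (with zero matched-normal variant
        reads) for a call to count as pileup-supported in the benchmark.
    """

    # candidate stage
    min_carrier_cells: int = 2
    binomial_alpha: float = 0.05
    # final filter
    fisher_alpha: float = 1e-4
    min_enrichment_factor: float = 5.0
    min_variant_cells: int = 5
    min_reference_cells: int = 20
    # strand-bias class filter
    strand_bias_alpha: float = 0.005
    strand_min_class_size: int = 10
    # proximity filter
    proximity_bp: int = 4
    # BAM adapter
    min_base_quality: int = 20
    min_mapping_quality: int = 30
    cell_barcode_tag: str = "CB"
    # DNA benchmark
    fp_max_var_reads: int = 5
    fp_min_ref_reads: int = 20
    pileup_min_var_reads: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.binomial_alpha < 1.0):
            raise ValueError("binomial_alpha must be in (0, 1)")
        if not (0.0 < self.fisher_alpha < 1.0):
            raise ValueError("fisher_alpha must be in (0, 1)")
        if not (0.0 < self.strand_bias_alpha < 1.0):
            raise ValueError("strand_bias_alpha must be in (0, 1)")
        if self.min_carrier_cells < 1:
            raise ValueError("min_carrier_cells must be >= 1")
        if self.proximity_bp < 0:
            raise ValueError("proximity_bp must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a plain-text key-value (YAML) file.

        Unknown keys are rejected so that typos do not silently fall back
        to defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
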