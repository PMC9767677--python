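"""End-to-end orchestration of the calling cascade.

Order of operations: candidate enumeration -> singlet removal ->
cross-lineage removal -> per-cell binomial allelic filter -> annotation ->
enrichment statistics -> fixed final thresholds -> strand-bias class
filter -> proximity-cluster filter.  Candidate counts are non-increasing
through every stage; the attrition log records each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .candidate_filter import (
    annotate,
    binomial_allelic_filter,
    remove_cross_lineage_shared,
    remove_singlets,
)
from .config import PipelineConfig
from .enrichment import (
    MutationCall,
    apply_final_thresholds,
    compute_enrichment,
    proximity_filter,
    strand_bias_filter,
)
from .io_ingest import (
    AlleleCountMatrix,
    CellRecord,
    MaskSet,
    enumerate_candidates,
)

logger = logging.getLogger(__name__)


@dataclass
class CallResult:
    """Final calls plus every scored call and the per-stage attrition."""

    passed: list[MutationCall]
    scored: list[MutationCall]
    attrition: dict[str, int] = field(default_factory=dict)


def call_mutations(
    matrix: AlleleCountMatrix,
    cells: Sequence[CellRecord],
    masks: MaskSet,
    reference: Mapping[str, str],
    config: PipelineConfig | None = None,
    grouping: str = "lineage",
) -> CallResult:
    """Run the full filter cascade and return the final mutation calls.

    With ``grouping='clonotype'`` the universe is restricted to
    clonotyped cells and enrichment/thresholds use clonotype groups with
    otherwise identical metrics (the TCR benchmark configuration); the
    standard pipeline uses major-lineage groups.
    """
    cfg = config or PipelineConfig()
    attrition: dict[str, int] = {}

    if grouping == "clonotype":
        cells = [c for c in cells if c.clonotype_id is not None]
        if not cells:
            raise ValueError("clonotype grouping requires clonotyped cells")
        matrix = matrix.subset_cells({c.cell_id for c in cells})

    candidates = enumerate_candidates(matrix, cells)
    attrition["candidates"] = len(candidates)

    candidates = remove_singlets(candidates, cfg.min_carrier_cells)
    attrition["after_singlet_filter"] = len(candidates)

    candidates = remove_cross_lineage_shared(candidates, cells)
    attrition["after_cross_lineage_filter"] = len(candidates)

    candidates = binomial_allelic_filter(
        matrix, candidates, cfg.binomial_alpha, cfg.min_carrier_cells
    )
    attrition["after_binomial_filter"] = len(candidates)

    annotated = annotate(candidates, reference, masks)

    has_clonotypes = any(c.clonotype_id is not None for c in cells)
    calls: list[MutationCall] = []
    for ann in annotated:
        stats = compute_enrichment(ann, matrix, cells, grouping)
        clono_stats = None
        if grouping == "lineage" and has_clonotypes:
            clonotyped = {
                c.cell_id for c in cells
                if c.patient_id == ann.patient_id and c.clonotype_id is not None
            }
            if ann.carrier_cells & clonotyped:
                clono_stats = compute_enrichment(ann, matrix, cells, "clonotype")
        calls.append(MutationCall(annotated=ann, stats=stats,
                                  clonotype_stats=clono_stats))
    attrition["scored"] = len(calls)

    surviving = apply_final_thresholds(calls, masks, calls, cfg)
    attrition["after_final_thresholds"] = len(surviving)

    surviving = strand_bias_filter(
        surviving, cfg.strand_min_class_size, cfg.strand_bias_alpha
    )
    attrition["after_strand_bias_filter"] = len(surviving)

    surviving = proximity_filter(surviving, cfg.proximity_bp)
    attrition["after_proximity_filter"] = len(surviving)

    logger.info("attrition: %s", attrition)
    return CallResult(passed=surviving, scored=calls, attrition=attrition)
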