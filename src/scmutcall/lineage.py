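"""Mutation-burden profiles and mutation-sharing lineage tracing.

Per (patient, lineage), the burden profile is the proportion of cells
carrying exactly 1, 2, 3 or more than 3 final mutation calls; groups
under 100 cells are excluded for lack of discriminatory power.  For
lineage tracing, calls are reduced to a binary mutation x subtype
presence matrix (dropping mutations in any cluster's top differentially
expressed genes, whose detection tracks expression rather than ancestry),
pairwise subtype distances are asymmetric-binary (Jaccard) distances, and
the subtype tree is reconstructed by neighbor joining with bootstrap
supports from resampling mutation rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import MutationCall
from .io_ingest import CellRecord, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------

def burden_profile(
    calls: Sequence[MutationCall],
    cells: Sequence[CellRecord],
    min_cells: int = 100,
) -> pd.DataFrame:
    """Proportions of cells with 1, 2, 3, >3 mutations per (patient, lineage).

    A cell's mutation count is the number of PASS calls it carries
    (post-binomial carrier flags).  Only (patient, lineage) groups with
    at least ``min_cells`` cells are reported.
    """
    n_muts = {c.cell_id: 0 for c in cells}
    for call in calls:
        for cell_id in call.carrier_cells:
            if cell_id in n_muts:
                n_muts[cell_id] += 1

    rows = []
    key = lambda c: (c.patient_id, c.lineage)
    for (patient, lineage) in sorted({key(c) for c in cells}):
        group = [c for c in cells if key(c) == (patient, lineage)]
        if len(group) < min_cells:
            logger.info(
                "burden: %s/%s excluded (%d cells < %d)",
                patient, lineage, len(group), min_cells,
            )
            continue
        counts = np.array([n_muts[c.cell_id] for c in group])
        n = len(group)
        rows.append({
            "patient_id": patient,
            "lineage": lineage,
            "n_cells": n,
            "prop_0": float(np.mean(counts == 0)),
            "prop_1": float(np.mean(counts == 1)),
            "prop_2": float(np.mean(counts == 2)),
            "prop_3": float(np.mean(counts == 3)),
            "prop_gt3": float(np.mean(counts > 3)),
        })
    return pd.DataFrame(
        rows, columns=["patient_id", "lineage", "n_cells",
                       "prop_0", "prop_1", "prop_2", "prop_3", "prop_gt3"]
    )


# ---------------------------------------------------------------------------
# Mutation x subtype matrix
# ---------------------------------------------------------------------------

def mutation_label(call: MutationCall) -> str:
    loc = call.locus
    return f"{call.patient_id}:{loc.chrom}:{loc.pos}{loc.ref_base}>{loc.alt_base}"


def build_mutation_matrix(
    calls: Sequence[MutationCall],
    cells: Sequence[CellRecord],
    deg_lists: dict[str, list[str]] | None = None,
    min_carriers: int = 1,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Binary mutation x subtype presence matrix for tree building.

    A mutation is present in a subtype iff >= ``min_carriers`` cells of
    that subtype carry it.  Mutations whose gene appears in any cluster's
    top-DEG list are excluded (their detection follows expression, not
    ancestry), as are all-zero rows.  Returns the matrix and a
    provenance map of excluded mutations -> reason.
    """
    subtypes = sorted({c.subtype for c in cells})
    subtype_of = {c.cell_id: c.subtype for c in cells}
    if deg_lists is None:
        logger.warning("no DEG lists supplied; skipping expression-driven exclusion")
        deg_union: set[str] = set()
    else:
        deg_union = {g for genes in deg_lists.values() for g in genes}

    excluded: dict[str, str] = {}
    rows = {}
    for call in calls:
        label = mutation_label(call)
        gene = call.annotated.gene
        if gene is not None and gene in deg_union:
            excluded[label] = f"gene {gene} in top-DEG list"
            continue
        counts = {s: 0 for s in subtypes}
        for cell_id in call.carrier_cells:
            s = subtype_of.get(cell_id)
            if s is not None:
                counts[s] += 1
        presence = [int(counts[s] >= min_carriers) for s in subtypes]
        if not any(presence):
            excluded[label] = "no carriers in any subtype"
            continue
        rows[label] = presence

    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=subtypes)
    matrix = matrix.sort_index()
    logger.info(
        "mutation matrix: %d mutations x %d subtypes (%d excluded)",
        len(matrix), len(subtypes), len(excluded),
    )
    return matrix, excluded


def binary_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Asymmetric-binary (Jaccard) distance between subtypes.

    d(a, b) = |mutations in exactly one| / |mutations in at least one|;
    double absences are ignored, and d = 0 when the union is empty.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("binary distance needs >= 2 subtypes")
    m = matrix.to_numpy(dtype=np.int64)
    inter = m.T @ m
    sums = m.sum(axis=0)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, (union - inter) / np.maximum(union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class SubtypeTree:
    """Unrooted NJ tree over subtypes.

    ``bipartitions`` maps each internal edge (as the canonical leaf-set
    side not containing the alphabetically first leaf) to its branch
    length; ``supports`` holds bootstrap votes out of the replicate count
    for the same keys.  Negative NJ branch lengths are clamped to zero
    and counted in ``n_clamped``.
    """

    leaves: tuple[str, ...]
    newick: str
    bipartitions: dict[frozenset, float]
    n_clamped: int = 0
    supports: dict[frozenset, int] | None = None
    n_bootstrap: int | None = None

    def has_split(self, side: set[str] | frozenset) -> bool:
        return self._canonical(side) in self.bipartitions

    def _canonical(self, side) -> frozenset:
        side = frozenset(side)
        first = min(self.leaves)
        return frozenset(self.leaves) - side if first in side else side


def _clamp(length: float) -> tuple[float, int]:
    return (0.0, 1) if length < 0 else (float(length), 0)


def nj_tree(distances: pd.DataFrame) -> SubtypeTree:
    """Saitou-Nei neighbor joining with a deterministic tie rule.

    Q-criterion ties are broken by lexicographic order of the joined
    leaf-name pairs, so degenerate (e.g. equidistant) inputs always
    yield the same tree.  Negative branch lengths are clamped to 0 and
    flagged.  Requires >= 3 taxa and a symmetric zero-diagonal matrix.
    """
    labels = list(distances.index)
    if len(labels) < 3:
        raise ValidationError("neighbor joining requires >= 3 taxa")
    if list(distances.columns) != labels:
        raise ValidationError("distance matrix index/columns mismatch")
    arr = distances.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValidationError("distance matrix diagonal must be zero")

    # active nodes keyed by the sorted tuple of leaf names below them
    nodes: dict[tuple[str, ...], tuple] = {}  # key -> (children: ((key, length), ...))
    active = sorted((lab,) for lab in labels)
    d = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[frozenset([(a,), (b,)])] = arr[i, j]
    for key in active:
        nodes[key] = ()

    n_clamped = 0

    def dist(x, y):
        return d[frozenset([x, y])]

    while len(active) > 3:
        n = len(active)
        r = {x: sum(dist(x, y) for y in active if y != x) for x in active}
        best = None
        best_q = None
        for i in range(n):
            for j in range(i + 1, n):
                x, y = active[i], active[j]
                q = (n - 2) * dist(x, y) - r[x] - r[y]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (x, y)
        x, y = best
        dxy = dist(x, y)
        lx = 0.5 * dxy + (r[x] - r[y]) / (2 * (n - 2))
        ly = dxy - lx
        lx, c1 = _clamp(lx)
        ly, c2 = _clamp(ly)
        n_clamped += c1 + c2
        new = tuple(sorted(x + y))
        nodes[new] = ((x, lx), (y, ly))
        for z in active:
            if z in (x, y):
                continue
            d[frozenset([new, z])] = 0.5 * (dist(x, z) + dist(y, z) - dxy)
        active = sorted(k for k in active if k not in (x, y)) + [new]
        active.sort()

    # join the last three nodes at the central (unrooted) vertex
    x, y, z = active
    lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
    ly = 0.5 * (dist(x, y) + dist(y, z) - dist(x, z))
    lz = 0.5 * (dist(x, z) + dist(y, z) - dist(x, y))
    lx, c1 = _clamp(lx)
    ly, c2 = _clamp(ly)
    lz, c3 = _clamp(lz)
    n_clamped += c1 + c2 + c3
    center = ((x, lx), (y, ly), (z, lz))

    leaves = tuple(sorted(labels))
    first = min(leaves)
    all_set = frozenset(leaves)

    bipartitions: dict[frozenset, float] = {}

    def canonical(side: frozenset) -> frozenset:
        return all_set - side if first in side else side

    def collect(key, length) -> None:
        side = frozenset(key)
        if 2 <= len(side) <= len(leaves) - 2:
            bipartitions[canonical(side)] = length
        for child_key, child_len in nodes[key]:
            collect(child_key, child_len)

    for key, length in center:
        collect(key, length)

    def to_newick(key, length, supports=None) -> str:
        children = nodes[key]
        if not children:
            return f"{key[0]}:{length:.6g}"
        inner = ",".join(to_newick(k, l, supports) for k, l in children)
        label = ""
        if supports is not None:
            canon = canonical(frozenset(key))
            if canon in supports:
                label = str(supports[canon])
        return f"({inner}){label}:{length:.6g}"

    newick = "(" + ",".join(to_newick(k, l) for k, l in center) + ");"

    tree = SubtypeTree(
        leaves=leaves,
        newick=newick,
        bipartitions=bipartitions,
        n_clamped=n_clamped,
    )
    # stash the structure so bootstrap can re-render newick with supports
    tree._nodes = nodes          # type: ignore[attr-defined]
    tree._center = center        # type: ignore[attr-defined]
    tree._to_newick = to_newick  # type: ignore[attr-defined]
    return tree


def bootstrap_support(
    matrix: pd.DataFrame,
    n_reps: int = 100,
    seed: int = 0,
) -> SubtypeTree:
    """NJ tree with bootstrap supports from resampling mutation rows.

    Mutations (rows) are resampled with replacement ``n_reps`` times;
    the distance matrix and NJ tree are recomputed, and each internal
    edge's support is the number of replicates whose tree contains the
    same bipartition.  Indices are drawn explicitly from a seeded
    generator, so results are platform- and row-order-invariant.
    """
    if len(matrix) < 1:
        raise ValidationError("mutation matrix must have >= 1 row")
    # canonical row order so supports do not depend on input permutation
    ordered = matrix.sort_index()
    tree = nj_tree(binary_distance(ordered))
    supports = {split: 0 for split in tree.bipartitions}
    rng = np.random.default_rng(seed)
    n_rows = len(ordered)
    for _ in range(n_reps):
        idx = rng.integers(0, n_rows, size=n_rows)
        sample = ordered.iloc[idx]
        rep = nj_tree(binary_distance(sample))
        for split in supports:
            if split in rep.bipartitions:
                supports[split] += 1
    tree.supports = supports
    tree.n_bootstrap = n_reps
    tree.newick = (
        "("
        + ",".join(tree._to_newick(k, l, supports) for k, l in tree._center)
        + ");"
    )
    return tree


def write_newick(tree: SubtypeTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick + "\n")
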