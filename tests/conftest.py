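"""Shared fixtures and independent oracles.

Simulated datasets are session-scoped (they are deterministic under
their seeds).  Oracles here recompute statistics from first principles
-- exact rational arithmetic and brute-force enumeration -- independent
of the library code paths they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import scmutcall as sm


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def exact_binom_cdf(k: int, n: int) -> Fraction:
    """P(X <= k), X ~ Binomial(n, 1/2), exact by summation."""
    if n == 0:
        return Fraction(1)
    return Fraction(sum(math.comb(n, i) for i in range(k + 1)), 2 ** n)


def exact_fisher_greater(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided Fisher p by full enumeration of tables with fixed margins."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0:
        return Fraction(1)
    denom = math.comb(n, col1)
    num = 0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        if k >= a:
            num += math.comb(row1, k) * math.comb(n - row1, col1 - k)
    return Fraction(num, denom)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random unrooted binary tree and its additive distance matrix.

    Returns (distance DataFrame, set of canonical non-trivial
    bipartitions).  Built by sequential leaf insertion on random edges
    with random positive branch lengths.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # edges as dict id -> (node_a, node_b, length); nodes are ints, leaves 0..n-1
    next_node = n_taxa
    edges = {}
    eid = 0

    def add_edge(a, b, ln):
        nonlocal eid
        edges[eid] = [a, b, ln]
        eid += 1
        return eid - 1

    def blen():
        return float(rng.uniform(0.1, 1.0))

    add_edge(0, 1, blen())
    for leaf in range(2, n_taxa):
        target = int(rng.choice(list(edges)))
        a, b, ln = edges.pop(target)
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.2, 0.8)) * ln
        add_edge(a, mid, split)
        add_edge(mid, b, ln - split)
        add_edge(mid, leaf, blen())

    # adjacency for path distances and bipartitions
    adj: dict[int, list[tuple[int, float, int]]] = {}
    for e, (a, b, ln) in edges.items():
        adj.setdefault(a, []).append((b, ln, e))
        adj.setdefault(b, []).append((a, ln, e))

    def leaves_beyond(start, blocked_edge):
        seen, stack, out = {start}, [start], set()
        while stack:
            node = stack.pop()
            if node < n_taxa:
                out.add(labels[node])
            for nxt, _, e in adj[node]:
                if e != blocked_edge and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return out

    all_leaves = frozenset(labels)
    first = min(labels)
    splits = set()
    for e, (a, b, _) in edges.items():
        side = frozenset(leaves_beyond(a, e))
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(all_leaves - side if first in side else side)

    dist = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        # Dijkstra-free BFS: tree, so simple DFS accumulating lengths
        stack = [(i, 0.0)]
        seen = {i}
        while stack:
            node, acc = stack.pop()
            if node < n_taxa:
                dist[i, node] = acc
            for nxt, ln, _ in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, acc + ln))
    return pd.DataFrame(dist, index=labels, columns=labels), splits


def enumerate_unrooted_topologies(labels: list[str]):
    """All unrooted binary topologies as sets of canonical bipartitions.

    Recursive edge-insertion enumeration: 3 topologies for 4 taxa, 15
    for 5.  Used to verify NJ picks the (unique, zero-error) additive
    topology by exhaustive least-squares comparison.
    """
    n = len(labels)
    all_leaves = frozenset(labels)
    first = min(labels)

    def canon(side):
        side = frozenset(side)
        return all_leaves - side if first in side else side

    # recursively build unrooted trees as nested tuples around a 3-way center
    def topologies(lbls):
        if len(lbls) == 3:
            yield (lbls[0], lbls[1], lbls[2])
            return
        head, rest = lbls[-1], lbls[:-1]
        for t in topologies(rest):
            for spot, new in _insertions(t, head):
                yield new

    def _insertions(tree, leaf):
        # tree: tuple of 3 subtrees (unrooted center); subtree: label or pair
        def insert_all(sub):
            yield (sub, leaf)
            if isinstance(sub, tuple) and len(sub) == 2:
                for rep in insert_all(sub[0]):
                    yield (rep, sub[1])
                for rep in insert_all(sub[1]):
                    yield (sub[0], rep)

        for i in range(3):
            for rep in insert_all(tree[i]):
                lst = list(tree)
                lst[i] = rep
                yield i, tuple(lst)

    def splits_of(tree):
        found = set()

        def leaves(sub):
            if isinstance(sub, str):
                return {sub}
            return leaves(sub[0]) | leaves(sub[1])

        def walk(sub):
            lv = leaves(sub) if not isinstance(sub, str) else {sub}
            if 2 <= len(lv) <= n - 2:
                found.add(canon(lv))
            if isinstance(sub, tuple):
                walk(sub[0])
                walk(sub[1])

        for sub in tree:
            walk(sub)
        return frozenset(found)

    return {splits_of(t) for t in topologies(labels)}


def ls_error(dist: pd.DataFrame, splits: frozenset) -> float:
    """Least-squares fit error of a topology to a distance matrix.

    Branch lengths are fit by unconstrained OLS over the path-indicator
    design; for an additive matrix the generating topology fits with
    error 0 and every other topology with error > 0.
    """
    labels = list(dist.index)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    # edge set: trivial (leaf) splits + internal splits
    cols = [frozenset([lab]) for lab in labels] + [set(s) for s in splits]
    design = np.zeros((len(pairs), len(cols)))
    for r, (i, j) in enumerate(pairs):
        for c, side in enumerate(cols):
            side = set(side)
            # edge separates i from j iff exactly one of them is in `side`
            if (labels[i] in side) != (labels[j] in side):
                design[r, c] = 1.0
    y = np.array([dist.iloc[i, j] for i, j in pairs])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(np.sum((design @ coef - y) ** 2))


# ---------------------------------------------------------------------------
# Simulated-dataset fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def noise_free_sim():
    return sm.simulate_dataset(sm.noise_free_config(seed=11))


@pytest.fixture(scope="session")
def noise_free_result(noise_free_sim):
    s = noise_free_sim
    return sm.call_mutations(s.matrix, s.cells, s.masks, s.reference)


@pytest.fixture(scope="session")
def artifact_sim():
    return sm.simulate_dataset(sm.artifact_config(seed=7))


@pytest.fixture(scope="session")
def artifact_result(artifact_sim):
    s = artifact_sim
    return sm.call_mutations(s.matrix, s.cells, s.masks, s.reference)


@pytest.fixture(scope="session")
def default_sim():
    return sm.simulate_dataset(sm.default_config(seed=5))


@pytest.fixture(scope="session")
def default_result(default_sim):
    s = default_sim
    return sm.call_mutations(s.matrix, s.cells, s.masks, s.reference)
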