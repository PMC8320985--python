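"""Exact ground truth for small instances.

Enumerates every valid codeword for a profile, builds the compatibility
graph (edges join words at Hamming distance >= d) and finds an exact maximum
clique — i.e. the largest possible code — by branch and bound with greedy
colouring bounds.  A code set is exactly a clique in this graph, so the
clique number is the true optimum that heuristics can be measured against.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import (
    GC_DIGITS,
    CodeSet,
    Codeword,
    ConstraintProfile,
)

__all__ = [
    "ENUMERATION_GUARD",
    "CLIQUE_GUARD",
    "ConflictGraph",
    "enumerate_valid_codewords",
    "build_conflict_graph",
    "max_clique_exact",
    "greedy_random_baseline",
]

#: Default guard on word length for exhaustive 4^n enumeration.
ENUMERATION_GUARD = 12
#: Default guard on vertex count for exact clique search.
CLIQUE_GUARD = 2000


def enumerate_valid_codewords(
    profile: ConstraintProfile, guard: int = ENUMERATION_GUARD, force: bool = False
) -> list[Codeword]:
    """All valid words for the profile, in canonical digit order.

    Depth-first construction over digits 0..3 with GC-count and runlength
    pruning, so the output comes out canonically sorted without a final sort.
    """
    if profile.n > guard and not force:
        raise ValueError(
            f"n={profile.n} exceeds the enumeration guard ({guard}); "
            "use the heuristic search or pass force=True"
        )
    n, w = profile.n, profile.w
    out: list[Codeword] = []
    digits = [0] * n

    def rec(i: int, gc_used: int) -> None:
        if i == n:
            out.append(Codeword.from_digits(digits))
            return
        remaining = n - 1 - i
        for d in range(4):
            if profile.nrl and i > 0 and d == digits[i - 1]:
                continue
            g = gc_used + (1 if d in GC_DIGITS else 0)
            if not 0 <= w - g <= remaining:
                continue
            digits[i] = d
            rec(i + 1, g)

    rec(0, 0)
    return out


@dataclass
class ConflictGraph:
    """Valid codewords as vertices; edges mark pairs usable together."""

    profile: ConstraintProfile
    words: list[Codeword]
    graph: nx.Graph  # nodes are indices into ``words``

    def __len__(self) -> int:
        return len(self.words)


def build_conflict_graph(
    profile: ConstraintProfile, guard: int = ENUMERATION_GUARD, force: bool = False
) -> ConflictGraph:
    """Compatibility graph over all valid words: edge iff H(u, v) >= d."""
    words = enumerate_valid_codewords(profile, guard=guard, force=force)
    g = nx.Graph()
    g.add_nodes_from(range(len(words)))
    if words:
        mat = np.array([w.digits for w in words], dtype=np.int8)
        dist = (mat[:, None, :] != mat[None, :, :]).sum(axis=-1)
        ii, jj = np.nonzero(np.triu(dist >= profile.d, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return ConflictGraph(profile, words, g)


def max_clique_exact(
    cg: ConflictGraph, guard: int = CLIQUE_GUARD, force: bool = False
) -> CodeSet:
    """Exact maximum clique by branch and bound with greedy-colouring bounds.

    Vertices are visited in canonical order and ties broken toward lower
    indices, so the returned witness set (not just its size) is
    deterministic.
    """
    n_vert = len(cg.words)
    if n_vert > guard and not force:
        raise ValueError(
            f"{n_vert} vertices exceed the exact-search guard ({guard}); "
            "use greedy_random_baseline or pass force=True"
        )
    if n_vert == 0:
        return CodeSet(cg.profile)

    adj = [0] * n_vert
    for u, v in cg.graph.edges():
        adj[u] |= 1 << v
        adj[v] |= 1 << u

    best: list[int] = []

    def bits(mask: int):
        while mask:
            low = mask & -mask
            yield low.bit_length() - 1
            mask ^= low

    def expand(clique: list[int], cand: int) -> None:
        nonlocal best
        # greedy colouring over candidates in canonical order; branching then
        # walks colour classes from last to first, so the vertex list must be
        # flattened class by class to keep the bound non-decreasing
        classes: list[int] = []
        members: list[list[int]] = []
        for v in bits(cand):
            for ci in range(len(classes)):
                if not (classes[ci] & adj[v]):
                    classes[ci] |= 1 << v
                    members[ci].append(v)
                    break
            else:
                classes.append(1 << v)
                members.append([v])
        order: list[int] = []
        bound: list[int] = []
        for ci, vs in enumerate(members):
            order.extend(vs)
            bound.extend([ci + 1] * len(vs))
        for i in range(len(order) - 1, -1, -1):
            if len(clique) + bound[i] <= len(best):
                return
            v = order[i]
            clique.append(v)
            nxt = cand & adj[v]
            if nxt:
                expand(clique, nxt)
            elif len(clique) > len(best):
                best = clique.copy()
            clique.pop()
            cand &= ~(1 << v)

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, n_vert + 1000))
    try:
        expand([], (1 << n_vert) - 1)
    finally:
        sys.setrecursionlimit(old_limit)

    return CodeSet(cg.profile, [cg.words[i] for i in sorted(best)])


def greedy_random_baseline(
    profile: ConstraintProfile,
    restarts: int = 10,
    seed: int | None = None,
    guard: int = ENUMERATION_GUARD,
) -> CodeSet:
    """Best maximal compatible set over seeded random-order greedy passes."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    words = enumerate_valid_codewords(profile, guard=guard)
    mat = np.array([w.digits for w in words], dtype=np.int8)
    best_idx: list[int] = []
    for _ in range(restarts):
        perm = rng.permutation(len(words))
        chosen: list[int] = []
        for i in perm:
            if not chosen:
                chosen.append(int(i))
                continue
            dist = (mat[chosen] != mat[i]).sum(axis=1)
            if (dist >= profile.d).all():
                chosen.append(int(i))
        if len(chosen) > len(best_idx):
            best_idx = chosen
    return CodeSet(profile, [words[i] for i in sorted(best_idx)])
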