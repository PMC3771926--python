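"""Statistical grouping: connected components, group splitting, maximal
cliques, and fractional-Hamming redundant-clique elimination.

Maximal cliques group sequences that all share one regional similarity;
requiring full pairwise interconnection is what prevents domain chaining
through multi-domain intermediates.  Near-duplicate cliques (an underlying
clique missing a few edges) are collapsed by clustering cliques at a
fractional Hamming distance threshold and keeping the largest member of
each cluster.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

Clique = tuple[str, ...]


def connected_components(g: nx.Graph) -> tuple[list[set[str]], list[str]]:
    """Partition nodes into connected components.

    Returns ``(components, singletons)``: components of size >= 2 sorted by
    (size desc, member ids), and isolated nodes sorted by id.
    """
    comps = [set(c) for c in nx.connected_components(g)]
    multi = sorted(
        (c for c in comps if len(c) > 1), key=lambda c: (-len(c), sorted(c))
    )
    singles = sorted(min(c) for c in comps if len(c) == 1)
    return multi, singles


def split_large_components(
    comp: set[str], max_size: int = 100, rng: np.random.Generator | None = None
) -> list[list[str]]:
    """Randomly split a component into groups of at most ``max_size`` members.

    A component of 850 yields 9 groups: eight of 100 and one of 50.
    Deterministic for a given ``rng`` state.
    """
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    members = sorted(comp)
    if len(members) <= max_size:
        return [members]
    rng = rng or np.random.default_rng(0)
    order = rng.permutation(len(members))
    shuffled = [members[i] for i in order]
    return [
        sorted(shuffled[i : i + max_size]) for i in range(0, len(shuffled), max_size)
    ]


def maximal_cliques(g: nx.Graph, members: list[str] | None = None) -> list[Clique]:
    """Maximal cliques (size >= 2) of ``g`` restricted to ``members``.

    Uses pivoting Bron-Kerbosch enumeration; output is canonicalized as
    sorted member tuples, sorted lexicographically.
    """
    sub = g.subgraph(members) if members is not None else g
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(sub) if len(c) >= 2]
    return sorted(cliques)


def fractional_hamming(a: Clique | set[str], b: Clique | set[str]) -> float:
    """Symmetric-difference size over the summed clique sizes, in [0, 1]."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("cliques must be non-empty")
    return len(sa ^ sb) / (len(sa) + len(sb))


def eliminate_redundant(cliques: list[Clique], threshold: float = 0.3) -> list[Clique]:
    """Collapse near-duplicate cliques.

    Cliques are single-linkage clustered over the graph whose edges are pairs
    with fractional Hamming distance <= ``threshold``; each cluster is
    replaced by its largest member (ties broken by the lexicographically
    smallest sorted member tuple).  Output is sorted and deterministic.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    cliques = sorted({tuple(sorted(c)) for c in cliques})
    if len(cliques) <= 1:
        return list(cliques)

    universe = sorted({m for c in cliques for m in c})
    idx = {m: i for i, m in enumerate(universe)}
    memb = np.zeros((len(cliques), len(universe)), dtype=np.int32)
    for r, c in enumerate(cliques):
        for m in c:
            memb[r, idx[m]] = 1
    sizes = memb.sum(axis=1)
    inter = memb @ memb.T
    symdiff = sizes[:, None] + sizes[None, :] - 2 * inter
    dist = symdiff / (sizes[:, None] + sizes[None, :])
    adj = csr_matrix(dist <= threshold)
    _, labels = _cc(adj, directed=False)

    out: list[Clique] = []
    for lbl in np.unique(labels):
        group = [cliques[i] for i in np.flatnonzero(labels == lbl)]
        out.append(min(group, key=lambda c: (-len(c), c)))
    return sorted(out)
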