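"""Neighbour-Joining trees from K2P distance matrices.

Standard Saitou & Nei (1987) agglomeration with the Studier & Keppler Q
criterion.  The implementation is deterministic: ties in the Q matrix are
broken by the lexicographically smallest (sorted) pair of cluster keys,
where a cluster's key is the smallest leaf label it contains.  Negative
branch lengths — a well-known artefact of NJ on non-additive matrices — are
clamped to zero with the deficit transferred to the sibling branch, and
flagged on the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .distances import DistanceMatrix


@dataclass
class PhyloTree:
    """Unrooted tree as an undirected graph; leaf nodes are specimen ids.

    Internal nodes are synthetic ``_inner<k>`` ids and have degree 3 (the
    unrooted NJ topology).  Edge attribute ``length`` is in
    substitutions/site.
    """

    graph: nx.Graph
    leaves: list[str]
    species: dict[str, str] = field(default_factory=dict)
    clamped_branches: int = 0

    def leaf_set(self) -> set[str]:
        return set(self.leaves)

    def path_length_matrix(self) -> np.ndarray:
        """Leaf-to-leaf path lengths, in the order of ``self.leaves``."""
        n = len(self.leaves)
        out = np.zeros((n, n))
        lengths = dict(nx.all_pairs_dijkstra_path_length(self.graph, weight="length"))
        for i, a in enumerate(self.leaves):
            for j, b in enumerate(self.leaves):
                out[i, j] = lengths[a][b]
        return out

    def bipartitions(self) -> list[tuple[frozenset[str], frozenset[str]]]:
        """Leaf bipartition induced by each internal edge."""
        all_leaves = self.leaf_set()
        out = []
        for u, v in self.graph.edges():
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = {x for x in nx.node_connected_component(g, u) if x in all_leaves}
            out.append((frozenset(side), frozenset(all_leaves - side)))
        return out

    def to_newick(self) -> str:
        """Newick string rooted arbitrarily at an internal node (or the first
        leaf for 2-taxon trees); labels quoted when they need it."""
        internal = [n for n in self.graph.nodes if n not in self.leaf_set()]
        root = internal[0] if internal else self.leaves[0]

        def quote(label: str) -> str:
            if any(c in label for c in " ():;,'[]"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def rec(node, parent) -> str:
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                return quote(node)
            inner = ",".join(
                f"{rec(c, node)}:{self.graph[node][c]['length']:.10f}"
                for c in children
            )
            return f"({inner})"

        return rec(root, None) + ";"


def neighbour_joining(m: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei Neighbour-Joining on a full (no-UNDEFINED) distance matrix.

    Raises on UNDEFINED (NaN) entries, listing the offending pairs.
    """
    n = len(m)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    bad = m.undefined_pairs()
    if bad:
        raise ValueError(f"UNDEFINED distances present for pairs: {bad}")

    D = m.d.astype(float).copy()
    # active clusters: node id -> sort key (smallest contained leaf label)
    node_ids = list(m.labels)
    keys = {lab: lab for lab in m.labels}
    active = list(range(n))
    g = nx.Graph()
    clamped = 0
    next_inner = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        Q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        Q = np.minimum(Q, Q.T)  # exact symmetry despite float non-associativity
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # all index pairs attaining the minimum, tie-broken lexicographically
        cand = np.argwhere(Q <= qmin)
        best = None
        for a, b in cand:
            if a >= b:
                continue
            i, j = active[a], active[b]
            key = tuple(sorted((keys[node_ids[i]], keys[node_ids[j]])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        lj = dij - li
        # transfer any negative deficit to the sibling branch
        if li < 0:
            lj += li
        elif lj < 0:
            li += lj
        li, lj = clamp(li), clamp(lj)
        new = f"_inner{next_inner}"
        next_inner += 1
        g.add_edge(node_ids[i], new, length=li)
        g.add_edge(node_ids[j], new, length=lj)
        # reduced distances to the new node
        newrow = np.empty(len(D) + 1)
        for c in active:
            if c in (i, j):
                continue
            newrow[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = len(D) - 1
        for c in active:
            if c in (i, j):
                continue
            D[k, c] = D[c, k] = newrow[c]
        node_ids.append(new)
        keys[new] = min(keys[node_ids[i]], keys[node_ids[j]])
        active = [c for c in active if c not in (i, j)] + [k]

    # final three-way join
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = clamp(0.5 * (dij + dik - djk))
    lj = clamp(0.5 * (dij + djk - dik))
    lk = clamp(0.5 * (dik + djk - dij))
    hub = f"_inner{next_inner}"
    g.add_edge(node_ids[i], hub, length=li)
    g.add_edge(node_ids[j], hub, length=lj)
    g.add_edge(node_ids[k], hub, length=lk)

    species = (
        dict(zip(m.labels, m.species)) if m.species is not None else {}
    )
    return PhyloTree(g, list(m.labels), species, clamped)


def species_cluster_check(t: PhyloTree) -> dict[str, str]:
    """Per-species cluster-exclusivity verdict on an NJ tree.

    ``exclusive`` iff some edge bipartition separates exactly that species'
    leaves from everything else; ``singleton`` for species with one leaf;
    ``non_exclusive`` otherwise.
    """
    if not t.species:
        raise ValueError("tree carries no species labels")
    by_species: dict[str, set[str]] = {}
    for leaf in t.leaves:
        by_species.setdefault(t.species.get(leaf, ""), set()).add(leaf)
    sides = set()
    for a, b in t.bipartitions():
        sides.add(a)
        sides.add(b)
    out = {}
    for sp, leaves in by_species.items():
        if len(leaves) == 1:
            out[sp] = "singleton"
        elif frozenset(leaves) in sides:
            out[sp] = "exclusive"
        else:
            out[sp] = "non_exclusive"
    return out
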