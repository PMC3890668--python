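"""Intraspecific analysis: haplotypes, diversity indices, median-joining
networks and haplogroup partitions.

Identical sequences collapse into haplotypes; the standard diversity indices
are haplotype diversity

    h = n/(n-1) * (1 - sum_i (n_i/n)^2)

(the probability that two sequences drawn without replacement differ, with
the n/(n-1) small-sample correction) and Nei's nucleotide diversity pi, the
mean per-site pairwise difference under pairwise deletion and with no
multiple-hit correction.

The median-joining network (Bandelt, Forster & Roehl 1999) combines the
minimum-spanning network of observed haplotypes with inferred intermediate
("median vector") haplotypes: the union-of-MSTs network is computed, majority
-consensus medians of node triples are added when they shorten connections,
and the process iterates to a fixpoint; obsolete medians (those on no
shortest connection between observed haplotypes) are removed.  Indels and
ambiguity codes are treated as missing, not as a fifth state.  Haplogroups
are read off the network by cutting every edge carrying at least
``min_cut_mutations`` mutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .distances import _counts_from_encoded, _encode_one
from .seqio import MISSING, AlignedSeqSet


@dataclass
class HaplotypeSet:
    """Distinct haplotypes with their frequencies and member specimens."""

    haplotypes: dict[str, str]  # haplotype id -> representative sequence
    counts: dict[str, int]
    members: dict[str, list[str]]  # haplotype id -> specimen ids
    ambiguous: list[str] = field(default_factory=list)  # flagged specimen ids
    source: AlignedSeqSet | None = None

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def H(self) -> int:
        return len(self.haplotypes)


def collapse_haplotypes(s: AlignedSeqSet) -> HaplotypeSet:
    """Collapse an aligned set into haplotypes.

    Sequences without missing data group by exact identity.  A sequence with
    missing data merges into a complete haplotype only when it is compatible
    (agrees wherever both are called) with exactly one of them; otherwise it
    stays its own haplotype and its specimens are flagged ambiguous.
    Haplotype ids H1, H2, ... are assigned by descending frequency, then by
    first occurrence.
    """
    mat = s.encoded()
    complete = [(mat[i] != MISSING).all() for i in range(len(s))]
    groups: dict[str, list[int]] = {}
    for i, seq in enumerate(s.sequences):
        groups.setdefault(seq, []).append(i)
    complete_keys = [seq for seq in groups if complete[groups[seq][0]]]
    ambiguous: list[str] = []
    merged: dict[str, list[int]] = {seq: list(groups[seq]) for seq in complete_keys}
    leftovers: dict[str, list[int]] = {}
    for seq, idxs in groups.items():
        if complete[idxs[0]]:
            continue
        enc = mat[idxs[0]]
        called = enc != MISSING
        compat = [
            ck for ck in complete_keys
            if (enc[called] == mat[groups[ck][0]][called]).all()
        ]
        if len(compat) == 1:
            merged[compat[0]].extend(idxs)
        else:
            leftovers[seq] = idxs
            ambiguous.extend(s.ids[i] for i in idxs)
    ordered = sorted(
        list(merged.items()) + list(leftovers.items()),
        key=lambda kv: (-len(kv[1]), min(kv[1])),
    )
    haplotypes: dict[str, str] = {}
    counts: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for k, (seq, idxs) in enumerate(ordered, start=1):
        hid = f"H{k}"
        haplotypes[hid] = seq
        counts[hid] = len(idxs)
        members[hid] = [s.ids[i] for i in sorted(idxs)]
    return HaplotypeSet(haplotypes, counts, members, ambiguous, s)


@dataclass
class DiversityStats:
    n: int
    S: int
    H: int
    h: float  # haplotype diversity
    pi: float  # nucleotide diversity
    length: int
    polymorphism_percent: float


def diversity(hs: HaplotypeSet, length: int | None = None) -> DiversityStats:
    """Haplotype and nucleotide diversity of a haplotype set.

    pi is computed over all sequence pairs of the underlying set (pairwise
    deletion, raw p-distances, no correction) so it agrees exactly with the
    mean pairwise p-distance of the distances module.
    """
    n = hs.n
    if n < 2:
        raise ValueError("diversity needs n >= 2 sequences")
    freqs = np.array(list(hs.counts.values()), dtype=float) / n
    h = (n / (n - 1)) * (1.0 - float((freqs**2).sum()))
    if hs.source is not None:
        seqs = hs.source.sequences
        L = hs.source.alignment_length
        mat = hs.source.encoded()
    else:
        seqs = [
            hs.haplotypes[hid]
            for hid in hs.haplotypes
            for _ in range(hs.counts[hid])
        ]
        L = len(next(iter(hs.haplotypes.values())))
        mat = np.stack([_encode_one(q) for q in seqs])
    total = 0.0
    npairs = 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            c = _counts_from_encoded(mat[i], mat[j])
            if c.n_compared > 0:
                total += c.p_distance
            npairs += 1
    pi = total / npairs
    S = 0
    for col in mat.T:
        if len(np.unique(col[col != MISSING])) >= 2:
            S += 1
    L = length if length is not None else L
    return DiversityStats(n, S, len(hs.haplotypes), h, pi, L, 100.0 * S / L)


@dataclass
class NetworkEdge:
    a: str
    b: str
    n_mutations: int
    positions: list[int]  # 1-based alignment coordinates


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # nodes carry attr observed: bool; edges attr weight, positions
    observed: list[str]
    median_vectors: list[str]
    node_sequences: dict[str, str]
    merged_into: dict[str, str] = field(default_factory=dict)

    def edges(self) -> list[NetworkEdge]:
        return [
            NetworkEdge(u, v, d["weight"], d["positions"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def to_edge_tsv(self) -> str:
        lines = ["node_a\tnode_b\tn_mutations\tpositions"]
        for e in sorted(self.edges(), key=lambda e: (e.a, e.b)):
            pos = ",".join(str(p) for p in e.positions)
            lines.append(f"{e.a}\t{e.b}\t{e.n_mutations}\t{pos}")
        return "\n".join(lines) + "\n"

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, observed=bool(d["observed"]))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=int(d["weight"]),
                       positions=",".join(map(str, d["positions"])))
        nx.write_graphml(g, path)


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    both = (a != MISSING) & (b != MISSING)
    return int((both & (a != b)).sum())


def _diff_positions(a: np.ndarray, b: np.ndarray) -> list[int]:
    both = (a != MISSING) & (b != MISSING)
    return [int(p) + 1 for p in np.flatnonzero(both & (a != b))]


def _msn_links(
    nodes: dict[str, np.ndarray], epsilon: int = 0
) -> list[tuple[str, str, int]]:
    """Epsilon-relaxed minimum-spanning network links.

    A link (u, v) of Hamming length d is feasible iff u and v fall in
    different connected components of the graph of all links strictly shorter
    than d - epsilon.  With epsilon=0 this is exactly the union of all
    minimum spanning trees.
    """
    labels = sorted(nodes)
    pairs = [
        (u, v, _hamming(nodes[u], nodes[v]))
        for u, v in itertools.combinations(labels, 2)
    ]
    links = []
    for u, v, d in pairs:
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from(
            (a, b) for a, b, dd in pairs if dd < d - epsilon
        )
        if not nx.has_path(g, u, v):
            links.append((u, v, d))
    return links


def _median(a: np.ndarray, b: np.ndarray, c: np.ndarray,
            tie_source: np.ndarray) -> np.ndarray:
    """Site-wise majority consensus; ties resolved from ``tie_source`` (the
    lexicographically smallest-labelled parent), missing when nothing called."""
    out = np.empty_like(a)
    for k in range(len(a)):
        states = [x for x in (a[k], b[k], c[k]) if x != MISSING]
        if not states:
            out[k] = MISSING
            continue
        vals, cnt = np.unique(states, return_counts=True)
        if cnt.max() >= 2:
            out[k] = vals[int(np.argmax(cnt))]
        else:
            out[k] = tie_source[k] if tie_source[k] != MISSING else vals[0]
    return out


def median_joining_network(
    hs: HaplotypeSet, epsilon: int = 0, max_rounds: int = 25
) -> HaplotypeNetwork:
    """Median-joining network of a haplotype set (needs H >= 2).

    Zero-distance haplotype pairs (possible when missing-data haplotypes were
    kept separate) are merged into a single network node, recorded in
    ``merged_into``.  Deterministic: all tie-breaks are lexicographic on node
    labels.
    """
    if hs.H < 2:
        raise ValueError("median-joining network needs >= 2 haplotypes")
    enc = {hid: _encode_one(seq) for hid, seq in hs.haplotypes.items()}
    # merge zero-distance nodes (keep the lexicographically smallest label)
    merged_into: dict[str, str] = {}
    for u, v in itertools.combinations(sorted(enc), 2):
        if u in merged_into or v in merged_into:
            continue
        if _hamming(enc[u], enc[v]) == 0:
            merged_into[v] = u
    nodes = {h: enc[h] for h in enc if h not in merged_into}
    observed = sorted(nodes)

    mv_count = 0
    for _ in range(max_rounds):
        links = _msn_links(nodes, epsilon)
        linkset = {frozenset((u, v)) for u, v, _ in links}
        candidates: list[tuple[int, str, tuple[int, ...]]] = []
        seen_median: set[tuple[int, ...]] = set()
        for u, v, w in itertools.combinations(sorted(nodes), 3):
            n_linked = sum(
                frozenset(p) in linkset
                for p in ((u, v), (u, w), (v, w))
            )
            if n_linked < 2:
                continue
            m = _median(nodes[u], nodes[v], nodes[w], nodes[u])
            key = tuple(int(x) for x in m)
            if key in seen_median:
                continue
            if any(_hamming(m, arr) == 0 for arr in nodes.values()):
                continue
            seen_median.add(key)
            cost = (_hamming(m, nodes[u]) + _hamming(m, nodes[v])
                    + _hamming(m, nodes[w]))
            candidates.append((cost, u, key))
        if not candidates:
            break
        lam = min(c[0] for c in candidates)
        added = False
        for cost, _, key in sorted(candidates):
            if cost > lam + epsilon:
                break
            arr = np.array(key, dtype=np.uint8)
            if any(_hamming(arr, x) == 0 for x in nodes.values()):
                continue
            mv_count += 1
            nodes[f"mv{mv_count}"] = arr
            added = True
        if not added:
            break

    # final network over observed + medians, then prune obsolete medians:
    # keep only nodes/edges on a shortest connection between observed types.
    links = _msn_links(nodes, epsilon)
    g = nx.Graph()
    for lab in nodes:
        g.add_node(lab, observed=lab in set(observed))
    for u, v, d in links:
        g.add_edge(u, v, weight=d,
                   positions=_diff_positions(nodes[u], nodes[v]))
    sp_len = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    keep_edges = set()
    for u, v, d in g.edges(data=True):
        w = d["weight"]
        for s_obs, t_obs in itertools.combinations(observed, 2):
            if (
                sp_len[s_obs].get(u, math.inf) + w + sp_len[v].get(t_obs, math.inf)
                == sp_len[s_obs].get(t_obs, math.inf)
            ) or (
                sp_len[s_obs].get(v, math.inf) + w + sp_len[u].get(t_obs, math.inf)
                == sp_len[s_obs].get(t_obs, math.inf)
            ):
                keep_edges.add(frozenset((u, v)))
                break
    pruned = nx.Graph()
    for lab in nodes:
        pruned.add_node(lab, observed=lab in set(observed))
    for u, v, d in g.edges(data=True):
        if frozenset((u, v)) in keep_edges:
            pruned.add_edge(u, v, **d)
    drop = [
        n for n, d in pruned.nodes(data=True)
        if not d["observed"] and pruned.degree(n) == 0
    ]
    pruned.remove_nodes_from(drop)
    medians = sorted(n for n, d in pruned.nodes(data=True) if not d["observed"])
    node_seqs = {
        lab: "".join("ACGT"[x] if x != MISSING else "N" for x in nodes[lab])
        for lab in pruned.nodes
    }
    return HaplotypeNetwork(pruned, observed, medians, node_seqs, merged_into)


@dataclass
class HaplogroupPartition:
    groups: dict[str, int]  # observed haplotype id -> group index (1-based)
    n_groups: int
    cut_edges: list[NetworkEdge]

    def group_of(self, haplotype_id: str) -> int:
        return self.groups[haplotype_id]


def haplogroup_partition(
    net: HaplotypeNetwork, min_cut_mutations: int = 2
) -> HaplogroupPartition:
    """Partition the network into haplogroups by cutting every edge with
    >= ``min_cut_mutations`` mutations; components containing at least one
    observed haplotype become groups (median-only components are dropped).
    Group 1 is the component containing the smallest observed label.
    """
    if not net.is_connected():
        raise ValueError("haplogroup partition requires a connected network")
    g = net.graph.copy()
    cut = [
        NetworkEdge(u, v, d["weight"], d["positions"])
        for u, v, d in g.edges(data=True)
        if d["weight"] >= min_cut_mutations
    ]
    g.remove_edges_from([(e.a, e.b) for e in cut])
    comps = [
        sorted(c) for c in nx.connected_components(g)
        if any(n in set(net.observed) for n in c)
    ]
    comps.sort(key=lambda c: min(n for n in c if n in set(net.observed)))
    groups: dict[str, int] = {}
    for gi, comp in enumerate(comps, start=1):
        for n in comp:
            if n in set(net.observed):
                groups[n] = gi
    for hap, canon in net.merged_into.items():
        groups[hap] = groups[canon]
    return HaplogroupPartition(groups, len(comps), cut)
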