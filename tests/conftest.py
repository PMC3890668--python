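import numpy as np
import networkx as nx
import pytest

from barcodekit.seqio import AlignedSeqSet, Specimen


@pytest.fixture
def make_set():
    """Factory: build an AlignedSeqSet from sequences (+ optional species)."""

    def _make(seqs, species=None, ids=None, locus="COI"):
        n = len(seqs)
        ids = ids or [f"s{i + 1}" for i in range(n)]
        species = species or ["Species X"] * n
        specimens = [
            Specimen(i, species=sp, locus=locus) for i, sp in zip(ids, species)
        ]
        return AlignedSeqSet(specimens, [s.upper() for s in seqs])

    return _make


@pytest.fixture
def random_additive_matrix():
    """Factory: random tree with random branch lengths -> its leaves and
    exact path-length (additive) distance matrix."""

    def _make(n, rng):
        g = nx.Graph()
        leaves = [f"L{i:02d}" for i in range(n)]
        g.add_edge(leaves[0], leaves[1], length=float(rng.uniform(0.05, 1.0)))
        inner = 0
        for leaf in leaves[2:]:
            u, v = list(g.edges())[int(rng.integers(0, g.number_of_edges()))]
            L = g[u][v]["length"]
            f = float(rng.uniform(0.2, 0.8))
            g.remove_edge(u, v)
            h = f"I{inner}"
            inner += 1
            g.add_edge(u, h, length=L * f)
            g.add_edge(h, v, length=L * (1 - f))
            g.add_edge(h, leaf, length=float(rng.uniform(0.05, 1.0)))
        D = np.zeros((n, n))
        sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                D[i, j] = sp[a][b]
        return leaves, D

    return _make


def brute_force_k2p(seq_a: str, seq_b: str) -> float:
    """Independent K2P oracle: pure-python site loop + direct formula.

    Written separately from the vectorized implementation: explicit
    transition-pair table, per-character loop, math on floats.
    """
    import math

    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in transitions:
            ts += 1
        else:
            tv += 1
    if n == 0:
        return float("nan")
    P, Q = ts / n, tv / n
    if (1 - 2 * P - Q) <= 0 or (1 - 2 * Q) <= 0:
        return float("nan")
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


def random_sequences(rng, n, length, missing_frac=0.0):
    """Random ACGT sequences with optional gap/N contamination.

    Unrelated uniform sequences sit near the K2P saturation boundary, so
    these mostly exercise the UNDEFINED path."""
    alphabet = np.array(list("ACGT"))
    out = []
    for _ in range(n):
        chars = alphabet[rng.integers(0, 4, size=length)]
        if missing_frac:
            mask = rng.random(length) < missing_frac
            noise = np.array(list("N-"))[rng.integers(0, 2, size=length)]
            chars = np.where(mask, noise, chars)
        out.append("".join(chars))
    return out


def infinite_sites_haplotypes(rng, n_haplotypes, length):
    """Random perfect-phylogeny haplotypes: grow a genealogy by copying an
    existing haplotype and adding 1-3 mutations at never-reused positions.
    Hamming distances are then exactly additive on the genealogy — the
    low-homoplasy regime in which mtDNA haplotype networks operate."""
    alphabet = "ACGT"
    root = rng.integers(0, 4, size=length)
    haps = [root.copy()]
    free = list(rng.permutation(length))
    while len(haps) < n_haplotypes:
        parent = haps[int(rng.integers(0, len(haps)))].copy()
        for _ in range(int(rng.integers(1, 4))):
            pos = free.pop()
            parent[pos] = (parent[pos] + int(rng.integers(1, 4))) % 4
        haps.append(parent)
    return ["".join(alphabet[x] for x in h) for h in haps]


def related_sequences(rng, n, length, sub_rate=0.1, missing_frac=0.0):
    """Sequences mutated independently from one random root: pairwise
    divergences stay inside the K2P domain, so distances are defined."""
    alphabet = np.array(list("ACGT"))
    root = rng.integers(0, 4, size=length)
    out = []
    for _ in range(n):
        seq = root.copy()
        mask = rng.random(length) < sub_rate
        seq[mask] = (seq[mask] + rng.integers(1, 4, size=mask.sum())) % 4
        chars = alphabet[seq]
        if missing_frac:
            mmask = rng.random(length) < missing_frac
            noise = np.array(list("N-"))[rng.integers(0, 2, size=length)]
            chars = np.where(mmask, noise, chars)
        out.append("".join(chars))
    return out
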