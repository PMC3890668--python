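"""Haplotype collapsing, diversity indices, median-joining networks."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodekit.distances import count_site_patterns
from barcodekit.popgen import (
    HaplotypeSet,
    collapse_haplotypes,
    diversity,
    haplogroup_partition,
    median_joining_network,
)
from barcodekit.simulate import simulate_two_haplogroups
from .conftest import infinite_sites_haplotypes, related_sequences


def hamming(a, b):
    return sum(
        x != y for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
    )


class TestCollapse:
    def test_clones_collapse(self, make_set):
        hs = collapse_haplotypes(make_set(["ACGT"] * 4))
        assert hs.H == 1 and hs.counts == {"H1": 4}

    def test_two_haplotypes_with_counts(self, make_set):
        hs = collapse_haplotypes(make_set(["ACGT", "ACGA", "ACGT"]))
        assert hs.counts == {"H1": 2, "H2": 1}
        assert hs.members["H1"] == ["s1", "s3"]

    def test_missing_merges_into_unique_compatible(self, make_set):
        hs = collapse_haplotypes(make_set(["ACGT", "ACGA", "NCGT"]))
        # NCGT only compatible with ACGT
        assert hs.counts == {"H1": 2, "H2": 1}
        assert not hs.ambiguous

    def test_missing_compatible_with_two_stays_separate(self, make_set):
        hs = collapse_haplotypes(make_set(["ACGT", "ACGA", "ACGN"]))
        assert hs.H == 3
        assert hs.ambiguous == ["s3"]

    def test_planted_spectrum_recovered(self):
        s, truth = simulate_two_haplogroups(
            n=30, length=500, between_steps=4, within_steps=1, seed=13
        )
        hs = collapse_haplotypes(s)
        # every member group carries identical sequences
        for hid, members in hs.members.items():
            seqs = {s.sequences[s.ids.index(m)] for m in members}
            assert len(seqs) == 1
        assert hs.n == 30


def spectrum_set(counts, length=64):
    """Haplotype set with given counts; haplotype i carries a private
    mutation at site i (every distinct pair differs at exactly 2 sites)."""
    base = list("A" * length)
    haps = {}
    for i in range(len(counts)):
        seq = base.copy()
        seq[i] = "G"
        haps[f"H{i + 1}"] = "".join(seq)
    members = {}
    k = 0
    for i, c in enumerate(counts):
        members[f"H{i + 1}"] = [f"s{k + j}" for j in range(c)]
        k += c
    return HaplotypeSet(haps, {f"H{i+1}": c for i, c in enumerate(counts)},
                        members)


class TestDiversity:
    def test_monomorphic(self, make_set):
        hs = collapse_haplotypes(make_set(["ACGTAA"] * 4))
        d = diversity(hs)
        assert d.h == 0.0 and d.pi == 0.0 and d.S == 0

    def test_hand_computed_spectrum(self):
        # counts (2,1,1): h = (4/3)(1 - 0.25^2*... ) = 0.8333...
        d = diversity(spectrum_set([2, 1, 1]))
        assert d.h == pytest.approx((4 / 3) * (1 - (0.25 + 0.0625 + 0.0625)))
        assert d.h == pytest.approx(0.833333333333, abs=1e-9)

    def test_exhaustive_small_spectra_match_closed_forms(self):
        """For every haplotype spectrum with n <= 8: h matches the closed
        form and pi matches the hand formula for one-private-site haplotypes
        (each distinct pair differs at exactly 2 of L sites)."""
        L = 64

        def partitions(n, maxpart=None):
            maxpart = maxpart or n
            if n == 0:
                yield ()
                return
            for first in range(min(n, maxpart), 0, -1):
                for rest in partitions(n - first, first):
                    yield (first,) + rest

        for n in range(2, 9):
            for counts in partitions(n):
                d = diversity(spectrum_set(list(counts), L))
                freqs = [c / n for c in counts]
                h_expected = (n / (n - 1)) * (1 - sum(f * f for f in freqs))
                pairs_diff = sum(
                    ci * cj for ci, cj in itertools.combinations(counts, 2)
                )
                pi_expected = (2 / L) * pairs_diff / (n * (n - 1) / 2)
                assert d.h == pytest.approx(h_expected, abs=1e-12)
                assert d.pi == pytest.approx(pi_expected, abs=1e-12)

    def test_evenness_maximizes_h(self):
        """For fixed n and H, haplotype diversity peaks when counts are as
        even as possible (exhaustive over n <= 8)."""
        def partitions(n, maxpart=None):
            maxpart = maxpart or n
            if n == 0:
                yield ()
                return
            for first in range(min(n, maxpart), 0, -1):
                for rest in partitions(n - first, first):
                    yield (first,) + rest

        for n in range(2, 9):
            by_H = {}
            for counts in partitions(n):
                h = diversity(spectrum_set(list(counts))).h
                by_H.setdefault(len(counts), []).append((counts, h))
            for H, items in by_H.items():
                most_even = min(items, key=lambda ch: max(ch[0]) - min(ch[0]))
                assert most_even[1] == pytest.approx(
                    max(h for _, h in items), abs=1e-12
                )

    @given(st.permutations(list(range(4))))
    @settings(deadline=None)
    def test_h_invariant_under_relabelling(self, perm):
        counts = [4, 3, 2, 1]
        base = diversity(spectrum_set(counts)).h
        shuffled = diversity(spectrum_set([counts[i] for i in perm])).h
        assert shuffled == pytest.approx(base, abs=1e-15)

    def test_pi_equals_mean_pairwise_p_distance(self, make_set):
        rng = np.random.default_rng(14)
        seqs = related_sequences(rng, 8, 200, sub_rate=0.02, missing_frac=0.02)
        s = make_set(seqs)
        d = diversity(collapse_haplotypes(s))
        pd = []
        for a, b in itertools.combinations(seqs, 2):
            c = count_site_patterns(a, b)
            pd.append(c.p_distance)
        assert d.pi == pytest.approx(np.mean(pd), abs=1e-12)

    def test_needs_two_sequences(self, make_set):
        with pytest.raises(ValueError):
            diversity(collapse_haplotypes(make_set(["ACGT"])))


class TestMedianJoiningNetwork:
    def test_two_haplotypes_single_edge(self, make_set):
        hs = collapse_haplotypes(make_set(["ACGT", "ACGA"]))
        net = median_joining_network(hs)
        edges = net.edges()
        assert len(edges) == 1
        assert edges[0].n_mutations == 1
        assert edges[0].positions == [4]
        assert net.median_vectors == []

    def test_three_equidistant_resolve_through_median(self, make_set):
        # checked by hand: pairwise distance 2, consensus GGG links all three
        hs = collapse_haplotypes(make_set(["GGA", "AGG", "GAG"]))
        net = median_joining_network(hs)
        assert len(net.median_vectors) == 1
        mv = net.median_vectors[0]
        assert net.node_sequences[mv] == "GGG"
        assert sorted(
            (e.n_mutations for e in net.edges())
        ) == [1, 1, 1]
        assert all(mv in (e.a, e.b) for e in net.edges())

    def test_random_instances_connected_and_contain_an_mst(self, make_set):
        """eps=0 network is connected and realizes every edge of an
        independently computed MST as a path of equal mutation count.

        Instances are random perfect-phylogeny genealogies — the
        low-homoplasy regime of real mtDNA haplotype data."""
        rng = np.random.default_rng(15)
        for _ in range(25):
            H = int(rng.integers(4, 9))
            seqs = infinite_sites_haplotypes(rng, H, 120)
            s = make_set(seqs, ids=[f"x{i}" for i in range(len(seqs))])
            hs = collapse_haplotypes(s)
            if hs.H < 2:
                continue
            net = median_joining_network(hs)
            assert net.is_connected()
            # independent MST via networkx on the complete Hamming graph
            g = nx.Graph()
            reps = {h: hs.haplotypes[h] for h in hs.haplotypes}
            for a, b in itertools.combinations(reps, 2):
                g.add_edge(a, b, weight=hamming(reps[a], reps[b]))
            mst = nx.minimum_spanning_tree(g)
            for u, v, d in mst.edges(data=True):
                u = net.merged_into.get(u, u)
                v = net.merged_into.get(v, v)
                if u == v:
                    continue
                plen = nx.shortest_path_length(
                    net.graph, u, v, weight="weight"
                )
                assert plen == d["weight"]

    def test_single_haplotype_rejected(self, make_set):
        with pytest.raises(ValueError):
            median_joining_network(collapse_haplotypes(make_set(["ACGT"] * 3)))


class TestHaplogroupPartition:
    def test_single_low_weight_edge_is_one_group(self, make_set):
        net = median_joining_network(
            collapse_haplotypes(make_set(["ACGT", "ACGA"]))
        )
        part = haplogroup_partition(net)
        assert part.n_groups == 1

    def test_two_clusters_split_on_heavy_edge(self, make_set):
        left = "A" * 40
        right = "G" * 4 + "A" * 36  # 4 mutations away
        seqs = [left, left[:39] + "C", left[:38] + "TA",
                right, right[:39] + "C", right[:38] + "TA"]
        net = median_joining_network(collapse_haplotypes(make_set(seqs)))
        part = haplogroup_partition(net, min_cut_mutations=2)
        assert part.n_groups == 2
        groups = {part.groups[h] for h in part.groups}
        assert groups == {1, 2}

    def test_planted_bipartition_recovered(self):
        for seed in range(10):
            s, truth = simulate_two_haplogroups(
                n=24, length=400, between_steps=4, within_steps=1, seed=seed
            )
            hs = collapse_haplotypes(s)
            net = median_joining_network(hs)
            part = haplogroup_partition(net)
            pred = {
                sid: part.groups[hid]
                for hid, members in hs.members.items()
                for sid in members
            }
            same = lambda m, a, b: m[a] == m[b]
            for a, b in itertools.combinations(truth.haplogroup, 2):
                assert same(pred, a, b) == same(truth.haplogroup, a, b)
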