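"""Kimura 2-parameter distances, barcode-gap summaries and nearest-neighbour
species identification.

The Kimura (1980) two-parameter model distinguishes transitions (A<->G,
C<->T, proportion P of compared sites) from transversions (proportion Q) and
corrects the observed divergence for multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))    [substitutions/site]

Missing data (gaps, N, other IUPAC ambiguity codes) are handled by pairwise
deletion: a site is excluded from a pair's comparison only when either
sequence is missing there.  When the log argument is non-positive the pair is
saturated and the distance is UNDEFINED — represented as NaN and always
carried as an explicit flag, never silently as 0.

Distances are stored in substitutions/site and reported as percent in the
barcode-gap report, which tabulates per species the maximal intraspecific
distance and the minimal distance to the nearest-neighbour (NN) species — the
two quantities whose separation (the "barcode gap") makes threshold-based
species identification possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import MISSING, UNDETERMINED, AlignedSeqSet

NOT_APPLICABLE = float("nan")

#: species complexes whose members cannot be told apart at the barcode locus;
#: a nearest neighbour inside a declared complex forces an AMBIGUOUS verdict.
DELPHININAE = frozenset(
    {"Delphinus delphis", "Stenella coeruleoalba", "Stenella frontalis",
     "Tursiops truncatus"}
)


@dataclass(frozen=True)
class SitePatternCounts:
    """Per-pair site-pattern tally under pairwise deletion."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("more substitutions than compared sites")

    @property
    def p(self) -> float:
        return self.n_transitions / self.n_compared

    @property
    def q(self) -> float:
        return self.n_transversions / self.n_compared

    @property
    def p_distance(self) -> float:
        return (self.n_transitions + self.n_transversions) / self.n_compared


def count_site_patterns(seq_a: str, seq_b: str) -> SitePatternCounts:
    """Tally compared sites, transitions and transversions for two aligned
    sequences (equal length required; pairwise deletion of missing sites)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    a = _encode_one(seq_a)
    b = _encode_one(seq_b)
    return _counts_from_encoded(a, b)


def _encode_one(seq: str) -> np.ndarray:
    lut = np.full(256, MISSING, dtype=np.uint8)
    for base, code in zip("ACGT", range(4)):
        lut[ord(base)] = code
    return lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _counts_from_encoded(a: np.ndarray, b: np.ndarray) -> SitePatternCounts:
    both = (a != MISSING) & (b != MISSING)
    n_comp = int(both.sum())
    diff = both & (a != b)
    # transitions connect states of equal parity under A=0 C=1 G=2 T=3
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    return SitePatternCounts(n_comp, ts, tv)


def k2p_distance(c: SitePatternCounts) -> float:
    """K2P distance in substitutions/site; NaN when UNDEFINED (saturation or
    no comparable sites)."""
    if c.n_compared == 0:
        return float("nan")
    p, q = c.p, c.q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


def k2p_from_pq(p: float, q: float) -> float:
    """K2P distance from raw transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    # the log argument never exceeds 1, so the distance is >= 0; the max()
    # only normalizes -0.0 for identical sequences
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distance matrix with comparable-site counts.

    ``d`` holds substitutions/site; UNDEFINED (saturated / zero-overlap) pairs
    are NaN and listed by :meth:`undefined_pairs`.
    """

    labels: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray
    species: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if self.species is not None and len(self.species) != n:
            raise ValueError("species list length does not match labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.d[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_dataframe(self, percent: bool = False) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        return pd.DataFrame(self.d * scale, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        """PHYLIP square format (names truncated/padded to 10 chars)."""
        lines = [f"{len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            name = (lab[:10]).ljust(10)
            vals = " ".join(f"{v:.6f}" for v in self.d[i])
            lines.append(f"{name} {vals}")
        return "\n".join(lines) + "\n"

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        sp = [self.species[i] for i in idx] if self.species else None
        return DistanceMatrix(
            list(labels), self.d[np.ix_(idx, idx)],
            self.comparable_sites[np.ix_(idx, idx)], sp
        )


def distance_matrix(s: AlignedSeqSet) -> DistanceMatrix:
    """All-pairs K2P distances of an aligned set (pairwise deletion)."""
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    mat = s.encoded()
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    present = mat != MISSING
    parity = mat & 1
    for i in range(n):
        both = present[i] & present[i + 1 :]
        diff = both & (mat[i] != mat[i + 1 :])
        ts = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1)
        tot = diff.sum(axis=1)
        ncmp = both.sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            comp[i, j] = comp[j, i] = ncmp[k]
            if ncmp[k] == 0:
                d[i, j] = d[j, i] = float("nan")
                continue
            p = ts[k] / ncmp[k]
            q = (tot[k] - ts[k]) / ncmp[k]
            d[i, j] = d[j, i] = k2p_from_pq(p, q)
        comp[i, i] = int(present[i].sum())
    return DistanceMatrix(list(s.ids), d, comp, list(s.species))


def polymorphic_sites(s: AlignedSeqSet) -> tuple[int, int, float]:
    """Segregating sites S, alignment length, and polymorphism percent.

    A column is polymorphic when it shows >= 2 distinct unambiguous bases
    among the sequences that are called there.
    """
    if len(s) < 2:
        raise ValueError("need at least 2 sequences")
    mat = s.encoded()
    S = 0
    for col in mat.T:
        states = np.unique(col[col != MISSING])
        if len(states) >= 2:
            S += 1
    L = s.alignment_length
    return S, L, 100.0 * S / L


@dataclass
class SpeciesGapRow:
    species: str
    n_seqs: int
    max_intraspecific: float  # percent; NaN for singletons
    nearest_neighbour: str
    min_nn_distance: float  # percent


@dataclass
class BarcodeGapReport:
    per_species: list[SpeciesGapRow]
    n_polymorphic_sites: int
    alignment_length: int
    polymorphism_percent: float
    n_undefined_excluded: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.per_species])

    @property
    def min_nn_distance_overall(self) -> float:
        vals = [r.min_nn_distance for r in self.per_species
                if not math.isnan(r.min_nn_distance)]
        return min(vals) if vals else float("nan")

    @property
    def max_intraspecific_overall(self) -> float:
        vals = [r.max_intraspecific for r in self.per_species
                if not math.isnan(r.max_intraspecific)]
        return max(vals) if vals else float("nan")


def barcode_gap_report(
    m: DistanceMatrix, species: list[str] | None = None,
    seqset: AlignedSeqSet | None = None
) -> BarcodeGapReport:
    """Per-species barcode-gap table (percent distances) plus global
    polymorphism statistics when the sequence set is supplied."""
    labels = m.labels
    sp = species if species is not None else m.species
    if sp is None:
        raise ValueError("species labels required")
    n = len(labels)
    undef = 0
    intra: dict[str, float] = {}
    counts: dict[str, int] = {}
    nn: dict[str, tuple[float, str]] = {}
    for s_name in sp:
        counts[s_name] = counts.get(s_name, 0) + 1
    for i in range(n):
        for j in range(i + 1, n):
            dij = m.d[i, j]
            if math.isnan(dij):
                undef += 1
                continue
            si, sj = sp[i], sp[j]
            if si == sj:
                intra[si] = max(intra.get(si, 0.0), dij)
            else:
                for a, b in ((si, sj), (sj, si)):
                    if a not in nn or dij < nn[a][0]:
                        nn[a] = (dij, b)
    rows = []
    for s_name in sorted(counts):
        max_intra = (
            100.0 * intra.get(s_name, 0.0) if counts[s_name] >= 2 else NOT_APPLICABLE
        )
        nn_d, nn_sp = nn.get(s_name, (float("nan"), ""))
        rows.append(
            SpeciesGapRow(s_name, counts[s_name], max_intra,
                          nn_sp, 100.0 * nn_d)
        )
    if seqset is not None:
        S, L, pct = polymorphic_sites(seqset)
    else:
        S, L, pct = 0, 0, float("nan")
    return BarcodeGapReport(rows, S, L, pct, undef)


@dataclass
class NNAssignment:
    query_id: str
    best_species: str
    best_distance: float  # percent
    margin_to_second_species: float  # percent; inf when only one species
    verdict: str  # ASSIGNED | AMBIGUOUS | NO_MATCH
    note: str = ""


def identify_query(
    query_seq: str,
    reference: AlignedSeqSet,
    threshold: float = 2.0,
    tie_epsilon: float = 0.05,
    complexes: tuple[frozenset[str], ...] = (DELPHININAE,),
    min_overlap: int = 100,
    query_id: str = "query",
) -> NNAssignment:
    """Nearest-neighbour species identification of one query sequence.

    ASSIGNED iff the best species' minimal distance is <= ``threshold`` (%)
    and the runner-up species is strictly farther by more than ``tie_epsilon``
    (%).  AMBIGUOUS when the two best species tie within ``tie_epsilon`` or
    the best species belongs to a declared low-divergence complex.  NO_MATCH
    when the best distance exceeds the threshold, or when the query shares
    fewer than ``min_overlap`` comparable sites with every reference.
    """
    if len(query_seq) != reference.alignment_length:
        raise ValueError("query must be aligned to the reference alignment")
    labelled = [k for k, sp in enumerate(reference.specimens)
                if sp.species != UNDETERMINED]
    if not labelled:
        raise ValueError("reference set has no labelled species")
    q = _encode_one(query_seq)
    mat = reference.encoded()
    best: dict[str, float] = {}
    any_overlap = False
    for k in labelled:
        c = _counts_from_encoded(q, mat[k])
        if c.n_compared >= min_overlap:
            any_overlap = True
        dk = k2p_distance(c)
        if math.isnan(dk):
            continue
        sp = reference.specimens[k].species
        if c.n_compared >= min_overlap and (sp not in best or dk < best[sp]):
            best[sp] = dk
    if not any_overlap or not best:
        return NNAssignment(query_id, "", float("nan"), float("nan"),
                            "NO_MATCH", "insufficient overlap with references")
    ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    best_sp, best_d = ranked[0]
    best_pct = 100.0 * best_d
    margin = 100.0 * (ranked[1][1] - best_d) if len(ranked) > 1 else float("inf")
    if best_pct > threshold:
        return NNAssignment(query_id, best_sp, best_pct, margin, "NO_MATCH",
                            f"best distance exceeds threshold {threshold}%")
    for cx in complexes:
        if best_sp in cx:
            return NNAssignment(query_id, best_sp, best_pct, margin, "AMBIGUOUS",
                                "nearest species belongs to a low-divergence complex")
    if margin <= tie_epsilon:
        return NNAssignment(query_id, best_sp, best_pct, margin, "AMBIGUOUS",
                            f"runner-up within tie epsilon {tie_epsilon}%")
    return NNAssignment(query_id, best_sp, best_pct, margin, "ASSIGNED")


def identify_queries(
    queries: AlignedSeqSet, reference: AlignedSeqSet, **kwargs
) -> list[NNAssignment]:
    return [
        identify_query(seq, reference, query_id=sp.id, **kwargs)
        for sp, seq in zip(queries.specimens, queries.sequences)
    ]
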