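"""Aligned sequence sets with specimen metadata.

The universal input of the pipeline: a pre-computed multiple alignment of
mitochondrial sequences (COI or control region) in FASTA, paired with a TSV
of specimen metadata.  Alignment itself is out of scope — sequences arrive
aligned and equal-length.  IUPAC ambiguity codes are retained on read but all
downstream site comparisons treat anything outside {A,C,G,T} as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

UNDETERMINED = "UNDETERMINED"

#: nucleotide encoding used everywhere downstream: A=0 C=1 G=2 T=3, missing=255.
#: transitions are A<->G and C<->T, i.e. codes of equal parity.
MISSING = np.uint8(255)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_VALID_CHARS = set("ACGTUNRYSWKMBDHV-.?")


class AlignmentError(ValueError):
    """Raised on ragged alignments, id mismatches or invalid characters."""


@dataclass(frozen=True)
class Specimen:
    id: str
    species: str = UNDETERMINED
    taxon_hint: str = ""
    locus: str = ""  # COI | MCR (free-form accepted)
    date: str = ""
    place: str = ""


@dataclass
class AlignedSeqSet:
    """Equal-length nucleotide sequences with per-specimen metadata."""

    specimens: list[Specimen]
    sequences: list[str]
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.specimens) != len(self.sequences):
            raise AlignmentError("one sequence per specimen required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            bad = {
                sp.id: len(seq)
                for sp, seq in zip(self.specimens, self.sequences)
                if len(seq) != len(self.sequences[0])
            }
            raise AlignmentError(f"ragged alignment; offending records: {bad}")
        if self.sequences and len(self.sequences[0]) == 0:
            raise AlignmentError("alignment length must be > 0")
        ids = [sp.id for sp in self.specimens]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate specimen ids: {dupes}")

    @property
    def ids(self) -> list[str]:
        return [sp.id for sp in self.specimens]

    @property
    def species(self) -> list[str]:
        return [sp.species for sp in self.specimens]

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.specimens)

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix; anything outside A/C/G/T encodes as missing."""
        if self._encoded is None:
            n, L = len(self.sequences), self.alignment_length
            mat = np.full((n, L), MISSING, dtype=np.uint8)
            lut = np.full(256, MISSING, dtype=np.uint8)
            for base, code in _CODE.items():
                lut[ord(base)] = code
            for i, seq in enumerate(self.sequences):
                mat[i] = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            self._encoded = mat
        return self._encoded

    def subset(self, ids: list[str]) -> "AlignedSeqSet":
        index = {sp.id: k for k, sp in enumerate(self.specimens)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise AlignmentError(f"unknown specimen ids: {missing}")
        ks = [index[i] for i in ids]
        return AlignedSeqSet(
            [self.specimens[k] for k in ks], [self.sequences[k] for k in ks]
        )

    def trim(self, start: int, end: int) -> "AlignedSeqSet":
        """Restrict to alignment columns ``start``..``end`` (1-based, inclusive)."""
        if not (1 <= start <= end <= self.alignment_length):
            raise AlignmentError(
                f"trim bounds {start}..{end} outside 1..{self.alignment_length}"
            )
        return AlignedSeqSet(
            list(self.specimens), [s[start - 1 : end] for s in self.sequences]
        )

    def concat(self, other: "AlignedSeqSet") -> "AlignedSeqSet":
        if other.alignment_length != self.alignment_length:
            raise AlignmentError("cannot concatenate sets of different lengths")
        return AlignedSeqSet(
            list(self.specimens) + list(other.specimens),
            list(self.sequences) + list(other.sequences),
        )


def _normalize(seq: str, rec_id: str) -> str:
    s = seq.upper().replace("U", "T").replace(".", "-").replace("?", "N")
    bad = set(s) - _VALID_CHARS - set("ACGT")
    if bad:
        raise AlignmentError(f"record {rec_id}: invalid characters {sorted(bad)}")
    return s


def read_metadata(path: str | Path) -> dict[str, Specimen]:
    """Read specimen metadata TSV (header ``id<TAB>species<TAB>taxon_hint<TAB>locus<TAB>date<TAB>place``)."""
    import csv

    out: dict[str, Specimen] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sp = Specimen(
                id=row["id"].strip(),
                species=(row.get("species") or UNDETERMINED).strip() or UNDETERMINED,
                taxon_hint=(row.get("taxon_hint") or "").strip(),
                locus=(row.get("locus") or "").strip(),
                date=(row.get("date") or "").strip(),
                place=(row.get("place") or "").strip(),
            )
            if sp.id in out:
                raise AlignmentError(f"duplicate id in metadata: {sp.id}")
            out[sp.id] = sp
    return out


def read_alignment(fasta_path: str | Path, metadata_path: str | Path | None = None) -> AlignedSeqSet:
    """Read an aligned FASTA (+ optional metadata TSV) into an AlignedSeqSet.

    FASTA ids must match metadata ids exactly; the error on mismatch lists the
    symmetric difference.  Sequences are uppercased; U->T, '.'->'-', '?'->'N'.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    seqs = [_normalize(str(r.seq), r.id) for r in records]
    ids = [r.id for r in records]
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        only_fasta = sorted(set(ids) - set(meta))
        only_meta = sorted(set(meta) - set(ids))
        if only_fasta or only_meta:
            raise AlignmentError(
                f"id mismatch between FASTA and metadata; "
                f"FASTA-only: {only_fasta}, metadata-only: {only_meta}"
            )
        specimens = [meta[i] for i in ids]
    else:
        specimens = [Specimen(id=i) for i in ids]
    return AlignedSeqSet(specimens, seqs)


def write_alignment(
    s: AlignedSeqSet, fasta_path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write FASTA (70-column wrapped) and, optionally, the metadata TSV."""
    recs = [
        SeqRecord(Seq(seq), id=sp.id, description="")
        for sp, seq in zip(s.specimens, s.sequences)
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(recs)
    if metadata_path is not None:
        with open(metadata_path, "w") as fh:
            fh.write("id\tspecies\ttaxon_hint\tlocus\tdate\tplace\n")
            for sp in s.specimens:
                fh.write(
                    f"{sp.id}\t{sp.species}\t{sp.taxon_hint}\t{sp.locus}\t{sp.date}\t{sp.place}\n"
                )


@dataclass
class Rejection:
    id: str
    reason: str
    called_bp: int
    ambiguous_frac: float


def quality_filter(
    s: AlignedSeqSet,
    min_unambiguous_bp: int = 500,
    max_ambiguity_frac: float = 0.02,
) -> tuple[AlignedSeqSet, list[Rejection]]:
    """Drop sequences that fail the quality gates.

    A sequence is kept when it has at least ``min_unambiguous_bp`` positions
    that are plain A/C/G/T and the fraction of its non-gap positions that are
    N or another IUPAC ambiguity code is at most ``max_ambiguity_frac``.
    An empty survivor set is legal; callers should check the report.
    Idempotent: survivors always pass the same gates again.
    """
    mat = s.encoded()
    called = (mat != MISSING).sum(axis=1)
    gaps = np.array([seq.count("-") for seq in s.sequences])
    non_gap = np.array([len(seq) for seq in s.sequences]) - gaps
    ambig = non_gap - called
    keep_idx: list[int] = []
    rejections: list[Rejection] = []
    for k, sp in enumerate(s.specimens):
        frac = float(ambig[k] / non_gap[k]) if non_gap[k] else 1.0
        if called[k] < min_unambiguous_bp:
            rejections.append(
                Rejection(sp.id, f"only {called[k]} unambiguous bp "
                          f"(< {min_unambiguous_bp})", int(called[k]), frac)
            )
        elif frac > max_ambiguity_frac:
            rejections.append(
                Rejection(sp.id, f"ambiguity fraction {frac:.3f} "
                          f"(> {max_ambiguity_frac})", int(called[k]), frac)
            )
        else:
            keep_idx.append(k)
    kept = AlignedSeqSet(
        [s.specimens[k] for k in keep_idx], [s.sequences[k] for k in keep_idx]
    ) if keep_idx else AlignedSeqSet([], [])
    return kept, rejections


def mark_undetermined(sp: Specimen) -> Specimen:
    return replace(sp, species=UNDETERMINED)
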