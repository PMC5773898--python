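"""Sequence I/O, PAM matching and strand/coordinate primitives.

All coordinates in this package are 0-based, half-open, and reported on the
plus strand; a minus-strand feature is described by the plus-strand interval
it occupies plus a strand flag.  Sequences are normalized to upper-case
A/C/G/T/N (any other letter becomes N).  A PAM pattern's ``N`` matches any
concrete base but never an ``N`` in the genome, because a genomic N is an
unknown base, not a wildcard.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "PamPolicy",
    "PROTOSPACER_LEN",
    "PAM_LEN",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "matches_pam",
    "find_pam_adjacent_sites",
    "write_bed6",
    "seq_to_codes",
    "codes_to_seq",
]

PROTOSPACER_LEN = 20
PAM_LEN = 3

# base codes: A=0 C=1 G=2 T=3, N (and anything else) = 4
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE_TABLE[_b] = _i

_BASES = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# complement in code space: A<->T, C<->G, N->N
_COMP_CODES = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_NORMALIZE = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in map(chr, range(65, 91))}
)


def _normalize_seq(seq: str) -> str:
    return str(seq).upper().translate(_NORMALIZE)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_BASE_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence normalized to the A/C/G/T/N alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = _normalize_seq(self.seq)
        self._codes: np.ndarray | None = None
        self._rc_codes: np.ndarray | None = None
        self._rc_seq: str | None = None

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        """uint8 code array, cached."""
        if self._codes is None:
            self._codes = seq_to_codes(self.seq)
        return self._codes

    @property
    def rc_codes(self) -> np.ndarray:
        """Code array of the reverse complement, cached."""
        if self._rc_codes is None:
            self._rc_codes = _COMP_CODES[self.codes[::-1]]
        return self._rc_codes

    @property
    def rc_seq(self) -> str:
        """Reverse-complement sequence string, cached."""
        if self._rc_seq is None:
            self._rc_seq = codes_to_seq(self.rc_codes)
        return self._rc_seq

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(id=self.id, seq=reverse_complement(self.seq))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; an involution."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"disallowed characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PamPolicy:
    """Primary and secondary PAM patterns (3 symbols over A/C/G/T/N).

    Defaults are the SpCas9 motifs: NGG primary; NAG, NCG, NGA secondary.
    Secondary PAMs are weaker but must be considered for off-target search;
    ``use_secondary`` switches them off for design-style scans.
    """

    primary: frozenset = frozenset({"NGG"})
    secondary: frozenset = frozenset({"NAG", "NCG", "NGA"})
    use_secondary: bool = True

    def __post_init__(self) -> None:
        self.primary = frozenset(self.primary)
        self.secondary = frozenset(self.secondary)
        for pat in self.primary | self.secondary:
            if len(pat) != PAM_LEN or set(pat) - set("ACGTN"):
                raise ValueError(f"invalid PAM pattern: {pat!r}")
        if self.primary & self.secondary:
            raise ValueError("primary and secondary PAM sets must be disjoint")

    def active_patterns(self) -> frozenset:
        pats = self.primary
        if self.use_secondary:
            pats = pats | self.secondary
        return pats


def _pattern_matches(triplet: str, pattern: str) -> bool:
    # pattern N matches any concrete base; genomic N matches nothing
    return all(t in "ACGT" and (p == "N" or p == t) for t, p in zip(triplet, pattern))


def matches_pam(triplet: str, policy: PamPolicy) -> str:
    """Classify a 3-base triplet as ``"primary"``, ``"secondary"`` or ``"none"``."""
    if len(triplet) != PAM_LEN:
        raise ValueError(f"PAM triplet must have length 3, got {triplet!r}")
    if any(_pattern_matches(triplet, p) for p in policy.primary):
        return "primary"
    if policy.use_secondary and any(
        _pattern_matches(triplet, p) for p in policy.secondary
    ):
        return "secondary"
    return "none"


def read_fasta(path: str) -> List[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = [SequenceRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str) -> None:
    """Write records as FASTA, wrapped to 60 columns."""
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def _classify_triplet_starts(codes: np.ndarray, policy: PamPolicy) -> np.ndarray:
    """Vectorized PAM class (0 none / 1 primary / 2 secondary) per triplet start."""
    n = len(codes) - PAM_LEN + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint8)
    cols = [codes[i : i + n] for i in range(PAM_LEN)]

    def any_match(patterns: Iterable[str]) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        for pat in patterns:
            m = np.ones(n, dtype=bool)
            for col, pc in zip(cols, pat):
                if pc == "N":
                    m &= col < 4
                else:
                    m &= col == _CODE_TABLE[ord(pc)]
            out |= m
        return out

    cls = np.zeros(n, dtype=np.uint8)
    if policy.use_secondary:
        cls[any_match(policy.secondary)] = 2
    cls[any_match(policy.primary)] = 1
    return cls


def _strand_site_arrays(codes: np.ndarray, policy: PamPolicy) -> Tuple[np.ndarray, np.ndarray]:
    """PAM-anchored site starts on one strand, in that strand's own coordinates.

    Returns (pam_start, pam_class) arrays for positions where the triplet at
    ``pam_start`` matches a PAM, a full 20-base protospacer fits upstream, and
    the 23-base protospacer+PAM window is free of N.
    """
    cls = _classify_triplet_starts(codes, policy)
    if cls.size == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.uint8)
    starts = np.nonzero(cls)[0]
    starts = starts[starts >= PROTOSPACER_LEN]
    if starts.size:
        # reject windows containing N via a prefix sum of the N indicator
        n_cum = np.concatenate(([0], np.cumsum(codes == 4)))
        window_n = n_cum[starts + PAM_LEN] - n_cum[starts - PROTOSPACER_LEN]
        starts = starts[window_n == 0]
    return starts.astype(np.int64), cls[starts]


def find_pam_adjacent_sites(
    record: SequenceRecord, policy: PamPolicy
) -> List[Tuple[int, str, str]]:
    """All PAM-anchored protospacer sites on both strands of ``record``.

    Each site is reported as ``(pam_start, strand, pam_class)`` where
    ``pam_start`` is the plus-strand 0-based start of the 3-base PAM triplet
    read on the site's own strand.  A site requires the full 20-base
    protospacer window upstream of the PAM (on the site's strand) and no N
    anywhere in the 23-base window.
    """
    L = record.length
    out: List[Tuple[int, str, str]] = []
    names = {1: "primary", 2: "secondary"}
    fwd_starts, fwd_cls = _strand_site_arrays(record.codes, policy)
    for p, c in zip(fwd_starts, fwd_cls):
        out.append((int(p), "+", names[int(c)]))
    rc_starts, rc_cls = _strand_site_arrays(record.rc_codes, policy)
    for t, c in zip(rc_starts, rc_cls):
        # rc coordinate t <-> plus-strand start of the PAM triplet L - t - 3
        out.append((int(L - t - PAM_LEN), "-", names[int(c)]))
    out.sort(key=lambda s: (s[0], s[1]))
    return out


def write_bed6(
    intervals: Sequence[Tuple[str, int, int, str, int, str]], path: str
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
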