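"""PAM-restricted, base-4-encoded 12-mer seed index.

Every protospacer site keeps its 12 PAM-proximal bases (the seed, the zone
least tolerant of mismatches).  Each seed 12-mer is encoded as an integer in
base 4 (A=0, C=1, G=2, T=3, digit i weighted 4**i with i=0 at the 5'-most
base of the 12-mer read on the protospacer's own strand), and the index maps
that key to the signed genomic positions of every PAM-adjacent occurrence.
The sign carries the strand: positive for the sense strand, negative for the
antisense strand.  Offsets are stored with a +1 bias so position 0 keeps a
well-defined sign.

Records are concatenated into a global coordinate space and grouped into
chunks of bounded size, so genomes far larger than one machine word of
addressable bases are representable; the magnitude of a stored position is
``record_global_offset + local_offset + 1``.

Internally the index is a pair of parallel arrays (keys, signed positions)
sorted by key; lookups are binary searches.  The index stores sites, not
sequences — the 12-mer is re-read from the genome when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .genome_io import (
    PAM_LEN,
    PROTOSPACER_LEN,
    PamPolicy,
    SequenceRecord,
    _strand_site_arrays,
    seq_to_codes,
)

__all__ = [
    "SEED_LEN",
    "NUM_KEYS",
    "encode_kmer",
    "decode_kmer",
    "GenomeLayout",
    "SeedIndex",
    "build_index",
]

SEED_LEN = 12
NUM_KEYS = 4**SEED_LEN  # 16,777,216

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

DEFAULT_CHUNK_SIZE = 1_500_000_000  # bases per chunk; two chunks cover a human genome


def encode_kmer(seq: str) -> int:
    """Base-4 encode a 12-mer: sum of code(seq[i]) * 4**i, i=0 at the 5' end."""
    if len(seq) != SEED_LEN:
        raise ValueError(f"seed k-mer must have length {SEED_LEN}, got {len(seq)}")
    value = 0
    try:
        for i, base in enumerate(seq):
            value += _CODE[base] << (2 * i)
    except KeyError:
        raise ValueError(f"seed k-mer contains a non-ACGT base: {seq!r}") from None
    return value


def decode_kmer(key: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    if not 0 <= key < NUM_KEYS:
        raise ValueError(f"seed key out of range [0, 4^12): {key}")
    return "".join(_BASES[(key >> (2 * i)) & 3] for i in range(SEED_LEN))


def _encode_kmer_windows(codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Vectorized base-4 keys of the 12-mers beginning at ``starts``."""
    keys = np.zeros(len(starts), dtype=np.uint32)
    for i in range(SEED_LEN):
        keys |= codes[starts + i].astype(np.uint32) << np.uint32(2 * i)
    return keys


@dataclass
class GenomeLayout:
    """Record order, lengths, global offsets and chunk assignment."""

    record_ids: List[str]
    lengths: np.ndarray  # int64 per record
    offsets: np.ndarray  # int64 global start per record
    chunk_map: Dict[str, int]

    @classmethod
    def from_records(
        cls, records: Sequence[SequenceRecord], chunk_size: int = DEFAULT_CHUNK_SIZE
    ) -> "GenomeLayout":
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in genome")
        lengths = np.array([r.length for r in records], dtype=np.int64)
        offsets = np.concatenate(([0], np.cumsum(lengths)))[:-1].astype(np.int64)
        chunk_map: Dict[str, int] = {}
        chunk, filled = 0, 0
        for rid, ln in zip(ids, lengths):
            if filled and filled + ln > chunk_size:
                chunk, filled = chunk + 1, 0
            chunk_map[rid] = chunk
            filled += int(ln)
        return cls(ids, lengths, offsets, chunk_map)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def encode_position(self, record_id: str, offset: int, strand: str) -> int:
        """Signed global position; +1 bias keeps offset 0 representable."""
        i = self.record_ids.index(record_id)
        if not 0 <= offset < self.lengths[i]:
            raise ValueError(f"offset {offset} outside record {record_id}")
        value = int(self.offsets[i]) + offset + 1
        if strand == "+":
            return value
        if strand == "-":
            return -value
        raise ValueError(f"invalid strand {strand!r}")

    def resolve_position(self, pos: int) -> Tuple[str, int, str]:
        """Invert :meth:`encode_position`: -> (record id, 0-based offset, strand)."""
        if pos == 0:
            raise ValueError("0 is not a valid signed position")
        strand = "+" if pos > 0 else "-"
        g = abs(pos) - 1
        if g >= self.total_length:
            raise ValueError(f"position {pos} beyond genome end")
        i = int(np.searchsorted(self.offsets, g, side="right")) - 1
        return self.record_ids[i], int(g - self.offsets[i]), strand


@dataclass
class SeedIndex:
    """Sorted-array map from seed keys to signed PAM-adjacent positions."""

    keys: np.ndarray  # uint32, sorted
    positions: np.ndarray  # int64, parallel to keys
    pam_policy: PamPolicy
    layout: GenomeLayout
    genome_ref: str = ""

    @property
    def n_sites(self) -> int:
        return len(self.keys)

    @property
    def chunk_map(self) -> Dict[str, int]:
        return self.layout.chunk_map

    def lookup(self, key: int) -> np.ndarray:
        """Signed positions stored under ``key`` (empty array if absent)."""
        if not 0 <= key < NUM_KEYS:
            raise ValueError(f"seed key out of range: {key}")
        lo = np.searchsorted(self.keys, key, side="left")
        hi = np.searchsorted(self.keys, key, side="right")
        return self.positions[lo:hi]

    def lookup_many(self, keys: np.ndarray) -> np.ndarray:
        """Concatenated positions for a batch of keys."""
        keys = np.asarray(keys, dtype=np.uint32)
        lo = np.searchsorted(self.keys, keys, side="left")
        hi = np.searchsorted(self.keys, keys, side="right")
        chunks = [self.positions[a:b] for a, b in zip(lo, hi) if b > a]
        if not chunks:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(chunks)

    def resolve_position(self, pos: int) -> Tuple[str, int, str]:
        return self.layout.resolve_position(pos)

    def save(self, path: str) -> None:
        """Versioned binary serialization (numpy .npz container)."""
        np.savez_compressed(
            path,
            magic=np.frombuffer(b"OFFSCAN1", dtype=np.uint8),
            k=np.int64(SEED_LEN),
            keys=self.keys,
            positions=self.positions,
            record_ids=np.array(self.layout.record_ids, dtype=object),
            lengths=self.layout.lengths,
            pam_primary=np.array(sorted(self.pam_policy.primary), dtype=object),
            pam_secondary=np.array(sorted(self.pam_policy.secondary), dtype=object),
            use_secondary=np.bool_(self.pam_policy.use_secondary),
            genome_ref=np.array([self.genome_ref], dtype=object),
        )

    @classmethod
    def load(cls, path: str) -> "SeedIndex":
        with np.load(path, allow_pickle=True) as z:
            if bytes(z["magic"].tobytes()) != b"OFFSCAN1" or int(z["k"]) != SEED_LEN:
                raise ValueError(f"not an offscan seed index: {path}")
            policy = PamPolicy(
                primary=frozenset(z["pam_primary"].tolist()),
                secondary=frozenset(z["pam_secondary"].tolist()),
                use_secondary=bool(z["use_secondary"]),
            )
            ids = z["record_ids"].tolist()
            lengths = z["lengths"].astype(np.int64)
            chunk_map: Dict[str, int] = {}
            chunk, filled = 0, 0
            for rid, ln in zip(ids, lengths):
                if filled and filled + int(ln) > DEFAULT_CHUNK_SIZE:
                    chunk, filled = chunk + 1, 0
                chunk_map[rid] = chunk
                filled += int(ln)
            layout = GenomeLayout(
                record_ids=ids,
                lengths=lengths,
                offsets=np.concatenate(([0], np.cumsum(lengths)))[:-1].astype(np.int64),
                chunk_map=chunk_map,
            )
            return cls(
                keys=z["keys"],
                positions=z["positions"],
                pam_policy=policy,
                layout=layout,
                genome_ref=str(z["genome_ref"][0]),
            )


def build_index(
    records: Sequence[SequenceRecord],
    policy: PamPolicy | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    genome_ref: str = "",
) -> SeedIndex:
    """Index the PAM-proximal seed 12-mer of every PAM-adjacent site.

    For each site found by the PAM scan (both strands, full 20-base window,
    no N), the 12 bases immediately 5' of the PAM — read 5'->3' on the
    protospacer's own strand — are base-4 encoded and the site's signed
    position appended under that key.  The stored magnitude addresses the
    leftmost plus-strand coordinate of the 12-mer, with the +1 bias.
    """
    policy = policy or PamPolicy()
    layout = GenomeLayout.from_records(records, chunk_size=chunk_size)
    all_keys: List[np.ndarray] = []
    all_pos: List[np.ndarray] = []
    for rec in records:
        L = rec.length
        base = int(layout.offsets[layout.record_ids.index(rec.id)])
        fwd_starts, _ = _strand_site_arrays(rec.codes, policy)
        if fwd_starts.size:
            # plus strand: PAM at p, 12-mer occupies [p-12, p)
            q = fwd_starts - SEED_LEN
            all_keys.append(_encode_kmer_windows(rec.codes, q))
            all_pos.append(base + q + 1)
        rc_starts, _ = _strand_site_arrays(rec.rc_codes, policy)
        if rc_starts.size:
            # minus strand: PAM at rc coordinate t; 12-mer = rc[t-12, t),
            # leftmost plus coordinate of that interval is L - t
            all_keys.append(_encode_kmer_windows(rec.rc_codes, rc_starts - SEED_LEN))
            all_pos.append(-(base + (L - rc_starts) + 1))
    if all_keys:
        keys = np.concatenate(all_keys).astype(np.uint32)
        positions = np.concatenate(all_pos).astype(np.int64)
        order = np.lexsort((positions, keys))
        keys, positions = keys[order], positions[order]
    else:
        keys = np.zeros(0, dtype=np.uint32)
        positions = np.zeros(0, dtype=np.int64)
    return SeedIndex(
        keys=keys, positions=positions, pam_policy=policy, layout=layout,
        genome_ref=genome_ref,
    )
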