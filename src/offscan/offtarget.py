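"""Off-target homology search: seed variants, DP calling, paired screening.

The search proceeds in two stages.  First, every 12-mer that could appear
PAM-adjacent at a homologous locus is generated from the guide's seed
(Hamming distance <= 2, or one indel against the seed) and looked up in the
:class:`~offscan.seed_index.SeedIndex`; this retrieval never loses a locus
that the full scoring would accept under the default policy.  Second, each
retrieved locus is expanded to PAM-anchored DNA windows of 18-22 bases and
scored by the five-layer dynamic program (H, L1, R1, L2, R2); the first
qualifying layer wins.

Scoring is in mismatch-equivalents: a bulge costs ``bulge_penalty`` (3 by
default, 2 when the bulge lies in the seed), a second RNA-bulge base adds
``rna_bulge_ext_penalty`` (1), a second DNA-bulge base adds
``dna_bulge_ext_penalty`` (2), and a locus qualifies when mismatches plus
penalties stay within ``max_mismatches`` (4) and the seed zone carries at
most ``seed_max_mismatches`` (2) mismatches — or, if the bulge itself sits
in the seed, no seed mismatch at all.  Under these defaults a 2-base DNA
bulge (3+2=5) can never qualify and a 2-base RNA bulge (3+1=4) qualifies
only with zero mismatches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import yaml

from . import _kernels
from .genome_io import (
    PAM_LEN,
    PROTOSPACER_LEN,
    PamPolicy,
    SequenceRecord,
    _strand_site_arrays,
    codes_to_seq,
    matches_pam,
    seq_to_codes,
)
from .seed_index import SEED_LEN, SeedIndex, encode_kmer

__all__ = [
    "HomologyPolicy",
    "HomologyCall",
    "HomologyHit",
    "generate_seed_variants",
    "dp_homology",
    "search_offtargets",
    "brute_force_scan",
    "paired_offtarget_scan",
    "hits_to_tsv",
]

CLASS_NAMES = ("H", "L1", "R1", "L2", "R2")
# (bulge kind, bulge length, DNA window length) per class, 20-base guide
CLASS_INFO = {
    "H": ("none", 0, 20),
    "L1": ("dna", 1, 21),
    "R1": ("rna", 1, 19),
    "L2": ("dna", 2, 22),
    "R2": ("rna", 2, 18),
}

_BASES = "ACGT"


@dataclass
class HomologyPolicy:
    """Thresholds and penalties defining what counts as an off-target homology.

    Defaults implement the standard SpCas9 working assumptions: at most four
    mismatch-equivalents in total, at most two mismatches or one indel inside
    the 12-base seed, at most one bulge (penalty 3, or 2 in the seed), no
    2-base DNA bulge, a 2-base RNA bulge only with zero mismatches, and no
    2-base bulge inside the seed.
    """

    max_mismatches: int = 4
    seed_len: int = 12
    seed_max_mismatches: int = 2
    bulge_penalty: int = 3
    seed_bulge_penalty: int = 2
    rna_bulge_ext_penalty: int = 1
    dna_bulge_ext_penalty: int = 2
    allow_two_base_bulge_in_seed: bool = False
    seed_indel_excludes_seed_mismatch: bool = True
    pam_policy: PamPolicy = field(default_factory=PamPolicy)

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not 0 < self.seed_len <= PROTOSPACER_LEN:
            raise ValueError("seed_len must be in (0, 20]")
        for name in ("bulge_penalty", "seed_bulge_penalty",
                     "rna_bulge_ext_penalty", "dna_bulge_ext_penalty"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def seed_start(self) -> int:
        """First 0-based guide index inside the seed (guide read 5'->3')."""
        return PROTOSPACER_LEN - self.seed_len

    def _kernel_args(self, shortcut: bool = True) -> tuple:
        return (
            self.seed_start,
            self.max_mismatches,
            self.seed_max_mismatches,
            self.bulge_penalty,
            self.seed_bulge_penalty,
            self.rna_bulge_ext_penalty,
            self.dna_bulge_ext_penalty,
            self.allow_two_base_bulge_in_seed,
            self.seed_indel_excludes_seed_mismatch,
            shortcut,
        )

    def to_yaml(self, path: str) -> None:
        data = {
            "max_mismatches": self.max_mismatches,
            "seed_len": self.seed_len,
            "seed_max_mismatches": self.seed_max_mismatches,
            "bulge_penalty": self.bulge_penalty,
            "seed_bulge_penalty": self.seed_bulge_penalty,
            "rna_bulge_ext_penalty": self.rna_bulge_ext_penalty,
            "dna_bulge_ext_penalty": self.dna_bulge_ext_penalty,
            "allow_two_base_bulge_in_seed": self.allow_two_base_bulge_in_seed,
            "seed_indel_excludes_seed_mismatch": self.seed_indel_excludes_seed_mismatch,
            "pam": {
                "primary": sorted(self.pam_policy.primary),
                "secondary": sorted(self.pam_policy.secondary),
                "use_secondary": self.pam_policy.use_secondary,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "HomologyPolicy":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        pam = data.pop("pam", None)
        kwargs = dict(data)
        if pam is not None:
            kwargs["pam_policy"] = PamPolicy(
                primary=frozenset(pam.get("primary", {"NGG"})),
                secondary=frozenset(pam.get("secondary", {"NAG", "NCG", "NGA"})),
                use_secondary=bool(pam.get("use_secondary", True)),
            )
        return cls(**kwargs)


@dataclass(frozen=True)
class HomologyCall:
    """Outcome of scoring one candidate DNA window against a guide."""

    is_homology: bool
    alignment_class: str  # H, L1, R1, L2, R2
    mismatches: int
    seed_mismatches: int
    bulge_kind: str  # none, dna, rna
    bulge_len: int
    bulge_in_seed: bool
    weighted_score: int
    bulge_pos: int = -1  # leftmost gap placement index within the window


@dataclass(frozen=True)
class HomologyHit:
    """One off-target homology call at a genomic locus."""

    guide_id: str
    record_id: str
    start: int
    end: int
    strand: str
    pam: str
    pam_class: str  # primary / secondary
    dna: str  # aligned DNA window, 5'->3' on the hit strand
    call: HomologyCall

    @property
    def five_prime_end(self) -> int:
        """Plus-strand coordinate of the aligned window's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


def _call_from_row(row: Sequence[int]) -> HomologyCall:
    qualified, cls, mm, smm, bpos, inseed, pen = (int(x) for x in row[:7])
    name = CLASS_NAMES[cls]
    kind, blen, _ = CLASS_INFO[name]
    return HomologyCall(
        is_homology=bool(qualified),
        alignment_class=name,
        mismatches=mm,
        seed_mismatches=smm,
        bulge_kind=kind,
        bulge_len=blen,
        bulge_in_seed=bool(inseed),
        weighted_score=mm + pen,
        bulge_pos=bpos,
    )


def dp_homology(
    dna: str, rna: str, policy: HomologyPolicy | None = None, shortcut: bool = True
) -> HomologyCall:
    """Score one PAM-anchored DNA window (18-22 bases) against a 20-base guide.

    ``dna`` is the candidate window with its 3' end at the (already verified)
    PAM, ``rna`` the protospacer 5'->3'.  Layers whose window length exceeds
    ``len(dna)`` are skipped; the first qualifying layer in the order H, L1,
    R1, L2, R2 is returned.  ``shortcut=False`` disables the penalty-bound
    layer skip (the result is identical; the flag exists for validation).
    """
    policy = policy or HomologyPolicy()
    if len(rna) != PROTOSPACER_LEN or set(rna) - set(_BASES):
        raise ValueError("rna must be a 20-base ACGT protospacer")
    if not PROTOSPACER_LEN - 2 <= len(dna) <= PROTOSPACER_LEN + 2:
        raise ValueError("dna window must be 18-22 bases")
    if set(dna) - set(_BASES) - {"N"}:
        raise ValueError("dna window must be over ACGTN")
    row = _kernels.dp_call(
        seq_to_codes(dna), seq_to_codes(rna), *policy._kernel_args(shortcut)
    )
    return _call_from_row(row)


def generate_seed_variants(seed: str, policy: HomologyPolicy | None = None) -> Set[int]:
    """All seed-index keys a homologous locus could carry next to its PAM.

    The set contains (a) every 12-mer within Hamming distance
    ``seed_max_mismatches`` of the guide seed, (b) every 12-mer formed by
    deleting one seed base and prepending an arbitrary base at the PAM-distal
    end (the footprint of an RNA bulge inside the seed), and (c) every 12-mer
    formed by inserting one arbitrary base and dropping the PAM-distal base
    (DNA bulge inside the seed).  ``seed`` is read 5'->3', PAM-proximal base
    last.
    """
    policy = policy or HomologyPolicy()
    if len(seed) != SEED_LEN or set(seed) - set(_BASES):
        raise ValueError(f"seed must be a {SEED_LEN}-base ACGT string")
    variants: Set[str] = set()
    # (a) Hamming distance <= seed_max_mismatches
    max_d = min(policy.seed_max_mismatches, SEED_LEN)
    for ndiff in range(max_d + 1):
        for pos in itertools.combinations(range(SEED_LEN), ndiff):
            alts = [[b for b in _BASES if b != seed[p]] for p in pos]
            for combo in itertools.product(*alts):
                s = list(seed)
                for p, b in zip(pos, combo):
                    s[p] = b
                variants.add("".join(s))
    # (b) RNA bulge in seed: delete seed[j], prepend x at the PAM-distal end
    for j in range(SEED_LEN):
        core = seed[:j] + seed[j + 1:]
        for x in _BASES:
            variants.add(x + core)
    # (c) DNA bulge in seed: insert x before seed[j], drop the PAM-distal base
    for j in range(SEED_LEN + 1):
        for x in _BASES:
            variants.add((seed[:j] + x + seed[j:])[1:])
    return {encode_kmer(v) for v in variants}


def _assemble_hits(
    record: SequenceRecord,
    strand: str,
    anchors: np.ndarray,
    rows: np.ndarray,
    guide_id: str,
    policy: HomologyPolicy,
) -> List[HomologyHit]:
    """Turn qualifying DP rows at PAM anchors into HomologyHit objects."""
    hits: List[HomologyHit] = []
    L = record.length
    seq = record.seq if strand == "+" else None
    rc_seq = record.rc_seq if strand == "-" else None
    for a in range(len(anchors)):
        if not rows[a, 0]:
            continue
        p = int(anchors[a])  # PAM start, working-strand coordinates
        if strand == "+":
            pam = seq[p : p + PAM_LEN]
        else:
            pam = rc_seq[p : p + PAM_LEN]
        pam_class = matches_pam(pam, policy.pam_policy)
        if pam_class == "none":
            continue
        call = _call_from_row(rows[a])
        wlen = CLASS_INFO[call.alignment_class][2]
        if strand == "+":
            start, end = p - wlen, p
            window = seq[start:end]
        else:
            # working (rc) window [p-wlen, p) maps to plus interval [L-p, L-p+wlen)
            start, end = L - p, L - p + wlen
            window = rc_seq[p - wlen : p]
        hits.append(
            HomologyHit(
                guide_id=guide_id,
                record_id=record.id,
                start=start,
                end=end,
                strand=strand,
                pam=pam,
                pam_class=pam_class,
                dna=window,
                call=call,
            )
        )
    return hits


def _guide_attrs(guide) -> Tuple[str, str]:
    """(protospacer, id) from a GuideRNA or a plain sequence string."""
    if isinstance(guide, str):
        return guide, guide
    name = getattr(guide, "name", None) or getattr(guide, "protospacer")
    return guide.protospacer, name


def search_offtargets(
    guide,
    index: SeedIndex,
    records: Sequence[SequenceRecord],
    policy: HomologyPolicy | None = None,
    include_self: bool = True,
    shortcut: bool = True,
) -> List[HomologyHit]:
    """Find every off-target homology of ``guide`` in ``records``.

    ``guide`` may be a :class:`~offscan.design.GuideRNA` or a bare 20-base
    protospacer string.  Candidate loci are retrieved from the seed index via
    the guide's seed variants, deduplicated by locus, expanded to PAM-anchored
    windows and scored with the DP; qualifying loci are returned sorted by
    record and start.  ``include_self=False`` suppresses the guide's own
    locus (exact-coordinate match).
    """
    policy = policy or HomologyPolicy()
    protospacer, guide_id = _guide_attrs(guide)
    if len(protospacer) != PROTOSPACER_LEN or set(protospacer) - set(_BASES):
        raise ValueError("guide protospacer must be a 20-base ACGT string")
    seed = protospacer[-SEED_LEN:]
    keys = np.fromiter(generate_seed_variants(seed, policy), dtype=np.uint32)
    positions = np.unique(index.lookup_many(np.sort(keys)))
    rec_by_id: Dict[str, SequenceRecord] = {r.id: r for r in records}
    rna = seq_to_codes(protospacer)
    kargs = policy._kernel_args(shortcut)

    hits: List[HomologyHit] = []
    if positions.size:
        g = np.abs(positions) - 1
        rec_idx = np.searchsorted(index.layout.offsets, g, side="right") - 1
        local = g - index.layout.offsets[rec_idx]
        for ri in np.unique(rec_idx):
            rid = index.layout.record_ids[int(ri)]
            rec = rec_by_id.get(rid)
            if rec is None:
                raise ValueError(f"record {rid!r} in index but not provided")
            L = rec.length
            sel = rec_idx == ri
            q = local[sel]
            sign = positions[sel] > 0
            # plus strand: seed 12-mer at [q, q+12), PAM at q+12
            plus_anchors = (q[sign] + SEED_LEN).astype(np.int64)
            if plus_anchors.size:
                rows = _kernels.eval_anchors(rec.codes, plus_anchors, rna, *kargs)
                hits.extend(_assemble_hits(rec, "+", plus_anchors, rows, guide_id, policy))
            # minus strand: stored q = L - t (t = PAM start in rc coordinates)
            minus_anchors = (L - q[~sign]).astype(np.int64)
            if minus_anchors.size:
                rows = _kernels.eval_anchors(rec.rc_codes, minus_anchors, rna, *kargs)
                hits.extend(_assemble_hits(rec, "-", minus_anchors, rows, guide_id, policy))

    if not include_self and not isinstance(guide, str):
        hits = [
            h for h in hits
            if not (h.record_id == guide.source_id and h.start == guide.start
                    and h.end == guide.end and h.strand == guide.strand)
        ]
    order = {rid: i for i, rid in enumerate(index.layout.record_ids)}
    hits.sort(key=lambda h: (order[h.record_id], h.start, h.strand))
    return hits


def brute_force_scan(
    guide,
    records: Sequence[SequenceRecord],
    policy: HomologyPolicy | None = None,
    shortcut: bool = True,
) -> List[HomologyHit]:
    """Score every PAM-anchored window on both strands (no seed index).

    The exhaustive reference scan: identical scoring, but candidates come
    from a full PAM sweep instead of seed-variant retrieval.  Used to verify
    that retrieval loses no loci.
    """
    policy = policy or HomologyPolicy()
    protospacer, guide_id = _guide_attrs(guide)
    rna = seq_to_codes(protospacer)
    kargs = policy._kernel_args(shortcut)
    hits: List[HomologyHit] = []
    for rec in records:
        fwd_anchors, _ = _strand_site_arrays(rec.codes, policy.pam_policy)
        if fwd_anchors.size:
            rows = _kernels.eval_anchors(rec.codes, fwd_anchors, rna, *kargs)
            hits.extend(_assemble_hits(rec, "+", fwd_anchors, rows, guide_id, policy))
        rc_anchors, _ = _strand_site_arrays(rec.rc_codes, policy.pam_policy)
        if rc_anchors.size:
            rows = _kernels.eval_anchors(rec.rc_codes, rc_anchors, rna, *kargs)
            hits.extend(_assemble_hits(rec, "-", rc_anchors, rows, guide_id, policy))
    rec_order = {r.id: i for i, r in enumerate(records)}
    hits.sort(key=lambda h: (rec_order[h.record_id], h.start, h.strand))
    return hits


def paired_offtarget_scan(
    pair,
    hits_left: Sequence[HomologyHit],
    hits_right: Sequence[HomologyHit],
    min_offset: int = -34,
    max_offset: int = 110,
) -> List[Tuple[HomologyHit, HomologyHit]]:
    """Off-target site pairs that could support unintended paired nicking.

    Two single-guide hits form a candidate pair when they lie on the same
    record on opposite strands with an offset — the distance between the two
    aligned windows' 5' ends, signed so that head-to-head (PAM-out) overlaps
    are small and positive — inside ``[min_offset, max_offset]`` (default
    -34..110, outside which paired nicking loses efficacy).
    """
    out: List[Tuple[HomologyHit, HomologyHit]] = []
    by_record: Dict[str, List[HomologyHit]] = {}
    for h in hits_right:
        by_record.setdefault(h.record_id, []).append(h)
    for a in hits_left:
        for b in by_record.get(a.record_id, ()):
            if a.strand == b.strand:
                continue
            minus, plus = (a, b) if a.strand == "-" else (b, a)
            offset = minus.five_prime_end - plus.five_prime_end
            if min_offset <= offset <= max_offset:
                out.append((a, b))
    return out


def hits_to_bed6_rows(hits: Iterable[HomologyHit]) -> List[tuple]:
    return [
        (h.record_id, h.start, h.end,
         f"{h.guide_id}|{h.call.alignment_class}", 0, h.strand)
        for h in hits
    ]


def hits_to_tsv(hits: Iterable[HomologyHit], path: str) -> None:
    cols = (
        "guide\trecord\tstart\tend\tstrand\tclass\tmismatches\tseed_mismatches"
        "\tbulge_kind\tbulge_len\tbulge_in_seed\tweighted_score\tpam\tpam_class\tdna\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for h in hits:
            c = h.call
            fh.write(
                f"{h.guide_id}\t{h.record_id}\t{h.start}\t{h.end}\t{h.strand}"
                f"\t{c.alignment_class}\t{c.mismatches}\t{c.seed_mismatches}"
                f"\t{c.bulge_kind}\t{c.bulge_len}\t{int(c.bulge_in_seed)}"
                f"\t{c.weighted_score}\t{h.pam}\t{h.pam_class}\t{h.dna}\n"
            )
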