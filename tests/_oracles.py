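"""Independent reference implementations used only by the tests.

Everything here is deliberately written with plain string slicing and
explicit enumeration of every legal gap placement — no prefix sums, no
compiled kernels — so it exercises a different computational route from
the package's DP and batch scanners.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from offscan.genome_io import (
    PamPolicy,
    SequenceRecord,
    find_pam_adjacent_sites,
    reverse_complement,
)
from offscan.offtarget import HomologyPolicy

GUIDE_LEN = 20
CLASS_ORDER = ("H", "L1", "R1", "L2", "R2")


def _mis(d: str, r: str) -> bool:
    return d != r or d == "N"


def _alignments(dna: str, rna: str, cls: str, seed_start: int):
    """Yield (pairs, bulge_pos, bulge_in_seed) for every legal placement.

    ``pairs`` is a list of (dna_char, rna_char, rna_index) tuples for the
    aligned positions of one explicit gap placement.
    """
    n = len(rna)
    if cls == "H":
        if len(dna) < n:
            return
        w = dna[-n:]
        yield [(w[i], rna[i], i) for i in range(n)], -1, False
    elif cls in ("L1", "L2"):
        gap = 1 if cls == "L1" else 2
        if len(dna) < n + gap:
            return
        w = dna[-(n + gap):]
        for k in range(n + 1):  # skipped DNA bases w[k .. k+gap-1]
            pairs = [(w[j], rna[j], j) for j in range(k)]
            pairs += [(w[j], rna[j - gap], j - gap) for j in range(k + gap, n + gap)]
            yield pairs, k, k >= seed_start + 1
    else:  # R1 / R2: skipped guide bases rna[k .. k+gap-1]
        gap = 1 if cls == "R1" else 2
        if len(dna) < n - gap:
            return
        w = dna[-(n - gap):]
        for k in range(n - gap + 1):
            pairs = [(w[i], rna[i], i) for i in range(k)]
            pairs += [(w[i], rna[i + gap], i + gap) for i in range(k, n - gap)]
            yield pairs, k, (k + gap - 1) >= seed_start


def oracle_dp(dna: str, rna: str, policy: Optional[HomologyPolicy] = None) -> Dict:
    """Explicit gap-placement enumeration scorer, first-qualifying-class."""
    policy = policy or HomologyPolicy()
    seed_start = GUIDE_LEN - policy.seed_len
    ext = {"H": 0, "L1": policy.dna_bulge_ext_penalty, "L2": policy.dna_bulge_ext_penalty,
           "R1": policy.rna_bulge_ext_penalty, "R2": policy.rna_bulge_ext_penalty}
    fallback = None
    for cls in CLASS_ORDER:
        gap = {"H": 0, "L1": 1, "R1": 1, "L2": 2, "R2": 2}[cls]
        best = None
        for pairs, pos, in_seed in _alignments(dna, rna, cls, seed_start):
            mm = sum(1 for d, r, _ in pairs if _mis(d, r))
            smm = sum(1 for d, r, i in pairs if _mis(d, r) and i >= seed_start)
            if cls == "H":
                pen = 0
            else:
                pen = (policy.seed_bulge_penalty if in_seed else policy.bulge_penalty)
                pen += (gap - 1) * ext[cls]
            weighted = mm + pen
            if fallback is None:
                fallback = dict(is_homology=False, alignment_class=cls, mismatches=mm,
                                seed_mismatches=smm, bulge_pos=pos,
                                bulge_in_seed=in_seed, weighted_score=weighted)
            ok = True
            if cls == "H":
                ok = mm <= policy.max_mismatches and smm <= policy.seed_max_mismatches
            else:
                if gap == 2 and in_seed and not policy.allow_two_base_bulge_in_seed:
                    ok = False
                if weighted > policy.max_mismatches:
                    ok = False
                if smm > policy.seed_max_mismatches:
                    ok = False
                if (in_seed and policy.seed_indel_excludes_seed_mismatch and smm != 0):
                    ok = False
            if ok and (best is None or weighted < best["weighted_score"]):
                best = dict(is_homology=True, alignment_class=cls, mismatches=mm,
                            seed_mismatches=smm, bulge_pos=pos, bulge_in_seed=in_seed,
                            weighted_score=weighted)
        if best is not None:
            return best
    return fallback


def oracle_pam_sites(record: SequenceRecord, policy: PamPolicy) -> List[Tuple[int, str, str]]:
    """Per-position triplet scan of both strands, plain Python."""

    def match(trip: str, pats) -> bool:
        return any(
            all(t in "ACGT" and (p == "N" or p == t) for t, p in zip(trip, pat))
            for pat in pats
        )

    def classify(trip: str) -> str:
        if match(trip, policy.primary):
            return "primary"
        if policy.use_secondary and match(trip, policy.secondary):
            return "secondary"
        return "none"

    sites = []
    seq = record.seq
    L = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for t in range(GUIDE_LEN, L - 2):
            window = s[t - GUIDE_LEN : t + 3]
            if "N" in window:
                continue
            cls = classify(s[t : t + 3])
            if cls != "none":
                pos = t if strand == "+" else L - t - 3
                sites.append((pos, strand, cls))
    sites.sort(key=lambda x: (x[0], x[1]))
    return sites


def oracle_scan(
    guide_seq: str, records, policy: Optional[HomologyPolicy] = None
) -> set:
    """Fully independent whole-genome scan: every PAM-anchored window on both
    strands through the enumeration scorer.  Returns a set of hit signatures
    (record, strand, plus-strand PAM start, class, mismatches, seed mm)."""
    policy = policy or HomologyPolicy()
    out = set()
    for rec in records:
        L = len(rec.seq)
        rc = reverse_complement(rec.seq)
        for pos, strand, _cls in oracle_pam_sites(rec, policy.pam_policy):
            if strand == "+":
                anchor = pos
                ctx = rec.seq[max(0, anchor - 22) : anchor]
            else:
                anchor = L - pos - 3  # PAM start in rc coordinates
                ctx = rc[max(0, anchor - 22) : anchor]
            call = oracle_dp(ctx, guide_seq, policy)
            if call["is_homology"]:
                out.add((rec.id, strand, pos, call["alignment_class"],
                         call["mismatches"], call["seed_mismatches"]))
    return out


def hit_signature(h) -> tuple:
    """Signature of a package HomologyHit comparable with oracle_scan output."""
    pam_plus_start = h.end if h.strand == "+" else h.start - 3
    return (h.record_id, h.strand, pam_plus_start, h.call.alignment_class,
            h.call.mismatches, h.call.seed_mismatches)
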