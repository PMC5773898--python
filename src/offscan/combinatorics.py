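"""Closed-form model of off-target homology probability on a random genome.

Treating the genome as i.i.d. uniform A/C/G/T, the number of 20-base DNA
sequences homologous to a given guide is counted exactly: for every split of
the mismatch budget between the 12-base seed (at most 2 mismatches) and the
8-base non-seed region (total at most 4), the count of sequences with n
mismatches over m positions is C(m, n) * 3^n.  Single-bulge and 2-base
RNA-bulge terms are added from the model's position-count constants (see
:data:`BulgePositionCounts`).  Dividing by 4^20 gives the per-window
homology probability; multiplying by the PAM probability (the fraction of
the 64 triplets matching a primary or secondary PAM) gives the per-window
off-target probability; scaling by the number of 23-base windows in the
genome (six billion for a human-sized genome, both strands) gives the
expected number of off-target homologies per guide.

All counts are exact Python integers; ``p_no_offtarget`` is evaluated in
log space since it underflows intuition (order 1e-143) if not care is
taken, though it still fits in a float64.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Tuple

from .genome_io import PamPolicy, matches_pam

__all__ = [
    "CombinatoricsInput",
    "CombinatoricsReport",
    "BulgePositionCounts",
    "mismatch_combinations",
    "total_mismatch_combinations",
    "bulge_combinations",
    "pam_probability",
    "report",
    "format_report",
]


def mismatch_combinations(m: int, n: int) -> int:
    """C(m, n) * 3^n: DNA sequences of length m with exactly n mismatches."""
    if not 0 <= n <= m:
        raise ValueError(f"need 0 <= n <= m, got m={m}, n={n}")
    return math.comb(m, n) * 3**n


@dataclass(frozen=True)
class BulgePositionCounts:
    """Allowed bulge positions in the counting model.

    The model only credits a bulge when it can trade off at least five
    mismatches of the ungapped alignment, which requires the DNA fragment
    5' of the bulge to be at least four bases; that leaves 16 insertion
    positions for a 1-base DNA bulge (12 in the seed + 4 in the non-seed
    region), 15 deletion positions for a 1-base RNA bulge (11 + 4), and 2
    placements for a 2-base RNA bulge (non-seed only).  These counts are
    constants of the model's accounting — a device to avoid double counting
    against the pure-mismatch classes — not search-time rules.
    """

    dna_total: int = 16
    dna_seed: int = 12
    dna_non_seed: int = 4
    rna_total: int = 15
    rna_seed: int = 11
    rna_non_seed: int = 4
    rna_two_base: int = 2


@dataclass
class CombinatoricsInput:
    """Model parameters; defaults describe SpCas9 on a human-sized genome."""

    guide_len: int = 20
    seed_len: int = 12
    max_mm: int = 4
    seed_max_mm: int = 2
    genome_windows: int = 6_000_000_000  # 23-base windows, both strands
    pam_policy: PamPolicy = field(default_factory=PamPolicy)
    bulge_positions: BulgePositionCounts = field(default_factory=BulgePositionCounts)

    def __post_init__(self) -> None:
        if self.seed_len > self.guide_len:
            raise ValueError("seed_len must be <= guide_len")
        if self.seed_max_mm > self.max_mm:
            raise ValueError("seed_max_mm must be <= max_mm")


def total_mismatch_combinations(inp: CombinatoricsInput | None = None) -> int:
    """Exact count of pure-mismatch homologies within the budget.

    Sum over seed mismatches s <= seed_max_mm of C(seed, s) 3^s times the
    count of non-seed patterns with at most max_mm - s mismatches.
    """
    inp = inp or CombinatoricsInput()
    non_seed = inp.guide_len - inp.seed_len
    total = 0
    for s in range(min(inp.seed_max_mm, inp.seed_len) + 1):
        seed_ways = mismatch_combinations(inp.seed_len, s)
        rest = sum(
            mismatch_combinations(non_seed, t)
            for t in range(min(inp.max_mm - s, non_seed) + 1)
        )
        total += seed_ways * rest
    return total


def bulge_combinations(
    inp: CombinatoricsInput | None = None,
) -> Tuple[int, int, int, int, int]:
    """(dna_0mm, rna_0mm, dna_1mm, rna_1mm, rna_2b) homology counts.

    With zero mismatches every allowed bulge position times 4 inserted (or
    4 flanking, for deletions) bases counts once.  With one mismatch, a
    bulge in the seed confines the mismatch to the non-seed region (8
    positions); a non-seed bulge leaves the mismatch free over the aligned
    length (20 for a DNA bulge, 19 for an RNA bulge).
    """
    inp = inp or CombinatoricsInput()
    bp = inp.bulge_positions
    non_seed = inp.guide_len - inp.seed_len
    dna_0mm = bp.dna_total * 4
    rna_0mm = bp.rna_total * 4
    dna_1mm = (
        bp.dna_seed * 4 * mismatch_combinations(non_seed, 1)
        + bp.dna_non_seed * 4 * mismatch_combinations(inp.guide_len, 1)
    )
    rna_1mm = (
        bp.rna_seed * 4 * mismatch_combinations(non_seed, 1)
        + bp.rna_non_seed * 4 * mismatch_combinations(inp.guide_len - 1, 1)
    )
    rna_2b = bp.rna_two_base * 4 * 4
    return dna_0mm, rna_0mm, dna_1mm, rna_1mm, rna_2b


def pam_probability(policy: PamPolicy | None = None) -> float:
    """Fraction of the 64 concrete triplets matching any active PAM pattern."""
    policy = policy or PamPolicy()
    n = sum(
        1
        for trip in map("".join, product("ACGT", repeat=3))
        if matches_pam(trip, policy) != "none"
    )
    return n / 64


@dataclass(frozen=True)
class CombinatoricsReport:
    """All model quantities for one parameterization."""

    mismatch_total: int
    dna_bulge_0mm: int
    rna_bulge_0mm: int
    dna_bulge_1mm: int
    rna_bulge_1mm: int
    rna_bulge_2b: int
    total: int
    sequence_space: int  # 4^guide_len
    p_window: float
    p_pam: float
    p_offtarget: float
    genome_windows: int
    expected_hits: float
    p_no_offtarget: float
    log10_p_no_offtarget: float

    @property
    def expected_hits_rounded(self) -> int:
        return round(self.expected_hits)


def report(inp: CombinatoricsInput | None = None) -> CombinatoricsReport:
    inp = inp or CombinatoricsInput()
    mm_total = total_mismatch_combinations(inp)
    d0, r0, d1, r1, r2b = bulge_combinations(inp)
    total = mm_total + d0 + r0 + d1 + r1 + r2b
    space = 4**inp.guide_len
    p_window = total / space
    p_pam = pam_probability(inp.pam_policy)
    p_off = p_window * p_pam
    n = inp.genome_windows
    expected = n * p_off
    log_p_none = n * math.log1p(-p_off)
    return CombinatoricsReport(
        mismatch_total=mm_total,
        dna_bulge_0mm=d0,
        rna_bulge_0mm=r0,
        dna_bulge_1mm=d1,
        rna_bulge_1mm=r1,
        rna_bulge_2b=r2b,
        total=total,
        sequence_space=space,
        p_window=p_window,
        p_pam=p_pam,
        p_offtarget=p_off,
        genome_windows=n,
        expected_hits=expected,
        p_no_offtarget=math.exp(log_p_none),
        log10_p_no_offtarget=log_p_none / math.log(10),
    )


def format_report(rep: CombinatoricsReport) -> str:
    """Aligned-text rendering of the model's counting table."""
    rows = [
        ("Total combination of 20 bp", f"{rep.sequence_space:,}"),
        ("Total base mismatches", f"{rep.mismatch_total:,}"),
        ("DNA bulge with 0 base mismatch", f"{rep.dna_bulge_0mm:,}"),
        ("RNA bulge with 0 base mismatch", f"{rep.rna_bulge_0mm:,}"),
        ("DNA bulge with 1 base mismatch", f"{rep.dna_bulge_1mm:,}"),
        ("RNA bulge with 1 base mismatch", f"{rep.rna_bulge_1mm:,}"),
        ("RNA bulge of two bases", f"{rep.rna_bulge_2b:,}"),
        ("Total combinations of homologies", f"{rep.total:,}"),
        ("Homology probability of a 20-base sequence", f"{rep.p_window:.11f}"),
        ("Probability of potential PAM", f"{rep.p_pam:.4f}"),
        ("Off-target homology probability", f"{rep.p_offtarget:.11f}"),
        ("Genome windows (both strands)", f"{rep.genome_windows:,}"),
        ("Expected off-target homologies per guide", f"{rep.expected_hits:.2f}"),
        ("P(no off-target homology)", f"{rep.p_no_offtarget:.3g}"),
    ]
    width = max(len(k) for k, _ in rows)
    return "\n".join(f"{k:<{width}}  {v:>18}" for k, v in rows)
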