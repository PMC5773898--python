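"""Numba-compiled cores for homology calling.

The DP evaluates five alignment layers in a fixed order — H (ungapped),
L1 (1-base DNA bulge), R1 (1-base RNA bulge), L2 (2-base DNA bulge),
R2 (2-base RNA bulge) — and stops at the first layer that qualifies.
All alignments are anchored with their 3' end at the PAM.  Per-layer
placement mismatch counts are assembled from prefix/suffix mismatch sums
(one pass per layer); seed-zone mismatches are tracked separately.

Conventions (guide length n, seed = the s PAM-proximal guide bases,
0-based guide index i, seed iff i >= n - s):

* a mismatch at DNA position aligned to guide index i is a seed mismatch
  iff i >= n - s (an N in the DNA mismatches everything);
* a bulged (unaligned) DNA base whose gap lies between guide indices
  k-1 and k is in the seed iff k >= n - s + 1, which includes the gap
  between the seed and the PAM — this gives s in-seed DNA gap positions;
* a bulged guide base is in the seed iff its own index is >= n - s;
* ties between equal-score placements go to the leftmost (5'-most) gap.

Return layout of ``dp_call`` (8 int64s):
(qualified, cls, mismatches, seed_mismatches, bulge_pos, bulge_in_seed,
penalty, evaluated_any) with cls 0..4 = H, L1, R1, L2, R2 and
bulge_pos = -1 for H.  When nothing qualifies the first evaluable layer's
best-scoring placement is reported for diagnostics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# class ids
CLS_H, CLS_L1, CLS_R1, CLS_L2, CLS_R2 = 0, 1, 2, 3, 4

# aligned DNA window length per class for a 20-base guide: 20, 21, 19, 22, 18
CLS_DNA_EXTRA = (0, 1, -1, 2, -2)


@njit(cache=True)
def _layer_bulge(
    w, r, gap_len, is_dna, seed_start, max_mm, seed_max_mm,
    bulge_pen, seed_bulge_pen, ext_pen, allow2seed, indel_excl,
):
    """Best qualifying placement for one bulge layer.

    ``w`` is the 3'-anchored DNA window; for a DNA bulge len(w) = n + gap_len
    (placements skip DNA bases), for an RNA bulge len(w) = n - gap_len
    (placements skip guide bases).  Returns (qualified, mm, smm, pos,
    in_seed, pen, best_any, bmm, bsmm, bpos, binseed, bpen): the first six
    describe the best qualifying placement, the last six the best placement
    regardless of qualification (for diagnostics).
    """
    n = r.shape[0]
    if is_dna:
        n_place = w.shape[0] - 1 if gap_len == 1 else w.shape[0] - 2
        # prefix: w[j] vs r[j] for j < k
        plen = n_place + 1
    else:
        n_place = n - 1 if gap_len == 1 else n - 2
        plen = n_place + 1
    P = np.zeros(plen + 1, dtype=np.int64)
    Ps = np.zeros(plen + 1, dtype=np.int64)
    S = np.zeros(plen + 1, dtype=np.int64)
    Ss = np.zeros(plen + 1, dtype=np.int64)

    if is_dna:
        # prefix unshifted: w[j] aligned to r[j], j = 0..n_place-1
        for j in range(n_place):
            m = 1 if w[j] != r[j] else 0
            P[j + 1] = P[j] + m
            Ps[j + 1] = Ps[j] + (m if j >= seed_start else 0)
        # suffix shifted by gap_len: w[j] aligned to r[j-gap_len], j > k+gap_len-1
        for k in range(n_place - 1, -1, -1):
            j = k + gap_len
            m = 1 if w[j] != r[j - gap_len] else 0
            S[k] = S[k + 1] + m
            Ss[k] = Ss[k + 1] + (m if (j - gap_len) >= seed_start else 0)
    else:
        # skip guide bases r[j..j+gap_len-1]; w[i] vs r[i] for i < j
        for i in range(n_place):
            m = 1 if w[i] != r[i] else 0
            P[i + 1] = P[i] + m
            Ps[i + 1] = Ps[i] + (m if i >= seed_start else 0)
        # w[i] vs r[i+gap_len] for i >= j
        for j in range(n_place - 1, -1, -1):
            i = j
            m = 1 if w[i] != r[i + gap_len] else 0
            S[j] = S[j + 1] + m
            Ss[j] = Ss[j + 1] + (m if (i + gap_len) >= seed_start else 0)

    q_found = 0
    q_mm = q_smm = q_pos = q_inseed = q_pen = 0
    q_score = 1 << 30
    b_found = 0
    b_mm = b_smm = b_pos = b_inseed = b_pen = 0
    b_score = 1 << 30

    for k in range(n_place + 1):
        if is_dna:
            in_seed = 1 if k >= seed_start + 1 else 0
        else:
            # skipped guide bases are r[k..k+gap_len-1]
            in_seed = 1 if (k + gap_len - 1) >= seed_start else 0
        mm = P[k] + S[k]
        smm = Ps[k] + Ss[k]
        pen = (seed_bulge_pen if in_seed else bulge_pen) + (gap_len - 1) * ext_pen
        score = mm + pen
        if score < b_score:
            b_found, b_mm, b_smm, b_pos, b_inseed, b_pen, b_score = (
                1, mm, smm, k, in_seed, pen, score)
        if gap_len == 2 and in_seed and not allow2seed:
            continue
        if score > max_mm:
            continue
        if smm > seed_max_mm:
            continue
        if in_seed and indel_excl and smm != 0:
            continue
        if score < q_score:
            q_found, q_mm, q_smm, q_pos, q_inseed, q_pen, q_score = (
                1, mm, smm, k, in_seed, pen, score)
    return (q_found, q_mm, q_smm, q_pos, q_inseed, q_pen,
            b_found, b_mm, b_smm, b_pos, b_inseed, b_pen)


@njit(cache=True)
def dp_call(
    d, r, seed_start, max_mm, seed_max_mm, bulge_pen, seed_bulge_pen,
    rna_ext, dna_ext, allow2seed, indel_excl, shortcut,
):
    n = r.shape[0]
    Lc = d.shape[0]

    rep_set = 0
    rep = (0, CLS_H, 0, 0, -1, 0, 0, 0)

    # ---- layer H ----
    if Lc >= n:
        off = Lc - n
        mm = 0
        smm = 0
        for i in range(n):
            if d[off + i] != r[i]:
                mm += 1
                if i >= seed_start:
                    smm += 1
        if mm <= max_mm and smm <= seed_max_mm:
            return (1, CLS_H, mm, smm, -1, 0, 0, 1)
        rep = (0, CLS_H, mm, smm, -1, 0, 0, 1)
        rep_set = 1

    min_1b_pen = seed_bulge_pen if seed_bulge_pen < bulge_pen else bulge_pen

    # ---- layer L1: 1-base DNA bulge ----
    if Lc >= n + 1 and ((not shortcut) or min_1b_pen <= max_mm):
        res = _layer_bulge(
            d[Lc - n - 1:], r, 1, True, seed_start, max_mm, seed_max_mm,
            bulge_pen, seed_bulge_pen, dna_ext, allow2seed, indel_excl)
        if res[0]:
            return (1, CLS_L1, res[1], res[2], res[3], res[4], res[5], 1)
        if not rep_set and res[6]:
            rep = (0, CLS_L1, res[7], res[8], res[9], res[10], res[11], 1)
            rep_set = 1

    # ---- layer R1: 1-base RNA bulge ----
    if Lc >= n - 1 and ((not shortcut) or min_1b_pen <= max_mm):
        res = _layer_bulge(
            d[Lc - (n - 1):], r, 1, False, seed_start, max_mm, seed_max_mm,
            bulge_pen, seed_bulge_pen, rna_ext, allow2seed, indel_excl)
        if res[0]:
            return (1, CLS_R1, res[1], res[2], res[3], res[4], res[5], 1)
        if not rep_set and res[6]:
            rep = (0, CLS_R1, res[7], res[8], res[9], res[10], res[11], 1)
            rep_set = 1

    # ---- layer L2: 2-base DNA bulge ----
    min_l2 = (min_1b_pen if allow2seed else bulge_pen) + dna_ext
    if Lc >= n + 2 and ((not shortcut) or min_l2 <= max_mm):
        res = _layer_bulge(
            d[Lc - n - 2:], r, 2, True, seed_start, max_mm, seed_max_mm,
            bulge_pen, seed_bulge_pen, dna_ext, allow2seed, indel_excl)
        if res[0]:
            return (1, CLS_L2, res[1], res[2], res[3], res[4], res[5], 1)
        if not rep_set and res[6]:
            rep = (0, CLS_L2, res[7], res[8], res[9], res[10], res[11], 1)
            rep_set = 1

    # ---- layer R2: 2-base RNA bulge ----
    min_r2 = (min_1b_pen if allow2seed else bulge_pen) + rna_ext
    if Lc >= n - 2 and ((not shortcut) or min_r2 <= max_mm):
        res = _layer_bulge(
            d[Lc - (n - 2):], r, 2, False, seed_start, max_mm, seed_max_mm,
            bulge_pen, seed_bulge_pen, rna_ext, allow2seed, indel_excl)
        if res[0]:
            return (1, CLS_R2, res[1], res[2], res[3], res[4], res[5], 1)
        if not rep_set and res[6]:
            rep = (0, CLS_R2, res[7], res[8], res[9], res[10], res[11], 1)
            rep_set = 1

    return rep


@njit(cache=True)
def eval_anchors(
    codes, anchors, r, seed_start, max_mm, seed_max_mm, bulge_pen,
    seed_bulge_pen, rna_ext, dna_ext, allow2seed, indel_excl, shortcut,
):
    """Run ``dp_call`` at every PAM anchor of one strand.

    ``codes`` are the working-strand base codes (forward codes for plus-strand
    anchors, reverse-complement codes for minus-strand anchors) and ``anchors``
    the PAM triplet starts in those coordinates.  The DNA context handed to
    the DP is the up-to-(n+2)-base window ending at the anchor.

    Returns an (n_anchors, 8) int64 matrix with the ``dp_call`` rows.
    """
    n = r.shape[0]
    out = np.empty((anchors.shape[0], 8), dtype=np.int64)
    for a in range(anchors.shape[0]):
        p = anchors[a]
        lo = p - (n + 2)
        if lo < 0:
            lo = 0
        res = dp_call(
            codes[lo:p], r, seed_start, max_mm, seed_max_mm, bulge_pen,
            seed_bulge_pen, rna_ext, dna_ext, allow2seed, indel_excl, shortcut)
        for j in range(8):
            out[a, j] = res[j]
    return out
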