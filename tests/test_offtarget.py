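import numpy as np
import pytest

from offscan.design import GuideRNA
from offscan.genome_io import PamPolicy, SequenceRecord, reverse_complement
from offscan.offtarget import (
    HomologyPolicy,
    brute_force_scan,
    dp_homology,
    generate_seed_variants,
    paired_offtarget_scan,
    search_offtargets,
)
from offscan.seed_index import build_index, decode_kmer, encode_kmer
from offscan.simulate import random_genome, sample_guides

from _oracles import hit_signature, oracle_dp, oracle_scan
from conftest import random_seq

RNA = "ACGTACGTACGTACGTACGT"  # non-repetitive shifted alignments


def mutate(seq: str, pos: int, rng=None, base=None) -> str:
    alt = base or next(b for b in "ACGT" if b != seq[pos])
    return seq[:pos] + alt + seq[pos + 1:]


class TestPolicy:
    def test_defaults_encode_working_assumptions(self):
        p = HomologyPolicy()
        assert (p.max_mismatches, p.seed_len, p.seed_max_mismatches) == (4, 12, 2)
        assert (p.bulge_penalty, p.seed_bulge_penalty) == (3, 2)
        assert (p.rna_bulge_ext_penalty, p.dna_bulge_ext_penalty) == (1, 2)
        assert not p.allow_two_base_bulge_in_seed
        assert p.seed_indel_excludes_seed_mismatch

    def test_yaml_round_trip(self, tmp_path):
        p = HomologyPolicy(max_mismatches=3, pam_policy=PamPolicy(use_secondary=False))
        f = str(tmp_path / "p.yaml")
        p.to_yaml(f)
        assert HomologyPolicy.from_yaml(f) == p

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            HomologyPolicy(max_mismatches=-1)
        with pytest.raises(ValueError):
            HomologyPolicy(bulge_penalty=0)


class TestDpHomology:
    def test_identity_is_class_h(self):
        c = dp_homology(RNA, RNA)
        assert (c.is_homology, c.alignment_class, c.mismatches) == (True, "H", 0)

    def test_five_mismatches_rejected(self):
        d = RNA
        for p in (0, 3, 6, 10, 15):
            d = mutate(d, p)
        assert not dp_homology(d, RNA).is_homology

    def test_l1_bulge_plus_nonseed_mismatch(self):
        """One inserted base plus one non-seed substitution scores 1+3=4."""
        d = mutate(RNA, 6)
        d21 = d[:4] + "C" + d[4:]
        c = dp_homology(d21, RNA)
        assert (c.alignment_class, c.mismatches, c.weighted_score) == ("L1", 1, 4)
        assert c.is_homology and c.bulge_kind == "dna" and not c.bulge_in_seed

    def test_bulge_and_mismatch_both_in_seed_rejected(self):
        d = mutate(RNA, 10)  # seed mismatch
        d21 = d[:15] + "A" + d[15:]  # DNA bulge inside the seed
        assert not dp_homology(d21, RNA).is_homology

    def test_two_base_rna_bulge_needs_zero_mismatches(self):
        d18 = RNA[:2] + RNA[4:]
        c = dp_homology(d18, RNA)
        assert (c.is_homology, c.alignment_class, c.mismatches) == (True, "R2", 0)
        assert not dp_homology(mutate(d18, 0), RNA).is_homology

    def test_l2_never_qualifies_with_defaults(self):
        d22 = RNA[:5] + "GG" + RNA[5:]
        c = dp_homology(d22, RNA)
        assert c.alignment_class != "L2" or not c.is_homology

    def test_length_validation(self):
        with pytest.raises(ValueError):
            dp_homology("ACGT", RNA)
        with pytest.raises(ValueError):
            dp_homology(RNA, RNA[:19])

    def test_n_in_dna_counts_as_mismatch(self):
        d = RNA[:5] + "N" + RNA[6:]
        c = dp_homology(d, RNA)
        assert (c.alignment_class, c.mismatches) == ("H", 1)

    @pytest.mark.parametrize("length", [18, 19, 20, 21, 22])
    def test_agrees_with_enumeration_oracle(self, rng, length):
        """Random DNA/RNA pairs: the DP must reproduce the explicit
        enumeration of every legal gap placement, per window length."""
        for _ in range(400):
            rna = random_seq(rng, 20)
            mode = rng.integers(0, 3)
            if mode == 0:
                dna = random_seq(rng, length)
            else:
                # near-homologous: derive from rna by indels+substitutions
                dna = rna
                while len(dna) > length:
                    k = int(rng.integers(0, len(dna)))
                    dna = dna[:k] + dna[k + 1:]
                while len(dna) < length:
                    k = int(rng.integers(0, len(dna) + 1))
                    dna = dna[:k] + random_seq(rng, 1) + dna[k:]
                for _ in range(int(rng.integers(0, 4))):
                    dna = mutate(dna, int(rng.integers(0, length)),
                                 base=random_seq(rng, 1))
            got = dp_homology(dna, rna)
            exp = oracle_dp(dna, rna)
            assert got.is_homology == exp["is_homology"], (dna, rna)
            if exp["is_homology"]:
                assert (
                    got.alignment_class, got.mismatches, got.seed_mismatches,
                    got.bulge_in_seed, got.weighted_score, got.bulge_pos,
                ) == (
                    exp["alignment_class"], exp["mismatches"], exp["seed_mismatches"],
                    exp["bulge_in_seed"], exp["weighted_score"], exp["bulge_pos"],
                ), (dna, rna)

    def test_shortcut_never_changes_calls(self, rng):
        for _ in range(300):
            rna = random_seq(rng, 20)
            dna = random_seq(rng, int(rng.integers(18, 23)))
            assert dp_homology(dna, rna, shortcut=True) == dp_homology(
                dna, rna, shortcut=False
            )


class TestSeedVariants:
    def test_hamming_subset_size(self):
        """0/1/2-mismatch seed patterns: 1 + 36 + 594 = 631 twelve-mers."""
        seed = RNA[-12:]
        keys = generate_seed_variants(seed)
        ham = [k for k in keys
               if sum(a != b for a, b in zip(decode_kmer(k), seed)) <= 2]
        assert len(ham) == 631

    def test_contains_single_mismatch_variant(self):
        keys = generate_seed_variants("A" * 12)
        assert encode_kmer("AAAACAAAAAAA") in keys

    def test_contains_indel_footprints(self):
        seed = "ACGTACGTACGT"
        keys = generate_seed_variants(seed)
        # RNA bulge in seed: delete seed[5], prepend arbitrary base
        assert encode_kmer(("T" + seed[:5] + seed[6:])) in keys
        # DNA bulge in seed: insert before seed[7], drop PAM-distal base
        assert encode_kmer((seed[:7] + "G" + seed[7:])[1:]) in keys

    def test_invalid_seed_rejected(self):
        with pytest.raises(ValueError):
            generate_seed_variants("ACGT")
        with pytest.raises(ValueError):
            generate_seed_variants("N" * 12)


def _plant(genome: str, pos: int, payload: str) -> str:
    return genome[:pos] + payload + genome[pos + len(payload):]


class TestSearch:
    def test_planted_guide_found(self, rng):
        g = random_seq(rng, 20000)
        guide = random_seq(rng, 20)
        g = _plant(g, 5000, guide + "TGG")
        rec = SequenceRecord("chr", g)
        idx = build_index([rec])
        hits = search_offtargets(guide, idx, [rec])
        exact = [h for h in hits if (h.start, h.end, h.strand) == (5000, 5020, "+")]
        assert len(exact) == 1
        assert exact[0].call.alignment_class == "H"
        assert exact[0].call.mismatches == 0

    def test_planted_second_copy_with_nonseed_mismatches(self, rng):
        g = random_seq(rng, 20000)
        guide = random_seq(rng, 20)
        copy2 = mutate(mutate(guide, 2), 5)  # both outside the seed
        g = _plant(g, 3000, guide + "TGG")
        g = _plant(g, 9000, copy2 + "AGG")
        rec = SequenceRecord("chr", g)
        idx = build_index([rec])
        starts = {h.start for h in search_offtargets(guide, idx, [rec])}
        assert {3000, 9000} <= starts

    def test_equals_fully_independent_oracle_scan(self, rng):
        """Indexed search vs a plain-Python all-window enumeration scan."""
        for _ in range(3):
            rec = SequenceRecord("chr", random_seq(rng, 8000))
            idx = build_index([rec])
            guides = sample_guides(rec, 3, int(rng.integers(0, 2**31)))
            for gu in guides:
                got = {hit_signature(h)
                       for h in search_offtargets(gu, idx, [rec])}
                assert got == oracle_scan(gu.protospacer, [rec])

    def test_matches_brute_force_scan(self, small_genome):
        idx = build_index([small_genome])
        for gu in sample_guides(small_genome, 10, 77):
            a = search_offtargets(gu, idx, [small_genome])
            b = brute_force_scan(gu, [small_genome])
            assert [hit_signature(h) for h in a] == [hit_signature(h) for h in b]

    def test_monotonic_in_mismatch_budget(self, small_genome):
        idx = build_index([small_genome])
        lo = HomologyPolicy(max_mismatches=3)
        hi = HomologyPolicy(max_mismatches=4)
        for gu in sample_guides(small_genome, 5, 99):
            hits3 = {(h.record_id, h.start, h.end, h.strand)
                     for h in search_offtargets(gu, idx, [small_genome], lo)}
            hits4 = {(h.record_id, h.start, h.end, h.strand)
                     for h in search_offtargets(gu, idx, [small_genome], hi)}
            assert hits3 <= hits4

    def test_include_self_flag(self, rng):
        g = random_seq(rng, 20000)
        guide_seq = random_seq(rng, 20)
        g = _plant(g, 5000, guide_seq + "TGG")
        rec = SequenceRecord("chr", g)
        gu = GuideRNA(protospacer=guide_seq, pam="TGG", source_id="chr",
                      start=5000, end=5020, strand="+")
        idx = build_index([rec])
        with_self = search_offtargets(gu, idx, [rec], include_self=True)
        without = search_offtargets(gu, idx, [rec], include_self=False)
        own = [(h.start, h.end, h.strand) for h in with_self]
        assert (5000, 5020, "+") in own
        assert (5000, 5020, "+") not in [(h.start, h.end, h.strand) for h in without]

    def test_secondary_pam_recorded_for_post_filter(self, small_genome):
        idx = build_index([small_genome])
        (gu,) = sample_guides(small_genome, 1, 7)
        both = search_offtargets(gu, idx, [small_genome], HomologyPolicy())
        primary_only = search_offtargets(
            gu, idx, [small_genome],
            HomologyPolicy(pam_policy=PamPolicy(use_secondary=False)),
        )
        keep = [h for h in both if h.pam_class == "primary"]
        assert [hit_signature(h) for h in keep] == [
            hit_signature(h) for h in primary_only
        ]

    def test_n_seed_rejected(self, small_genome):
        idx = build_index([small_genome])
        with pytest.raises(ValueError):
            search_offtargets("A" * 8 + "N" + "A" * 11, idx, [small_genome])


class TestPairedScan:
    def _hit_pairs(self, rng):
        # guide pair planted PAM-out at offset -1 (adjacent, non-overlapping),
        # plus a decoy pair at offset 111 (just outside the screen window)
        g = random_seq(rng, 30000)
        left_seq = random_seq(rng, 20)
        right_seq = random_seq(rng, 20)
        # minus-strand guide occupying [1003, 1023): plus carries CCA + rc(protospacer)
        g = _plant(g, 1000, "CCA" + reverse_complement(left_seq))
        # plus-strand guide at [1023, 1043): offset = 1022 - 1023 = -1
        g = _plant(g, 1023, right_seq + "TGG")
        # decoy: minus at [20003, 20023), plus at [19911, 19931): offset 111
        g = _plant(g, 20000, "CCA" + reverse_complement(left_seq))
        g = _plant(g, 19911, right_seq + "TGG")
        rec = SequenceRecord("chr", g)
        idx = build_index([rec])
        gl = GuideRNA(protospacer=left_seq, pam="TGG", source_id="chr",
                      start=1003, end=1023, strand="-")
        gr = GuideRNA(protospacer=right_seq, pam="TGG", source_id="chr",
                      start=1023, end=1043, strand="+")
        hl = search_offtargets(gl, idx, [rec])
        hr = search_offtargets(gr, idx, [rec])
        from offscan.design import GuidePair

        pair = GuidePair(left=gl, right=gr, offset=-1)
        return pair, hl, hr

    def test_on_target_pair_found_decoy_excluded(self, rng):
        pair, hl, hr = self._hit_pairs(rng)
        found = paired_offtarget_scan(pair, hl, hr)
        locs = {(a.start, b.start) for a, b in found}
        assert any(a == 1003 and b == 1023 for a, b in locs)
        # decoy at offset 111 must be excluded at the default 110 bound
        assert not any(a == 20003 and b == 19911 for a, b in locs)
        wide = paired_offtarget_scan(pair, hl, hr, max_offset=111)
        wide_locs = {(a.start, b.start) for a, b in wide}
        assert any(a == 20003 and b == 19911 for a, b in wide_locs)

    def test_different_records_never_pair(self):
        from offscan.offtarget import HomologyCall, HomologyHit

        call = HomologyCall(True, "H", 0, 0, "none", 0, False, 0)
        a = HomologyHit("g", "chr1", 100, 120, "+", "AGG", "primary", "A" * 20, call)
        b = HomologyHit("g", "chr2", 130, 150, "-", "AGG", "primary", "A" * 20, call)
        from offscan.design import GuidePair

        pair_stub = GuidePair.__new__(GuidePair)  # offsets not needed here
        assert paired_offtarget_scan(pair_stub, [a], [b]) == []

    def test_same_strand_never_pairs(self):
        from offscan.offtarget import HomologyCall, HomologyHit
        from offscan.design import GuidePair

        call = HomologyCall(True, "H", 0, 0, "none", 0, False, 0)
        a = HomologyHit("g", "chr1", 100, 120, "+", "AGG", "primary", "A" * 20, call)
        b = HomologyHit("g", "chr1", 130, 150, "+", "AGG", "primary", "A" * 20, call)
        pair_stub = GuidePair.__new__(GuidePair)
        assert paired_offtarget_scan(pair_stub, [a], [b]) == []
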