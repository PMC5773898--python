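# offscan

Whole-genome CRISPR/SpCas9 sgRNA design and off-target homology search, with
an exact combinatorial model of how many off-target homologies a guide is
expected to have on a genome of a given size.

## The problem

A 20-base single guide RNA (sgRNA) directs Cas9 to any genomic locus that is
complementary to the guide and carries a protospacer adjacent motif (PAM —
NGG for SpCas9, with weaker secondary PAMs NAG, NCG, NGA) immediately 3' of
the protospacer.  Cas9 also cleaves *off-target* loci whose sequence is
merely similar to the guide: up to four mismatches, or one bulge (an
unpaired base on the DNA or RNA side) plus a mismatch, with the 12
PAM-proximal bases (the *seed*) tolerating at most two mismatches or one
indel.  `offscan` answers two questions for anyone designing guides:

1. **How likely is a guide to be off-target-free at all?**  Counting every
   20-base sequence within the tolerance of a given guide gives 240,637
   homologous combinations out of 4^20 ≈ 1.1 × 10^12.  With the PAM
   requirement (16 of 64 triplets) and six billion 23-base windows in a
   human-sized genome (both strands), the expected number of off-target
   homologies per guide is ~328 and the probability of having none is
   ~2.7 × 10^-143: essentially every guide has potential off-targets, and
   the question becomes finding all of them.
2. **Where are they?**  A seed index — a hash from base-4-encoded,
   PAM-adjacent 12-mers to signed genomic positions — retrieves every
   candidate locus for a guide from the ~700 twelve-mer *variants* its seed
   tolerates (≤ 2 mismatches or one indel), and a five-layer dynamic
   program (ungapped; 1- and 2-base DNA bulge; 1- and 2-base RNA bulge)
   scores each candidate.  Retrieval is provably complete under the default
   policy: the test suite checks it hit-for-hit against brute-force scans
   of every PAM-anchored window.

## The scoring model

For DNA window *d* (18–22 bases, 3'-anchored at the PAM) and guide *r*
(20 bases), the five alignment layers H, L1, R1, L2, R2 are evaluated in
order and the first qualifying one wins.  A layer qualifies when

    mismatches + bulge penalties <= 4                (mismatch-equivalents)
    seed mismatches              <= 2
    bulge in seed  =>  no seed mismatch
    2-base bulge   =>  never in the seed

with a bulge penalty of 3 (2 inside the seed), +1 per extra RNA-bulge base
and +2 per extra DNA-bulge base.  Under these defaults a 2-base DNA bulge
(3+2=5) can never qualify and a 2-base RNA bulge (3+1=4) requires a perfect
match elsewhere.  Every threshold is a field of `HomologyPolicy`.

## Worked example

```
$ offscan expect
Total combination of 20 bp                   1,099,511,627,776
Total base mismatches                                  236,401
DNA bulge with 0 base mismatch                              64
RNA bulge with 0 base mismatch                              60
DNA bulge with 1 base mismatch                           2,112
RNA bulge with 1 base mismatch                           1,968
RNA bulge of two bases                                      32
Total combinations of homologies                       240,637
Homology probability of a 20-base sequence       0.00000021886
Probability of potential PAM                            0.2500
Off-target homology probability                  0.00000005471
Genome windows (both strands)                    6,000,000,000
Expected off-target homologies per guide                328.29
P(no off-target homology)                            2.67e-143
```

The rows are the counting model: 236,401 pure-mismatch sequences plus the
bulge classes give 240,637 homologous combinations; dividing by 4^20 and
multiplying by the PAM probability 0.25 gives the per-window probability,
and six billion windows give the ~328 expected hits per guide.

Searching a guide sampled from a 100-kb random genome (Python API):

```python
from offscan import build_index, search_offtargets
from offscan.simulate import random_genome, sample_guides

genome = random_genome(100_000, seed=7, record_id="sim")
index = build_index([genome])
guide = sample_guides(genome, 5, seed=11)[4]
hits = search_offtargets(guide, index, [genome])
```

prints, hit by hit (record, interval, strand, class, mismatches, seed
mismatches, PAM, PAM class):

```
sim   39212  39233  -  L1  0  0  GGA  secondary
sim   39213  39233  -  H   0  0  CGG  primary
sim   39214  39233  -  R1  0  0  TCG  secondary
```

The middle row is the guide's own locus (perfect ungapped match, class H);
the flanking rows are its one-base-shifted anchors, which qualify as
seed-bulge alignments against slipped secondary PAMs — a reminder that
"off-target count" depends on whether such echoes of a perfect site are
counted.  The same engine runs from the shell: `offscan index`, `offscan
design` (CDS FASTA or genome + BED/GFF3 intervals), `offscan search`,
`offscan pairs` (paired-nickase design, 5'-offset −4..20), and `offscan
simulate`.

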