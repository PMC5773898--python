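# Methods

## Scope and model organism

`offscan` implements whole-genome sgRNA design and off-target homology
search for SpCas9 (NGG primary PAM; NAG/NCG/NGA secondary PAMs), plus a
closed-form combinatorial model of off-target homology probability on an
i.i.d. uniform genome and a simulation harness that validates the model.
The engine is genome-agnostic: any multi-record FASTA can be indexed and
searched, and the coordinate scheme (chunked 64-bit global offsets with a
strand sign and a +1 bias) addresses genomes beyond 2^40 bases.  All
coordinates are 0-based, half-open, reported on the plus strand with a
strand flag.

## Homology definition

A locus is an off-target homology of a 20-base guide when a PAM (primary
or secondary) sits immediately 3' of an 18–22-base DNA window that aligns
to the guide within budget.  The budget, in mismatch-equivalents
(`HomologyPolicy` defaults in parentheses):

* total weighted score ≤ `max_mismatches` (4);
* mismatches inside the 12-base PAM-proximal seed ≤ `seed_max_mismatches` (2);
* at most one bulge; opening costs `bulge_penalty` (3), or
  `seed_bulge_penalty` (2) inside the seed; each additional bulged base
  costs `rna_bulge_ext_penalty` (1) or `dna_bulge_ext_penalty` (2);
* a bulge inside the seed excludes any seed mismatch
  (`seed_indel_excludes_seed_mismatch`, on), mirroring the "two mismatches
  **or** one indel in the seed" tolerance;
* a 2-base bulge never sits in the seed (`allow_two_base_bulge_in_seed`,
  off).

Consequences of the defaults: a 2-base DNA bulge (3+2=5) can never
qualify; a 2-base RNA bulge (3+1=4) qualifies only with zero mismatches.

### The five-layer DP

Alignments are 3'-anchored at the PAM and evaluated in the fixed order
H (ungapped, 20-base window), L1 (1-base DNA bulge, 21), R1 (1-base RNA
bulge, 19), L2 (2-base DNA bulge, 22), R2 (2-base RNA bulge, 18); the
first qualifying layer is reported (a locus homologous under several
classes appears once).  Within a bulge layer, every gap placement is
scored from prefix/suffix mismatch sums in one pass; seed-zone mismatches
are tracked separately throughout.  A penalty-bound shortcut skips a layer
whose minimum possible penalty already exceeds the budget (with defaults
this eliminates L2); a flag disables the shortcut, and a property test
asserts it never changes a call.

Conventions that the data do not force and were therefore frozen:

* a mismatch belongs to the seed iff the guide base it is aligned to lies
  in the 12 PAM-proximal guide positions;
* a bulged DNA base belongs to the seed iff its gap lies between guide
  positions k−1 and k with k ≥ 9 (0-based; seed = positions 8–19).  This
  includes the gap between the seed and the PAM, giving 12 in-seed DNA gap
  positions — consistent with the counting model's 12×4 in-seed DNA-bulge
  factor;
* a bulged guide base belongs to the seed iff its own position is ≥ 8;
* ties between equal-score placements go to the leftmost (5'-most) gap;
* an N in the genome mismatches every guide base, and a PAM pattern's N
  matches any concrete base but never a genomic N;
* 23-base windows containing N, and windows whose 20-base protospacer
  would cross a record boundary, are excluded entirely.

## Seed index and retrieval completeness

Every PAM-adjacent site (both strands, full window, no N) contributes one
entry: the base-4 key of its 12 PAM-proximal bases (A,C,G,T → 0..3, digit
i weighted 4^i, i = 0 at the 5'-most base of the 12-mer on the site's own
strand) mapped to a signed position (sign = strand).  Internally the index
is a key-sorted pair of arrays with binary-search lookup; sites are
stored, not sequences.

For a query, every 12-mer the seed tolerates is generated: Hamming
distance ≤ 2 (1 + 36 + 594 = 631 patterns), plus the PAM-adjacent
footprints of one seed indel — delete one seed base and prepend an
arbitrary base (RNA bulge), or insert an arbitrary base and drop the
5'-most base (DNA bulge).  Because an in-seed bulge excludes seed
mismatches, these exact footprints are sufficient, and retrieval loses no
locus that the DP would accept: the acceptance suite verifies equality
with a brute-force scan of every PAM-anchored window on 20 random 100-kb
genomes × 50 guides, and the variant generator against an exhaustive
filter of all 4^12 twelve-mers.

## Design rules

Guides are designed on both strands of a spliced CDS (given directly as
FASTA or extracted from a genome via BED6/GFF3 intervals): primary PAM
only; the whole 20-base protospacer inside the first half of the CDS
(positions [0, ceil(L/2)) — the boundary is configurable since only
"first half" is specified by the underlying design practice); no TTTT or
AAAA run in the protospacer *as written 5'→3'* (the rule targets the
guide's own sequence, e.g. the Pol III terminator TTTT); GC content
reported, with optional bounds that default to report-only because the GC
rule is qualitative.  Paired-nickase pairs are opposite-strand guides with
a 5'-end offset in [−4, 20]; the offset is signed as (5' end of the
leftward-PAM guide) − (5' end of the rightward-PAM guide), so PAM-out
head-to-head designs with overlapping 5' ends get small positive offsets.
Paired off-target screening uses the same convention with the efficacy
window [−34, 110].

## Counting model

Pure-mismatch homologies: Σ over seed mismatches s ≤ 2 of C(12,s)·3^s ×
Σ over non-seed mismatches t ≤ 4−s of C(8,t)·3^t = 236,401.  The bulge
classes use the model's position-count constants (16 = 12 seed + 4
non-seed insertion points for a DNA bulge, 15 = 11 + 4 deletion points
for an RNA bulge, 2 placements for a 2-base RNA bulge): 64, 60, 2112,
1968 and 32 combinations, total 240,637.  The position restrictions exist
to avoid double counting against the mismatch class (a bulge is only
credited where it trades off at least five mismatches); they are
accounting devices of the model, not search-time rules, so the search
reports bulged loci the model does not separately count.  Per-window
probability 240,637/4^20, times PAM probability 16/64, times 6 × 10^9
windows gives 328.3 expected homologies per guide;
P(no homology) = (1−p)^N is evaluated via N·log1p(−p) (order 10^-143).

## Simulation harness

`run_offtarget_census` generates an i.i.d. uniform A/C/G/T genome, indexes
it, samples guides uniformly without replacement from primary-PAM loci on
both strands, searches each with the default policy, and scales the mean
hit count by (6 × 10^9)/(2L).  A root seed derives the genome (seed+1)
and guide-sample (seed+2) streams, so each stage and the whole census are
reproducible.

Two accounting choices matter at reduced scale:

* **Own-locus exclusion.**  A sampled guide's perfect site is a guaranteed
  hit, and its one-base-shifted anchors frequently qualify as 0-mismatch
  seed-bulge alignments against slipped secondary PAMs.  Both are
  conditioned on the sampled locus rather than on random sequence, so the
  census drops hits overlapping the guide's own locus on its own strand.
  At full genome scale this is ~1 hit in ~328; at scale factor 150 keeping
  them would inflate the scaled mean by roughly +200.
* **Indel fraction.**  Hits of classes L1/R1/R2 over all hits.  On a
  uniform genome this runs ~4–6%, the same order as (but not equal to) the
  model's 1.76% combination share, because the search counts every
  qualifying bulged anchor as a locus while the model's restricted
  position counts deliberately fold most bulged patterns into the
  mismatch class.

Default census conditions are a 20-Mb genome and 300 guides, sized so the
whole census (index build + 300 searches) completes in seconds on one CPU
while leaving the scaled-mean standard error at ~13, tight enough to
resolve the ~328 expectation.  What the harness does *not* emulate: real
genomes are not i.i.d. — repeat families give some guides enormous hit
counts and push the genome-wide mean well above the uniform-model
expectation — so passing censuses say the engine and the model agree with
each other, not that real-genome counts will match 328.

## Numerical and engineering notes

* The DP core and batch window evaluators are numba-compiled; a pure-Python
  gap-placement enumeration oracle in the test suite provides the
  independent check on ≥ 10,000 random pairs per run.
* All combinatorial counts are arbitrary-precision integers; probabilities
  only become floats at the final division.
* The seed index serializes to a versioned `.npz` container so a genome is
  indexed once per PAM policy.
* Guides containing N, empty genomes, CDS shorter than 23 bases, and
  absent keys all degrade to empty results or explicit `ValueError`s;
  degenerate policies (e.g. `max_mismatches=0`) are valid and tested.

## Known limitations

* Completeness of seed-variant retrieval is guaranteed for the default
  seed tolerance (≤ 2 mismatches or one in-seed indel with no seed
  mismatch).  Loosening `seed_max_mismatches` above 2 or allowing in-seed
  indels to coexist with seed mismatches would require a wider variant
  generator; the brute-force scanner remains available as the reference
  for such policies.
* No activity/efficiency scoring (CFD, MIT specificity, Doench scores) —
  calls are binary homology judgements under the policy.
* The census extrapolation is linear in window count; it corrects for
  scale but not for base composition or repeat structure.
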