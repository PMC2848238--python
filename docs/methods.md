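# Methods

## The problem and the approach

Multiple alignment of long, closely related nucleotide sequences (sets of
mitochondrial genomes, strains of one bacterial species) is dominated by
the cost of pairwise comparison in conventional progressive aligners.
`anchormsa` sidesteps pairwise comparison entirely: it looks for short
oligonucleotides whose occurrence statistics alone mark them as probable
homology signals, uses them to pin the sequences together, and only runs a
conventional aligner on the short regions left between the pins.

The pipeline, in the order the code runs it:

1. **k-tuple dictionary** (`kdict`). One pass over the data counts, for
   every k in 1..M and every window of length k consisting solely of
   A/C/G/T, the total occurrence count, the number of distinct sequences
   containing the tuple, and the index of the last sequence in which it was
   seen (the bookkeeping that makes the per-sequence count maintainable in
   a single pass). A second step adds, to each materialized tuple, the
   *inexact* count: its own count plus the counts of its 3k one-substitution
   neighbours. Insertions, deletions and double substitutions are never
   part of the neighbourhood.

2. **Seed finding** (`kdict` + `seeds`). In a random sequence of total
   length L = A·N, a given k-tuple is expected L/4^k times, so tuples with
   exactly one (inexact) occurrence per sequence become informative once
   4^k is comparable to the mean sequence length A; using every k up to a
   cap M avoids guessing the right k. Tuples whose inexact count equals N
   are *candidates*; a second pass over the residues verifies that each
   candidate has exactly one Hamming-distance-≤1 window in every sequence
   and records that window's start. Survivors are *seeds*. The aggregate
   count cannot by itself certify per-sequence uniqueness (all N matches
   could sit in one sequence), which is why verification is a separate
   stage.

3. **Compatibility resolution** (`seeds`). The best T seeds are kept
   (longer tuples first, then tuples exactly matching more sequences, then
   smaller position in sequence 0; the tuple string breaks residual ties,
   so the order is total and independent of input order). For every pair,
   the incompatibility distance counts sequences whose relative order of
   the two seeds deviates from the majority; windows that overlap in a
   sequence support neither order and count against both. The T×T distance
   matrix is then reduced by repeatedly removing the seed with the largest
   row sum (ties: the worst-ranked seed goes) until no incompatibility
   remains. If every pair conflicted, exactly one seed survives. A second
   removal pass on an overlap-count matrix enforces pairwise non-overlap in
   every sequence; because overlap already counts as an order violation,
   this pass is a safety net and normally removes nothing.

4. **Divide and conquer** (`divide`). Each anchor contributes a gap-free
   block of k columns (each sequence's window is the tuple itself or one
   substitution away — no indel can occur inside a block, so emitting the
   windows as-is is exact). The regions between consecutive anchors are
   homologous by collinearity and are aligned independently: recursively
   with further anchoring rounds while they are long, by the sub-aligner
   once the longest interval is at most `segment_threshold` or the depth
   budget `max_depth` is exhausted, and directly whenever any interval is
   empty (a segment with an empty row cannot contain a seed present in
   every sequence). A recursion that finds zero anchors falls through to
   the sub-aligner for that segment; zero anchors at the top level send
   the whole dataset to the sub-aligner. Partial alignments and anchor
   blocks are concatenated in order.

5. **Seeds-only mode**. With `seeds_only` the sub-aligner is never
   invoked: leaf segments are rendered unaligned, each row left-justified
   and padded with gaps to the longest interval. Combined with
   `max_depth=1` this is the recommended triage run for a new dataset:
   it takes seconds, and finding *zero* seeds is a strong signal that the
   data is very hard or impossible to align (uniform random sequences
   reliably produce zero seeds at N=50, 20 kb). The CLI distinguishes this
   outcome with exit code 2.

This divide-and-conquer scheme assumes the sequences align linearly; it
cannot represent duplications, inversions or rearrangements, and it is at
its best on closely related sequences where seeds are abundant.

## Scoring

Alignment quality is summarized by the sum-of-pairs identity score:
S_ij = 100·M_ij/L, where M_ij counts columns in which rows i and j carry
the same non-gap character and L is the alignment width including gaps;
the reported score is the unweighted mean of S_ij over all pairs. Columns
gapped in both rows count toward L and never toward M_ij — a literal
reading of the formula's gap-inclusive denominator. Comparison is
case-insensitive and identical ambiguity characters (N/N) count as
matches.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| M | 12 | largest tuple length in the dictionary; 4^12 ≈ 1.7·10^7 suits megabase-scale data, and the sparse dictionary makes it cheap. Hard cap 14. |
| T | 600 | seeds kept for the T×T compatibility matrix. |
| max_depth | unlimited | anchoring rounds; 1 reproduces the screening behaviour, small values can help when the first round already yields short blocks. |
| segment_threshold | 2000 bp | longest interval that goes straight to the sub-aligner; conservative relative to the ~4 kb blocks that conventional aligners handle comfortably. |
| scoring (builtin) | 1 / −1 / −4 / −1 | match, mismatch, gap open (first gap character), gap extend — common nucleotide defaults. |
| size_cap (builtin) | 200 000 | rows × longest row; above this the builtin aligner refuses and suggests an external tool. |

The dictionary is stored sparsely (per-k sorted arrays of 2-bit-packed
codes with parallel count columns) rather than as dense 4^k tables: only
tuples that actually occur are materialized, which is what makes M=12
affordable without a packed byte-level layout.

## The builtin sub-aligner

A self-contained progressive profile aligner exists so that the whole
pipeline and its tests run with zero external binaries; any
FASTA-in/FASTA-out tool (MAFFT, CLUSTAL W, or an arbitrary command
template) can be substituted through the external adapter, which restores
record order and verifies the degap round trip on the tool's output.
Sequences join the profile in length-descending order (segments between
anchors are short and similar, so a guide tree would add little); each
joins by global affine-gap DP over profile columns, a column scored by the
mean substitution score against its residues (gap rows contribute zero to
the numerator; the denominator is the number of profile rows). The
three-state recurrence is vectorized row-wise, with the along-row gap
state recovered from a running prefix maximum; traceback tie-breaking is
fixed (diagonal, then gap-in-profile, then gap-in-sequence), making the
output deterministic. Gap-state-to-gap-state switches that the recurrence
omits cannot be optimal under the default scores (two gap openings cost
−8, worse than any substitution), and the pairwise case is verified
against an exhaustive affine optimum in the tests.

## Synthetic data

The generator produces (a) uniform i.i.d. random sequence sets — the
negative control: unrelated sequences in which seed finding should come
up empty — and (b) homologous families evolved from one random ancestor
by a star phylogeny with per-site substitutions and geometric-length
indels (default mean 3 bp), recording every edit and the monotone
ancestor-to-descendant coordinate map. A star phylogeny rather than a
tree keeps the expected divergence directly interpretable (two
descendants differ at ≈ 2·sub_rate of sites) and is sufficient for
anchor-recovery and round-trip properties. What it does not emulate:
tree-shaped correlation between lineages, rate heterogeneity, repeats and
compositional bias of real genomes — so passing tests demonstrate
correctness of the machinery on known-truth data, not alignment quality
on hard biological inputs.

Study conditions used in the tests, chosen once: the random-data control
uses 50 sequences of 20 kb; the high-conservation regime uses
substitution-only families of 50 sequences, 16.5 kb, per-site rate 0.003
(the nucleotide diversity of human mtDNA population datasets); the
round-trip battery spans n ∈ {3, 5, 10}, ancestors 5–50 kb and rates
{0, 0.003, 0.05} with and without indels, with sizes paired so the whole
battery completes in minutes on one CPU.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; sequence index = position
  in input file order.
- Windows overlapping any non-ACGT character are excluded from counting
  (the dictionary assumes a 4-letter alphabet); ambiguity codes are
  otherwise preserved in sequences and alignments.
- `'-'` is the only gap character; `'.'` on input is rejected.
- All tie-breaks (seed ranking, removal order, DP traceback) are fixed and
  documented; two runs on the same input produce identical output.
- Degapping every emitted row must equal the corresponding input; this is
  asserted inside the pipeline on every assembly, not only in tests.
- A width-0 alignment scores 0 (with a warning); empty segment rows become
  all-gap rows, forced by the round-trip invariant.

## Known limitations

- The T-cap interacts with highly conserved data: at mtDNA-level
  conservation tens of thousands of tuples verify as seeds, so each
  anchoring round can only use the 600 best-ranked ones, and which
  individual tuple ends up an anchor is effectively a selection lottery
  among equally-ranked neighbours. The *regions* are still anchored and
  every emitted anchor sits at truly homologous coordinates, but no
  guarantee attaches to one specific tuple becoming an anchor. The
  seed-ranking tertiary key (position in sequence 0) concentrates each
  round's anchors toward the start of the unanchored region; recursion
  then sweeps the remainder.
- Rearranged, duplicated or inverted sequence cannot be modelled; the
  screening mode is the intended guard for such inputs.
- The builtin aligner is a correctness-first stand-in: for large or
  divergent segments an external aligner will produce better alignments
  faster.
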