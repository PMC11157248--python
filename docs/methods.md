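# Methods

## Problem and model

Human centromeres are built from tandem ~171-bp alpha-satellite
*monomers*. Monomers group into *types* (families): any two monomers of
one type diverge by less than 5%, while different types within a repeat
unit diverge by roughly 20–40%. A *higher-order repeat* (HOR) is a unit
of *n* monomers (an *n*mer) repeated in tandem, with copy-to-copy
divergence again below 5%. In Willard's type HORs each canonical copy
contains every type exactly once (τ = n, where τ is the number of
distinct types per canonical copy). In *cascading* HORs at least one
type recurs within the canonical copy (τ < n); such copies are displayed
as multi-row schemes with monomers of one type aligned vertically.

`horscan` implements the full chain: monomer detection by consensus
alignment, family clustering, periodicity diagrams, and cascading copy
schemes, plus a generator of synthetic arrays with ground truth.

## Monomer detection (`scan`)

The subject sequence is searched with a single ~171-bp consensus query
in both orientations using edlib infix alignment. Detection is
best-first: the best-scoring hit in an interval is accepted (edlib
reports all co-optimal locations; ties are taken leftmost, plus strand
first), and the flanking intervals are searched recursively. Accepted
hits never overlap, which reproduces the tandem tiling of satellite
arrays exactly.

Parameters:

- `max_div` (default 0.30) — maximum normalised edit distance between
  query and monomer. Monomer types diverge by up to ~40% from each
  other, hence roughly half that from a central consensus; 0.30 leaves
  headroom for the per-copy mutation layer while excluding random
  sequence (two random DNA strings align at ~0.45–0.50).
- length bounds (default 0.5–1.5 × query length) — reject fragments and
  fused dimers. With `max_div < 0.5` the band constraint already keeps
  alignments inside these bounds.
- *divergence* is `edit_distance / max(len_a, len_b)`: symmetric,
  within [0, 1], zero only for identity, tolerant of indels.

Boundary behaviour: when a mutation sits on the first or last base of a
monomer, the optimal alignment may shrink the reported interval by a
base or two; coordinates are therefore exact up to a few bp at copy
boundaries, and counts are exact.

## Family assignment (`families`)

All-vs-all divergences define a graph with an edge wherever divergence
is below the threshold (default 0.05); families are the connected
components (single linkage). Single linkage is the reading of
"all monomers that differ from each other by less than 5%" as a
graph-component rule; it is order-independent, and the transitive
closure matters in practice because a family's diameter can slightly
exceed the threshold while consecutive members stay below it. Labels
are dense integers renumbered by first occurrence along the enumeration
(the first monomer is always t1), which also fixes the phase convention
for canonical units below.

Two computational routes exist: the exact route uses banded alignment
with early abort above the threshold (identical result to the full
matrix, much faster), and a representative-first approximation
(`mode="greedy"`) compares each monomer to one representative per
family; both agree whenever families are separated, which the test
suite checks.

A caveat the synthetic experiments make visible: with per-copy mutation
rate *m* the expected within-family divergence is ≈ 2m(1−m); at m = 1%
that is ~2%, safely below 5%, but the Poisson tail means a rare
hypermutated monomer (≥ 9 substitutions on 171 bp) can exceed the
threshold to *every* family-mate and split off as a singleton family.
On a 1700-monomer array this happens in a few percent of seeds; it
shifts family and MD-point counts by ~0.1%, and is a property of the
threshold rule, not a detection failure.

Per-family consensus: the family medoid (member minimising summed
divergence) anchors a star alignment; the consensus is the per-column
majority with ties broken A < C < G < T, majority deletions dropping
the column, and insertions kept only when shared by more than half of
the members. Under a substitution-dominated mutation process this
equals the full-MSA majority consensus.

## Periodicity diagrams (`periodicity`)

For each monomer, its *period* is the distance in monomer units to the
next monomer of the same family, capped at `max_period` (default 50 —
generously above the periods of interest, which are ≲ 40). The set of
(enumeration index, period) pairs is the MD diagram; its histogram over
periods is the GRM diagram. The two are defined as identical by
construction. Closed forms for a pure tandem of C cascading 17mer
copies (unit t1..t15, t1, t16): 15(C−1) points at period 17 (the 14
once-per-copy types plus t16), C points at period 15 (the intra-copy
t1→t1 distance), C−1 at period 2 (the inter-copy t1→t1 distance across
the t1,t16 doublet), and in total N − k points for N monomers in k
families.

MD-line segments: per period, points chain into a segment while
consecutive indices differ by at most `max_gap`
(default `max(5 × period, 50)`; the floor matters because subfragment
points recur once per HOR copy, i.e. with spacing equal to the HOR
period, which exceeds 5 × period for small periods such as the
period-2 doublet), and segments need `min_support` points (default 10).
Among segments whose intervals overlap by ≥ 50% (of the shorter
interval), the one with the greatest support is the HOR of that
interval; the co-located others are subfragments. Support, not period
magnitude, is the tiebreak: in a cascading nmer the n-period segment
collects points from every non-repeated type and therefore dominates.

Limitation: in extremely cascading units the HOR period may *not* carry
the top segment (in the 36mer below, ten types recur at spacing 18,
outnumbering the six once-per-unit types at spacing 36). The aligned
scheme, not the MD diagram, identifies such units; the analysis
functions therefore accept an explicit HOR order.

## Arrays, canonical units, copies, schemes (`cascade`)

Arrays are maximal monomer runs with genomic gaps ≤ `max_gap_bp`
(default 2000 bp ≈ 11 monomer lengths); each is annotated with its HOR
and subfragment periods computed on its own slice.

**Canonical unit.** The most frequent length-n window of the label
sequence, counted up to cyclic rotation so that every phase of the
tandem contributes to one class. The winning class is rotated to the
phase that most often starts a copy — the rotation that most often
follows the end of an identical copy — with ties resolved towards the
rotation matching the start of the array (consistent with label
renumbering, which makes the array's first monomer t1). For an array
trimmed mid-copy, the original phase is unrecoverable from labels alone
and the unit anchors at the enumeration start.

**Copy partition.** Greedy left-to-right. An exact occurrence of the
canonical unit opens a canonical copy (consuming its full row layout,
so interior rows of units like the 36mer, which themselves resemble the
unit's start, cannot split it); otherwise the copy opens with the row
at the cursor. The copy then absorbs subsequent rows unless a row opens
the next copy; a row opens the next copy when it matches at least the
first two labels of the canonical unit and is not a repeat of the
previous row. Row repeats extend the copy (row multiplication, the
"2 × 15 + 2" … "6 × 15 + 2" extended copies), and rows matching fewer
than two unit labels — the trailing t1,t16 doublets that generate
tertiary period-2 repeats — attach to the running copy. A row equal to
the complete unit (only possible for Willard's type, where the whole
copy is one row) always starts a new copy. A copy is canonical iff its
label sequence equals the unit exactly. One consequence worth knowing:
identical consecutive partial copies (say two adjacent copies missing
the same type) merge into one variant as row multiplication.

**Layout.** Each monomer's column is its type's position in the
canonical type ordering (first occurrence); types absent from the unit
get fresh rightmost columns. A new row starts whenever the next
monomer's column is not strictly to the right of the previous one, so
every row reads through increasing columns and same-type monomers align
vertically. (A "new row on repeated type within the row" trigger is
weaker: it would let a row run past a column regression through unseen
types, and cannot produce the 6/17/8/5 rows of the canonical 36mer.)

**Signatures.** Row lengths joined with "+"; a row that is not one
contiguous piece of the canonical layout — two row neighbours never
adjacent within any canonical row, marking a deletion gap — is written
as the parenthesised sum of its pieces. Hence "15 + 2" (canonical
17mer; t1,t16 are adjacent in the canonical second row, so the doublet
is one piece of size 2), "15 + 15 + 2", "(6 + 4)+2". Column-run
contiguity alone would wrongly split the t1,t16 doublet, whose columns
are 1 and 16.

**Summary.** Copy counts, percent canonical (rounded to the nearest
integer), and lengths of maximal consecutive-variant runs.

## Synthetic arrays (`synthetic`)

The generator emulates the structure the method assumes: k type seeds
are independent mutants of one random ancestor (as alphoid monomers
derive from a shared consensus), at a branch rate solved from
2r − 4r²/3 = D so realised pairwise type divergence is ≈ D (default
0.25, the middle of the 20–40% band; a construction loop enforces a
0.8·D floor). Copies concatenate type seeds with i.i.d. per-base
substitutions (default 1%, i.e. within-family divergence ≈ 2%,
inside the <5% regime; optionally a fraction of mutation events are
single-base indels, exercising the scanner's length tolerance).
Variant events duplicate a canonical row (times = total multiplicity),
delete types, or insert a row. Flanks are random DNA; minus-strand
arrays are whole-sequence reverse complements with mirrored truth
coordinates. Multi-array chromosomes share one ancestor so one query
detects all arrays, and use disjoint type-label spaces. Everything is a
pure function of the seed.

What the generator does **not** emulate: layered expansion history,
gene conversion tracts, CpG-biased or indel-rich mutation spectra,
assembly gaps, and divergence gradients at array edges. Passing tests
therefore demonstrate correctness of the method's logic under its own
model assumptions, not performance on real centromeres; the
length-bound and boundary behaviour of real data are exercised only
through the indel option.

## Problem sizes and numerics

The test suite and the acceptance script run desk-scale fixtures chosen
to make every structural quantity exact in closed form: a 100-copy
cascading 17mer (1700 monomers, ~292 kb) for the MD/GRM counts, 8–10
copy arrays for the variant-signature structures, a 5-copy 36mer, a
100-copy Willard 10mer with six deletion variants (94% canonical), and
~500-monomer mixed two-array chromosomes for recovery across seeds.
All-vs-all family assignment is banded with early abort, so the 1700-
monomer case clusters in a few seconds on one core.

Determinism: ties in greedy hit selection break by position then
strand; consensus ties alphabetically; unit rotation ties by prefix
match then lexicographically. Degenerate inputs: an empty subject
yields an empty monomer list; fewer than two monomers yield empty
diagrams with a warning; unit inference requires at least two full
units and raises otherwise.

## Packaged consensus

The shipped default query (`data/alphoid_consensus_synthetic.fasta`) is
a synthetic 171-bp sequence with alphoid-like AT-rich composition,
intended for self-contained demonstrations; for real assemblies supply
a published alphoid consensus via `--query`.
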