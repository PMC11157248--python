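# horscan

Detection and structural analysis of **alpha-satellite higher-order
repeats (HORs)** — including *cascading* HORs whose canonical copies
repeat monomer types — from genomic sequence.

Human centromeres are tiled with ~171-bp alpha-satellite monomers.
Monomers cluster into **types** (mutual divergence < 5%; different
types diverge ~20–40%), and runs of *n* monomers repeat in tandem as
*n*mer HORs. In Willard's type HORs every type occurs once per
canonical copy (τ = n distinct types); in cascading HORs some types
recur (τ < n), which classical single-row HOR notation cannot express.
`horscan` finds the monomers, clusters them into types, locates HOR
arrays by their periodicity, and renders each copy as a multi-row
*cascading aligned scheme* in which monomers of one type align
vertically — classifying copies as canonical or variant with row
signatures such as `15 + 2`, `15 + 15 + 2`, or `(6 + 4)+2`.

It is intended for researchers annotating satellite DNA in long-read
assemblies, and for method work on tandem-repeat periodicity.

## Method

1. **Monomer scan** — a consensus query (nominally 171 bp) is aligned
   against the subject with edlib on both strands; non-overlapping hits
   with normalised edit distance ≤ 0.30 are selected best-score-first,
   giving an ordered, enumerated monomer list.
2. **Families** — monomers are clustered by single linkage at < 5%
   divergence (connected components of the sub-threshold link graph);
   each family gets a star-alignment majority consensus.
3. **GRM / MD diagrams** — each monomer's *period* is the distance, in
   monomer units, to the next monomer of its family. The histogram of
   periods is the GRM (global repeat map) diagram: a peak at period *n*
   marks an *n*mer HOR. The scatter of (enumeration, period) is the MD
   (monomer distance) diagram: dense horizontal segments localise HOR
   arrays, and co-located shorter segments are *subfragments* — e.g. a
   cascading 17mer with unit t1…t15, t1, t16 yields periods 15
   (intra-copy t1→t1) and 2 (inter-copy t1→t1) beneath its period-17
   line.
4. **Cascading schemes** — per array, the canonical unit is the most
   frequent length-*n* label window (up to rotation); copies are
   partitioned greedily and laid out in rows with strictly increasing
   type columns; copies equal to the unit are canonical, others are
   variants with row signatures.

See `docs/methods.md` for the full model, parameter defaults, and
design decisions.

## Worked example

Generate a synthetic cascading 17mer array — 10 copies, 1% per-base
mutation, copy 7 carrying a duplicated first row — and run the full
pipeline:

```python
from horscan import ArraySpec, VariantEvent, build_array
from horscan.io import write_fasta

spec = ArraySpec(
    n_copies=10, per_base_mutation=0.01,
    variant_events=(VariantEvent(copy=6, kind="duplicate_row", row=0, times=2),),
    seed=7,
)
seq, truth = build_array(spec)
write_fasta("chr_demo.fasta", [("chr_demo", seq)])
write_fasta("query.fasta", [("consensus", truth["query"])])
```

```sh
horscan -v all --subject chr_demo.fasta --query query.fasta --out out
```

prints

```
INFO monfinder: 185 monomers detected on chr_demo
INFO grmhor: 185 monomers in 16 families
INFO grmhor: 169 MD points, 2 MD-line segments
INFO grmhor: array 0-185: 17mer (tau=16), 10 copies, 90% canonical
185 monomers, 16 families -> out/
```

The 185 monomers (9 × 17 + one 32-monomer variant) fall into 16
families, as expected for a cascading 17mer with one repeated type.
`out/grm.tsv` holds the period spectrum — 134 points at the HOR period
17, 25 at subfragment period 15, 9 at period 2 — and `out/scheme.txt`
the aligned scheme, one row per line, each copy's first row prefixed
with its 1-based genomic start:

```
       501  t1  t2  t3  t4  t5  t6  t7  t8  t9  t10 t11 t12 t13 t14 t15
            t1                                                          t16   [canonical 15 + 2]
```

with copy 7 rendered as three rows and signature `15 + 15 + 2`
(a 32-monomer variant). `out/summary.json` aggregates the array:
period 17, τ = 16, 10 copies, 90% canonical. Other outputs:
`monomers.bed`/`monomers.fasta` (scan), `families.tsv`,
`family_consensus.fasta`, `md_points.tsv`, `md_segments.tsv`,
`scheme.tsv`.

The subcommands mirror the two analysis stages: `horscan monfinder`
(scan only), `horscan grmhor` (from a monomer FASTA), `horscan all`,
and `horscan simulate` (synthetic arrays with ground truth). Without
`--query`, a packaged synthetic alphoid-style consensus is used; for
real assemblies supply a published alphoid consensus.

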