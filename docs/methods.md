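# Methods

This note records the conventions, parameters and design choices behind
each stage, what the synthetic fixtures emulate, and what the tests do
and do not demonstrate about real data.

## Coordinates and the duplex-pairing model

All coordinates are 0-based; intervals are half-open. GFF3 input
(1-based inclusive) is converted on read.

GATC is its own reverse complement, so one + strand occurrence at start
*s* describes both strands of a duplex locus: the top-strand modifiable
G is at *s*, and the bottom-strand modifiable G lies opposite the
top-strand C at *s + 3*. A PT call stores the + strand coordinate of
the base physically carrying its modified G; duplex pairing is then
pure integer arithmetic (a + call at *p* partners a − call at *p + 3*)
with no fuzzy matching. Calls that match no scanned locus are returned
as orphans, never dropped; a second call on the same strand of a locus
is an error rather than a silent dedup.

## PT summary conventions

The printed statistics pin the following conventions, chosen so that
the strand-count and fraction bookkeeping stays mutually consistent:

* `pct_modified` = strand-level calls / motif loci × 100, printed to
  1 decimal. Counting *calls* (not duplex loci) over loci is the
  convention under which 1,229 (+) and 1,222 (−) calls over 94,316
  sites print as 2.6 % (2,451).
* `pct_hemi` = hemi calls / all calls × 100, printed to the nearest
  integer (1,141 / 2,451 → 47). A full locus contributes two calls,
  a hemi locus one.
* Duplex-locus counts (`n_full`, `n_hemi`, `n_modified_loci`) are kept
  as separate fields; conservation `n_full + n_hemi_plus + n_hemi_minus
  + n_none = n_motifs` holds on every input and is property-tested.
* `calls_per_10kb` = calls / (2 × genome length) × 10⁴ — a density per
  10 kb of double-stranded genome. It is a genome-level proxy and is
  deliberately *not* comparable to chromatographic (LC-MS style)
  per-dinucleotide modification frequencies, which measure a different
  quantity on a different denominator.
* Spacing is the set of consecutive differences of modified-G
  coordinates, by default per strand (both-strand pooling is available
  as `combined`); genomes are treated as linear, with circular
  wrap-around behind an explicit flag because the convention on ring
  closure is otherwise ambiguous.
* Flanking-base bias compares base frequencies at offsets −1/+1 among
  modified loci against all motif loci; loci lacking a flank at the
  genome edge are excluded from numerator and background alike, and
  zero-frequency cells yield an undefined (None) enrichment rather
  than ±inf.

## Neighbourhood mining

Homology hits are kept iff e-value ≤ 10⁻¹⁰ **and** aligned length ≥
30 % of the query protein, both thresholds inclusive. The 30 % boundary
is kept-inclusive by design (an exactly-30 % hit passes); the filter is
configurable for the exclusive reading. Hits reduce to one annotation
per (genome, query) — the best by (e-value, then identity) — a minimal,
standard reduction.

Neighbourhood phrases of the form "1 bp–20 kb" are read as an
edge-to-edge gene gap in [0, W]: overlapping or abutting genes count as
within the window, and gaps are measured from the anchor cluster's span
edges, never its midpoint. dndC pairs with its nearest dndD at gap
≤ 5 kb (ties to the smaller start; unpaired genes are reported).
Restriction presence requires **all three** of dndF/G/H within the
window; pbe presence requires both pbeA and pbeC, the two cassette
members large enough to be annotated reliably. For the pbeAC-centric
classification the modification partner "DndCD" is the *paired cluster*:
the gap is measured to the cluster span, not to each gene separately —
otherwise a cassette whose near edge is 9 kb away would be rejected
because its far gene ends past 10 kb, which is not what "DndCD within
10 kb" means. Categories (dnd_only / mtase_only / both / solitary, and
pbe / dndFGH / both / none) are pure functions of the presence flags
and partition any input set.

## Synthetic data

The generators define the study conditions; their defaults are the
conditions the analyses are quoted under:

* **Genome**: 4 Mb, GC 0.65 (haloarchaeal chromosome scale), with
  exactly 94,316 + strand GATC occurrences. Planted starts are ≥ 4 bp
  apart; spontaneous occurrences are destroyed by local resampling
  (iterated scan-and-mutate outside planted windows) so motif counts
  are exact denominators, not approximations.
* **Calls**: 655 full, 574 hemi(+), 567 hemi(−) loci assigned uniformly
  at random — i.e. 1,229 (+) calls, 1,222 (−) calls, 2,451 in total,
  1,141 of them hemi. This is the unique composition consistent with
  all of the quoted strand counts and fractions at once.
* **Neighbourhoods**: one planted anchor (pbeAC or dndCD cluster) per
  genome with partners at gaps drawn from `gap_range` (default
  0–9 kb, safely inside the 10 kb window); "absent" partners are
  planted *just beyond* the window so the boundary is exercised rather
  than left vacuous. The survey default partitions 553 pbeAC loci as
  128 / 155 / 105 / 165 (dndCD / MTase / both / solitary). A gap range
  that straddles the relevant window is refused.
* **Protein families**: per strain, substitution fractions (d_mod,
  d_res) are drawn from a Gaussian copula over `sub_rate_range`
  (default 0.05–0.5 substitutions/site). A target Spearman correlation
  ρ_s is mapped to the Gaussian parameter 2·sin(πρ_s/6) (the inverse of
  the copula's Spearman function), and ±1 collapse to exactly co- or
  antimonotone draws. Sequences carry exactly round(d·L) substitutions
  to uniformly chosen different residues and no indels, so the realised
  divergence is an exact mismatch fraction and stays interpretable
  against alignment similarity; indel robustness is the aligner's
  concern, not the mutation model's.
* **Homology tables**: one passing row per planted gene plus decoys
  violating exactly one filter rule, with truth labels, so the filter
  is scored without reference to generator internals.

What the fixtures do **not** emulate: sequencing error and kinetic
calling (calls are consumed as ground truth), compositional
heterogeneity and repeats of real genomes, indels and rate variation
across protein sites, phylogenetic (non-independent) sampling of
strains, and operonic gene order within planted cassettes. Passing
tests therefore demonstrate correctness of the *computations* under
controlled conditions, not robustness to every artefact of real
surveys.

## Alignment and coevolution

The aligner is a three-state Gotoh dynamic programme: BLOSUM62
(including B/Z/X and *), gap open 10, gap extend 0.5, a gap of length k
costing open + k·extend, and end gaps free by default — the classic
global-alignment convention in which similarity values are routinely
reported. Identity is identical columns over alignment length;
similarity is positively scoring columns over alignment length (an
identical pair counts as similar even where its self-score is
non-positive, e.g. X/X); gap columns inflate the denominator only.
Traceback ties resolve diagonal > up > left, making the emitted
alignment deterministic. The implementation is vectorised row-wise
(the in-row horizontal-gap recurrence is a prefix max over entry
points), and is verified in tests against exhaustive recursion on short
pairs and an independent pairwise aligner on longer ones.

Similarity rates concatenate each strain's component proteins in fixed
gene order (C then D; A then C) before aligning against the
concatenated reference — averaging per-protein similarities instead is
exposed as a flag, since either reading is defensible and the choice
must simply be pinned. Strains missing a component are skipped with a
warning. The fit reports Spearman ρ as the headline (rank correlation
is invariant under the similarity ↔ divergence flip s → 100 − s applied
to both columns) alongside Pearson r and the least-squares line of
restriction on modification similarity; a constant column flags the fit
degenerate with NaN statistics rather than raising mid-pipeline.

## Distances and trees

Family trees use d = 1 − identity/100 from all-vs-all global alignments
and canonical neighbour joining with deterministic tie-breaking (lowest
index pair at the minimal Q). NJ is exact on additive matrices — the
property suite checks path-length recovery to 10⁻⁹ — and negative
branch-length estimates are clamped to zero with a warning. Full
maximum-likelihood inference with bootstrap support is intentionally
out of scope: NJ is the initial-tree method of the workflow being
modelled and is the right desk-scale tool; thousand-taxon ML runs are
not.

## Assay formulas

EOP = test titre / reference titre; relative viral load =
2^(CT(radA) − CT(repA)) with the sign exactly as defined (chromosomal
reference minus viral target, so more viral DNA ⇒ larger fold);
unadsorbed % = 100 × titre(t) / titre(0). All three are pure and
scale-free where dimensionally required.

## Problem sizes and seeds

The default test-and-acceptance sizes — one 4 Mb genome, a 553-locus
and a 2,322-genome survey, 200-strain coevolution families with 120-aa
references, 100-seed classifier/generator sweeps on 15–50 kb genomes —
were chosen as the smallest sizes at which every statistic reaches its
quoted printing precision while the whole suite stays interactive on a
single CPU. Every random draw flows from one master seed via stable
per-stage hashing (CRC32 of "seed:stage", kept below 2³¹), so stages
are individually reproducible and identical configurations produce
byte-identical outputs. Spearman estimates at n = 200 carry a sampling
SD of roughly 0.065; calibration checks therefore average several
independent draws rather than trusting a single one.
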