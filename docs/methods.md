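# Methods

## The inference problem

All core eudicots share an ancient genome triplication ("gamma"
hexaploidy), while several basal eudicot lineages are ancient tetraploids.
Three histories can relate a basal tetraploidy to the core hexaploidy:

1. the hexaploidy predates the basal/core split and the basal lineage
   added its own tetraploidy on top (basal genomes then carry 6 copies of
   each ancestral chromosome against the core's 3);
2. the split came first and the two polyploidies are independent (2 vs 3);
3. a single tetraploidy at the base of all eudicots is shared, and the
   core lineage later acquired a third genome copy — either by duplicating
   one of its own subgenomes (autohexaploidy) or by hybridization with a
   diploid (allohexaploidy), in which case one of the three core
   subgenomes is a detectable "outlier".

`wgdkit` implements the gene-order machinery that discriminates these
histories — collinear synteny-block chaining, chromosome "word" encoding
with sliding-window local alignment, permutation tests of chromosome
pairing, karyotype event accounting, gene-tree support bookkeeping and
dosage-balance enrichment — together with a simulator of polyploid genome
evolution that generates labelled datasets under each history, so every
stage is testable against a known truth.

Throughout, the basal lineage is called "columbine" and the core lineage
"grape" after the genomes that motivate the defaults; nothing in the code
depends on those organisms.

## Coordinates and chaining

Gene *rank* (ordinal position along a chromosome) is the working
coordinate; base-pair positions are metadata.  Synteny blocks are chains
of homologous gene pairs with strictly increasing query rank and monotone
subject rank, where consecutive matches may skip at most `D` intervening
genes on either chromosome (`D = 0` means strictly consecutive) and a
block needs at least `A` pairs (default `D:A = 20:5`; a relaxed `30:3`
setting serves eroded regions).  Chains maximise pair count; ties break by
smaller total rank gap, then by the lexicographically smallest
`(rank_a, rank_b)` sequence, making output fully deterministic.  Blocks
are extracted by greedy peeling (best chain out, matches removed, repeat);
both parallel and antiparallel (inverted) chains are found.  The affine
internal scoring of chaining tools such as DAGChainer is deliberately not
reproduced: every downstream statistic uses only block membership and
order.  The chaining DP is verified against exhaustive chain enumeration
on all random instances with ≤ 14 matches.

Block divergence is the median Ks (synonymous substitutions per
synonymous site) of its gene pairs after excluding Ks > 10 (saturation);
putative WGD-derived blocks are those with median Ks in the inclusive
band [1, 2].  A block whose every pair exceeds the cap is flagged
"median undefined", never silently dropped.

## Word encoding and window alignment

Homologous regions are recoded as sequences of opaque "word" symbols:
anchors are runs of ≥ 3 strictly consecutive matching genes between the
two genomes (`D:A = 0:3`; `0:2` for more diverged pairs, since `0:4` is
too sparse), words then propagate to paralogous copies through
intragenomic gene-to-gene homology (`0:1`) by transitive closure; only
components containing an anchored gene receive a word.  Gene-order
similarity between a query and a target chromosome is the profile of
Smith–Waterman-style local alignment scores of each length-`N` query
window (and its reversal — inversions are handled by whole-window
reversal, not per-gene strand) against the entire target, with match = 4,
gap = −1 and mismatch = −1.  Only match and gap are canonical; any
negative mismatch preserves the ranking logic, so the mismatch penalty is
exposed as a parameter.  Windows shorter than `N` at the sequence end are
not scored, so a profile has `len(query) − N + 1` entries.  `N` defaults
to 8 from the useful 4–15 range (20–50 for sparse, diverged comparisons).
The alignment kernel is a hand-written linear-gap local DP (numba-jitted,
pure-Python fallback) validated against Biopython's `PairwiseAligner` on
random inputs.

## Pairing statistics

For one basal paralog against its core triplet, the statistic is the
Wilcoxon rank-sum W (number of pairs `x > y` plus half the ties) between
the best-hit profile and the pooled profiles of the other triplet
members.  Significance comes from a permutation null: all triplet words
are pooled and redrawn without replacement into pseudo-chromosomes of the
observed sizes, profiles and W recomputed, and `p` is the one-sided
exceedance fraction on the `1/n_perm` grid (`n_perm = 100` by default).
Because the best hit is *selected*, the permuted reference statistic is
the **maximum** W across pseudo-chromosomes; this mirrors the selection
and keeps the test conservative, so the p-value of a *fixed* target is
super-uniform while the best-hit p is calibrated (this is the detail the
calibration test checks).  "Others" are restricted to the triplet.

A duplicated-partner route guards the autopolyploid case, where the best
hit is diluted by its own duplicate: when the single-best test fails, the
top two profiles pooled are tested against the third (with the top-two
selection repeated inside each permutation), and the pair is accepted only
if the runner-up matches at *partner level* — median profile score at
least 0.9 of the best hit's.  The partner-level guard is what prevents one
strong plus one mediocre target from masquerading as a duplicated pair.

## Scenario classification

Per ancestral color (homology group), the two basal paralog chromosomes
are tested against the core triplet on word sequences restricted to that
color's region.  A triplet votes:

* **allo** — both paralogs have significant, *distinct* single partners
  (exclusive pairing); the leftover member is then itself run as a query
  against the two basal paralogs (`classify_leftover`): if that reverse
  test is significant *and* the match is at partner level (ratio ≥ 0.9 of
  the paralog's own partner), the leftover is a duplicated partner and the
  vote flips to **auto**; otherwise the leftover is the
  hybridization-derived outlier.
* **auto** — directly, when one paralog carries a disjoint duplicated
  partner pair and the other a single, covering the triplet.
* **none** — anything else (collisions, non-significance).

The reverse test exists because a weak lean of the outlier toward one
paralog is *expected* even under hybridization: biased fractionation
leaves one subgenome systematically more complete.  Only a partner-level
match identifies a duplicate.

The history call: a modal basal:core partner-count ratio near 6:3 calls
the extra-WGD history (scenario 1) outright; with a 2:3 ratio, at least
**two** triplets voting allo/auto call the shared tetraploidy (scenario
3) — "none" votes are uninformative rather than contrary, and simulations
under independent histories essentially never produce two spurious votes
(0/40 replicates in the package's calibration experiment) — otherwise the
events are called independent (scenario 2).  Among shared calls the mode
is the majority vote, with ties leaning auto (false allo votes, from
reverse-test misses, are the common error; false auto votes are doubly
guarded).  Reported outlier chromosomes are the union over allo-voting
triplets.

A shared ancestral chromosome fusion is a further discriminator:
`detect_shared_fusion` calls a fusion ancestral when both homologous
portions of the fused query chromosome pair confidently inside their
designated partner sets (a set, to allow for a partner later split by
fission).

## Karyotype accounting

A painted karyotype labels each chromosome as an ordered list of
(ancestral color, WGD copy) segments.  Counting is parsimony-based
("as few events as possible"): each unit split across k chromosomes
implies k−1 fissions; fusions follow from
`initial_units − n_chromosomes + fissions`; a junction joining two copies
of one color is a fusion between WGD-derived paralogous chromosomes.
On simulations without inversions the counts recover the logged history
exactly; inversions that cross a fusion junction interleave the two
units' segments, after which the logged history is no longer expressible
by fusions/fissions alone and the paralog/different split of the painting
may differ (totals and fissions remain exact).  Translocations are not
modelled.

## Gene trees and enrichment

Tree support uses Kimura-corrected protein distances
(`d = −ln(1 − p − 0.2 p²)` over pairwise-ungapped columns; saturation is
an error, not a silent value) and a hand-written UPGMA with a
deterministic lexicographic tie-break, returning ultrametric scikit-bio
trees.  A tree is informative when it holds a leaf from every required
chromosome; it supports the synteny pairing when every expected
(basal, core) pair forms a clade containing only those two chromosomes'
leaves — the clade-containment reading of a loosely specified criterion.
Multiple sequence alignment is out of scope: inputs are equal-length
alignments (simulated or user-supplied).  At realistic divergence depths
the support fraction is intrinsically tiny — the pairing signal lives in
gene order, not in individual gene trees — and the trend test therefore
runs in a shallow-split regime where clean trees do support the pairing.

Enrichment is the standard 2×2 Fisher exact test (two-sided, by
probability-mass summation, since both enrichment and depletion are
reported) per category with Benjamini–Hochberg FDR, on flat gene→term
tables; GO-graph propagation is out of scope.  Tandem families are
connected components of same-chromosome homolog pairs within
`max_gap = 10` intervening genes (the threshold is not canonical and is
exposed).  Note the BH step-up is *not* idempotent on arbitrary adjusted
vectors; its fixed points are constant vectors, which is what the
idempotence test uses.

## The simulator

`generate_scenario` builds an ancestral genome of 7 chromosomes × 200
genes (unique family per gene, dosage-sensitivity flags at 8%), then
applies the configured history.  Event ages are expressed directly in Ks
units (the clock rate is absorbed): tetraploidy at 1.5, basal/core split
at 1.35 and hexaploidy at 1.2 under scenario 3, matching the observed
structure of two within-core Ks peaks with the basal-core ortholog peak
between them.  Scenario 2 defaults move the split to 1.7; scenario 1 uses
1.5/1.3/1.1 with the extra basal WGD at 0.8 (an age the history requires
but the three canonical knobs cannot express, hence the extra `t_extra`
parameter).

Each inter-event interval applies one diploidization round: biased
fractionation (each multi-copy, non-dosage-sensitive family loses one
copy with probability 0.25, from the designated sensitive subgenome with
probability 0.7 — dosage-sensitive families are never reduced), 4
inversions (uniform breakpoints, length-weighted chromosome choice), and,
in terminal intervals, tandem duplication (3% per gene, copy inserted at
rank+1 with a uniform birth age).  The round in the *shared* tetraploid
ancestor is what differentiates the two subgenomes before the split, and
its inheritance by both lineages is the signal every pairing test
detects.  Karyotype plans default to the inferred histories: one
ancestral fusion in the tetraploid ancestor (joining one copy each of the
first two colors), 7 basal fusions (5 between different colors, 2 joining
whole paralogous chromosomes) plus 1 fission (13 → 7 chromosomes), and 1
core fusion (20 → 19).

Hexaploidy adds subgenome "C": autopolyploidy duplicates the first
subgenome's chromosomes; allopolyploidy merges an independently evolved
copy of the ancestral genome (uniform deletions at the fractionation
rate and a double inversion round — the hybridizing diploid is modelled
as substantially diverged in gene order, the analogue of the reduced
genomes that formed allopolyploid wheat or *Arabidopsis suecica*).  Its
*sequence* divergence age is set at the hexaploidy age (configurable):
a simulator abstraction — a real progenitor's Ks divergence would predate
the tetraploidy — chosen so the within-core Ks distribution keeps exactly
two age peaks while the discriminating signal stays in gene order.

Ks per homolog pair is its divergence age plus zero-mean Gaussian noise
(σ = 0.15, truncated at 0); pairs diverged at the same event share an
age.  Every stochastic choice is logged; replaying the log from the
ancestral genome reproduces the emitted genomes exactly, and identical
config+seed gives byte-identical output on any platform (all randomness
flows from `numpy.random.default_rng` seeded via `SeedSequence`).

What the simulator does **not** emulate: nucleotide/codon evolution (Ks
is assigned, not measured), transposable elements, gene conversion,
segmental duplications beyond tandems, translocations, and
population-level processes.  Passing tests therefore show the *method*
recovers planted histories under these idealised conditions; they do not
certify performance on real annotations with fragmented assemblies or
noisy homology calls.

## Problem sizes and numerical choices

The bundled experiments use: full size (7 × 200 genes, 100 permutations)
for single-dataset checks such as the true-pairing significance; 7 × 100
for the 20+20-replicate partner-ratio experiment; and 7 × 120 with 50
permutations and up to 5 color triplets per replicate for the
120-replicate scenario-recovery design (~75 s total).  Alpha defaults to
0.05, mirroring the reported p = 0–0.05 band.  Colors eligible for
pairing analysis are those whose basal units sit on two distinct
chromosomes and core units on three (fissioned or co-fused units are
skipped).  Degenerate inputs are explicit errors (empty Wilcoxon samples,
saturated Kimura distances, infeasible event counts) or flagged values
(undefined block medians, zero-margin Fisher tables at p = 1).

## Known limitations

* Real-data mode covers ingestion, chaining, filtering and Ks summaries;
  the pairing tests additionally need homologous-region definitions
  (color maps), which on real genomes come from curated triplet tables
  rather than a ledger, and are supplied through the library API.
* The partner-level threshold (0.9) in the duplicated-partner logic is a
  calibrated design constant, not a fitted parameter; histories whose
  added subgenome diverged only marginally before the merge blur the
  auto/allo boundary by construction, and no threshold can separate them.
* The event counter assumes fusions/fissions/inversions only; histories
  with translocations will be attributed extra fusions and fissions.
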