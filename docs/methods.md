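# Methods

## Problem and design

The package detects genes of algal origin in an animal proteome by the
standard two-evidence design: a similarity screen that flags queries far
more similar to donor-group homologs than to non-donor homologs, followed
by phylogenetic confirmation that donor and recipient sequences form a
supported clade.  Because real screens of this kind cannot be validated
directly (the true history is unknown), the package ships a sequence
simulator that implants transfers with known ground truth; every
quantitative claim the package makes is computed on that benchmark.

## Screening statistic

For query q, S_d(q) is the best Smith–Waterman bit score against any
donor-group subject and S_n(q) the best against any non-donor subject
(close relatives, other eukaryotes, prokaryotes).  Recipient-group
sequences are excluded from both databases: a query's own-lineage paralogs
are uninformative about origin and would otherwise mask the signal.
A query is a candidate iff S_d/S_n > τ (τ = 1.5, strict) or S_n is absent
while S_d is present ("donor-only distribution").

* **Identifiable homolog** is operationalised as ≥ 50 bits.  A fixed
  bit-score floor is database-size independent, unlike an E-value cutoff
  which would depend on search-space parameters the method does not
  otherwise need.
* Bit scores use fixed gapped-BLOSUM62 Karlin–Altschul constants
  (λ = 0.267, K = 0.041).  Only ratios and a floor are consumed, so the
  constants' exact values are not critical; fixing them keeps results
  reproducible across databases.
* Alignment is exact Smith–Waterman (affine gaps; a gap of length g costs
  11 + g).  At desk scale exactness is affordable and lets the scorer be
  verified against an independent naive dynamic program; a heuristic
  search tool could be substituted behind the same interface.
* Ties at exactly τ are non-candidates (the criterion is "over" the
  threshold).

## Alignment and trimming

Candidate homolog sets are aligned progressively: an NJ guide tree on
3-mer distances, then profile–profile global alignment with affine gaps,
merging leaf-to-root.  Column scores are **frequency-weighted (average)
sum-of-pairs** BLOSUM62 scores with gap characters contributing zero.
Averaging rather than summing is deliberate: summed scores grow with
profile depth while gap penalties stay constant, which in development
caused deep profiles to shred alignments with spurious gaps; averaged
scores keep the score-to-penalty balance depth-invariant.

Manual alignment curation is replaced by two deterministic column filters:
drop columns with gap fraction > 0.5, and optionally columns whose
majority residue falls below a frequency floor (off by default).  Rows
(sequences) are never removed automatically — there is no defensible
automatic criterion for "misaligned sequence" — but a per-row mean-identity
report is available for human review.

## Distances, trees, support

Pairwise distances use Kimura's empirical correction
d = −ln(1 − p − p²/5), with p the fraction of differing residues over
mutually ungapped columns.  The argument reaches zero at p ≈ 0.8541;
saturated pairs (and any correction above 10) are capped at d_max = 10
with a warning rather than aborting, since simulated datasets legitimately
contain saturated pairs.  Neighbor-joining is the standard Saitou–Nei
agglomeration with Q-matrix ties broken at the lowest index pair and
negative branch estimates clamped to zero; on additive matrices it
provably recovers the generating tree, which the tests verify.  Bootstrap
pseudoreplicates (default 100) resample columns with replacement; supports
are the percentage of replicates containing each split of the
full-alignment NJ tree, rounded half-up to integers.  The majority-rule
consensus of the replicate forest is also available; supports are mapped
onto the full-alignment tree because that is the tree reported.

## Monophyly rule

On the unrooted candidate tree, a side S of a split **qualifies** when it
contains every recipient-group leaf, at least one donor-group leaf, and no
leaf from any other group.  The verdict is *pass* when a qualifying side
has bootstrap support ≥ 70, *uninformative* when the tree has no leaf
outside donor ∪ recipient, and *fail* otherwise; among supported
qualifying sides the smallest is reported.

One subtlety: the complement of a single outside-group leaf is a split of
*every* tree on the same leaf set, so it can never be evidence of
monophyly — otherwise a tree in which recipients interleave freely with
outside groups would still pass whenever exactly one outside leaf is
present.  Such tautological sides are excluded from qualification.  Other
trivial splits count as support 100 where they qualify, since column
resampling cannot remove a pendant edge.

The 70% rule is applied to the distance-bootstrap support alone; a
likelihood analysis could supply a second support value, but the decision
rule here uses one.

## Classification and families

Categories: *algal_phylogenetic* (monophyly pass), *algal_distribution_only*
(donor-only distribution with an uninformative or unbuildable tree),
*candidate_unresolved* (screening candidate, monophyly fail or absent),
*rejected* (everything else).  Every query receives exactly one category.
Shared domain architecture (the query's ordered domain list occurring in a
donor sequence and in no other non-recipient group) is recorded as
corroborating evidence only; it never changes a category on its own.

Algae-related genes are clustered into families by single linkage at 30%
identity.  Identity here is the local-alignment identity count normalised
by the shorter sequence length, not by aligned columns alone: two
unrelated proteins sharing a 20-residue island can exceed 30% identity
within that island, and column-normalised identity was observed (in
development) to merge unrelated genes into one family.  Length
normalisation leaves genuine family members (full-length alignments at
30–80% identity) unaffected.  A Robinson–Foulds-based note on topology
similarity between member trees is attached for information; it is not a
clustering criterion.

## Simulator

Sequences evolve site-independently under the 20-state equal-rates
(Poisson) model: on a branch of length t (expected substitutions/site)
each site changes with probability (19/20)(1 − e^(−20t/19)), to a uniform
other state.  The model was chosen over empirical matrices (WAG/JTT)
because it admits the closed-form identity decay

P(identical) = 1/20 + (19/20)·e^(−(20/19)d),

which provides an analytic oracle for the simulator itself; the pipeline
under test is model-agnostic.  No indels are simulated, so correct
alignments are gapless and alignment quality can be audited exactly.

The species tree is fixed-shape: four clades arranged
((recipient, close_relative), (donor, other_eukaryote)) with ultrametric
balanced subtrees.  Geometry in fractions of the vertical depth v
(default 1.2): within-clade height v/8, recipient and close stems v/4,
donor and other stems v/8, central edge 3v/8.  This places recipient–donor
leaves exactly v apart, recipient–close at 3v/4, donor–other at v/2.  Two
properties of this layout matter:

* Non-donor lineages sit on **both** sides of the tree.  With a single
  coherent outgroup clade, the complement of that clade is always a
  donor+recipient split, and every vertical family would pass the
  monophyly test; interleaving the non-donor groups is what makes the
  test discriminating, as in real multi-group databases.
* At v = 1.2, most within-family identities fall in the 30–80% band
  typical of curated cross-kingdom families (seed-1 benchmark: median
  0.37, 76% of pairs in band).

Transfers are implemented as replacement: for a transferred family the
recipient subtree is re-evolved from a randomly chosen donor leaf's
sequence, with the new recipient ancestor transfer_depth (default 0.3)
beyond that leaf and the subtree's own branch lengths reused below it.
Replacement (rather than addition) keeps per-family ground truth
unambiguous.  The number of transfers is exactly
round(transfer_fraction × n_families).  Per-family rate multipliers are
drawn uniformly from rate_jitter = (0.9, 1.1) — enough to decorrelate
family-wise scores without pushing distant homologs below the detection
floor; real rate variation across families is far larger, which is one
reason benchmark performance overstates performance on real data.

Default study conditions (the "standard benchmark"): 50 families, 20 taxa
(6 donor, 6 recipient, 4 close, 4 other), 300 residues, transfer fraction
0.2, transfer depth 0.3 vs vertical depth 1.2, five replicate seeds.
These sizes keep a full end-to-end run under a minute while leaving every
stage (screening, alignment, 100-replicate bootstraps, clustering)
genuinely exercised.

## What the benchmark does and does not show

Passing tests demonstrate: the algorithmic cores are exact (verified
against independent oracles), the simulator matches its closed form, and
under the stated conditions the decision rules recover implanted transfers
with high sensitivity and near-zero false positives.  They do **not**
demonstrate performance on real proteomes, where gene families have
indels, heterogeneous rates across sites and lineages, duplications and
losses, database taxon sampling is ragged, and ancient transfers are far
more diverged than the benchmark's.  The distribution-only category in
particular depends entirely on database completeness, which the simulator
idealises.

## Numerical and degenerate-input choices

* Seeding: one integer seed fans out through numpy SeedSequence spawning
  to the simulator and to each candidate's bootstrap, so full runs are
  byte-identical under a fixed config.
* NJ ties: lowest (row, column) index pair; guide-tree and report
  orderings are lexicographic; supports round half-up.
* Bootstrap replicates in which some pair shares no ungapped column are
  redrawn (at most 10 attempts, logged).
* Alignments of identical rows yield zero-length star trees without error.
* Queries sharing an id with a subject are excluded from that comparison
  with a logged note.
* Unknown residues map to X (protein) / N (nucleotide) at the file
  boundary; domain coordinates are 1-based inclusive externally.

## Known limitations

* Distance-based trees only; no likelihood stage, no substitution-model
  selection, no among-site rate heterogeneity.
* No indel simulation; the trimming stage is exercised by synthetic gapped
  fixtures rather than by the simulator.
* Family clustering uses identity linkage only; topology similarity is
  reported but not enforced.
* The six-frame translation utility keeps frame-suffixed ids; mapping
  peptides back to source ESTs is left to the caller.
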