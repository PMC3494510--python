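# xenoscreen

Phylogenomic screening for anciently acquired algal genes in animal
proteomes.

Animal genomes occasionally carry genes that arrived not by vertical
descent but by horizontal transfer from algae or cyanobacteria — relics,
in some lineages, of historical plastids or phagotrophic feeding.
`xenoscreen` implements the classic two-stage screen for such genes and a
simulator that generates proteomes with implanted transfers so the whole
pipeline can be validated against known ground truth.

## Method

**1. Similarity screen (alien / bit-score ratio).**  Every query protein is
aligned by full Smith–Waterman (BLOSUM62, affine gaps 11/1) against a donor
database (algae, cyanobacteria) and a non-donor database (close relatives,
other eukaryotes, prokaryotes; the recipient's own lineage is excluded from
both sides).  Raw scores become bit scores via the Karlin–Altschul
conversion, bits = (λ·S − ln K)/ln 2 with λ = 0.267, K = 0.041.  A query is
a **candidate** when

&nbsp;&nbsp;&nbsp;&nbsp;best donor bits / best non-donor bits **> 1.5**,

or when it has identifiable homologs (≥ 50 bits) only in donor groups.

**2. Phylogenetic confirmation.**  Each candidate's homolog set is aligned
(progressive alignment over an NJ guide tree, automated column trimming),
converted to Kimura-corrected distances d = −ln(1 − p − p²/5), and analysed
by neighbor-joining with **100 bootstrap pseudoreplicates**.  A candidate is
confirmed (**algal_phylogenetic**) when some tree split unites all
recipient sequences with at least one donor sequence — and nothing else —
at **≥ 70%** bootstrap support.  Candidates whose trees are uninformative
but whose homologs are donor-exclusive become **algal_distribution_only**;
the remainder are **candidate_unresolved** or **rejected**.

Confirmed genes are grouped into families by single-linkage clustering at
30% identity, and shared donor-exclusive domain architectures (from an
optional Pfam-style annotation table) are recorded as corroborating
evidence.

## Worked example

```bash
xenoscreen simulate --seed 1 --outdir data/seed1
xenoscreen run --query data/seed1/query.fasta \
               --subjects data/seed1/subjects.fasta \
               --taxonomy data/seed1/taxonomy.yaml \
               --outdir runs/seed1 --seed 1
```

The simulated dataset holds 50 gene families across 20 taxa (6 algae,
6 animals, 4 fungi, 4 plastid-bearing protists); 10 families were re-rooted
onto an algal donor lineage at transfer depth 0.3 substitutions/site
(vertical depth 1.2).  The run prints

```json
{
  "algal_phylogenetic": 10,
  "algal_distribution_only": 0,
  "candidate_unresolved": 0,
  "rejected": 40
}
```

— all 10 implanted transfers confirmed phylogenetically, all 40 vertical
families rejected.  At the screening stage the candidate bit-score ratios
span 1.88–4.40 while vertical families stay well below the 1.5 threshold;
`runs/seed1/gene_calls.tsv` lists the per-query scores, monophyly verdicts
and clade supports, and `runs/seed1/trees/` holds one bootstrap-annotated
Newick per candidate.

The same steps are scripted as a narrative analysis under `analysis/`
(01 simulate → 02 screen → 03 calls → 04 multi-seed benchmark), writing
tables to `results/`.  Across seeds 1–5 the pipeline recovers 50/50
implanted transfers with zero false positives among 200 vertical families.

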