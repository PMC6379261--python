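# Methods

This note records the models, parameter choices and numerical
conventions behind `taxongauge`, and what the synthetic-data tests do
and do not demonstrate about real assemblies.

## Fragment ANI

The query genome is cut per contig into consecutive, non-overlapping
windows of `fragment_length` (default 1,020 bp, the convention of the
fragment-based ANI scripts in wide use); trailing remainders and
fragments with more than 50% ambiguous bases are discarded, and
fragments never span contig boundaries. Each fragment is aligned
locally against both strands of the reference. Because the method is
defined operationally by BLASTN, any reimplementation must fix concrete
scoring; ours is match +1, mismatch −2, gap open −4, gap extend −2
(affine; a k-base gap costs 4 + 2(k−1)), seeded by exact 15-mers
grouped into 64-column diagonal bands, with the fragment realigned
against a padded reference window around the best bands
(`Bio.Align.PairwiseAligner`, local mode). On desk-scale genomes the
seeded search reproduces exhaustive Smith–Waterman optima; the test
suite asserts score equality against an independent dynamic-programming
implementation (`skbio.alignment.pair_align`) on ~1 kb × 6–10 kb
instances. Sequences diverged beyond roughly 40% start to lose 15-mer
seeds; that regime is far below the identity filter and irrelevant to
species delineation.

A hit qualifies when identity ≥ 30% and ≥ 70% of the fragment aligns
(`min_identity`, `min_alignable`); qualifying hits contribute their
full identity (filtered, not trimmed), with identity counted over
alignment columns, gap columns counting against it. One-way ANI is the
unweighted mean identity over qualifying hits; the two-way value
weights the two directions by hit counts. Self-comparison is exactly
100. Pairs with no qualifying hits in either direction are flagged "no
signal" and propagate as missing matrix entries; clustering refuses
matrices with missing entries rather than imputing.

## POCP

For each protein of proteome A, the best local alignment against
proteome B under BLOSUM62 (gap open −11, extend −1) is evaluated
against three filters: E-value < 1e−5, identity ≥ 40% of alignment
columns, and coverage ≥ 50% of the query ("alignable region of the
query" read per-direction). `C1` counts A-proteins passing in B, `C2`
the converse; `POCP = 100(C1+C2)/(T1+T2)`. No reciprocal-best
requirement: the statistic counts conserved proteins, not ortholog
pairs. The E-value is a Karlin–Altschul approximation with
ungapped-regime BLOSUM62 constants (K = 0.041, λ = 0.267) over a search
space of query length × total target residues; no external BLAST is
run. At the 40%/50% cut-offs the identity and coverage filters
dominate, so the approximation changes essentially nothing — the
empirical-null test (shuffled decoys) confirms that random best hits
clear E < 1e−5 almost never. Genus assignment takes the arithmetic
mean POCP against each candidate genus (self-comparisons excluded,
intra-genus self-pairs likewise excluded from group means); exactly one
genus ≥ 60% names the genus, none → "neither", several → "ambiguous".

## Tetranucleotide signatures

Counts of all 256 4-mers in sliding windows (step 1), forward strand
only (the compseq default; strand-summed counting is available behind a
flag but off by default), windows containing any non-ACGT character
skipped, counts summed over contigs. Frequencies (not z-scored counts)
enter a PCA with column centering only; scores on the first three
components feed average-linkage hierarchical clustering cut at a caller
chosen height, with labels A, B, … assigned by cluster size descending.
The clustering is a deterministic surrogate for by-eye grouping of a
3-D PCA plot; no specific cut height is claimed to regenerate any
published cluster lettering, and the packaged evidence panel therefore
carries its TNA cluster column as transcribed reference data rather
than a recomputed output.

## Distance phylogenetics

Marker genes arrive pre-aligned (aligned FASTA); alignment itself is
upstream of this package, and the synthetic generator emits aligned
data directly. Gap handling is complete deletion: every column with
'-', '.', 'N' or 'X' in any row is removed before analysis. MLSA
concatenates gap-filtered genes in a fixed order (atpD–leuS–rplB–gyrB
for the shipped four-gene scheme). Distances are p-distance or JC69
(`d = −(3/4)·ln(1 − 4p/3)`, undefined at p ≥ 0.75, which errors naming
the pair). Trees come from in-repo NJ (canonical Q-criterion,
deterministic lexicographic tie-breaking, negative branch lengths
clamped to zero with a log entry, unrooted trifurcating root) and UPGMA
(node heights tracked; output ultrametric to 1e−9); both are
cross-checked in the tests against `skbio.tree.nj` and closed-form
3/4-taxon constructions. Likelihood tree estimation is deliberately out
of scope: at the genus/species resolution this pipeline needs, clade
membership from distance trees is equivalent, and the consensus engine
consumes clade assignments, not branch lengths. Bootstrap resamples
columns with replacement (seeded, deterministic); support is the
percentage of replicates containing each internal bipartition.
Midpoint rooting is provided; no outgroup-aware rooting.

## Consensus reclassification engine

Thresholds: POCP genus boundary 60%; ANI species threshold 90% for
*Cupriavidus* and for clusters containing the *R. pickettii* type
strain, 95% for other *Ralstonia*. ANI clusters are the maximal UPGMA
subtrees (on d = 1 − ANI/100) whose merge distance is below
1 − threshold/100; cut extraction is monotone in the threshold and
always yields a partition. Precomputed cluster ids (as in the packaged
evidence panel) are accepted in place of a genome-derived matrix.

Decision order per strain:

1. **Genus** = the POCP call when it names exactly one genus;
   "neither" → `Other`; ambiguous/missing → majority genus of the
   16S and MLSA clades; no usable method at all is an error.
2. **Species** from the ANI cluster. A species *anchors* a cluster via
   its type strain when the type strain is in the panel; otherwise via
   a strict plurality of at least two strains currently carrying the
   name (a single strain cannot confirm a grouping). Within the
   *R. solanacearum* complex the cluster phylotype overrides: I/III →
   *R. pseudosolanacearum*, II → *R. solanacearum*, IV → *R. syzygii*
   (a strain's own phylotype first, else the cluster majority).
   Multiple anchors in one cluster (species indistinguishable at the
   threshold) keep the strain's current name when it is among them.
3. In an **unanchored** cluster, a named strain keeps its name unless
   contradicted — its species anchors elsewhere, or every available
   phylogenetic placement (16S/MLSA) puts it outside — in which case it
   demotes to "<genus> sp.". An unnamed strain in a *singleton* cluster
   (where ANI carries no grouping information) is promoted to a named
   species only when at least two of 16S clade, MLSA clade and the TNA
   cluster's plurality species agree; otherwise it stays "sp.".
4. Per-method agreement flags (agree / conflict / unavailable) are
   attached for 16S, MLSA, ANI, TNA and POCP; ANI takes precedence in
   species conflicts, and conflicts are recorded, never dropped. The
   flags are an algorithmic approximation of judgments that source
   reclassification tables make qualitatively; the names and the
   changed count are the contract, the flags are diagnostics.

Steps 2–3 extend the bare "type strain in cluster" rule: panels
routinely contain species whose type strain has no genome available,
and singleton clusters are common at 95%. Plurality anchoring,
keep-unless-contradicted and the 2-of-3 singleton rule are the minimal
deterministic formalisation of how such panels are actually resolved.

The packaged evidence table transcribes a published 150-strain
*Cupriavidus*/*Ralstonia* panel (SHA-256 checked at load). Current
names are the GenBank organism names of the time — for part of the
*R. solanacearum* complex these already reflected the
phylotype-based species split — so "changed" means a genuine conflict
between deposit name and genomic evidence. On this panel the engine
proposes 41 changes among 150 strains.

## Motif scanning

IUPAC consensus patterns (alternative groups like `(A/T)` normalised to
IUPAC codes) are scanned on both strands by counting class violations
per window; hits within the allowance are all reported (no greedy
masking), minus-strand hits in plus-strand coordinates. A genome `N`
never satisfies a non-`N` class. Shipped patterns: DnaA box
`TTWTNCACA` (≤ 1 mismatch), RepA iteron `CGCWGAWWYVGGTWCGS` and TrfA
iteron `VHGCCCCYCAWGTGTCA` (≤ 2 mismatches each; the iteron allowance
is a package default — the sources state allowances only for DnaA
boxes — and is configurable). Whole replicons are scanned; windowing
around a replication origin is the caller's job.

## COG enrichment

One 2×2 Fisher exact test per category (in-category vs not, replicon A
vs B), two-sided by the minimum-likelihood rule (scipy's convention;
the sidedness is a documented choice, the sources do not state one);
any zero margin gives p = 1 by convention. BH step-up q-values are
computed within the family of categories of one replicon pair (stars in
per-pair comparisons are per-pair; a global family is available by
adjusting the pooled p-values). Counts are protein–category
assignments: a multi-category protein contributes once per assigned
category.

## Synthetic data

Generators emulate: multi-contig genomes of controlled length and GC
(i.i.d. bases); divergence by site-wise substitution (uniform among the
three alternatives — JC-style, adequate for threshold-level recovery)
with optional geometric-length indels, off by default so expected
identity stays 1 − rate; strain panels with planted clade identity
structure (divergence split evenly between clade and strain branches,
so within-clade identity ≈ within², pairwise); proteome pairs with a
planted shared-ortholog fraction (orthologs at 5% amino-acid
divergence, the rest random); marker genes evolved site-wise under JC
along a given newick tree; and planted motif instances with exact
coordinates. Every generator takes a seed and returns its ground truth
separately from the data.

What the synthetic fixtures do **not** emulate: rearrangements,
horizontal transfer, repeats, mobile elements, assembly gaps and
contamination — the features that make real ANI/POCP values noisier
than the simulations. Passing the recovery tests shows the estimators
are calibrated under their own model (e.g. ANI 95.0 ± 0.5 at
substitution rate 0.05), not that real-genome values carry that
precision; accession-based spot checks against deposited assemblies are
supported by the same entry points (`two_way_ani`, `percent_identity`,
`genome_stats`, `mean_pocp_vs_group`) when assemblies are available
locally.

## Problem sizes and numerics

The shipped tests run the full pipeline at desk scale, chosen as the
smallest sizes at which the statistical claims are meaningful:
ANI calibration on 102 kb (100 fragments per direction), oracle
equivalence on ≤ 10 kb references, monotonicity on 10 kb over rates
0.01–0.15; POCP on 30–40-protein proteomes; PCA separation on 20 kb
genomes at GC 0.45 vs 0.65; bootstrap on 6 taxa × 1.5 kb with 50–400
replicates; motif oracles on 8–20 kb; Fisher enumeration over all
tables with margins ≤ 12 (sampled). Floating-point contracts:
UPGMA ultrametricity and newick branch-length round-trips to 1e−9; NJ
path-length recovery on additive matrices to 1e−6; Fisher p-values to
1e−7 relative; PCA variance fractions sum to 1 within 1e−9.
Coordinates are 0-based half-open throughout; strands are `+`/`−`;
sequence comparisons are case-insensitive and IUPAC ambiguity codes are
accepted (counted in lengths, excluded from GC and 4-mer windows).

## Known limitations

- ANI identity depends mildly on the fixed alignment scoring; values
  can drift at the ~0.1–0.5 point level relative to other
  BLASTN-parameterised implementations. Threshold decisions at 90/95%
  are robust to this; borderline pairs should be inspected.
- The E-value approximation in POCP uses ungapped-regime constants for
  a gapped search; it is conservative only in the regime the filters
  already dominate.
- TNA cluster lettering is cut-height dependent and not comparable
  across panels.
- The decision engine resolves ties deterministically (lexicographic);
  panels with genuinely ambiguous plurality anchors should be reviewed
  manually via the conflict flags.
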