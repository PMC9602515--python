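# Methods

`ogpeel` implements a semi-automatic classification workflow for large plant
gene families, with the GDSL-type esterase/lipase (GELP) family as its
reference case.  The workflow has four stages: iterative divergent-cluster
peeling, orthogroup delineation at the monocot/dicot split, gene-structure
consistency checks, and profile-based expansion of the classification to new
proteomes.  A synthetic gene-family generator supplies truth-labelled data so
that each stage's recovery behaviour can be measured.

## The peeling procedure

Large families defeat single-pass phylogenetics: the more divergent the
sequence set, the fewer alignment columns survive block cleaning, and the
worse the resolution.  Peeling exploits the family's deep structure.  Each
round runs align → mask → distance → NJ tree → bootstrap supports, then
removes the best *divergent cluster* and repeats on the remainder.  Because
each removal makes the remaining set less divergent, masked alignments grow
longer round by round (the bundled curated GELP trace goes from 102 retained
columns at 248 sequences to 253 columns at 82).

"Clearly separated" is operationalized as a per-edge statistic: an edge
qualifies when

* bootstrap (or imported) support ≥ `min_support` (default 0.90, the support
  level used throughout the curated analysis),
* its smaller side has ≥ `min_cluster_size` leaves (default 5) from
  ≥ `min_species_in_cluster` species (default 2; species, not lineages, so
  clusters thin in the outgroup still qualify),
* the divergence ratio r = stem branch length / median internal branch
  length of the tree is ≥ θ (default 3.0).

The qualifying edge with maximal r is peeled (ties: higher support, then
smaller cluster, then smallest member id).  Termination: when the disjoint
qualifying clusters of the current tree jointly cover all (or all but fewer
than `min_cluster_size`) remaining sequences, they all become terminal
clusters in a single step — this reproduces the situation where the final
tree cleaves into several clusters at once rather than shedding one.
Otherwise, when no edge qualifies, the remainder is one terminal cluster.
Removed plus terminal clusters always partition the input; the `PeelTrace`
records totals, per-species counts, retained positions, and supports per
step, and validates the subtraction arithmetic.

θ and the terminal rule are this package's operationalization of a judgment
the original workflow made by expert eye; both are exposed in `PeelParams`,
and there is no claim that a given real dataset peels into exactly the same
clusters a curator would choose.

## Block masking

`msa_mask` re-implements conservation-block cleaning in the Gblocks style
with the *relaxed* options appropriate for divergent families: smaller final
blocks (`BL` = 5), gaps tolerated inside blocks (`gap_policy` = "half":
a column dies only when more than half its rows are gaps), and less strict
flanking (`FS` = `IS` = ⌊n/2⌋+1).  The five rules run in a fixed order
(classify columns → reject long non-conserved stretches (`CP` = 8) → trim
flanks to highly conserved columns → apply the gap policy → drop short
blocks).  Conservation counts ignore gaps and X.  Only the three relaxations
are inherited from the reference workflow; the numeric defaults are this
package's and bit-identity with any external binary is not claimed.
Monotonicity (tightening the gap policy or raising `IS` never adds columns)
is property-tested.

## Trees

The built-in inference path is deliberately desk-scale: Kimura-corrected
protein distances d = −ln(1 − D − 0.2·D²) over mutually non-gap, non-X
retained columns (D ≥ 0.85 capped at 5.2), canonical neighbor joining with
a lowest-index tie-break and negative-branch clamping (deficit moved to the
sibling edge), and bootstrap bipartition frequencies in the support slot.
The rest of the pipeline needs only the (topology, lengths, per-edge support
in [0,1]) interface, so maximum-likelihood trees with aLRT supports can be
injected as newick at any stage boundary; internal-node labels > 1 are read
as percentages and normalized, since both support scales occur in practice.
NJ correctness is tested against an additivity oracle (random trees →
path-length matrices → exact topology recovery).

## Orthogroup delineation

Orthogroups are defined relative to the last common ancestor of monocots and
dicots: the smallest clades containing both lineages.  Trees are rooted on
the edge isolating the maximal outgroup-only clade (non-monophyletic
outgroups root at the best split, with a warning).  Delineation recurses on
the lineage content L(v) of each clade, outgroup leaves ignored:

a. ≥ 2 lineage-mixed children → v is a duplication that predates the split;
   recurse into every child (pure children become lineage-specific OGs —
   this is how dicot-only OGs arise);
b. exactly one mixed child → recurse into it; a pure sibling becomes its own
   OG when its subtending support ≥ 0.90 and it spans ≥ 2 species, else it
   merges into the first OG delineated inside the mixed sibling;
c. mixed with no mixed child → one OG.

Rule (b) is the central curator judgment of the workflow (merge a
lineage-specific expansion into its sister OG, or split it out); the
support + two-species criteria reproduce both outcomes, and a
curator-override table can pin individual genes to named OGs for the
genuinely judgment-bound cases.  Outgroup sequences are annotated to the
nearest OG for reporting but never counted as members.  OGs are lettered
`a, b, c …` in tree-traversal order (single-OG clusters get no letter);
whether the original lettering followed traversal or curation order is not
knowable, so traversal order is fixed here.

## Exon architecture and tandem arrays

Intron positions are mapped through the CDS to residues (a junction inside a
codon belongs to that codon's residue, i.e. residue ⌈offset/3⌉) and then to
alignment columns.  An OG's consensus architecture is the modal
junction-column set; members matching it within ±5 columns per junction are
conformant, and a member missing exactly one modal junction while matching
the rest is reported as a fusion of the adjacent exons.  The consensus is
assigned to one of five canonical architecture classes (two-exon with a
dominant second exon; six-exon; and three five-exon variants distinguished
by the second/third junction) by relative junction positions, else "novel".

Tandem arrays group family genes on one chromosome whose neighbours are
separated by at most `max_intervening_genes` (default 5) other annotated
genes, using gene ranks computed from the full annotation at GFF3 read time.
Arrays spanning two OGs witness duplications older than the OG split.

## Profiles and expansion

Per-OG profiles are position-specific scoring models: match columns are
alignment columns with ≤ 50% gaps; emissions are log₂((c_a + q_a)/(N+1)/q_a)
with background frequencies q estimated from the curated set; X scores 0
everywhere.  Scoring is query-local / profile-global dynamic programming
with affine gaps (open 4 bits, extend 0.25 bits), batched with numpy.
E-values come from a Gumbel null fitted by moments to the scores of 200
length-matched shuffles of member sequences, scaled by the database size;
assignment goes to the minimum-e-value profile when it clears 1e-3 (the
threshold used for the family search), with the runner-up margin exported so
ambiguous calls are auditable.  Pairwise ranking for the top-k consensus
rule (assign only when the top min(k, hits) labels are unanimous, k = 5) is
Smith–Waterman under BLOSUM62 with gap open 11 / extend 1.  These scorers
replace external search tools so the whole decision layer is deterministic
and dependency-free; external tabular rankings can be imported instead.
Best-profile assignment is known to be least reliable for taxa outside the
monocot/dicot clades (the outgroup): such genes match some profile well but
belong to no OG by definition.

## The synthetic generator

`simfam` emulates the data regime the workflow assumes, on a nine-species
angiosperm panel (1 outgroup, 3 monocots, 5 dicots; unit root-to-tip depth)
or any configured panel/tree:

* **Clusters**: ancestral genes grouped into divergent clusters whose stem
  branches (default 1.5 expected substitutions/site) dwarf within-cluster
  divergence (OG stems 0.10) — long-stem separation is what the peel
  statistic detects.  Each cluster carries a protected active-site motif
  variant (GDSL, GDSY, GSSI, GDSI) at fixed columns.
* **Birth–death**: per-gene duplication/loss along the species tree.  A gene
  copy present at the monocot/dicot ancestor founds a true OG (pre-split
  duplications found sibling OGs); outgroup genes belong to no OG.  Per-OG
  rate multipliers (35% of OGs essentially stable; the rest lognormal,
  σ = 1.1, capped at 4.5) and a duplication intensity that decays as
  exp(−2t) with time since the ancestor reproduce the skewed copy-number
  spread of curated family tables — many single-copy OGs, a minority of
  several-fold, largely shared expansions — with loss uniform in time.
  Duplicates are tandem with probability 0.6 (adjacent ranks, shared array
  id) else dispersed.
* **Sequences**: stationary per-site replacement to background-frequency
  residues with gamma rate heterogeneity, no indels; hence the true
  alignment is the sequence set itself.  This is the generator's main
  abstraction: alignment inference and alignment error are outside the test
  loop, so green tests certify the clustering, delineation and
  classification layers, not robustness to misalignment.
* **Structure**: OG-level exon architectures from the five canonical
  classes, rare per-branch intron gain/loss (p = 0.02), pseudogene and
  truncation flags that annotate but never alter records (flagged sequences
  are tagged and kept, as in the curated workflow).

Everything is deterministic given the seed; `emit_fixture` writes
FASTA/GFF3/TSV files that round-trip through `core_io`.

## Problem sizes and measured properties

The test and acceptance workloads use desk-scale conditions chosen once:
default families of 6 ancestral OGs in 3 clusters (~60–130 genes, 180 aa),
20 seeds for recovery properties, bootstrap 50–100 replicates; the
expansion benchmark mirrors the real framework's shape with 25 ancestral
cluster genes in 10 clusters (~44 OGs at the ancestor) on a 20-species
panel with 120-aa proteins, profiles built from a 9-species subsample.  The
measured properties: NJ additivity recovery (100 random trees, n ≤ 12),
mask monotonicity (200 random alignments), delineation ARI on loss-free
full-support true trees, peel cluster recovery (Rand index vs planted
clusters), hold-out classification (≥95% of a held-out species' members to
the true OG; decoy false-positive rate at e ≤ 1e-3 below 1%), and the
seed-versus-panel per-OG copy-number correlation.  Each is computed by
`ogpeel.benchmarks`, asserted in the test suite, and reported by
`scripts/acceptance.py`.

## Known limitations

* No indels, alignment error, or annotation noise in the generator; real
  inputs require an external aligner (adapter provided) and inherit its
  artifacts.
* Distance-NJ-bootstrap is a stand-in for ML inference with aLRT; trees for
  publication-grade analyses should be injected via newick.
* θ-based peeling and the support-based merge/split rule approximate expert
  judgment; curator overrides exist because no rule reproduces every call.
* The seed-versus-panel correlation is bounded by birth–death sampling
  noise at a 20-species panel scale, which is smaller than the multi-decade
  panels such comparisons are usually run on.
* Gumbel calibration from 200 shuffles gives e-values accurate to roughly
  an order of magnitude in the far tail; the decision threshold (1e-3 with
  database-size scaling) sits well inside the calibrated range.
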