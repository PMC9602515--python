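# ogpeel

Iterative divergent-cluster peeling and orthogroup classification for large
plant gene families.

Families like the GDSL-type esterase/lipase (GELP) family count tens to
hundreds of members per genome.  Aligning all of them at once leaves few
usable columns after block cleaning and produces poorly resolved trees, so
classifying such families by orthology — the set of genes descending from a
single gene in the last common ancestor of monocots and dicots, an
*orthogroup* (OG) — takes a staged workflow.  `ogpeel` implements that
workflow as a tested, reusable library with a CLI:

1. **peel** — repeat align → Gblocks-style mask → NJ tree → bootstrap
   supports, each round removing the best *divergent cluster* (a clade
   behind a long, well-supported stem) until the tree cleaves into terminal
   clusters;
2. **delineate** — root each cluster with the outgroup and cut it into
   orthogroups at the monocot/dicot split, splitting or merging
   lineage-specific clades by support and species span;
3. **inspect** — exon-architecture consistency per OG and tandem-array
   detection from gene coordinates;
4. **expand** — build a position-specific scoring profile per OG (Gumbel
   e-value calibration) and classify whole proteomes, or assign single
   sequences by the top-5-unanimity similarity rule.

A synthetic gene-family generator (`ogpeel.simfam`) produces truth-labelled
proteomes, gene models and alignments with the statistical structure the
workflow assumes (divergent clusters, birth–death copy-number dynamics with
tandem duplication, active-site motif variants GDSL/GDSY/GSSI/GDSI, the five
canonical exon architectures, pseudogene flags), so every stage is testable
at desk scale without genome downloads.  The package also bundles the
curated nine-species GELP reference summaries (peel trace, cluster
compositions, the 44-OG copy-number matrix) for bookkeeping checks and as a
worked target of the data model.

See `docs/methods.md` for the models, parameter meanings and limitations.

## Worked example

Simulate a small loss-free family (3 divergent clusters, one ancestral OG
each, mild duplication) and run the full pipeline:

```python
from ogpeel.pipeline_report import RunConfig, run_pipeline
from ogpeel.simfam import SimConfig

cfg = RunConfig(
    sim=SimConfig(n_ancestral_ogs=3, n_clusters=3, og_rate_variation=False,
                  dup_rate=0.3, loss_rate=0.0, pseudogene_prob=0.0,
                  truncated_prob=0.0, seed=11),
    n_bootstrap=40, family="SIM", seed=11, out_dir="demo_run")
run_pipeline(cfg)
```

The run directory then contains `trace.tsv`:

```
step  n_total  n_per_species        positions  cluster  cluster_size  cluster_per_species  support  terminal
1     39       3-4-4-4-5-5-5-5-4    163        C1       13            1-1-1-1-2-2-2-2-1    1.0      1
1     39       3-4-4-4-5-5-5-5-4    163        C2       17            1-2-2-2-2-2-2-2-2    1.0      1
1     39       3-4-4-4-5-5-5-5-4    163        C3       9             1-1-1-1-1-1-1-1-1    1.0      1
```

All 39 genes enter step 1; 163 of 180 alignment columns survive masking; the
tree immediately cleaves into the three planted clusters (support 1.0), so
all three become terminal in one step.  Delineation then cuts each cluster
at the monocot/dicot split, profiles are built per OG, and the proteome is
re-classified against them.  `metrics.json` reports

```
{"n_genes": 39, "n_clusters": 3, "n_ogs": 3, "n_profiles": 3}
delineation ari: 1.0   classification ari: 1.0   unassigned: 0.0
```

— both the tree-based delineation and the profile-based re-classification
recover the simulated truth exactly (adjusted Rand index 1.0).  The
copy-number matrix (`matrix.tsv`) has the familiar OG × species layout,
with the outgroup kept in its own column:

```
Orthogroup  AMBTC  PHODA  MUSAC  ORYSA  VITVI  PRUMU  THECC  ARATH  COFCA  Total
OG-SIM-C1   1      1      1      1      2      2      2      2      1      13
OG-SIM-C2   1      2      2      2      2      2      2      2      2      17
OG-SIM-C3   1      1      1      1      1      1      1      1      1      9
Total       3      4      4      4      5      5      5      5      4      39
```

The same stages are available from the shell:

```sh
ogpeel simulate --seed 11 --out fixtures/
ogpeel mask fixtures/true_alignment.fasta --report mask.tsv
ogpeel tree fixtures/true_alignment.fasta --bootstrap 100 --seed 7 --out tree.nwk
ogpeel run run.yaml --seed 11 --out demo_run
ogpeel report demo_run
ogpeel classify proteome.fasta --profiles demo_run/profiles --evalue 1e-3
```

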