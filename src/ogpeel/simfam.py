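"""Synthetic gene-family generator with truth labels.

The generator emulates the data regime of a large plant gene family sampled
over a nine-species angiosperm panel (one outgroup, three monocots, five
dicots): a handful of anciently diverged *clusters* separated by long stem
branches, each containing one or more ancestral genes (*orthogroups*) present
in the monocot/dicot common ancestor, gene birth-death (duplication/loss)
along the species tree with a tandem/dispersed split, cluster-specific
active-site motif variants (GDSL/GDSY/GSSI/GDSI), orthogroup-specific exon
architectures with rare intron gain/loss, and occasional pseudogene flags.

Sequences evolve under a stationary per-site replacement process (a site hit
by a substitution draws a fresh residue from the background frequencies) with
gamma rate heterogeneity across sites and no indels, so the *true alignment*
of the family is the emitted sequences themselves.  That is a deliberate
simplification: the downstream stages under test operate on topology and
labels, not on alignment inference.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import shutil
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ogpeel.core_io import (
    GeneModel,
    ProteinRecord,
    SpeciesPanel,
    MOTIF_VARIANTS,
    write_fasta,
    write_gff3,
    write_species_panel,
)
from ogpeel.msa_mask import Alignment
from ogpeel.treekit import SupportTree, TreeNode, read_newick

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
#: Background amino-acid frequencies (Robinson–Robinson order-of-magnitude
#: values, renormalized).
BG_FREQS = np.array([
    0.079, 0.019, 0.054, 0.063, 0.040, 0.074, 0.022, 0.051, 0.057, 0.091,
    0.022, 0.045, 0.052, 0.041, 0.051, 0.068, 0.059, 0.065, 0.014, 0.032,
])
BG_FREQS = BG_FREQS / BG_FREQS.sum()

#: Motif columns (0-based) where the cluster-specific active-site variant is
#: implanted and protected from substitution.
MOTIF_START = 35

#: Canonical exon-architecture classes: junction positions as fractions of the
#: protein length.  Class 1 is the two-exon form with a dominant second exon;
#: classes 2 (six exons), 3, 4 and 5 (five exons with distinct second/third
#: junctions) mirror the main architectures seen across the family clusters.
ARCHITECTURE_CLASSES: dict[int, tuple[float, ...]] = {
    1: (0.12,),
    2: (0.15, 0.30, 0.48, 0.66, 0.84),
    3: (0.22, 0.42, 0.62, 0.82),
    4: (0.15, 0.35, 0.58, 0.78),
    5: (0.15, 0.45, 0.58, 0.78),
}

DEFAULT_SPECIES_TREE = (
    "(AMBTC:1.0,((PHODA:0.5,(MUSAC:0.35,ORYSA:0.35):0.15):0.5,"
    "(COFCA:0.6,(VITVI:0.45,(PRUMU:0.3,(THECC:0.2,ARATH:0.2):0.1):0.15):0.15):0.4):0.0);"
)

INTRON_LENGTH = 200
GENE_SPACING = 10_000
#: Rank gap left between unrelated family genes on a chromosome (i.e., number
#: of interleaved non-family genes is RANK_GAP - 1).
RANK_GAP = 30


@dataclass
class SimConfig:
    """Parameters of the synthetic family; the defaults define the reference
    study conditions (9-species panel, 3 divergent clusters, 6 ancestral OGs,
    moderate duplication with a tandem majority)."""

    species_tree_newick: str = DEFAULT_SPECIES_TREE
    panel: SpeciesPanel = field(default_factory=SpeciesPanel.default)
    n_ancestral_ogs: int = 6
    n_clusters: int = 3
    dup_rate: float = 1.2  # duplications per gene per unit branch length, at the root
    loss_rate: float = 0.15
    #: per-OG rate variation emulating the family's mixed dynamics: a
    #: ``stable_og_fraction`` of ancestral OGs stay essentially single-copy
    #: (rate multiplier 0.05); the rest draw a lognormal(0, expansion_sigma)
    #: multiplier capped at 4.5, so most OGs change little while a minority
    #: expand several-fold — matching the skewed copy-number spread seen in
    #: curated plant gene-family tables.
    og_rate_variation: bool = True
    stable_og_fraction: float = 0.35
    expansion_sigma: float = 1.1
    #: duplication intensity declines as exp(-decay * t) with time t since
    #: the monocot/dicot ancestor (or since the root, for lineages that never
    #: pass it): copy-number amplification concentrates just after the split
    #: and before the species radiations, with lineage-specific events
    #: becoming rarer toward the tips; loss stays uniform in time.
    dup_depth_decay: float = 2.0
    tandem_fraction: float = 0.6
    substitution_rate: float = 1.0  # expected substitutions/site/unit length
    gamma_shape: float = 1.0
    protein_length: int = 180
    cluster_stem_length: float = 1.5
    og_stem_length: float = 0.10
    intron_gain_prob: float = 0.02  # per gene lineage per species-tree branch
    intron_loss_prob: float = 0.02
    pseudogene_prob: float = 0.03
    truncated_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dup_rate, self.loss_rate, self.substitution_rate) < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.tandem_fraction <= 1:
            raise ValueError("tandem_fraction must be in [0, 1]")
        if self.n_ancestral_ogs < 1 or self.n_clusters < 1:
            raise ValueError("need >= 1 OG and >= 1 cluster")
        if self.n_clusters > self.n_ancestral_ogs:
            raise ValueError("cannot have more clusters than ancestral OGs")


@dataclass
class _Locus:
    chromosome: str
    array_id: int
    slot: float


@dataclass
class _Gene:
    """A sampled (tip) gene."""

    gene_id: str
    species: str
    sequence: str
    og: str
    cluster: str
    locus: _Locus
    junctions: tuple[int, ...]
    strand: str
    pseudogene: bool
    truncated: bool
    position_index: int = -1


@dataclass
class SimResult:
    config: SimConfig
    records: list[ProteinRecord]
    gene_models: list[GeneModel]
    true_alignment: Alignment
    truth: pd.DataFrame
    true_family_tree: SupportTree
    warnings: list[str]

    def og_members(self) -> dict[str, list[str]]:
        """Gene ids per true OG (outgroup genes, with empty OG, excluded)."""
        out: dict[str, list[str]] = {}
        for row in self.truth.itertuples(index=False):
            if row.true_og:
                out.setdefault(row.true_og, []).append(row.gene_id)
        return out

    def og_alignment(self, og: str) -> Alignment:
        ids = self.og_members()[og]
        return self.true_alignment.subset(ids)

    def alignment_provider(self):
        """An align-provider callable that restricts the true alignment."""

        def provide(records) -> Alignment:
            return self.true_alignment.subset([r.id for r in records])

        return provide


class _Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.species_tree = read_newick(config.species_tree_newick)
        tree_taxa = set(self.species_tree.leaf_labels())
        panel_taxa = set(config.panel.codes)
        if tree_taxa != panel_taxa:
            raise ValueError(
                f"species tree taxa {sorted(tree_taxa)} != panel {sorted(panel_taxa)}"
            )
        # the monocot/dicot ancestor: the smallest clade holding every
        # non-outgroup species; gene copies present at this node define the
        # true orthogroups (outgroup genes are never OG members)
        ingroup = {
            c for c in config.panel.codes
            if config.panel.lineage_of(c) != "outgroup"
        }
        node = self.species_tree.root
        while True:
            nxt = [
                c for c in node.children
                if ingroup <= {n.label for n in c.leaves()}
            ]
            if not nxt:
                break
            node = nxt[0]
        self.lca_node = node
        self.lca_copies: dict[str, int] = {}
        L = config.protein_length
        self.rates = self.rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, size=L)
        self.protected = np.zeros(L, dtype=bool)
        self.protected[MOTIF_START : MOTIF_START + 4] = True
        self.array_counter = 0
        self.slot_counter = 0
        self.gene_counter: dict[str, int] = {}
        self.genes: list[_Gene] = []
        self.warnings: list[str] = []
        # per-OG birth-death rates, set before each OG descent
        self.cur_dup = config.dup_rate
        self.cur_loss = config.loss_rate
        self.cur_lam = self.cur_dup + self.cur_loss

    def _og_rate_multiplier(self) -> float:
        if not self.cfg.og_rate_variation:
            return 1.0
        if self.rng.random() < self.cfg.stable_og_fraction:
            return 0.05
        return float(min(self.rng.lognormal(0.0, self.cfg.expansion_sigma), 4.5))

    # -- sequence evolution ----------------------------------------------

    def _random_seq(self) -> np.ndarray:
        return self.rng.choice(20, size=self.cfg.protein_length, p=BG_FREQS)

    def _evolve(self, seq: np.ndarray, t: float) -> np.ndarray:
        if t <= 0:
            return seq
        p = 1.0 - np.exp(-self.cfg.substitution_rate * self.rates * t)
        hit = (self.rng.random(seq.size) < p) & ~self.protected
        if hit.any():
            seq = seq.copy()
            seq[hit] = self.rng.choice(20, size=int(hit.sum()), p=BG_FREQS)
        return seq

    # -- locus bookkeeping -----------------------------------------------

    def _new_root_locus(self, og_index: int) -> _Locus:
        self.array_counter += 1
        return _Locus(f"chr{og_index % 5 + 1}", self.array_counter, 1000.0 * (og_index + 1))

    def _duplicate_locus(self, parent: _Locus) -> _Locus:
        self.slot_counter += 1
        if self.rng.random() < self.cfg.tandem_fraction:
            return _Locus(parent.chromosome, parent.array_id,
                          parent.slot + 1e-6 * self.slot_counter)
        self.array_counter += 1
        chrom = f"chr{int(self.rng.integers(1, 6))}"
        return _Locus(chrom, self.array_counter, float(self.rng.uniform(0, 1e6)))

    # -- birth-death descent ----------------------------------------------

    def _along_edge(self, seq, junctions, locus, remaining, species_node,
                    og, cluster, depth) -> TreeNode | None:
        """Evolve one gene lineage along (the rest of) a species-tree edge.

        ``depth`` is the distance from the species root at the start of the
        stretch; the duplication intensity decays with it (piecewise-constant
        per stretch).  Returns the gene subtree rooted at the top of the
        stretch (edge length includes it), or None on loss/extinction below.
        """
        eff_dup = self.cur_dup * np.exp(-self.cfg.dup_depth_decay * depth)
        lam = eff_dup + self.cur_loss
        dt = self.rng.exponential(1.0 / lam) if lam > 0 else np.inf
        if dt >= remaining:
            seq = self._evolve(seq, remaining)
            node = self._at_species_node(
                seq, junctions, locus, species_node, og, cluster, depth + remaining
            )
            if node is not None:
                node.length += remaining
            return node
        seq = self._evolve(seq, dt)
        if self.rng.random() < self.cur_loss / lam:
            return None  # loss
        # duplication: the new copy starts identical at a new locus
        new_locus = self._duplicate_locus(locus)
        left = self._along_edge(seq, junctions, locus, remaining - dt,
                                species_node, og, cluster, depth + dt)
        right = self._along_edge(seq.copy(), junctions, new_locus, remaining - dt,
                                 species_node, og, cluster, depth + dt)
        if left is not None and right is not None:
            node = TreeNode(length=dt, support=1.0)
            node.add(left)
            node.add(right)
            return node
        survivor = left if left is not None else right
        if survivor is not None:
            survivor.length += dt
        return survivor

    def _mutate_junctions(self, junctions: tuple[int, ...]) -> tuple[int, ...]:
        cfg, L = self.cfg, self.cfg.protein_length
        junc = list(junctions)
        if junc and self.rng.random() < cfg.intron_loss_prob:
            junc.pop(int(self.rng.integers(len(junc))))  # exon fusion
        if self.rng.random() < cfg.intron_gain_prob:
            pos = int(self.rng.integers(int(0.05 * L), int(0.95 * L)))
            if pos not in junc:
                junc.append(pos)
        return tuple(sorted(junc))

    def _at_species_node(self, seq, junctions, locus, species_node,
                         og, cluster, depth=0.0) -> TreeNode | None:
        if species_node is self.lca_node:
            # a gene copy reaching the monocot/dicot ancestor founds an OG;
            # the duplication-decay clock restarts here, so amplification
            # concentrates just after the split, before the species radiation
            k = self.lca_copies.get(og, 0) + 1
            self.lca_copies[og] = k
            og = og if k == 1 else f"{og}.{k}"
            depth = 0.0
        if species_node.is_leaf:
            species = species_node.label
            i = self.gene_counter.get(species, 0) + 1
            self.gene_counter[species] = i
            gene_id = f"{species}_g{i:04d}"
            is_outgroup = self.cfg.panel.lineage_of(species) == "outgroup"
            gene = _Gene(
                gene_id=gene_id,
                species=species,
                sequence="".join(AA20[seq]),
                og="" if is_outgroup else og,
                cluster=cluster,
                locus=locus,
                junctions=junctions,
                strand="+" if self.rng.random() < 0.5 else "-",
                pseudogene=self.rng.random() < self.cfg.pseudogene_prob,
                truncated=self.rng.random() < self.cfg.truncated_prob,
            )
            self.genes.append(gene)
            return TreeNode(label=gene_id, length=0.0)
        subtrees = []
        for child in species_node.children:
            child_junc = self._mutate_junctions(junctions)
            sub = self._along_edge(seq.copy(), child_junc, locus, child.length,
                                   child, og, cluster, depth)
            if sub is not None:
                subtrees.append(sub)
        if not subtrees:
            return None
        if len(subtrees) == 1:
            return subtrees[0]
        node = TreeNode(length=0.0, support=1.0)
        for s in subtrees:
            node.add(s)
        return node

    # -- whole family -----------------------------------------------------

    def run(self) -> SimResult:
        cfg = self.cfg
        root_seq = self._random_seq()
        family_root = TreeNode()
        og_index = 0
        motif_codes = {aa: i for i, aa in enumerate(AA20)}
        for c in range(cfg.n_clusters):
            cluster_name = f"CL{c + 1}"
            cluster_seq = self._evolve(root_seq, cfg.cluster_stem_length)
            variant = MOTIF_VARIANTS[c % len(MOTIF_VARIANTS)]
            cluster_seq = cluster_seq.copy()
            cluster_seq[MOTIF_START : MOTIF_START + 4] = [motif_codes[a] for a in variant]
            arch_class = c % len(ARCHITECTURE_CLASSES) + 1
            junctions = tuple(
                int(round(f * cfg.protein_length)) for f in ARCHITECTURE_CLASSES[arch_class]
            )
            n_ogs = cfg.n_ancestral_ogs // cfg.n_clusters + (
                1 if c < cfg.n_ancestral_ogs % cfg.n_clusters else 0
            )
            cluster_node = TreeNode(length=cfg.cluster_stem_length, support=1.0)
            for _ in range(n_ogs):
                og_index += 1
                og_name = f"OG{og_index:02d}"
                mult = self._og_rate_multiplier()
                self.cur_dup = cfg.dup_rate * mult
                self.cur_loss = cfg.loss_rate * mult
                self.cur_lam = self.cur_dup + self.cur_loss
                og_seq = self._evolve(cluster_seq, cfg.og_stem_length)
                locus = self._new_root_locus(og_index - 1)
                sub = self._at_species_node(
                    og_seq, junctions, locus, self.species_tree.root, og_name, cluster_name
                )
                if sub is None:
                    self.warnings.append(f"{og_name}: extinct in all species")
                    continue
                sub.length += cfg.og_stem_length
                if sub.support is None and not sub.is_leaf:
                    sub.support = 1.0
                cluster_node.add(sub)
            if cluster_node.children:
                family_root.add(cluster_node)
        return self._collect(family_root)

    def _collect(self, family_root: TreeNode) -> SimResult:
        cfg = self.cfg
        # per-lineage extinction warnings
        present = {g.species for g in self.genes}
        for code in cfg.panel.codes:
            if code not in present:
                self.warnings.append(f"no surviving genes in species {code}")

        # chromosome ranks: same-array genes adjacent, others RANK_GAP apart
        by_chrom: dict[tuple[str, str], list[_Gene]] = {}
        for g in self.genes:
            by_chrom.setdefault((g.species, g.locus.chromosome), []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: (g.locus.slot, g.gene_id))
            rank = 10
            prev = None
            for g in genes:
                if prev is not None and prev.locus.array_id == g.locus.array_id:
                    rank += 1
                else:
                    rank += RANK_GAP
                g.position_index = rank
                prev = g

        records, models, rows = [], [], []
        ids, seqs = [], []
        for g in sorted(self.genes, key=lambda g: g.gene_id):
            flags = set()
            if g.pseudogene:
                flags.add("pseudogene")
            if g.truncated:
                flags.add("truncated")
            records.append(
                ProteinRecord(g.gene_id, g.species, g.sequence, frozenset(flags))
            )
            models.append(self._gene_model(g))
            rows.append(
                (g.gene_id, g.species, g.og, g.cluster, g.locus.chromosome,
                 g.position_index,
                 g.locus.array_id if self._array_size(g) > 1 else "",
                 g.pseudogene)
            )
            ids.append(g.gene_id)
            seqs.append(g.sequence)
        truth = pd.DataFrame(
            rows,
            columns=["gene_id", "species_code", "true_og", "true_cluster",
                     "chromosome", "position_index", "tandem_array_id", "pseudogene"],
        )
        tree = SupportTree(family_root) if family_root.children else SupportTree(TreeNode())
        return SimResult(
            config=cfg,
            records=records,
            gene_models=models,
            true_alignment=Alignment(ids, seqs),
            truth=truth,
            true_family_tree=tree,
            warnings=self.warnings,
        )

    def _array_size(self, gene: _Gene) -> int:
        return sum(
            1 for g in self.genes
            if g.species == gene.species and g.locus.array_id == gene.locus.array_id
        )

    def _gene_model(self, g: _Gene) -> GeneModel:
        """Exon spans from the junction set; CDS includes the stop codon."""
        L = self.cfg.protein_length
        cds_nt = 3 * (L + 1)
        bounds = [0] + [3 * j for j in g.junctions] + [cds_nt]
        exon_lengths = [b - a for a, b in zip(bounds, bounds[1:])]
        start = g.position_index * GENE_SPACING + 1
        spans = []
        pos = start
        for ln in exon_lengths:
            spans.append((pos, pos + ln - 1))
            pos += ln + INTRON_LENGTH
        if g.strand == "-":
            spans = spans[::-1]  # transcription order for minus strand
        return GeneModel(
            gene_id=g.gene_id,
            protein_id=g.gene_id,
            chromosome=g.locus.chromosome,
            strand=g.strand,
            exons=spans,
            cds_segments=list(spans),
            position_index=g.position_index,
        )


def simulate_family(config: SimConfig | None = None) -> SimResult:
    """Simulate a truth-labelled gene family; deterministic given the seed."""
    result = _Simulator(config or SimConfig()).run()
    for w in result.warnings:
        warnings.warn(w)
    return result


def random_proteins(n: int, length: int, seed: int, species: str = "DECOY") -> list[ProteinRecord]:
    """Background-frequency random proteins (decoys for calibration tests)."""
    rng = np.random.default_rng(seed)
    return [
        ProteinRecord(f"{species.lower()}_{i:05d}", species,
                      "".join(AA20[rng.choice(20, size=length, p=BG_FREQS)]))
        for i in range(n)
    ]


def synthetic_panel_tree(
    n_monocot: int, n_dicot: int, outgroup_code: str = "OUTGR"
) -> tuple[SpeciesPanel, str]:
    """A synthetic panel of arbitrary size with a depth-1 species tree.

    Monocot codes M01.., dicot codes D01..; clades are balanced with the
    outgroup branching at the root, mirroring the shape of the default panel.
    """
    from ogpeel.core_io import PanelEntry, DICOT, MONOCOT, OUTGROUP

    def clade(taxa: list[str], depth: float) -> str:
        if len(taxa) == 1:
            return f"{taxa[0]}:{depth:.6g}"
        half = len(taxa) // 2
        stem = depth * 0.3
        left = clade(taxa[:half], depth - stem)
        right = clade(taxa[half:], depth - stem)
        return f"({left},{right}):{stem:.6g}"

    if n_monocot < 1 or n_dicot < 1:
        raise ValueError("need at least one monocot and one dicot")
    monocots = [f"M{i + 1:02d}" for i in range(n_monocot)]
    dicots = [f"D{i + 1:02d}" for i in range(n_dicot)]
    inner_depth = 0.5
    mono = clade(monocots, inner_depth)
    dico = clade(dicots, inner_depth)
    newick = f"({outgroup_code}:1.0,({mono},{dico}):{1.0 - inner_depth:.6g});"
    entries = [PanelEntry(outgroup_code, OUTGROUP, "synthetic outgroup")]
    entries += [PanelEntry(c, MONOCOT, f"synthetic monocot {c}") for c in monocots]
    entries += [PanelEntry(c, DICOT, f"synthetic dicot {c}") for c in dicots]
    return SpeciesPanel(entries), newick


def emit_fixture(sim: SimResult, out_dir: str | Path, force: bool = False) -> dict[str, Path]:
    """Write proteins.fasta, genes.gff3, truth.tsv, true_alignment.fasta, panel.tsv."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    if out.exists() and force:
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out / "proteins.fasta",
        "gff3": out / "genes.gff3",
        "truth": out / "truth.tsv",
        "alignment": out / "true_alignment.fasta",
        "panel": out / "panel.tsv",
    }
    write_fasta(sim.records, paths["proteins"])
    write_gff3(sim.gene_models, paths["gff3"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    sim.true_alignment.to_fasta(paths["alignment"])
    write_species_panel(sim.config.panel, paths["panel"])
    return paths
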