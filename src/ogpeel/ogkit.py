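"""Outgroup rooting, orthogroup delineation, exon-architecture consistency,
and tandem-array detection.

Orthogroups (OGs) are defined relative to the last common ancestor of
monocots and dicots: the smallest clades containing sequences from both
lineages.  The outgroup (which branches before that ancestor) roots the tree
but is never counted as an OG member; outgroup sequences are annotated to
their nearest OG for reporting only.

The merge-versus-split decision for a pure-lineage clade that is sister to a
mixed clade is the central curator judgment of the workflow.  It is
operationalized here: the pure clade becomes its own (lineage-specific) OG
when its subtending support reaches the threshold and it spans at least two
species; otherwise it is merged into the OG delineated inside its mixed
sibling.  A curator-override table can pin individual genes to named OGs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ogpeel.core_io import DICOT, MONOCOT, OUTGROUP, GeneModel, SpeciesPanel
from ogpeel.msa_mask import Alignment
from ogpeel.simfam import ARCHITECTURE_CLASSES
from ogpeel.treekit import SupportTree, TreeNode


class DelineationError(RuntimeError):
    pass


@dataclass
class Orthogroup:
    name: str
    members: list[str]
    source_cluster: str
    lineage_composition: dict
    delineation_support: float | None = None
    curator_override: bool = False
    outgroup_annotations: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def _og_letter(i: int) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = ""
    i0 = i
    while True:
        out = letters[i0 % 26] + out
        i0 = i0 // 26 - 1
        if i0 < 0:
            break
    return out


def root_with_outgroup(
    tree: SupportTree, panel: SpeciesPanel, species_of: dict
) -> SupportTree:
    """Root on the edge separating the maximal outgroup-only clade.

    If the outgroup is not monophyletic, the edge maximizing outgroup leaves
    on one side is used and a warning is emitted.
    """
    og_species = set(panel.outgroup_codes)
    leaves = tree.leaf_labels()
    og_leaves = {x for x in leaves if species_of[x] in og_species}
    if not og_leaves:
        raise DelineationError("no outgroup leaf in tree; supply a pre-rooted tree")
    all_set = frozenset(leaves)
    best_node, best_count = None, -1
    for node in tree.root.preorder():
        if node.parent is None:
            continue
        below = tree.leafset(node)
        for side in (below, all_set - below):
            if side and side <= og_leaves and len(side) > best_count:
                best_node, best_count = node, len(side)
    if best_count < len(og_leaves):
        warnings.warn("outgroup is not monophyletic; rooting at the best split")
    return tree.rooted_at_edge(best_node)


def _lineage_fn(panel: SpeciesPanel, species_of: dict):
    def lin(leaf: str) -> str:
        sp = species_of.get(leaf)
        if sp is None:
            raise DelineationError(f"leaf {leaf!r} has no species label")
        return panel.lineage_of(sp)

    return lin


def delineate_ogs(
    rooted_tree: SupportTree,
    panel: SpeciesPanel,
    species_of: dict,
    support_threshold: float = 0.90,
    family: str = "FAM",
    cluster: str = "C1",
    overrides: dict | None = None,
) -> list[Orthogroup]:
    """Delineate orthogroups at the monocot/dicot split on a rooted tree.

    Recursive rule on the lineage content L(v) of each clade v (outgroup
    leaves ignored):

    a. two or more children of v are lineage-mixed -> v is a pre-split
       duplication node; recurse into every child (pure children become
       lineage-specific OGs);
    b. exactly one child mixed -> recurse into it; each pure sibling becomes
       its own OG when supported (>= threshold) and spanning >= 2 species,
       else it is merged into the first OG delineated inside the mixed child;
    c. v mixed with no mixed child -> v's clade is one OG.
    """
    panel.validate_for_delineation()
    lin = _lineage_fn(panel, species_of)
    root = rooted_tree.root

    def ingroup_leaves(node: TreeNode) -> list[str]:
        return [n.label for n in node.leaves() if lin(n.label) != OUTGROUP]

    def lineages(node: TreeNode) -> set:
        return {lin(x) for x in ingroup_leaves(node)}

    def n_species(node: TreeNode) -> int:
        return len({species_of[x] for x in ingroup_leaves(node)})

    def rec(node: TreeNode) -> list[dict]:
        leaves_in = ingroup_leaves(node)
        if not leaves_in:
            return []
        lins = lineages(node)
        if lins != {MONOCOT, DICOT}:
            return [{"members": list(leaves_in), "support": node.support}]
        mixed = [c for c in node.children if lineages(c) == {MONOCOT, DICOT}]
        if not mixed:  # case (c)
            return [{"members": list(leaves_in), "support": node.support}]
        if len(mixed) >= 2:  # case (a): pre-split duplication
            out = []
            for c in node.children:
                out.extend(rec(c))
            return out
        # case (b)
        m = mixed[0]
        inner = rec(m)
        out = []
        for c in node.children:
            if c is m:
                out.extend(inner)
                continue
            members = ingroup_leaves(c)
            if not members:
                continue
            sup = c.support if not c.is_leaf else None
            if sup is not None and sup >= support_threshold and n_species(c) >= 2:
                out.append({"members": members, "support": sup})
            else:
                inner[0]["members"].extend(members)
        return out

    raw = rec(root)
    if not raw:
        raise DelineationError("no non-outgroup leaves to delineate")

    single = len(raw) == 1
    ogs = []
    for i, d in enumerate(raw):
        name = f"OG-{family}-{cluster}" + ("" if single else _og_letter(i))
        comp: dict = {}
        for x in d["members"]:
            sp = species_of[x]
            comp.setdefault(panel.lineage_of(sp), {}).setdefault(sp, 0)
            comp[panel.lineage_of(sp)][sp] += 1
        ogs.append(
            Orthogroup(
                name=name,
                members=sorted(d["members"]),
                source_cluster=cluster,
                lineage_composition=comp,
                delineation_support=d["support"],
            )
        )

    if overrides:
        by_name = {o.name: o for o in ogs}
        for gene, og_name in overrides.items():
            for o in ogs:
                if gene in o.members:
                    o.members.remove(gene)
            target = by_name.get(og_name)
            if target is None:
                target = Orthogroup(og_name, [], cluster, {}, curator_override=True)
                ogs.append(target)
                by_name[og_name] = target
            target.members.append(gene)
            target.members.sort()
            target.curator_override = True
        ogs = [o for o in ogs if o.members]

    # partition invariant over non-outgroup leaves
    all_in = [n.label for n in root.leaves() if lin(n.label) != OUTGROUP]
    seen: set = set()
    for o in ogs:
        dup = seen & set(o.members)
        if dup:
            raise DelineationError(f"genes in two OGs: {sorted(dup)[:3]}")
        seen |= set(o.members)
    if seen != set(all_in):
        raise DelineationError("OGs do not cover all non-outgroup leaves")

    _annotate_outgroup(rooted_tree, ogs, lin)
    return ogs


def _annotate_outgroup(tree: SupportTree, ogs: list[Orthogroup], lin) -> None:
    """Attach each outgroup leaf to the OG of its nearest ingroup neighbours."""
    member_og = {}
    for o in ogs:
        for m in o.members:
            member_og[m] = o.name
    by_name = {o.name: o for o in ogs}
    for leaf in tree.root.leaves():
        if lin(leaf.label) != OUTGROUP:
            continue
        node = leaf.parent
        while node is not None:
            inside = [n.label for n in node.leaves() if n.label in member_og]
            if inside:
                counts: dict = {}
                for x in inside:
                    counts[member_og[x]] = counts.get(member_og[x], 0) + 1
                best = max(sorted(counts), key=lambda k: counts[k])
                by_name[best].outgroup_annotations.append(leaf.label)
                break
            node = node.parent


# -- exon architecture ----------------------------------------------------


@dataclass
class ExonArchitecture:
    junction_columns: tuple[int, ...]  # 1-based alignment columns
    n_exons: int
    class_id: str  # "1".."5" or "novel"


@dataclass
class ArchitectureReport:
    consensus: ExonArchitecture | None
    conformity: dict  # member id -> "conformant" | "fused(i,j)" | "divergent"
    untestable: bool = False


def exon_junction_columns(
    gene_model: GeneModel, alignment: Alignment, row_id: str
) -> list[int]:
    """Map each intron position to a 1-based alignment column.

    The junction is assigned to the residue whose codon contains (or ends at)
    the junction, i.e. residue ``ceil(cds_offset / 3)``; the residue's
    alignment column is returned.
    """
    row = alignment.rows[alignment.ids.index(row_id)]
    protein_len = sum(1 for ch in row if ch != "-")
    cds_len = gene_model.cds_length
    if cds_len not in (3 * protein_len, 3 * protein_len + 3):
        raise DelineationError(
            f"{gene_model.gene_id}: CDS length {cds_len} inconsistent with "
            f"protein length {protein_len}"
        )
    # residue index per alignment column
    col_of_residue = {}
    res = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            res += 1
            col_of_residue[res] = col
    cols = []
    cum = 0
    for seg_start, seg_end in gene_model.cds_segments[:-1]:
        cum += abs(seg_end - seg_start) + 1
        residue = math.ceil(cum / 3)
        if residue in col_of_residue:
            cols.append(col_of_residue[residue])
    return cols


def _match_tolerant(a: tuple, b: tuple, tol: int) -> bool:
    return len(a) == len(b) and all(abs(x - y) <= tol for x, y in zip(sorted(a), sorted(b)))


def _classify_architecture(junctions: tuple[int, ...], width: int) -> str:
    if width <= 0:
        return "novel"
    rel = np.array(sorted(junctions)) / width
    best, best_err = None, np.inf
    for cid, template in ARCHITECTURE_CLASSES.items():
        if len(template) != len(rel):
            continue
        err = float(np.max(np.abs(rel - np.array(template)))) if len(rel) else 0.0
        if err < best_err:
            best, best_err = cid, err
    if best is not None and best_err <= 0.08:
        return str(best)
    return "novel"


def architecture_consistency(
    og: Orthogroup,
    alignment: Alignment,
    gene_models: dict[str, GeneModel],
    tolerance_cols: int = 5,
) -> ArchitectureReport:
    """Check that OG members share one exon architecture.

    The modal junction-column set is the consensus; members matching it
    within ``tolerance_cols`` per junction are conformant.  A member missing
    exactly one modal junction but matching elsewhere is labelled
    ``fused(i,i+1)`` (fusion of exons i and i+1).
    """
    junction_sets = {}
    for member in og.members:
        gm = gene_models.get(member)
        if gm is None or member not in alignment.ids:
            continue
        junction_sets[member] = tuple(exon_junction_columns(gm, alignment, member))
    if not junction_sets:
        return ArchitectureReport(None, {}, untestable=True)

    tallies: dict[tuple, int] = {}
    for js in junction_sets.values():
        tallies[js] = tallies.get(js, 0) + 1
    modal = max(sorted(tallies), key=lambda k: tallies[k])

    conformity = {}
    for member, js in junction_sets.items():
        if _match_tolerant(js, modal, tolerance_cols):
            conformity[member] = "conformant"
        else:
            fused = _detect_fusion(js, modal, tolerance_cols)
            conformity[member] = fused if fused else "divergent"

    width = alignment.n_cols
    consensus = ExonArchitecture(
        junction_columns=modal,
        n_exons=len(modal) + 1,
        class_id=_classify_architecture(modal, width),
    )
    return ArchitectureReport(consensus, conformity)


def _detect_fusion(js: tuple, modal: tuple, tol: int) -> str | None:
    if len(js) != len(modal) - 1:
        return None
    modal_s = sorted(modal)
    for skip in range(len(modal_s)):
        rest = modal_s[:skip] + modal_s[skip + 1 :]
        if _match_tolerant(js, tuple(rest), tol):
            return f"fused({skip + 1},{skip + 2})"
    return None


# -- tandem arrays ---------------------------------------------------------


@dataclass
class TandemGroup:
    species: str
    chromosome: str
    members: list[str]  # gene ids in chromosomal order
    ogs: set

    @property
    def is_array(self) -> bool:
        return len(self.members) >= 2

    @property
    def spans_multiple_ogs(self) -> bool:
        return len(self.ogs) > 1


def detect_tandem_arrays(
    gene_models: list[GeneModel],
    og_assignments: dict[str, str],
    max_intervening_genes: int = 5,
    species_of: dict | None = None,
) -> list[TandemGroup]:
    """Group family genes into physical neighbourhood groups per chromosome.

    Neighbouring family genes separated by at most ``max_intervening_genes``
    other annotated genes (from ``position_index`` ranks) join one maximal
    group; groups of two or more are tandem arrays.  Groups report the set of
    OGs they span (tandems that straddle two OGs witness duplications that
    predate the OG split).
    """
    species_of = species_of or {}
    fam = [m for m in gene_models if m.protein_id in og_assignments]
    buckets: dict[tuple, list[GeneModel]] = {}
    for m in fam:
        key = (species_of.get(m.gene_id, ""), m.chromosome)
        buckets.setdefault(key, []).append(m)
    groups = []
    for (species, chrom), models in sorted(buckets.items()):
        def rank(m: GeneModel):
            if m.position_index is not None:
                return m.position_index
            raise DelineationError(
                f"gene {m.gene_id} lacks a position index; re-read the full GFF3"
            )

        models.sort(key=rank)
        current = [models[0]]
        for prev, cur in zip(models, models[1:]):
            if rank(cur) - rank(prev) - 1 <= max_intervening_genes:
                current.append(cur)
            else:
                groups.append(_make_group(species, chrom, current, og_assignments))
                current = [cur]
        groups.append(_make_group(species, chrom, current, og_assignments))
    return groups


def _make_group(species, chrom, models, og_assignments) -> TandemGroup:
    return TandemGroup(
        species=species,
        chromosome=chrom,
        members=[m.gene_id for m in models],
        ogs={og_assignments[m.protein_id] for m in models},
    )
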