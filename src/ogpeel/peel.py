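"""Iterative divergent-cluster identification and removal ("peeling").

A large family alignment keeps few columns after block cleaning; peeling off
the most divergent, well-supported clade and repeating the whole
align -> mask -> tree cycle on the remainder recovers informative positions
and resolution step by step.  The expert's "clearly separated cluster" is
operationalized by a divergence ratio: the candidate clade's stem branch
length divided by the median internal branch length of the tree must reach a
threshold θ, alongside the support and composition minima.

When the final tree cleaves into several mutually disjoint qualifying
clusters that jointly cover all remaining sequences, they all become terminal
clusters in a single step; otherwise the remainder ends as one terminal
cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from ogpeel.core_io import ProteinRecord, SpeciesPanel
from ogpeel.msa_mask import Alignment, MaskParams, MaskedAlignment, mask_alignment
from ogpeel.treekit import SupportTree, bootstrap_support


class PeelError(RuntimeError):
    pass


@dataclass
class PeelParams:
    min_support: float = 0.90
    min_cluster_size: int = 5
    min_species_in_cluster: int = 2
    divergence_ratio_threshold: float = 3.0  # θ
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.min_support <= 1:
            raise ValueError("min_support must be in [0, 1]")
        if self.divergence_ratio_threshold <= 0:
            raise ValueError("divergence ratio threshold must be > 0")


@dataclass(frozen=True)
class DivergentCluster:
    members: frozenset
    support: float
    stem_length: float
    ratio: float

    @property
    def size(self) -> int:
        return len(self.members)

    def sort_key(self):
        # max ratio, then max support, then smallest cluster, then lexicographic
        return (-self.ratio, -self.support, self.size, min(self.members))


@dataclass
class PeelStep:
    step: int
    n_total: int
    n_per_species: tuple
    positions: int
    cluster: str
    cluster_size: int
    cluster_per_species: tuple
    support: float
    terminal: bool


@dataclass
class PeelTrace:
    steps: list[PeelStep] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.steps)

    def validate(self) -> None:
        """Bookkeeping invariants: counts at step k+1 equal counts at step k
        minus the removed cluster, per total and per species."""
        non_terminal = [s for s in self.steps if not s.terminal]
        terminal = [s for s in self.steps if s.terminal]
        for cur, nxt in zip(self.steps, self.steps[1:]):
            if nxt.step == cur.step:
                continue  # same terminal multi-split step
            if nxt.n_total != cur.n_total - cur.cluster_size:
                raise PeelError(
                    f"step {nxt.step}: n_total {nxt.n_total} != "
                    f"{cur.n_total} - {cur.cluster_size}"
                )
            expect = tuple(a - b for a, b in zip(cur.n_per_species, cur.cluster_per_species))
            if tuple(nxt.n_per_species) != expect:
                raise PeelError(f"step {nxt.step}: per-species bookkeeping broken")
        if terminal:
            last_total = terminal[0].n_total
            if sum(s.cluster_size for s in terminal) != last_total:
                raise PeelError("terminal cluster sizes do not sum to the final count")

    def final_count(self) -> int:
        """Sequence count entering the last step, from the bookkeeping alone."""
        first = self.steps[0]
        removed = sum(s.cluster_size for s in self.steps[:-1] if not s.terminal)
        return first.n_total - removed

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "n_total": s.n_total,
                    "n_per_species": "-".join(str(x) for x in s.n_per_species),
                    "positions": s.positions,
                    "cluster": s.cluster,
                    "cluster_size": s.cluster_size,
                    "cluster_per_species": "-".join(str(x) for x in s.cluster_per_species),
                    "support": s.support,
                    "terminal": int(s.terminal),
                }
                for s in self.steps
            ]
        )


def _candidate_clusters(
    tree: SupportTree, params: PeelParams, species_of: dict
) -> list[DivergentCluster]:
    if not tree.has_supports():
        raise PeelError(
            "tree carries no supports; run bootstrap_support or import a tree "
            "with support labels"
        )
    all_leaves = frozenset(tree.leaf_labels())
    median = tree.median_internal_branch_length()
    out = []
    for node in tree.internal_edges():
        if node.support is None or node.support < params.min_support:
            continue
        below = tree.leafset(node)
        side = below if len(below) * 2 <= len(all_leaves) else all_leaves - below
        if len(side) < params.min_cluster_size:
            continue
        species = {species_of[x] for x in side}
        if len(species) < params.min_species_in_cluster:
            continue
        ratio = node.length / median if median > 0 else math.inf
        if ratio < params.divergence_ratio_threshold:
            continue
        out.append(DivergentCluster(side, node.support, node.length, ratio))
    # deduplicate identical member sets (both orientations of an edge)
    best: dict[frozenset, DivergentCluster] = {}
    for c in out:
        if c.members not in best or c.sort_key() < best[c.members].sort_key():
            best[c.members] = c
    return sorted(best.values(), key=DivergentCluster.sort_key)


def find_divergent_cluster(
    tree: SupportTree, params: PeelParams, species_of: dict
) -> DivergentCluster | None:
    """Best qualifying divergent cluster, or None.

    An edge qualifies when its support reaches ``min_support``, the smaller
    side has at least ``min_cluster_size`` leaves from at least
    ``min_species_in_cluster`` species, and the stem-to-median branch-length
    ratio reaches θ.  Ties: larger support, then smaller cluster, then the
    lexicographically smallest member id.
    """
    cands = _candidate_clusters(tree, params, species_of)
    return cands[0] if cands else None


def _disjoint_cover(cands: list[DivergentCluster]) -> list[DivergentCluster]:
    chosen: list[DivergentCluster] = []
    for c in cands:
        if all(not (c.members & d.members) for d in chosen):
            chosen.append(c)
    return chosen


def default_tree_provider(n_bootstrap: int = 100, seed: int = 0) -> Callable:
    def provide(masked: MaskedAlignment) -> SupportTree:
        return bootstrap_support(masked, n_reps=n_bootstrap, seed=seed)

    return provide


def iterate_peel(
    records: Sequence[ProteinRecord],
    panel: SpeciesPanel,
    params: PeelParams | None = None,
    align_provider: Callable | None = None,
    mask_params: MaskParams | None = None,
    tree_provider: Callable | None = None,
) -> tuple[dict[str, frozenset], PeelTrace]:
    """Run the peel loop; returns cluster memberships and the step trace.

    ``align_provider(records) -> Alignment`` supplies an alignment for any
    subset (an external aligner adapter, or the simulator's true-alignment
    restriction).  ``tree_provider(MaskedAlignment) -> SupportTree`` defaults
    to NJ with bootstrap supports.
    """
    params = params or PeelParams()
    mask_params = mask_params or MaskParams()
    tree_provider = tree_provider or default_tree_provider()
    if align_provider is None:
        raise PeelError("align_provider is required")
    if len(records) < params.min_cluster_size:
        raise PeelError(
            f"need at least {params.min_cluster_size} sequences, got {len(records)}"
        )
    species_of = {r.id: r.species_code for r in records}
    missing = set(species_of.values()) - set(panel.codes)
    if missing:
        raise PeelError(f"species not in panel: {sorted(missing)}")

    def per_species(ids: Iterable[str]) -> tuple:
        ids = list(ids)
        return tuple(sum(1 for i in ids if species_of[i] == c) for c in panel.codes)

    current = list(records)
    clusters: dict[str, frozenset] = {}
    trace = PeelTrace()
    name_idx = 0
    step = 1
    while True:
        ids = [r.id for r in current]
        try:
            aln = align_provider(current)
            masked = mask_alignment(aln, mask_params)
            tree = tree_provider(masked)
        except Exception as e:
            raise PeelError(f"provider failure at step {step}: {e}") from e
        cands = _candidate_clusters(tree, params, species_of)
        n_total = len(current)

        def record_step(members: frozenset, support: float, terminal: bool, name: str):
            trace.steps.append(
                PeelStep(
                    step=step,
                    n_total=n_total,
                    n_per_species=per_species(ids),
                    positions=masked.n_retained,
                    cluster=name,
                    cluster_size=len(members),
                    cluster_per_species=per_species(members),
                    support=support,
                    terminal=terminal,
                )
            )

        if not cands:
            name_idx += 1
            members = frozenset(ids)
            clusters[f"C{name_idx}"] = members
            record_step(members, math.nan, True, f"C{name_idx}")
            break

        chosen = _disjoint_cover(cands)
        covered = frozenset().union(*(c.members for c in chosen))
        remainder = frozenset(ids) - covered
        if len(chosen) >= 1 and len(remainder) < params.min_cluster_size:
            # terminal multi-split: the qualifying clusters (plus any small
            # remainder) jointly exhaust the tree
            for c in chosen:
                name_idx += 1
                clusters[f"C{name_idx}"] = c.members
                record_step(c.members, c.support, True, f"C{name_idx}")
            if remainder:
                name_idx += 1
                clusters[f"C{name_idx}"] = remainder
                record_step(remainder, math.nan, True, f"C{name_idx}")
            break

        best = cands[0]
        name_idx += 1
        clusters[f"C{name_idx}"] = best.members
        record_step(best.members, best.support, False, f"C{name_idx}")
        current = [r for r in current if r.id not in best.members]
        step += 1
        if step > params.max_iterations or len(current) < params.min_cluster_size:
            if current:
                name_idx += 1
                members = frozenset(r.id for r in current)
                clusters[f"C{name_idx}"] = members
                n_total = len(current)
                ids = [r.id for r in current]
                trace.steps.append(
                    PeelStep(
                        step=step,
                        n_total=n_total,
                        n_per_species=per_species(ids),
                        positions=0,
                        cluster=f"C{name_idx}",
                        cluster_size=len(members),
                        cluster_per_species=per_species(members),
                        support=math.nan,
                        terminal=True,
                    )
                )
            break

    # conservation invariant: removed + terminal clusters partition the input
    union: set = set()
    total = 0
    for members in clusters.values():
        if union & members:
            raise PeelError("clusters overlap")
        union |= members
        total += len(members)
    if total != len(records) or union != set(species_of):
        raise PeelError("clusters do not partition the input sequences")
    return clusters, trace


def assign_to_clusters(
    extra_records: Sequence[ProteinRecord],
    db_records: Sequence[ProteinRecord],
    db_labels: dict[str, str],
    k: int = 5,
) -> dict[str, tuple[str | None, str]]:
    """Assign extra sequences to existing clusters by top-k hit unanimity.

    A label is assigned iff the top ``min(k, |db|)`` similarity hits all share
    one cluster label; otherwise the record is unassigned.  Small databases
    are flagged "reduced-k".
    """
    from ogpeel.classify_expand import rank_hits

    if not db_records:
        raise PeelError("empty cluster database")
    results = {}
    for rec in extra_records:
        hits = rank_hits(rec, db_records)
        top = hits[: min(k, len(hits))]
        labels = {db_labels[h.subject_id] for h in top}
        note = "reduced-k" if len(hits) < k else ""
        if len(labels) == 1:
            results[rec.id] = (labels.pop(), note)
        else:
            results[rec.id] = (None, note)
    return results
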