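"""Property-level evaluations of the pipeline on synthetic data.

Each function runs one of the package's verifiable properties end to end —
NJ consistency on additive distances, mask monotonicity, true-tree
orthogroup delineation, peel recovery, hold-out profile classification, and
the seed-versus-panel copy-number correlation — and returns plain numbers.
The test suite asserts on them and the acceptance script reports them; both
share this single implementation so the measured quantities are identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ogpeel.msa_mask import Alignment, MaskParams, mask_alignment
from ogpeel.peel import PeelParams, default_tree_provider, iterate_peel
from ogpeel.ogkit import delineate_ogs
from ogpeel.pipeline_report import evaluate_recovery
from ogpeel.simfam import SimConfig, SimResult, simulate_family, random_proteins, synthetic_panel_tree
from ogpeel.treekit import TreeNode, SupportTree, _nj_with_splits


# -- NJ consistency -------------------------------------------------------


def _random_additive_tree(n: int, rng) -> tuple[np.ndarray, list[str], set]:
    """Random binary tree with uniform branch lengths; returns its additive
    distance matrix, leaf labels, and canonical split set."""
    labels = [f"T{i + 1:02d}" for i in range(n)]
    nodes = [TreeNode(lab) for lab in labels]
    sets = [frozenset([lab]) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent = TreeNode()
        parent.add(a)
        parent.add(b)
        new_set = sets[i] | sets[j]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
        sets = [x for k, x in enumerate(sets) if k not in (i, j)] + [new_set]
    root = TreeNode()
    for x in nodes:
        x.length = float(rng.uniform(0.1, 1.0))
        root.add(x)
    tree = SupportTree(root)
    # additive distances from per-edge contributions
    full = frozenset(labels)
    index = {lab: k for k, lab in enumerate(labels)}
    D = np.zeros((n, n))
    for node in root.preorder():
        if node.parent is None:
            continue
        below = [index[x] for x in tree.leafset(node)]
        above = [index[x] for x in full - tree.leafset(node)]
        for bi in below:
            D[bi, above] += node.length
            D[above, bi] += node.length
    ref = min(labels)
    splits = set()
    for node in tree.internal_edges():
        s = tree.leafset(node)
        if 1 < len(s) < n - 1:
            splits.add(full - s if ref in s else s)
    return D, labels, splits


def nj_additivity_recovery(n_trees: int = 100, seed: int = 0, max_taxa: int = 12) -> float:
    """Fraction of random additive matrices whose NJ tree matches the
    generating topology exactly (split-set equality)."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_trees):
        n = int(rng.integers(4, max_taxa + 1))
        D, labels, true_splits = _random_additive_tree(n, rng)
        _, splits = _nj_with_splits(D, labels)
        ok += splits == true_splits
    return ok / n_trees


# -- mask monotonicity ----------------------------------------------------


def _random_alignment(rng) -> Alignment:
    n = int(rng.integers(4, 9))
    L = int(rng.integers(30, 81))
    alphabet = np.array(list("ACDEFGHIKL"))
    cols = []
    for _ in range(L):
        if rng.random() < 0.55:  # conserved-ish column
            base = alphabet[rng.integers(10)]
            col = np.where(rng.random(n) < 0.8, base, alphabet[rng.integers(0, 10, n)])
        else:
            col = alphabet[rng.integers(0, 10, n)]
        gapped = rng.random(n) < 0.15
        col = np.where(gapped, "-", col)
        cols.append(col)
    arr = np.stack(cols, axis=1)
    return Alignment([f"s{i}" for i in range(n)], ["".join(r) for r in arr])


def mask_monotonicity_violations(n_cases: int = 200, seed: int = 0) -> int:
    """Count violations of the masking monotonicity invariants: tightening
    the gap policy (all -> half -> none) or raising IS never increases the
    number of retained columns."""
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_cases):
        aln = _random_alignment(rng)
        n = aln.n_rows
        kept = {
            pol: mask_alignment(aln, MaskParams(gap_policy=pol)).n_retained
            for pol in ("all", "half", "none")
        }
        if not (kept["all"] >= kept["half"] >= kept["none"]):
            violations += 1
        base = n // 2 + 1
        for is_lo, is_hi in [(base, min(base + 1, n)), (base, n)]:
            lo = mask_alignment(
                aln, MaskParams(min_seqs_conserved=is_lo, min_seqs_flank=is_lo)
            ).n_retained
            hi = mask_alignment(
                aln, MaskParams(min_seqs_conserved=is_hi, min_seqs_flank=is_hi)
            ).n_retained
            if lo < hi:
                violations += 1
    return violations


# -- delineation on true trees -------------------------------------------


def delineation_recovery(
    n_seeds: int = 20, base_seed: int = 0, n_ogs: int = 6
) -> list[float]:
    """ARI of true-tree orthogroup delineation vs simulation truth, one value
    per seed, under loss-free full-support conditions."""
    out = []
    for s in range(n_seeds):
        cfg = SimConfig(
            n_ancestral_ogs=n_ogs, loss_rate=0.0, seed=base_seed * 1000 + s,
            pseudogene_prob=0.0, truncated_prob=0.0,
        )
        sim = simulate_family(cfg)
        out.append(_delineate_true_tree_ari(sim))
    return out


def _delineate_true_tree_ari(sim: SimResult) -> float:
    panel = sim.config.panel
    species_of = dict(zip(sim.truth.gene_id, sim.truth.species_code))
    predicted: dict[str, str] = {}
    tree = sim.true_family_tree
    for c_idx, cluster_node in enumerate(tree.root.children, start=1):
        sub = tree.subtree(cluster_node)
        ogs = delineate_ogs(sub, panel, species_of, family="SIM", cluster=f"C{c_idx}")
        for o in ogs:
            for g in o.members:
                predicted[g] = o.name
    return evaluate_recovery(predicted, sim.truth).ari


# -- peel recovery --------------------------------------------------------


def peel_cluster_recovery(
    n_seeds: int = 20, base_seed: int = 0, n_bootstrap: int = 50
) -> list[float]:
    """Rand index between peeled clusters and the true divergent-cluster
    partition, one value per seed, under the default divergent-cluster
    conditions."""
    from sklearn.metrics import rand_score

    out = []
    for s in range(n_seeds):
        cfg = SimConfig(seed=base_seed * 1000 + s)
        sim = simulate_family(cfg)
        clusters, trace = iterate_peel(
            sim.records,
            sim.config.panel,
            params=PeelParams(),
            align_provider=sim.alignment_provider(),
            tree_provider=default_tree_provider(n_bootstrap, seed=s),
        )
        trace.validate()
        label_of = {}
        for name, members in clusters.items():
            for g in members:
                label_of[g] = name
        truth_cluster = dict(zip(sim.truth.gene_id, sim.truth.true_cluster))
        genes = sorted(truth_cluster)
        out.append(
            float(rand_score([truth_cluster[g] for g in genes],
                             [label_of[g] for g in genes]))
        )
    return out


# -- hold-out profile classification --------------------------------------


def holdout_classification(
    n_seeds: int = 20,
    base_seed: int = 0,
    holdout_species: str = "ARATH",
    n_decoys_total: int = 1000,
) -> dict:
    """Build per-OG profiles without one species, then classify that species
    and random decoys.  Returns pooled assignment/false-positive rates."""
    from ogpeel.classify_expand import (
        background_frequencies, build_og_profile, classify_proteome,
    )

    n_members = n_correct = n_decoys = n_fp = 0
    per_seed_decoys = n_decoys_total // n_seeds
    for s in range(n_seeds):
        cfg = SimConfig(seed=base_seed * 1000 + s)
        sim = simulate_family(cfg)
        bg = background_frequencies(sim.records)
        members = sim.og_members()
        profiles = []
        for og, ids in sorted(members.items()):
            train = [i for i in ids if not i.startswith(holdout_species)]
            if len(train) < 2:
                continue
            og_aln = sim.true_alignment.subset(sorted(train))
            profiles.append(build_og_profile(og, og_aln, seed=s, background=bg))
        if not profiles:
            continue
        profiled = {p.og for p in profiles}
        truth = sim.truth
        pseudo = set(truth[truth.pseudogene].gene_id)
        true_of = dict(zip(truth.gene_id, truth.true_og))
        holdout = [
            r for r in sim.records
            if r.species_code == holdout_species
            and r.id not in pseudo
            and true_of.get(r.id, "") in profiled
        ]
        if holdout:
            for a in classify_proteome(holdout, profiles):
                n_members += 1
                n_correct += a.og == true_of[a.protein_id]
        decoys = random_proteins(per_seed_decoys, cfg.protein_length, seed=7_000_000 + s)
        for a in classify_proteome(decoys, profiles):
            n_decoys += 1
            n_fp += a.og is not None
    return {
        "n_members": n_members,
        "assignment_rate": n_correct / n_members if n_members else float("nan"),
        "n_decoys": n_decoys,
        "false_positive_rate": n_fp / n_decoys if n_decoys else float("nan"),
    }


# -- seed panel vs expanded panel -----------------------------------------


def seed_vs_panel(
    n_seeds: int = 10,
    base_seed: int = 0,
    n_monocot: int = 7,
    n_dicot: int = 12,
    n_ogs: int = 25,
    n_clusters: int = 10,
    protein_length: int = 120,
) -> list[float]:
    """Pearson r between per-OG totals of a 9-species curated subsample and
    profile-based classification of the full simulated panel, per seed.

    The family mirrors the curated reference framework: 25 ancestral cluster
    genes in 10 clusters, which (with pre-split duplications) found on the
    order of 44 orthogroups at the monocot/dicot ancestor.  Proteins are
    120 aa (profile scoring cost grows quadratically with length; margins
    are unaffected at this divergence).  Totals are taken over non-outgroup
    species in both matrices, matching the convention of keeping the
    outgroup in a separate column outside the family totals."""
    from ogpeel.classify_expand import (
        background_frequencies, build_og_profile, classify_proteome,
        copy_number_report, seed_vs_panel_correlation,
    )
    from ogpeel.core_io import CopyNumberMatrix

    panel, newick = synthetic_panel_tree(n_monocot, n_dicot)
    seed_species = (
        panel.outgroup_codes[:1]
        + panel.codes_for("monocot")[:3]
        + panel.codes_for("dicot")[:5]
    )
    rs = []
    for s in range(n_seeds):
        cfg = SimConfig(
            species_tree_newick=newick, panel=panel, seed=base_seed * 1000 + s,
            n_ancestral_ogs=n_ogs, n_clusters=n_clusters,
            protein_length=protein_length,
        )
        sim = simulate_family(cfg)
        bg = background_frequencies(sim.records)
        truth = sim.truth
        species_lookup = dict(zip(truth.gene_id, truth.species_code))
        members = sim.og_members()
        profiles, og_names = [], []
        for og, ids in sorted(members.items()):
            train = sorted(
                i for i in ids if species_lookup[i] in set(seed_species)
            )
            if len(train) < 2:
                continue
            og_aln = sim.true_alignment.subset(train)
            profiles.append(build_og_profile(og, og_aln, seed=s, background=bg))
            og_names.append(og)
        if len(og_names) < 3:
            continue
        species_of = dict(zip(truth.gene_id, truth.species_code))
        # curated seed matrix: truth counts over the 9 seed species
        seed_counts = pd.DataFrame(0, index=og_names, columns=panel.codes, dtype=int)
        for row in truth.itertuples(index=False):
            if row.true_og in set(og_names) and row.species_code in seed_species:
                seed_counts.loc[row.true_og, row.species_code] += 1
        ingroup = [c for c in panel.codes if c not in panel.outgroup_codes]
        matrix_seed = CopyNumberMatrix(seed_counts[ingroup])
        assignments = classify_proteome(sim.records, profiles)
        matrix_full, _ = copy_number_report(
            assignments, panel, species_of, og_names=og_names
        )
        matrix_full = CopyNumberMatrix(matrix_full.counts[ingroup])
        rs.append(seed_vs_panel_correlation(matrix_seed, matrix_full))
    return rs
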