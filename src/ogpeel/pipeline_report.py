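"""End-to-end orchestration, recovery metrics, and publication-style reports.

A run executes the full workflow — obtain data (simulate or ingest) ->
iterative peel -> per-cluster orthogroup delineation -> per-OG profile
construction -> proteome-wide classification — persisting a flat artifact
per stage (TSV/FASTA/newick/JSON), so externally computed alignments or
trees can be swapped in at any stage boundary and every reported number is
traceable to an on-disk artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ogpeel import __version__
from ogpeel.core_io import write_copy_number_matrix
from ogpeel.msa_mask import MaskParams, mask_alignment
from ogpeel.peel import PeelParams, default_tree_provider, iterate_peel
from ogpeel.ogkit import delineate_ogs, root_with_outgroup
from ogpeel.simfam import SimConfig, emit_fixture, simulate_family
from ogpeel.classify_expand import (
    build_og_profile,
    background_frequencies,
    classify_proteome,
    copy_number_report,
    profile_to_json,
)

log = logging.getLogger("ogpeel")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    sim: SimConfig = field(default_factory=SimConfig)
    peel: PeelParams = field(default_factory=PeelParams)
    mask: MaskParams = field(default_factory=MaskParams)
    delineation_support: float = 0.90
    consensus_k: int = 5
    evalue_max: float = 1e-3
    n_bootstrap: int = 100
    family: str = "FAM"
    seed: int = 0
    out_dir: str = "ogpeel_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["panel"] = [
            (e.code, e.lineage, e.display_name) for e in self.sim.panel.entries
        ]
        return d


@dataclass
class RecoveryMetrics:
    ari: float
    cluster_ari: float
    per_og: dict  # og -> {"precision": p, "recall": r}
    unassigned_fraction: float


def evaluate_recovery(predicted: dict[str, str], truth: pd.DataFrame) -> RecoveryMetrics:
    """Score a predicted OG labelling against the simulator truth table.

    ARI over the shared (non-outgroup) ids; per-OG precision/recall by
    Hungarian best-match mapping on the overlap-count matrix; the unassigned
    fraction (truth genes without a prediction) is reported separately.
    """
    from scipy.optimize import linear_sum_assignment
    from sklearn.metrics import adjusted_rand_score

    truth_in = truth[truth.true_og != ""]
    true_of = dict(zip(truth_in.gene_id, truth_in.true_og))
    cluster_of = dict(zip(truth_in.gene_id, truth_in.true_cluster))
    shared = [g for g in true_of if predicted.get(g) is not None]
    if not shared:
        raise ValueError("no overlap between predicted and truth ids")
    t = [true_of[g] for g in shared]
    p = [predicted[g] for g in shared]
    ari = float(adjusted_rand_score(t, p))
    c = [cluster_of[g] for g in shared]
    cluster_ari = float(adjusted_rand_score(c, p))

    t_names = sorted(set(t))
    p_names = sorted(set(p))
    overlap = np.zeros((len(t_names), len(p_names)))
    for ti, pi in zip(t, p):
        overlap[t_names.index(ti), p_names.index(pi)] += 1
    rows, cols = linear_sum_assignment(-overlap)
    per_og = {}
    for r, cidx in zip(rows, cols):
        inter = overlap[r, cidx]
        n_true = overlap[r].sum()
        n_pred = overlap[:, cidx].sum()
        per_og[t_names[r]] = {
            "precision": float(inter / n_pred) if n_pred else 0.0,
            "recall": float(inter / n_true) if n_true else 0.0,
        }
    unassigned = 1.0 - len(shared) / len(true_of)
    return RecoveryMetrics(ari, cluster_ari, per_og, unassigned)


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> peel -> delineate -> profile -> classify.

    Returns the run directory.  Stage artifacts: fixture/, trace.tsv,
    ogs.tsv, profiles/, assignments.tsv, matrix.tsv, metrics.json, run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("ogpeel %s", __version__)
        log.info("config: %s", json.dumps(config.to_dict(), default=str, sort_keys=True))
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), default=str, indent=2, sort_keys=True)
        )

        # stage 1: data
        sim = simulate_family(config.sim)
        emit_fixture(sim, out / "fixture", force=True)
        panel = config.sim.panel
        log.info("simulated %d genes in %d species", len(sim.records), len(panel.codes))

        # stage 2: peel
        clusters, trace = iterate_peel(
            sim.records,
            panel,
            params=config.peel,
            align_provider=sim.alignment_provider(),
            mask_params=config.mask,
            tree_provider=default_tree_provider(config.n_bootstrap, config.seed),
        )
        trace.validate()
        trace.to_frame().to_csv(out / "trace.tsv", sep="\t", index=False)
        log.info("peeled into %d clusters", len(clusters))

        # stage 3: delineate per cluster
        species_of = {r.id: r.species_code for r in sim.records}
        rec_by_id = {r.id: r for r in sim.records}
        all_ogs = []
        tree_provider = default_tree_provider(config.n_bootstrap, config.seed)
        for cname in sorted(clusters, key=lambda c: int(c[1:])):
            members = sorted(clusters[cname])
            sub_records = [rec_by_id[i] for i in members]
            ingroup = [i for i in members if panel.lineage_of(species_of[i]) != "outgroup"]
            if len(ingroup) == 0:
                log.info("%s: outgroup only, skipped", cname)
                continue
            if len(members) < 4 or len(ingroup) < 2:
                # too small for a tree: one OG per cluster
                from ogpeel.ogkit import Orthogroup

                all_ogs.append(
                    Orthogroup(f"OG-{config.family}-{cname}", sorted(ingroup), cname, {})
                )
                continue
            aln = sim.alignment_provider()(sub_records)
            masked = mask_alignment(aln, config.mask)
            tree = tree_provider(masked)
            has_outgroup = any(
                panel.lineage_of(species_of[i]) == "outgroup" for i in members
            )
            if has_outgroup:
                rooted = root_with_outgroup(tree, panel, species_of)
            else:
                longest = max(tree.internal_edges(), key=lambda n: n.length, default=None)
                rooted = tree.rooted_at_edge(longest) if longest else tree
            all_ogs.extend(
                delineate_ogs(
                    rooted, panel, species_of,
                    support_threshold=config.delineation_support,
                    family=config.family, cluster=cname,
                )
            )
        og_rows = [
            {"gene": g, "species": species_of[g], "og": o.name, "cluster": o.source_cluster}
            for o in all_ogs
            for g in o.members
        ]
        pd.DataFrame(og_rows).to_csv(out / "ogs.tsv", sep="\t", index=False)
        log.info("delineated %d orthogroups", len(all_ogs))

        # stage 4: profiles
        bg = background_frequencies(sim.records)
        profiles = []
        prof_dir = out / "profiles"
        prof_dir.mkdir(exist_ok=True)
        for o in all_ogs:
            if len(o.members) < 2:
                continue
            og_aln = sim.true_alignment.subset(sorted(o.members))
            prof = build_og_profile(o.name, og_aln, seed=config.seed, background=bg)
            profiles.append(prof)
            (prof_dir / f"{o.name}.json").write_text(
                json.dumps(profile_to_json(prof), sort_keys=True)
            )
        log.info("built %d profiles", len(profiles))

        # stage 5: classify the whole proteome
        metrics: dict = {
            "n_genes": len(sim.records),
            "n_clusters": len(clusters),
            "n_ogs": len(all_ogs),
            "n_profiles": len(profiles),
        }
        if profiles:
            assignments = classify_proteome(sim.records, profiles, config.evalue_max)
            pd.DataFrame(
                [
                    {
                        "protein": a.protein_id,
                        "og": a.og or "",
                        "bits": round(a.bits, 4),
                        "evalue": a.evalue,
                        "runner_up": a.runner_up or "",
                        "margin": round(a.margin, 4),
                    }
                    for a in assignments
                ]
            ).to_csv(out / "assignments.tsv", sep="\t", index=False)
            matrix, _ = copy_number_report(assignments, panel, species_of)
            write_copy_number_matrix(matrix, out / "matrix.tsv")

            predicted = {a.protein_id: a.og for a in assignments if a.og}
            m = evaluate_recovery(predicted, sim.truth)
            metrics["classification"] = {
                "ari": m.ari,
                "cluster_ari": m.cluster_ari,
                "unassigned_fraction": m.unassigned_fraction,
            }
        predicted_delineation = {
            g: o.name for o in all_ogs for g in o.members
        }
        md = evaluate_recovery(predicted_delineation, sim.truth)
        metrics["delineation"] = {
            "ari": md.ari,
            "cluster_ari": md.cluster_ari,
            "unassigned_fraction": md.unassigned_fraction,
            "per_og": md.per_og,
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
        log.info("metrics written")
        return out
    finally:
        log.removeHandler(handler)
        handler.close()


def render_reports(run_dir: str | Path, plots: bool = True) -> dict[str, Path]:
    """Render deterministic report tables (and optional plots) from artifacts.

    Nothing is recomputed: every rendered number comes from a persisted
    stage artifact; a missing artifact raises and names the stage to rerun.
    """
    run = Path(run_dir)
    outputs: dict[str, Path] = {}
    required = {"trace.tsv": "peel", "ogs.tsv": "delineate", "matrix.tsv": "classify"}
    for fname, stage in required.items():
        if not (run / fname).exists():
            raise FileNotFoundError(
                f"missing artifact {fname}; rerun the {stage!r} stage"
            )

    trace = pd.read_csv(run / "trace.tsv", sep="\t")
    report_trace = trace[
        ["step", "n_total", "n_per_species", "positions", "cluster",
         "cluster_size", "support"]
    ]
    p = run / "report_trace.tsv"
    report_trace.to_csv(p, sep="\t", index=False)
    outputs["trace"] = p

    matrix = pd.read_csv(run / "matrix.tsv", sep="\t", index_col=0)
    p = run / "report_matrix.tsv"
    matrix.to_csv(p, sep="\t")
    outputs["matrix"] = p

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        body = matrix.drop(index=[i for i in matrix.index if i == "Total"])
        body = body.drop(columns=[c for c in body.columns if c == "Total"])
        body = body.replace("-", 0).astype(int)
        fig, ax = plt.subplots(figsize=(8, 4))
        bottom = np.zeros(len(body.columns))
        for og, row in body.iterrows():
            ax.bar(body.columns, row.to_numpy(), bottom=bottom, label=og)
            bottom += row.to_numpy()
        ax.set_ylabel("family genes")
        ax.set_title("family copy numbers per species (stacked by OG)")
        fig.tight_layout()
        p = run / "report_counts.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        outputs["counts_plot"] = p

        truth_path = run / "fixture" / "truth.tsv"
        ogs_path = run / "ogs.tsv"
        if truth_path.exists() and ogs_path.exists():
            # per-OG totals: classified (matrix rows) vs delineated memberships
            delineated = pd.read_csv(ogs_path, sep="\t").groupby("og").size()
            classified = body.sum(axis=1)
            shared = sorted(set(delineated.index) & set(classified.index))
            if shared:
                fig, ax = plt.subplots(figsize=(4.5, 4.5))
                ax.scatter(delineated[shared], classified[shared], s=18)
                lim = max(delineated[shared].max(), classified[shared].max()) + 1
                ax.plot([0, lim], [0, lim], lw=0.8, color="grey")
                ax.set_xlabel("OG size (tree delineation)")
                ax.set_ylabel("OG size (profile classification)")
                ax.set_title("per-OG copy numbers: delineated vs classified")
                fig.tight_layout()
                p = run / "report_scatter.png"
                fig.savefig(p, dpi=100)
                plt.close(fig)
                outputs["scatter_plot"] = p
    return outputs
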