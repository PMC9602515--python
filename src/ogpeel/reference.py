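"""Loaders for the bundled reference summaries of the curated GELP
classification (nine angiosperm genomes: 1 outgroup, 3 monocots, 5 dicots).

Three small TSVs ship with the package:

* ``peel_trace_gelp.tsv`` — the per-step bookkeeping of the iterative peeling
  of the three-species global family tree (sequences analysed, retained
  alignment positions, removed divergent cluster and its size/support);
* ``cluster_compositions_gelp.tsv`` — per-cluster nine-species compositions
  used for the cluster-specific delineation trees;
* ``og_matrix_gelp.tsv`` — the final orthogroup x species copy-number matrix
  with the consensus exon structure per orthogroup.

These are inputs for worked examples and cross-checks; nothing in the
pipeline depends on them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ogpeel.core_io import CopyNumberMatrix, SpeciesPanel
from ogpeel.peel import PeelTrace, PeelStep


def _data(name: str):
    return resources.files("ogpeel.data").joinpath(name)


def load_reference_panel() -> SpeciesPanel:
    return SpeciesPanel.default()


def load_reference_trace() -> PeelTrace:
    """The iterative-peeling trace of the curated three-species analysis."""
    with _data("peel_trace_gelp.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    steps = []
    for row in df.itertuples(index=False):
        steps.append(
            PeelStep(
                step=int(row.step),
                n_total=int(row.n_total),
                n_per_species=tuple(int(x) for x in str(row.n_per_species).split("-")),
                positions=int(row.positions),
                cluster=row.cluster,
                cluster_size=int(row.cluster_size),
                cluster_per_species=tuple(
                    int(x) for x in str(row.cluster_per_species).split("-")
                ),
                support=float(row.support),
                terminal=bool(row.terminal),
            )
        )
    return PeelTrace(steps)


def load_reference_cluster_compositions() -> pd.DataFrame:
    """Per-cluster nine-species compositions; species counts expanded to columns."""
    with _data("cluster_compositions_gelp.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    panel = load_reference_panel()
    counts = df["n_per_species"].str.split("-", expand=True).astype(int)
    counts.columns = panel.codes
    return pd.concat([df[["cluster", "n_total", "positions"]], counts], axis=1)


def load_reference_og_matrix() -> tuple[CopyNumberMatrix, dict[str, str]]:
    """The curated orthogroup x species matrix and per-OG exon structures."""
    with _data("og_matrix_gelp.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    structures = df["exon_structure"].to_dict()
    body = df.drop(columns=["exon_structure"])
    body = body.map(lambda v: 0 if v in ("-", "") or pd.isna(v) else int(v))
    return CopyNumberMatrix(body), structures
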