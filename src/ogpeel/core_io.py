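"""Data model and readers/writers for the formats the pipeline touches.

Conventions
-----------
* Genomic coordinates are 1-based inclusive (GFF3); protein positions 1-based.
* Protein FASTA headers follow ``>SPECIES|id`` with optional suffix markers:
  a trailing ``*`` marks a curated (manually corrected) gene model, and
  ``;pseudogene`` / ``;truncated`` flag sequences that are tagged but always
  retained in the analyses.  The convention is configurable via a regex for
  third-party files.
* Copy-number matrices render zero cells as ``-`` (the convention of printed
  gene-family tables); a flag switches to plain ``0`` for machine use.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

OUTGROUP = "outgroup"
MONOCOT = "monocot"
DICOT = "dicot"
LINEAGES = (OUTGROUP, MONOCOT, DICOT)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET_X = AA_ALPHABET | {"X"}

#: Active-site motif variants observed across the family clusters.  The
#: canonical Gly-Asp-Ser-Leu (GDSL) motif is replaced by GDSY in one cluster
#: and by GSSI/GDSI in another.
MOTIF_VARIANTS = ("GDSL", "GDSY", "GSSI", "GDSI")

DEFAULT_HEADER_RE = re.compile(
    r"^(?P<species>[A-Za-z0-9]+)\|(?P<id>[^;|\s*]+)"
    r"(?P<curated>\*)?(?P<flags>(?:;(?:pseudogene|truncated))*)\s*$"
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class PanelEntry:
    code: str
    lineage: str
    display_name: str = ""


@dataclass
class SpeciesPanel:
    """Panel of species with lineage labels (outgroup / monocot / dicot)."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        dup = {c for c in codes if codes.count(c) > 1}
        if dup:
            raise FormatError(f"duplicate species code(s) in panel: {sorted(dup)}")
        bad = [e for e in self.entries if e.lineage not in LINEAGES]
        if bad:
            raise FormatError(
                f"unknown lineage label(s): {sorted({e.lineage for e in bad})}"
            )

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    def lineage_of(self, code: str) -> str:
        for e in self.entries:
            if e.code == code:
                return e.lineage
        raise KeyError(f"species code {code!r} not in panel")

    def codes_for(self, lineage: str) -> list[str]:
        return [e.code for e in self.entries if e.lineage == lineage]

    @property
    def outgroup_codes(self) -> list[str]:
        return self.codes_for(OUTGROUP)

    def validate_for_delineation(self) -> None:
        """Orthogroup delineation needs at least one monocot and one dicot."""
        if not self.codes_for(MONOCOT):
            raise FormatError("panel has no monocot species; cannot delineate OGs")
        if not self.codes_for(DICOT):
            raise FormatError("panel has no dicot species; cannot delineate OGs")

    @classmethod
    def default(cls) -> "SpeciesPanel":
        """Bundled nine-species angiosperm panel (1 outgroup, 3 monocots, 5 dicots)."""
        with resources.files("ogpeel.data").joinpath("panel_gelp9.tsv").open() as fh:
            return _parse_panel(fh)


def _parse_panel(fh) -> SpeciesPanel:
    df = pd.read_csv(fh, sep="\t", dtype=str, comment="#")
    required = {"code", "lineage", "name"}
    if not required.issubset(df.columns):
        raise FormatError(f"panel needs columns {sorted(required)}, got {list(df.columns)}")
    entries = [
        PanelEntry(row.code, row.lineage, row.name) for row in df.itertuples(index=False)
    ]
    return SpeciesPanel(entries)


def read_species_panel(path: str | Path) -> SpeciesPanel:
    with open(path) as fh:
        return _parse_panel(fh)


def write_species_panel(panel: SpeciesPanel, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.code, e.lineage, e.display_name) for e in panel.entries],
        columns=["code", "lineage", "name"],
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class ProteinRecord:
    """A protein sequence with its species and curation flags.

    Flagged records (pseudogene, truncated) are tagged but never dropped.
    """

    id: str
    species_code: str
    sequence: str
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - AA_ALPHABET_X
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )
        unknown = self.flags - {"curated", "pseudogene", "truncated"}
        if unknown:
            raise FormatError(f"record {self.id!r}: unknown flags {sorted(unknown)}")

    @property
    def curated(self) -> bool:
        return "curated" in self.flags


def read_fasta(
    path: str | Path,
    panel: SpeciesPanel | None = None,
    header_re: re.Pattern = DEFAULT_HEADER_RE,
) -> list[ProteinRecord]:
    """Read protein FASTA; species code and flags parsed from the header.

    Raises on duplicate ids, empty sequences, and (when a panel is supplied)
    species codes absent from the panel.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        header = seq_rec.description
        m = header_re.match(header)
        if not m:
            raise FormatError(f"header {header!r} does not match the header convention")
        flags = set()
        if m.group("curated"):
            flags.add("curated")
        for tok in (m.group("flags") or "").split(";"):
            if tok:
                flags.add(tok)
        species = m.group("species")
        rec_id = m.group("id")
        if panel is not None and species not in panel.codes:
            raise FormatError(f"record {rec_id!r}: species {species!r} not in panel")
        key = f"{species}|{rec_id}"
        if key in seen:
            raise FormatError(f"duplicate record id {key!r}")
        seen.add(key)
        records.append(
            ProteinRecord(rec_id, species, str(seq_rec.seq).upper(), frozenset(flags))
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_recs = []
    for r in records:
        suffix = "*" if r.curated else ""
        extra = "".join(f";{f}" for f in sorted(r.flags - {"curated"}))
        seq_recs.append(
            SeqRecord(Seq(r.sequence), id=f"{r.species_code}|{r.id}{suffix}{extra}",
                      description="")
        )
    SeqIO.write(seq_recs, str(path), "fasta")


@dataclass
class GeneModel:
    """Gene coordinates: exons and CDS segments in 1-based inclusive coordinates.

    ``exons`` and ``cds_segments`` are stored in transcription (5'->3') order,
    so for minus-strand genes starts are descending.  ``position_index`` is the
    rank of the gene among all annotated genes on its chromosome; it feeds the
    tandem-array neighbourhood rule.
    """

    gene_id: str
    protein_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]
    position_index: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise FormatError(f"gene {self.gene_id!r}: overlapping exons")
        for s, e in self.exons + self.cds_segments:
            if s > e:
                raise FormatError(f"gene {self.gene_id!r}: span start > end")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon/CDS); one model per mRNA.

    Minus-strand exon lists are reversed into transcription order.  Gene ranks
    per chromosome (``position_index``) are computed over all gene features.
    A trailing ``##FASTA`` section is ignored.
    """
    import gffutils

    text = Path(path).read_text()
    if "##FASTA" in text:
        text = text.split("##FASTA")[0]
    db = gffutils.create_db(
        text, ":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )

    genes = list(db.features_of_type("gene"))
    rank: dict[str, int] = {}
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.seqid, []).append(g)
    for chrom_genes in by_chrom.values():
        for i, g in enumerate(sorted(chrom_genes, key=lambda f: (f.start, f.id))):
            rank[g.id] = i

    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        if not parents:
            raise FormatError(f"mRNA {mrna.id!r}: missing Parent gene")
        gene = parents[0]
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            raise FormatError(f"mRNA {mrna.id!r}: no exons")
        exons.sort()
        cds.sort()
        for cs, ce in cds:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                raise FormatError(
                    f"mRNA {mrna.id!r}: CDS ({cs},{ce}) outside exon bounds"
                )
        if mrna.strand == "-":
            exons = exons[::-1]
            cds = cds[::-1]
        protein_id = mrna.attributes.get("protein_id", [mrna.id])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                protein_id=protein_id,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
                position_index=rank.get(gene.id),
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS, one mRNA per gene)."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda g: (g.chromosome, min(s for s, _ in g.exons))):
        spans = sorted(m.exons)
        g_start, g_end = spans[0][0], spans[-1][1]
        gid, tid = m.gene_id, f"{m.gene_id}.t1"
        lines.append(
            f"{m.chromosome}\togpeel\tgene\t{g_start}\t{g_end}\t.\t{m.strand}\t.\t"
            f"ID={gid}"
        )
        lines.append(
            f"{m.chromosome}\togpeel\tmRNA\t{g_start}\t{g_end}\t.\t{m.strand}\t.\t"
            f"ID={tid};Parent={gid};protein_id={m.protein_id}"
        )
        for i, (s, e) in enumerate(sorted(m.exons), 1):
            lines.append(
                f"{m.chromosome}\togpeel\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={tid}.exon{i};Parent={tid}"
            )
        for i, (s, e) in enumerate(sorted(m.cds_segments), 1):
            lines.append(
                f"{m.chromosome}\togpeel\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                f"ID={tid}.cds{i};Parent={tid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class MotifReport:
    variant: str  # one of MOTIF_VARIANTS or "absent"
    position: int | None  # 1-based position of the first motif residue


def motif_scan(record: ProteinRecord, window: int = 120) -> MotifReport:
    """Report the active-site motif variant in the N-terminal window.

    The serine-hydrolase block (GDSL or a variant) sits shortly after the
    signal peptide, so only the first ``window`` residues are scanned.  The
    earliest match of any variant wins; "absent" is a value, not an error.
    """
    region = record.sequence[:window]
    best: tuple[int, str] | None = None
    for variant in MOTIF_VARIANTS:
        pos = region.find(variant)
        if pos >= 0 and (best is None or pos < best[0]):
            best = (pos, variant)
    if best is None:
        return MotifReport("absent", None)
    return MotifReport(best[1], best[0] + 1)


def species_map_from_ids(ids: Iterable[str], panel: SpeciesPanel) -> dict:
    """Infer species codes from sequence ids (``SPECIES|x`` or ``SPECIES_x``).

    Used when tree leaves or FASTA ids follow the panel's code convention;
    ids that resolve to no panel code raise.
    """
    codes = set(panel.codes)
    out = {}
    for i in ids:
        for sep in ("|", "_"):
            prefix = i.split(sep)[0]
            if prefix in codes:
                out[i] = prefix
                break
        else:
            raise FormatError(f"cannot infer a panel species from id {i!r}")
    return out


class CopyNumberMatrix:
    """Orthogroup x species copy-number table with row/column totals."""

    def __init__(self, counts: pd.DataFrame):
        arr = counts.to_numpy()
        if not (arr == arr.astype(int)).all() or (arr < 0).any():
            raise FormatError("copy-number cells must be non-negative integers")
        self.counts = counts.astype(int)

    @property
    def og_names(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def dicot_specific_ogs(self, panel: SpeciesPanel, min_dicot_species: int = 2) -> list[str]:
        """OGs absent from every monocot but present in >= 2 dicot species."""
        monocots = [c for c in panel.codes_for(MONOCOT) if c in self.counts.columns]
        dicots = [c for c in panel.codes_for(DICOT) if c in self.counts.columns]
        out = []
        for og in self.og_names:
            row = self.counts.loc[og]
            if monocots and row[monocots].sum() == 0:
                if (row[dicots] > 0).sum() >= min_dicot_species:
                    out.append(og)
        return out

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CopyNumberMatrix) and self.counts.equals(other.counts)


def write_copy_number_matrix(
    matrix: CopyNumberMatrix, path: str | Path, dash_for_zero: bool = True
) -> None:
    df = matrix.counts.copy()
    df["Total"] = matrix.row_totals
    total_row = df.sum(axis=0)
    df.loc["Total"] = total_row
    out = df.astype(object)
    if dash_for_zero:
        body = out.iloc[:-1, :-1]
        out.iloc[:-1, :-1] = body.mask(body == 0, "-")
    out.index.name = "Orthogroup"
    out.to_csv(path, sep="\t")


def read_copy_number_matrix(path: str | Path) -> CopyNumberMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "Total" in df.columns:
        df = df.drop(columns=["Total"])
    if "Total" in df.index:
        df = df.drop(index=["Total"])

    def parse_cell(v) -> int:
        if pd.isna(v) or v in ("-", ""):
            return 0
        try:
            f = float(v)
        except ValueError as e:
            raise FormatError(f"non-numeric copy-number cell {v!r}") from e
        if f != int(f):
            raise FormatError(f"non-integer copy-number cell {v!r}")
        return int(f)

    parsed = df.map(parse_cell)
    return CopyNumberMatrix(parsed)
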