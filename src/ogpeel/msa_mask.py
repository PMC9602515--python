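"""Alignment ingestion and Gblocks-style block masking.

Poorly aligned alignment columns are removed before distance and tree
computation by a block-cleaning procedure in the style of Gblocks, with the
*relaxed* options commonly used for divergent families: smaller final blocks,
gap positions tolerated inside blocks, and less strict flanking positions.
The numeric defaults below encode that relaxed regime; identity with any
particular external binary is not claimed, and every parameter is exposed.

The five rules, applied in order:

1. classify each column by the count ``c`` of its most frequent non-gap,
   non-X residue: *non-conserved* (``c < IS``), *conserved* (``c >= IS``),
   *highly conserved* (``c >= FS``);
2. reject contiguous non-conserved stretches longer than ``CP`` columns;
3. trim the flanks of each remaining block inward to the nearest highly
   conserved column (blocks without one are dropped);
4. reject columns violating the gap policy (``none``: any gap; ``half``:
   >50% gaps; ``all``: gaps never reject a column);
5. reject surviving blocks shorter than ``BL`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """A plain multiple alignment: parallel lists of ids and aligned rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise AlignmentError("ragged alignment (unequal row lengths)")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subset(self, ids: list[str]) -> "Alignment":
        """Rows restricted to ``ids`` (order as given), all-gap columns dropped."""
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [self.rows[index[i]] for i in ids]
        arr = np.array([list(r) for r in rows])
        keep = ~(arr == GAP).all(axis=0)
        return Alignment(list(ids), ["".join(row) for row in arr[:, keep]])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            [SeqRecord(Seq(r), id=i, description="") for i, r in zip(self.ids, self.rows)],
            str(path),
            "fasta",
        )


@dataclass
class MaskParams:
    """Block-cleaning parameters (relaxed defaults; see module docstring).

    ``min_seqs_conserved`` (IS) and ``min_seqs_flank`` (FS) default to
    ``floor(n/2) + 1`` at mask time — FS equal to IS is the "less strict
    flanking" relaxation.
    """

    min_seqs_conserved: int | None = None  # IS
    min_seqs_flank: int | None = None  # FS
    max_contig_nonconserved: int = 8  # CP
    min_block_length: int = 5  # BL
    gap_policy: str = "half"  # none | half | all

    def resolve(self, n_rows: int) -> tuple[int, int]:
        is_ = self.min_seqs_conserved if self.min_seqs_conserved is not None else n_rows // 2 + 1
        fs = self.min_seqs_flank if self.min_seqs_flank is not None else is_
        if not (1 <= is_ <= fs <= n_rows):
            raise AlignmentError(f"need 1 <= IS({is_}) <= FS({fs}) <= n({n_rows})")
        if self.max_contig_nonconserved < 1 or self.min_block_length < 1:
            raise AlignmentError("CP and BL must be >= 1")
        if self.gap_policy not in ("none", "half", "all"):
            raise AlignmentError(f"unknown gap_policy {self.gap_policy!r}")
        return is_, fs


@dataclass
class MaskedAlignment:
    alignment: Alignment
    mask: np.ndarray  # boolean per column
    params: MaskParams = field(default_factory=MaskParams)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.alignment.n_cols,):
            raise AlignmentError("mask length must equal alignment length")

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) spans of consecutive True."""
    out = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(flags)))
    return out


def mask_alignment(aln: Alignment, params: MaskParams | None = None) -> MaskedAlignment:
    """Apply the five block-cleaning rules; the mask is True on kept columns."""
    params = params or MaskParams()
    if aln.n_rows < 2:
        raise AlignmentError("need at least 2 aligned rows")
    is_, fs = params.resolve(aln.n_rows)

    arr = np.array([list(r) for r in aln.rows])
    n, L = arr.shape
    # top non-gap, non-X residue count per column
    top = np.zeros(L, dtype=int)
    gaps = (arr == GAP).sum(axis=0)
    for j in range(L):
        col = arr[:, j]
        col = col[(col != GAP) & (col != "X")]
        if col.size:
            _, counts = np.unique(col, return_counts=True)
            top[j] = counts.max()
    conserved = top >= is_
    highly = top >= fs

    keep = np.ones(L, dtype=bool)
    # rule 2: long non-conserved stretches
    for s, e in _runs(~conserved):
        if e - s > params.max_contig_nonconserved:
            keep[s:e] = False
    # rule 3: trim block flanks to the nearest highly conserved column
    trimmed = np.zeros(L, dtype=bool)
    for s, e in _runs(keep):
        hc = np.nonzero(highly[s:e])[0]
        if hc.size:
            trimmed[s + hc[0] : s + hc[-1] + 1] = True
    keep = trimmed
    # rule 4: gap policy
    if params.gap_policy == "none":
        keep &= gaps == 0
    elif params.gap_policy == "half":
        keep &= gaps <= n / 2
    # rule 5: minimum block length
    final = keep.copy()
    for s, e in _runs(keep):
        if e - s < params.min_block_length:
            final[s:e] = False
    return MaskedAlignment(aln, final, params)


def apply_mask(masked: MaskedAlignment) -> Alignment:
    """Sub-alignment of retained columns; row order preserved."""
    import warnings

    if masked.n_retained == 0:
        warnings.warn("mask retains zero columns; downstream stages will fail")
    cols = np.nonzero(masked.mask)[0]
    arr = np.array([list(r) for r in masked.alignment.rows])
    return Alignment(list(masked.alignment.ids), ["".join(r) for r in arr[:, cols]])


def external_aligner_provider(command: str = "mafft"):
    """Align-provider backed by an external aligner (MAFFT-compatible CLI).

    The returned callable takes protein records, writes a temporary FASTA,
    runs ``command --auto <fasta>`` and parses the aligned FASTA from
    stdout.  Used when no precomputed alignment is available.
    """
    import subprocess
    import tempfile

    def provide(records) -> Alignment:
        with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.sequence}\n")
            path = fh.name
        try:
            proc = subprocess.run(
                [command, "--auto", "--anysymbol", path],
                capture_output=True, text=True, check=True,
            )
        except FileNotFoundError as e:
            raise AlignmentError(f"external aligner {command!r} not found") from e
        except subprocess.CalledProcessError as e:
            raise AlignmentError(
                f"external aligner failed: {e.stderr.splitlines()[-1] if e.stderr else e}"
            ) from e
        finally:
            Path(path).unlink(missing_ok=True)
        ids, rows, cur = [], [], []
        for line in proc.stdout.splitlines():
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur).upper())
                    cur = []
                ids.append(line[1:].split()[0])
            else:
                cur.append(line.strip())
        if cur:
            rows.append("".join(cur).upper())
        order = {i: k for k, i in enumerate(ids)}
        want = [r.id for r in records]
        return Alignment(want, [rows[order[i]] for i in want])

    return provide


def subset_alignment_provider(full: Alignment):
    """Align-provider that restricts a precomputed full alignment."""

    def provide(records) -> Alignment:
        return full.subset([r.id for r in records])

    return provide


def mask_report(masked: MaskedAlignment) -> "pd.DataFrame":
    """Per-column report: index, conservation class, kept flag."""
    import pandas as pd

    aln, params = masked.alignment, masked.params
    is_, fs = params.resolve(aln.n_rows)
    arr = np.array([list(r) for r in aln.rows])
    rows = []
    for j in range(aln.n_cols):
        col = arr[:, j]
        col = col[(col != GAP) & (col != "X")]
        top = 0
        if col.size:
            _, counts = np.unique(col, return_counts=True)
            top = int(counts.max())
        klass = "highly_conserved" if top >= fs else ("conserved" if top >= is_ else "non_conserved")
        rows.append((j, klass, bool(masked.mask[j])))
    return pd.DataFrame(rows, columns=["column", "class", "kept"])
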