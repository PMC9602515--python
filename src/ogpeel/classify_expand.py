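"""Similarity ranking, top-k consensus assignment, per-OG profiles, and
proteome-wide classification.

The similarity engine is deterministic and in-repo: Smith-Waterman local
alignment under BLOSUM62 with affine gaps for pairwise ranking, and a
position-specific scoring model (log-odds PSSM with affine gap penalties and
Gumbel-calibrated e-values) per orthogroup for profile search.  External
similarity or profile tools can be substituted through the tabular-ranking
adapter; only the decision rules layered on the scores (top-k unanimity,
best-profile-below-threshold) define the classification.

E-values follow the fitted Gumbel null: ``E = n_db * exp(-lambda * (S - mu))``
with (mu, lambda) estimated from scores of shuffled member sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ogpeel.core_io import AA_ALPHABET, ProteinRecord, SpeciesPanel, CopyNumberMatrix
from ogpeel.msa_mask import GAP, Alignment

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
X_CODE = 20
PAD_CODE = 21
NEG = -1e9

GAP_OPEN_BITS = 4.0
GAP_EXTEND_BITS = 0.25
EULER_GAMMA = 0.5772156649015329


class ClassifyError(RuntimeError):
    pass


def _encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        if ch in _AA_INDEX:
            out[i] = _AA_INDEX[ch]
        elif ch == "X":
            out[i] = X_CODE
        else:
            raise ClassifyError(f"non-amino-acid character {ch!r}")
    return out


# -- pairwise Smith-Waterman ----------------------------------------------

_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio.Align import PairwiseAligner, substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        mat = mat.copy()
        # X is a wildcard: zero against everything
        for ch in mat.alphabet:
            mat["X", ch] = 0.0
            mat[ch, "X"] = 0.0
        a = PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = mat
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def pairwise_score(query: str | ProteinRecord, subject: str | ProteinRecord) -> float:
    """Smith-Waterman local alignment score (BLOSUM62, gap open 11 extend 1)."""
    q = query.sequence if isinstance(query, ProteinRecord) else query
    s = subject.sequence if isinstance(subject, ProteinRecord) else subject
    if not q or not s:
        raise ClassifyError("empty sequence")
    for seq in (q, s):
        bad = set(seq) - AA_ALPHABET - {"X"}
        if bad:
            raise ClassifyError(f"non-amino-acid characters {sorted(bad)}")
    return float(_aligner().score(q, s))


@dataclass(frozen=True)
class Hit:
    subject_id: str
    score: float


def rank_hits(query: ProteinRecord, database: list[ProteinRecord]) -> list[Hit]:
    """Database hits in descending score order; ties by subject id."""
    if not database:
        raise ClassifyError("empty database")
    hits = [Hit(s.id, pairwise_score(query, s)) for s in database]
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def read_blast_tabular(path: str | Path) -> dict[str, list[Hit]]:
    """Adapter for external tabular rankings (12-column outfmt-6 style)."""
    out: dict[str, list[Hit]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ClassifyError(f"expected 12 tab-separated columns, got {len(parts)}")
        out.setdefault(parts[0], []).append(Hit(parts[1], float(parts[11])))
    return out


def consensus_assign(
    hits: list[Hit], labels: dict[str, str], k: int = 5
) -> tuple[str | None, str]:
    """Assign iff the top min(k, |hits|) hit labels are unanimous.

    Returns (label-or-None, note); small hit lists are flagged "reduced-k".
    """
    import warnings

    if not hits:
        warnings.warn("no hits; record left unassigned")
        return None, "no-hits"
    top = hits[: min(k, len(hits))]
    top_labels = {labels[h.subject_id] for h in top}
    note = "reduced-k" if len(hits) < k else ""
    if len(top_labels) == 1:
        return top_labels.pop(), note
    return None, note


# -- per-OG profiles -------------------------------------------------------


@dataclass
class Calibration:
    mu: float
    lam: float
    n_decoys: int
    seed: int


@dataclass
class OGProfile:
    og: str
    match_columns: list[int]  # alignment columns kept as match states
    emissions: np.ndarray  # (n_match, 22) log2-odds; X=0, pad=NEG
    background: np.ndarray  # (20,)
    gap_open: float = GAP_OPEN_BITS
    gap_extend: float = GAP_EXTEND_BITS
    calibration: Calibration | None = None

    @property
    def length(self) -> int:
        return self.emissions.shape[0]


def background_frequencies(records_or_alignment) -> np.ndarray:
    """Residue frequencies over a sequence collection (pseudocount 1)."""
    counts = np.ones(20)
    seqs = (
        records_or_alignment.rows
        if isinstance(records_or_alignment, Alignment)
        else [r.sequence for r in records_or_alignment]
    )
    for s in seqs:
        for ch in s:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
    return counts / counts.sum()


def build_og_profile(
    og_name: str,
    og_alignment: Alignment,
    seed: int,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
    n_decoys: int = 200,
) -> OGProfile:
    """PSSM from an OG alignment, with Gumbel calibration from shuffled decoys.

    Match columns are those with a gap fraction <= ``max_gap_fraction``;
    emissions are ``log2((c_a + q_a) / (N_col + 1) / q_a)`` with background
    pseudocounts.  Calibration scores ``n_decoys`` length-matched shuffles of
    member sequences and fits the Gumbel by moments.
    """
    if og_alignment.n_rows < 2:
        raise ClassifyError(f"{og_name}: need >= 2 member rows to build a profile")
    arr = np.array([list(r) for r in og_alignment.rows])
    n, L = arr.shape
    gap_frac = (arr == GAP).mean(axis=0)
    match_cols = [j for j in range(L) if gap_frac[j] <= max_gap_fraction]
    if not match_cols:
        raise ClassifyError(f"{og_name}: no match columns (alignment too gappy)")
    q = background if background is not None else background_frequencies(og_alignment)
    m = len(match_cols)
    emissions = np.full((m, 22), 0.0)
    for k, j in enumerate(match_cols):
        col = arr[:, j]
        counts = np.zeros(20)
        n_col = 0
        for ch in col:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
                n_col += 1
        emissions[k, :20] = np.log2((counts + q) / (n_col + 1) / q)
        emissions[k, X_CODE] = 0.0
        emissions[k, PAD_CODE] = NEG
    profile = OGProfile(og_name, match_cols, emissions, q)
    _calibrate(profile, og_alignment, n_decoys, seed)
    return profile


def _calibrate(profile: OGProfile, og_alignment: Alignment, n_decoys: int, seed: int) -> None:
    rng = np.random.default_rng(seed)
    members = ["".join(ch for ch in r if ch != GAP) for r in og_alignment.rows]
    decoys = []
    for _ in range(n_decoys):
        src = members[int(rng.integers(len(members)))]
        perm = rng.permutation(len(src))
        decoys.append("".join(src[i] for i in perm))
    scores = score_sequences(decoys, profile)
    mean, std = float(np.mean(scores)), float(np.std(scores))
    if std <= 0:
        raise ClassifyError(f"{profile.og}: degenerate decoy score distribution")
    lam = math.pi / (std * math.sqrt(6.0))
    mu = mean - EULER_GAMMA / lam
    profile.calibration = Calibration(mu, lam, n_decoys, seed)


def score_sequences(seqs: list[str], profile: OGProfile) -> np.ndarray:
    """Batched profile DP scores (bits), query-local / profile-global.

    All profile match columns must be consumed (deletions at gap cost);
    unaligned query prefixes/suffixes are free, internal query insertions pay
    the affine penalty.
    """
    if not seqs:
        return np.zeros(0)
    nmax = max(len(s) for s in seqs)
    B = len(seqs)
    q = np.full((B, nmax), PAD_CODE, dtype=np.int8)
    for b, s in enumerate(seqs):
        q[b, : len(s)] = _encode(s)
    open_, ext = profile.gap_open, profile.gap_extend
    m = profile.length
    emis = profile.emissions

    idx = np.arange(nmax + 1)
    # V[b, i]: best score with profile prefix consumed, query prefix ending at i
    V = np.zeros((B, nmax + 1))
    Iy = np.full((B, nmax + 1), NEG)
    for j in range(m):
        e = emis[j][q]  # (B, nmax)
        # query insertions between column j and j+1 (free before column 1)
        if j == 0:
            W = V
        else:
            A = np.maximum.accumulate(V + ext * idx[None, :], axis=1)
            ins = A[:, :-1] - open_ - ext * idx[None, 1:] + ext
            # ins[b, i-1] = max_{k<i} V[k] - open - (i-1-k)*ext, aligned to i>=1
            W = V.copy()
            W[:, 1:] = np.maximum(V[:, 1:], ins)
        M = np.full((B, nmax + 1), NEG)
        M[:, 1:] = e + W[:, :-1]
        Iy = np.maximum(V - open_, Iy - ext)
        V = np.maximum(M, Iy)
    return V.max(axis=1)


def profile_score(
    protein: str | ProteinRecord, profile: OGProfile, n_database: int = 1
) -> tuple[float, float]:
    """(bits, e-value) of one protein against one calibrated profile."""
    if profile.calibration is None:
        raise ClassifyError(f"profile {profile.og} is not calibrated")
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    bits = float(score_sequences([seq], profile)[0])
    return bits, _evalue(bits, profile, n_database)


def _evalue(bits: float, profile: OGProfile, n_database: int) -> float:
    cal = profile.calibration
    return float(n_database * math.exp(-cal.lam * (bits - cal.mu)))


def profile_to_json(profile: OGProfile) -> dict:
    cal = profile.calibration
    return {
        "format_version": 1,
        "og": profile.og,
        "match_columns": list(profile.match_columns),
        "emissions": profile.emissions.tolist(),
        "background": profile.background.tolist(),
        "gap_open": profile.gap_open,
        "gap_extend": profile.gap_extend,
        "calibration": None
        if cal is None
        else {"mu": cal.mu, "lam": cal.lam, "n_decoys": cal.n_decoys, "seed": cal.seed},
    }


def profile_from_json(d: dict) -> OGProfile:
    cal = d.get("calibration")
    return OGProfile(
        og=d["og"],
        match_columns=list(d["match_columns"]),
        emissions=np.array(d["emissions"]),
        background=np.array(d["background"]),
        gap_open=d["gap_open"],
        gap_extend=d["gap_extend"],
        calibration=None if cal is None else Calibration(**cal),
    )


@dataclass
class AssignmentResult:
    protein_id: str
    og: str | None
    bits: float
    evalue: float
    runner_up: str | None
    margin: float
    method: str = "profile"


def classify_proteome(
    records: list[ProteinRecord],
    profiles: list[OGProfile],
    evalue_max: float = 1e-3,
) -> list[AssignmentResult]:
    """Score every protein against every profile; assign to the best profile
    (minimum e-value) when it clears the threshold."""
    if not profiles:
        raise ClassifyError("need at least one calibrated profile")
    for p in profiles:
        if p.calibration is None:
            raise ClassifyError(f"profile {p.og} is not calibrated")
    n_db = len(records)
    seqs = [r.sequence for r in records]
    bits = np.stack([score_sequences(seqs, p) for p in profiles], axis=1)  # (N, P)
    evals = np.stack(
        [
            [_evalue(float(b), p, n_db) for b in bits[:, k]]
            for k, p in enumerate(profiles)
        ],
        axis=1,
    )
    results = []
    for i, rec in enumerate(records):
        order = np.lexsort((np.arange(len(profiles)), evals[i]))
        best = int(order[0])
        runner = int(order[1]) if len(profiles) > 1 else best
        e_best = float(evals[i, best])
        assigned = profiles[best].og if e_best <= evalue_max else None
        results.append(
            AssignmentResult(
                protein_id=rec.id,
                og=assigned,
                bits=float(bits[i, best]),
                evalue=e_best,
                runner_up=profiles[runner].og if len(profiles) > 1 else None,
                margin=float(bits[i, best] - bits[i, runner]),
            )
        )
    return results


def copy_number_report(
    assignments: list[AssignmentResult],
    panel: SpeciesPanel,
    species_of: dict,
    og_names: list[str] | None = None,
    proteome_sizes: dict | None = None,
) -> tuple[CopyNumberMatrix, dict]:
    """OG x species copy-number matrix plus per-species family percentages."""
    import warnings
    import pandas as pd

    assigned = [a for a in assignments if a.og is not None]
    ogs = og_names or sorted({a.og for a in assigned})
    counts = pd.DataFrame(0, index=ogs, columns=panel.codes, dtype=int)
    for a in assigned:
        sp = species_of[a.protein_id]
        if a.og in counts.index and sp in counts.columns:
            counts.loc[a.og, sp] += 1
    matrix = CopyNumberMatrix(counts)
    percentages = {}
    if proteome_sizes is not None:
        for sp in panel.codes:
            if sp not in proteome_sizes:
                warnings.warn(f"no proteome size for {sp}; percentage omitted")
                continue
            percentages[sp] = 100.0 * matrix.col_totals[sp] / proteome_sizes[sp]
    return matrix, percentages


def seed_vs_panel_correlation(
    matrix_seed: CopyNumberMatrix, matrix_full: CopyNumberMatrix
) -> float:
    """Pearson r between per-OG totals of the seed and expanded matrices."""
    from scipy.stats import pearsonr

    if set(matrix_seed.og_names) != set(matrix_full.og_names):
        raise ClassifyError("matrices must share the same OG row set")
    if len(matrix_seed.og_names) < 3:
        raise ClassifyError("need at least 3 OGs for a correlation")
    a = matrix_seed.row_totals.sort_index().to_numpy(dtype=float)
    b = matrix_full.row_totals.reindex(sorted(matrix_full.og_names)).to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ClassifyError("per-OG totals constant; correlation undefined")
    return float(pearsonr(a, b)[0])
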