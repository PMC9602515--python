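import json

import numpy as np
import pytest

from ogpeel.core_io import ProteinRecord
from ogpeel.msa_mask import Alignment
from ogpeel.classify_expand import (
    ClassifyError,
    Hit,
    build_og_profile,
    background_frequencies,
    classify_proteome,
    consensus_assign,
    copy_number_report,
    pairwise_score,
    profile_from_json,
    profile_score,
    profile_to_json,
    rank_hits,
    read_blast_tabular,
    score_sequences,
    seed_vs_panel_correlation,
)


def sw_oracle(a, b, open_=11, ext=1):
    """Brute-force Smith-Waterman, cell by cell, independent of the library
    path (affine gaps: first gap residue costs `open_`, then `ext`)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")

    def s(x, y):
        if "X" in (x, y):
            return 0.0
        return mat[x, y]

    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - open_, Ix[i - 1][j] - ext)
            Iy[i][j] = max(M[i][j - 1] - open_, Iy[i][j - 1] - ext)
            M[i][j] = max(
                0.0,
                s(a[i - 1], b[j - 1]) + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]),
            )
            best = max(best, M[i][j])
    return best


class TestPairwiseScore:
    def test_self_score_is_sum_of_diagonal_blosum(self):
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        seq = "MKLVINGDSLSAGYQPLAFSDKW" * 3
        assert pairwise_score(seq, seq) == sum(mat[c, c] for c in seq)

    @pytest.mark.parametrize(
        "a,b",
        [
            ("HEAGAWGHEE", "PAWHEAE"),
            ("MKLVINGDSL", "MKLINGDSL"),
            ("GDSLGDSLGDSL", "WWWWGDSLWWWW"),
            ("ACDEFGHIKLMNPQRSTVWY", "YWVTSRQPNMLKIHGFEDCA"),
        ],
    )
    def test_matches_independent_dp_oracle(self, a, b):
        assert pairwise_score(a, b) == sw_oracle(a, b)

    def test_score_is_symmetric(self):
        assert pairwise_score("HEAGAWGHEE", "PAWHEAE") == pairwise_score(
            "PAWHEAE", "HEAGAWGHEE"
        )

    def test_local_alignment_floor_is_zero(self):
        assert pairwise_score("AAAA", "WWWW") >= 0

    def test_x_is_a_zero_scoring_wildcard(self):
        assert pairwise_score("XXXX", "WWWW") == 0

    def test_invalid_characters_rejected(self):
        with pytest.raises(ClassifyError):
            pairwise_score("MK*L", "MKL")
        with pytest.raises(ClassifyError, match="empty"):
            pairwise_score("", "MKL")


class TestRankHits:
    def test_self_ranks_first(self):
        db = [
            ProteinRecord("self", "VITVI", "MKLVINGDSLSAGY"),
            ProteinRecord("decoy1", "VITVI", "WWWWPPPPGGGG"),
            ProteinRecord("decoy2", "VITVI", "CCCCHHHHYYYY"),
        ]
        hits = rank_hits(ProteinRecord("q", "VITVI", "MKLVINGDSLSAGY"), db)
        assert hits[0].subject_id == "self"

    def test_equal_scores_break_ties_lexicographically(self):
        db = [
            ProteinRecord("b", "VITVI", "MKLV"),
            ProteinRecord("a", "VITVI", "MKLV"),
        ]
        hits = rank_hits(ProteinRecord("q", "VITVI", "MKLV"), db)
        assert [h.subject_id for h in hits] == ["a", "b"]

    def test_blast_tabular_adapter_preserves_order(self, tmp_path):
        rows = [
            f"q1\ts{i}\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-{30 - i}\t{200 - i}"
            for i in range(7)
        ]
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join(rows) + "\n")
        hits = read_blast_tabular(p)["q1"]
        assert len(hits) == 7
        assert [h.subject_id for h in hits] == [f"s{i}" for i in range(7)]
        assert hits[0].score == 200.0


class TestConsensusAssign:
    LABELS = {f"h{i}": "OG-C10a" for i in range(6)} | {"z": "OG-C4e"}

    def test_unanimous_top5_assigns(self):
        hits = [Hit(f"h{i}", 50 - i) for i in range(5)]
        assert consensus_assign(hits, self.LABELS) == ("OG-C10a", "")

    def test_one_dissenting_hit_blocks_assignment(self):
        hits = [Hit("h0", 50), Hit("h1", 49), Hit("h2", 48), Hit("h3", 47), Hit("z", 46)]
        label, _ = consensus_assign(hits, self.LABELS)
        assert label is None

    def test_small_database_reduces_k_with_note(self):
        hits = [Hit("h0", 50), Hit("h1", 49), Hit("h2", 48), Hit("h3", 47)]
        assert consensus_assign(hits, self.LABELS) == ("OG-C10a", "reduced-k")

    def test_empty_hits_warn_and_unassign(self):
        with pytest.warns(UserWarning, match="no hits"):
            assert consensus_assign([], self.LABELS)[0] is None


class TestProfiles:
    def test_identical_rows_make_consensus_maximal(self):
        aln = Alignment(["a", "b"], ["MKLVINGDSL" * 4] * 2)
        p = build_og_profile("OG-X", aln, seed=1, n_decoys=50)
        assert len(p.match_columns) == 40
        seq = "MKLVINGDSL" * 4
        for k, col in enumerate(p.match_columns):
            code = "ACDEFGHIKLMNPQRSTVWY".index(seq[col])
            assert p.emissions[k, :20].argmax() == code

    def test_bits_equal_sum_of_column_maxima_for_consensus_query(self):
        aln = Alignment(["a", "b"], ["MKLVINGDSL" * 4] * 2)
        p = build_og_profile("OG-X", aln, seed=1, n_decoys=50)
        bits, _ = profile_score("MKLVINGDSL" * 4, p)
        assert bits == pytest.approx(p.emissions[:, :20].max(axis=1).sum())

    def test_gappy_columns_excluded_from_match_states(self):
        aln = Alignment(list("abcde"), ["MKWWL", "MK-WL", "M--WL", "MK-WL", "MKWWL"])
        p = build_og_profile("OG-X", aln, seed=1, n_decoys=50)
        assert 2 not in p.match_columns  # 3/5 gaps > 50%
        assert 1 in p.match_columns  # 1/5 gaps tolerated

    def test_calibration_is_seed_deterministic(self):
        aln = Alignment(["a", "b"], ["MKLVINGDSL" * 4] * 2)
        p1 = build_og_profile("OG-X", aln, seed=9, n_decoys=60)
        p2 = build_og_profile("OG-X", aln, seed=9, n_decoys=60)
        assert p1.calibration == p2.calibration

    def test_uncalibrated_profile_refuses_to_score(self):
        aln = Alignment(["a", "b"], ["MKLVINGDSL" * 4] * 2)
        p = build_og_profile("OG-X", aln, seed=1, n_decoys=50)
        p.calibration = None
        with pytest.raises(ClassifyError, match="calibrated"):
            profile_score("MKLV", p)

    def test_training_member_scores_below_evalue_threshold(self, noevent_sim):
        members = noevent_sim.og_members()
        og, ids = sorted(members.items())[0]
        aln = noevent_sim.true_alignment.subset(sorted(ids))
        p = build_og_profile(og, aln, seed=1)
        for row_id, row in zip(aln.ids, aln.rows):
            _, ev = profile_score(row.replace("-", ""), p)
            assert ev <= 1e-3

    def test_shuffled_members_score_like_noise(self, noevent_sim):
        members = noevent_sim.og_members()
        og, ids = sorted(members.items())[0]
        aln = noevent_sim.true_alignment.subset(sorted(ids))
        p = build_og_profile(og, aln, seed=1)
        rng = np.random.default_rng(0)
        evs = []
        for _ in range(100):
            src = list(aln.rows[int(rng.integers(len(aln.rows)))].replace("-", ""))
            rng.shuffle(src)
            _, ev = profile_score("".join(src), p)
            evs.append(ev)
        assert np.median(evs) > 1e-3

    def test_json_round_trip(self, tmp_path):
        aln = Alignment(["a", "b"], ["MKLVINGDSL" * 4] * 2)
        p = build_og_profile("OG-X", aln, seed=1, n_decoys=50)
        d = json.loads(json.dumps(profile_to_json(p)))
        q = profile_from_json(d)
        assert q.og == p.og
        assert q.calibration == p.calibration
        np.testing.assert_allclose(q.emissions, p.emissions)
        s1 = score_sequences(["MKLVINGDSL" * 4], p)
        s2 = score_sequences(["MKLVINGDSL" * 4], q)
        assert s1 == s2


@pytest.fixture(scope="module")
def profiles(noevent_sim):
    bg = background_frequencies(noevent_sim.records)
    out = []
    for og, ids in sorted(noevent_sim.og_members().items()):
        aln = noevent_sim.true_alignment.subset(sorted(ids))
        out.append(build_og_profile(og, aln, seed=2, background=bg))
    return out


class TestClassifyProteome:
    def test_training_members_assigned_to_their_own_og(self, noevent_sim, profiles):
        truth = dict(zip(noevent_sim.truth.gene_id, noevent_sim.truth.true_og))
        ingroup = [r for r in noevent_sim.records if truth[r.id]]
        for a in classify_proteome(ingroup, profiles):
            assert a.og == truth[a.protein_id]
            assert a.margin > 0

    def test_random_decoys_stay_unassigned(self, profiles):
        from ogpeel.simfam import random_proteins

        decoys = random_proteins(200, 180, seed=5)
        results = classify_proteome(decoys, profiles)
        assert sum(a.og is not None for a in results) == 0

    def test_empty_profile_list_is_an_error(self, noevent_sim):
        with pytest.raises(ClassifyError):
            classify_proteome(noevent_sim.records, [])


class TestCopyNumberReport:
    def _assignments(self, noevent_sim, profiles=None):
        from ogpeel.classify_expand import AssignmentResult

        truth = noevent_sim.truth
        return [
            AssignmentResult(r.gene_id, r.true_og or None, 100.0, 1e-9, None, 10.0)
            for r in truth.itertuples(index=False)
        ]

    def test_counts_match_truth(self, noevent_sim, panel):
        species_of = dict(
            zip(noevent_sim.truth.gene_id, noevent_sim.truth.species_code)
        )
        matrix, pct = copy_number_report(
            self._assignments(noevent_sim), panel, species_of,
            proteome_sizes={c: 1000 for c in panel.codes},
        )
        assert matrix.grand_total == 24  # 3 OGs x 8 ingroup species
        assert set(matrix.col_totals[panel.codes_for("monocot")]) == {3}
        assert pct["ORYSA"] == pytest.approx(0.3)

    def test_empty_assignments_give_empty_matrix(self, panel):
        matrix, _ = copy_number_report([], panel, {})
        assert matrix.grand_total == 0

    def test_missing_proteome_size_warns(self, noevent_sim, panel):
        species_of = dict(
            zip(noevent_sim.truth.gene_id, noevent_sim.truth.species_code)
        )
        with pytest.warns(UserWarning, match="proteome size"):
            copy_number_report(
                self._assignments(noevent_sim), panel, species_of,
                proteome_sizes={"VITVI": 1000},
            )


class TestSeedVsPanelCorrelation:
    def _matrix(self, data):
        import pandas as pd

        from ogpeel.core_io import CopyNumberMatrix

        return CopyNumberMatrix(
            pd.DataFrame(data, index=[f"og{i}" for i in range(len(data))],
                         columns=["S1", "S2"])
        )

    def test_identical_matrices_give_r_one(self):
        m = self._matrix([[1, 2], [3, 4], [5, 6]])
        assert seed_vs_panel_correlation(m, m) == pytest.approx(1.0)

    def test_constant_totals_are_an_error(self):
        m = self._matrix([[1, 1], [1, 1], [1, 1]])
        with pytest.raises(ClassifyError, match="constant"):
            seed_vs_panel_correlation(m, m)

    def test_fewer_than_three_ogs_is_an_error(self):
        m = self._matrix([[1, 2], [3, 4]])
        with pytest.raises(ClassifyError, match="3 OGs"):
            seed_vs_panel_correlation(m, m)

    def test_mismatched_og_sets_are_an_error(self):
        a = self._matrix([[1, 2], [3, 4], [5, 6]])
        b = self._matrix([[1, 2], [3, 4], [5, 6], [7, 8]])
        with pytest.raises(ClassifyError, match="row set"):
            seed_vs_panel_correlation(a, b)
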