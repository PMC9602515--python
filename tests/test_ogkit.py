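import warnings

import pytest

from ogpeel.msa_mask import Alignment
from ogpeel.core_io import GeneModel
from ogpeel.ogkit import (
    DelineationError,
    Orthogroup,
    architecture_consistency,
    delineate_ogs,
    detect_tandem_arrays,
    exon_junction_columns,
    root_with_outgroup,
)
from ogpeel.treekit import read_newick


PANEL_SP = {
    "m1": "ORYSA", "m2": "MUSAC", "m3": "PHODA",
    "d1": "VITVI", "d2": "PRUMU", "d3": "THECC", "d4": "ARATH", "d5": "COFCA",
    "o1": "AMBTC", "o2": "AMBTC", "o3": "AMBTC",
}


class TestRooting:
    def test_monophyletic_outgroup_roots_cleanly(self, panel):
        t = read_newick("((m1:0.2,d1:0.2)0.95:0.3,(o1:0.1,o2:0.1)0.9:0.4,d2:0.5);")
        rooted = root_with_outgroup(t, panel, PANEL_SP)
        sides = [sorted(rooted.leafset(c)) for c in rooted.root.children]
        assert ["o1", "o2"] in sides

    def test_single_outgroup_leaf_roots_on_pendant_edge(self, panel):
        t = read_newick("((m1:1,d1:1)0.9:1,o1:2,d2:3);")
        rooted = root_with_outgroup(t, panel, PANEL_SP)
        sides = [sorted(rooted.leafset(c)) for c in rooted.root.children]
        assert ["o1"] in sides

    def test_no_outgroup_is_an_error(self, panel):
        t = read_newick("((m1:1,d1:1)0.9:1,m2:1,d2:1);")
        with pytest.raises(DelineationError, match="outgroup"):
            root_with_outgroup(t, panel, PANEL_SP)

    def test_paraphyletic_outgroup_warns_and_maximizes(self, panel):
        # o1+o2 clade separated from o3; best edge keeps 2 of 3 together
        t = read_newick(
            "(((o1:.1,o2:.1)0.9:.3,m1:.4)0.8:.1,(o3:.5,d1:.3)0.7:.1,d2:.4);"
        )
        with pytest.warns(UserWarning, match="not monophyletic"):
            rooted = root_with_outgroup(t, panel, PANEL_SP)
        # exhaustive check: no edge separates more than 2 outgroup leaves
        best = max(
            len({x for x in t.leafset(n) if PANEL_SP[x] == "AMBTC"})
            for n in t.root.preorder()
            if n.parent is not None
            and {PANEL_SP[x] for x in t.leafset(n)} == {"AMBTC"}
        )
        assert best == 2
        sides = [sorted(rooted.leafset(c)) for c in rooted.root.children]
        assert ["o1", "o2"] in sides


class TestDelineation:
    def test_smallest_mixed_cluster_is_one_og(self, panel):
        t = read_newick("((m1:0.2,d1:0.2)0.95:0.3,o1:0.6,o2:0.7);")
        rooted = root_with_outgroup(t, panel, PANEL_SP)
        ogs = delineate_ogs(rooted, panel, PANEL_SP, family="GELP", cluster="C1")
        assert len(ogs) == 1
        assert ogs[0].name == "OG-GELP-C1"  # single OG: no letter
        assert ogs[0].members == ["d1", "m1"]
        assert ogs[0].outgroup_annotations == ["o1", "o2"]

    def test_three_supported_mixed_subclades_give_three_ogs(self, panel):
        t = read_newick(
            "((m1:.1,d1:.1)0.99:.2,((m2:.1,d2:.1)0.98:.2,(m3:.1,d3:.1)0.97:.2)0.5:.1,o1:.6);"
        )
        rooted = root_with_outgroup(t, panel, PANEL_SP)
        ogs = delineate_ogs(rooted, panel, PANEL_SP, family="GELP", cluster="C2")
        assert [o.name for o in ogs] == [
            "OG-GELP-C2a", "OG-GELP-C2b", "OG-GELP-C2c"
        ]
        assert {frozenset(o.members) for o in ogs} == {
            frozenset({"m1", "d1"}), frozenset({"m2", "d2"}), frozenset({"m3", "d3"})
        }

    def test_supported_pure_sibling_becomes_lineage_specific_og(self, panel):
        t = read_newick(
            "(((d1:.1,(d2:.1,d3:.1)0.9:.1)0.99:.2,(m1:.1,d4:.1)0.95:.2)0.9:.3,o1:.5);"
        )
        rooted = root_with_outgroup(t, panel, PANEL_SP)
        ogs = delineate_ogs(rooted, panel, PANEL_SP, family="GELP", cluster="C4")
        assert {frozenset(o.members) for o in ogs} == {
            frozenset({"d1", "d2", "d3"}), frozenset({"m1", "d4"})
        }

    def test_unsupported_pure_sibling_merges_into_mixed_og(self, panel):
        t = read_newick(
            "(((d1:.1,(d2:.1,d3:.1)0.9:.1)0.5:.2,(m1:.1,d4:.1)0.95:.2)0.9:.3,o1:.5);"
        )
        rooted = root_with_outgroup(t, panel, PANEL_SP)
        ogs = delineate_ogs(rooted, panel, PANEL_SP)
        assert len(ogs) == 1
        assert set(ogs[0].members) == {"d1", "d2", "d3", "m1", "d4"}

    def test_partition_and_leaf_order_invariance(self, panel):
        a = "(((d1:.1,(d2:.1,d3:.1)0.9:.1)0.99:.2,(m1:.1,d4:.1)0.95:.2)0.9:.3,o1:.5);"
        b = "((((d3:.1,d2:.1)0.9:.1,d1:.1)0.99:.2,(d4:.1,m1:.1)0.95:.2)0.9:.3,o1:.5);"
        out = []
        for text in (a, b):
            rooted = root_with_outgroup(read_newick(text), panel, PANEL_SP)
            ogs = delineate_ogs(rooted, panel, PANEL_SP)
            out.append({frozenset(o.members) for o in ogs})
            covered = set().union(*[set(o.members) for o in ogs])
            assert covered == {"d1", "d2", "d3", "d4", "m1"}
        assert out[0] == out[1]

    def test_curator_override_moves_gene(self, panel):
        t = read_newick("((m1:0.2,d1:0.2)0.95:0.3,(d2:0.2,o1:0.6)0.5:0.1);")
        rooted = root_with_outgroup(t, panel, PANEL_SP)
        ogs = delineate_ogs(
            rooted, panel, PANEL_SP, family="GELP", cluster="C5",
            overrides={"d2": "OG-GELP-C5x"},
        )
        by_name = {o.name: o for o in ogs}
        assert by_name["OG-GELP-C5x"].members == ["d2"]
        assert by_name["OG-GELP-C5x"].curator_override

    def test_unlabeled_leaf_is_an_error(self, panel):
        t = read_newick("((m1:0.2,zz:0.2)0.95:0.3,o1:0.6,d1:0.2);")
        with pytest.raises(DelineationError, match="zz"):
            delineate_ogs(
                root_with_outgroup(t, panel, PANEL_SP | {"zz": "VITVI"}),
                panel,
                PANEL_SP,
            )

    def test_true_tree_delineation_recovers_truth(self, noevent_sim):
        from ogpeel.benchmarks import _delineate_true_tree_ari

        assert _delineate_true_tree_ari(noevent_sim) == 1.0


def make_gene(gene_id, junctions_codons, L=100, chrom="chr1", rank=None, strand="+"):
    """Gene model with introns after the given codons (stop codon included)."""
    cds_nt = 3 * (L + 1)
    bounds = [0] + [3 * j for j in junctions_codons] + [cds_nt]
    spans = []
    pos = 1
    for a, b in zip(bounds, bounds[1:]):
        spans.append((pos, pos + (b - a) - 1))
        pos += (b - a) + 100
    return GeneModel(gene_id, gene_id, chrom, strand, spans, list(spans),
                     position_index=rank)


class TestExonJunctions:
    def test_junction_after_codon_maps_to_alignment_column(self):
        gm = make_gene("g", [40], L=100)
        row = "-" * 15 + "A" * 100  # residue 40 sits in column 55
        aln = Alignment(["g"], [row])
        assert exon_junction_columns(gm, aln, "g") == [55]

    def test_intronless_gene_has_no_junctions(self):
        gm = make_gene("g", [], L=100)
        aln = Alignment(["g"], ["A" * 100])
        assert exon_junction_columns(gm, aln, "g") == []

    def test_phase1_junction_assigned_to_split_codon(self):
        # 9-nt toy: codons |AAA|CC^C|GGG| with the junction inside codon 2
        gm = GeneModel("g", "g", "chr1", "+", [(1, 5), (200, 206)],
                       [(1, 5), (200, 206)])
        aln = Alignment(["g"], ["KPR"])  # 3 residues, cds 12 nt = 3*3+3
        assert exon_junction_columns(gm, aln, "g") == [2]

    def test_length_mismatch_is_an_error(self):
        gm = make_gene("g", [10], L=50)
        aln = Alignment(["g"], ["A" * 90])
        with pytest.raises(DelineationError, match="inconsistent"):
            exon_junction_columns(gm, aln, "g")


class TestArchitectureConsistency:
    def _og(self, members):
        return Orthogroup("OG-X", list(members), "C1", {})

    def test_two_exon_class_all_conformant(self):
        # junction at 12% of length: the two-exon architecture
        genes = {f"g{i}": make_gene(f"g{i}", [12], L=100) for i in range(4)}
        aln = Alignment(list(genes), ["A" * 100] * 4)
        rep = architecture_consistency(self._og(genes), aln, genes)
        assert rep.consensus.class_id == "1"
        assert set(rep.conformity.values()) == {"conformant"}

    def test_member_missing_one_junction_is_fused(self):
        full = [15, 30, 48, 66, 84]
        genes = {f"g{i}": make_gene(f"g{i}", full, L=100) for i in range(3)}
        genes["gf"] = make_gene("gf", [15, 48, 66, 84], L=100)  # lost junction 2
        aln = Alignment(list(genes), ["A" * 100] * 4)
        rep = architecture_consistency(self._og(genes), aln, genes)
        assert rep.consensus.class_id == "2"
        assert rep.conformity["gf"] == "fused(2,3)"
        assert rep.conformity["g0"] == "conformant"

    def test_single_member_trivially_consistent(self):
        genes = {"g0": make_gene("g0", [22, 42, 62, 82], L=100)}
        aln = Alignment(["g0"], ["A" * 100])
        rep = architecture_consistency(self._og(genes), aln, genes)
        assert rep.conformity == {"g0": "conformant"}

    def test_no_gene_models_is_untestable(self):
        aln = Alignment(["g0"], ["A" * 100])
        rep = architecture_consistency(self._og(["g0"]), aln, {})
        assert rep.untestable


class TestTandemArrays:
    def test_three_consecutive_same_og_genes_form_one_array(self):
        gms = [make_gene(f"g{i}", [12], rank=10 + i) for i in range(3)]
        groups = detect_tandem_arrays(gms, {f"g{i}": "OG-a" for i in range(3)})
        arrays = [g for g in groups if g.is_array]
        assert len(arrays) == 1
        assert arrays[0].members == ["g0", "g1", "g2"]
        assert not arrays[0].spans_multiple_ogs

    def test_adjacent_genes_of_two_ogs_form_multi_og_array(self):
        # the pattern of neighbouring paralog clusters from an ancient tandem:
        # three genes of one OG adjacent to one gene of a sister OG
        gms = [make_gene(f"g{i}", [12], rank=10 + i) for i in range(4)]
        ogs = {"g0": "OG-e", "g1": "OG-e", "g2": "OG-e", "g3": "OG-f"}
        groups = detect_tandem_arrays(gms, ogs)
        arrays = [g for g in groups if g.is_array]
        assert len(arrays) == 1
        assert arrays[0].spans_multiple_ogs
        assert arrays[0].ogs == {"OG-e", "OG-f"}

    def test_distant_genes_stay_singletons(self):
        gms = [make_gene("g0", [12], rank=10), make_gene("g1", [12], rank=60)]
        groups = detect_tandem_arrays(gms, {"g0": "OG-a", "g1": "OG-a"})
        assert len(groups) == 2
        assert not any(g.is_array for g in groups)

    def test_simulated_tandem_truth_recovered(self, small_sim):
        truth = small_sim.truth
        og_of = {
            r.gene_id: r.true_og or "outgroup"
            for r in truth.itertuples(index=False)
        }
        species_of = dict(zip(truth.gene_id, truth.species_code))
        groups = detect_tandem_arrays(
            small_sim.gene_models, og_of, species_of=species_of
        )
        found = {
            (g.species, m) for g in groups if g.is_array for m in g.members
        }
        expected = {
            (r.species_code, r.gene_id)
            for r in truth.itertuples(index=False)
            if r.tandem_array_id != ""
        }
        assert expected <= found
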