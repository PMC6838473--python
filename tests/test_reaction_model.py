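import numpy as np
import pytest

from conftest import molblock, random_graph
from enzrepo.reaction_model import (
    CompoundGraph,
    IntegrityError,
    Organism,
    OrthologCluster,
    ParseError,
    RawReaction,
    assemble_database,
    assign_atom_types,
    parse_compound,
    read_cluster_table,
    read_fasta,
    read_organism_table,
    read_reaction_table,
    write_fasta,
    write_reaction_table,
)


class TestParseCompound:
    def test_methane_strips_hydrogens(self, methane_molblock):
        g = parse_compound(methane_molblock, "C00001")
        assert len(g) == 1 and len(g.bonds) == 0
        assert g.atoms[0].atom_type == "C.sp3.ac.h0"

    def test_benzene_ring_perception(self, benzene_molblock):
        g = parse_compound(benzene_molblock, "C00002")
        assert len(g) == 6 and len(g.bonds) == 6
        assert all(a.ring_flag for a in g.atoms)
        assert all(a.atom_type == "C.ar.rg.h0" for a in g.atoms)

    def test_ethanol_types_distinguish_carbons(self, ethanol_molblock):
        g = parse_compound(ethanol_molblock, "C00003")
        assert len(g) == 3 and len(g.bonds) == 2
        types = {a.element: a.atom_type for a in g.atoms if a.element == "O"}
        c_types = sorted(a.atom_type for a in g.atoms if a.element == "C")
        assert c_types == ["C.sp3.ac.h0", "C.sp3.ac.h1"]
        assert types["O"] == "O.sp3.ac.h0"

    def test_malformed_counts_line_names_line(self):
        bad = "t\n  x\n\n  a  b\nM  END\n"
        with pytest.raises(ParseError, match="line 4"):
            parse_compound(bad, "X")

    def test_atom_count_mismatch_rejected(self):
        text = molblock(["C", "C"], [(0, 1, 1)])
        lines = text.splitlines()
        lines[3] = lines[3].replace("  2  1", "  9  1", 1)
        with pytest.raises(ParseError, match="mismatch"):
            parse_compound("\n".join(lines) + "\n", "X")

    def test_unknown_element_rejected(self):
        text = molblock(["Zz"], [])
        with pytest.raises(ParseError, match="Zz"):
            parse_compound(text, "X")


class TestAtomTypes:
    def test_idempotent(self, ethanol_molblock):
        g = parse_compound(ethanol_molblock, "C1")
        again = assign_atom_types(g)
        assert [a.atom_type for a in again.atoms] == [a.atom_type for a in g.atoms]

    @pytest.mark.parametrize("seed", range(10))
    def test_permutation_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 4, 9)
        n = len(g)
        perm = list(rng.permutation(n))
        inv = {old: new for new, old in enumerate(perm)}
        permuted = CompoundGraph.build(
            "perm",
            [g.element(perm[i]) for i in range(n)],
            [(inv[b.a], inv[b.b], b.order) for b in g.bonds],
        )
        for new, old in enumerate(perm):
            assert permuted.atom_type(new) == g.atom_type(old)

    def test_sp_class_from_triple_bond(self):
        g = CompoundGraph.build("yne", ["C", "C"], [(0, 1, 3)])
        assert all(a.atom_type == "C.sp.ac.h0" for a in g.atoms)


class TestReactionTable:
    def test_tsv_row_maps_fields(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("R001\tC001\tC002\t1.14.13.-\tOC1;OC2\n")
        rows = read_reaction_table(p, "tsv")
        assert rows[0].cluster_ids == frozenset({"OC1", "OC2"})
        assert rows[0].ec == "1.14.13.-"

    def test_empty_clusters_is_orphan(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("R001\tC001\tC002\t\t\tplant\n")
        rows = read_reaction_table(p, "tsv")
        assert rows[0].cluster_ids == frozenset()
        assert rows[0].pathway_taxa == frozenset({"plant"})

    def test_duplicate_reaction_id_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("R001\tC001\tC002\t\t\nR001\tC003\tC004\t\t\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_reaction_table(p, "tsv")

    def test_kegg_flat_main_pair_and_context(self, tmp_path):
        p = tmp_path / "r.kegg"
        p.write_text(
            "ENTRY       R00001              Reaction\n"
            "EQUATION    C001 + C009 <=> C002\n"
            "ENZYME      1.1.1.1\n"
            "ORTHOLOGY   OC1  some cluster\n"
            "///\n"
        )
        rows = read_reaction_table(p, "kegg-flat")
        r = rows[0]
        assert (r.substrate_id, r.product_id) == ("C001", "C002")
        assert r.context_compounds == ("C009",)
        assert r.cluster_ids == frozenset({"OC1"})

    def test_tsv_round_trip_byte_identical(self, tmp_path):
        rows = [
            RawReaction("R2", "C3", "C4", None, frozenset(), frozenset({"plant"})),
            RawReaction("R1", "C1", "C2", "1.1.1.1", frozenset({"OC2", "OC1"})),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_reaction_table(rows, p1)
        write_reaction_table(read_reaction_table(p1, "tsv"), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestClusterOrganismTables:
    def test_linked_records(self, tmp_path):
        cp = tmp_path / "c.tsv"
        cp.write_text("OC1\tsco\tSCO3770\tK00493 unspecific monooxygenase\n")
        op = tmp_path / "o.tsv"
        op.write_text(
            "sco\tStreptomyces coelicolor A3(2)\tbacteria\t"
            "Bacteria;Actinobacteria;Streptomycetaceae\n"
        )
        clusters = read_cluster_table(cp)
        orgs = read_organism_table(op)
        assert ("sco", "SCO3770") in clusters["OC1"].members
        assert orgs["sco"].taxon_group == "bacteria"
        assert orgs["sco"].lineage[-1] == "Streptomycetaceae"

    def test_unknown_taxon_group_lists_vocabulary(self, tmp_path):
        op = tmp_path / "o.tsv"
        op.write_text("xxx\tX\tfungi\t\n")
        with pytest.raises(IntegrityError, match="plant, bacteria, other"):
            read_organism_table(op)

    def test_cluster_with_unknown_organism_fails_assembly(self):
        orgs = {"ath": Organism("ath", "A. thaliana", "plant")}
        clusters = {"OC1": OrthologCluster("OC1", frozenset({("ghost", "g1")}))}
        with pytest.raises(IntegrityError, match="ghost"):
            assemble_database({}, [], clusters, orgs)

    def test_unresolvable_compound_lists_offenders(self):
        raw = [RawReaction("R1", "C404", "C405", None, frozenset())]
        with pytest.raises(IntegrityError, match="C404"):
            assemble_database({}, raw, {}, {})


class TestFasta:
    def test_basic_read_uppercases(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a desc here\nmkv\n>b\nAC\nDE\n")
        recs = read_fasta(p)
        assert recs == [("a", "MKV"), ("b", "ACDE")]

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMK\n>a\nVL\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(ParseError, match="empty"):
            read_fasta(p)

    def test_write_read_round_trip(self, tmp_path):
        p = tmp_path / "w.fasta"
        write_fasta([("x", "MKVLA" * 30)], p)
        assert read_fasta(p) == [("x", "MKVLA" * 30)]
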