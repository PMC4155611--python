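"""Substructure tables, PDB reading, distances, contact maps, fixtures."""

import math

import numpy as np
import pytest

import protier as p
from protier.structures import ContactMap

from conftest import single_atom_residue

TABLE_HEADER = "label,kind,range,sequence\n"


class TestSubstructureTable:
    def test_bundled_table_has_19_labelled_rows_in_order(self):
        defs = p.default_substructure_table()
        assert [d.label for d in defs] == [f"D{i}" for i in range(1, 20)]
        d1 = defs[0]
        assert (d1.kind, d1.start, d1.end, d1.sequence) == ("beta", 2, 15, "ARTFFVGGNFKLNG")
        assert len(d1.sequence) == d1.end - d1.start + 1 == 14

    def test_adjacent_rows_share_boundary_residue(self):
        defs = p.default_substructure_table()
        assert defs[0].end == defs[1].start == 15  # the shared G belongs to both

    def test_empty_table_gives_empty_list(self):
        assert p.parse_substructure_table(TABLE_HEADER) == []

    def test_combined_name_column_is_split(self):
        defs = p.parse_substructure_table(
            "name,range,sequence\nD1 -beta,2-15,ARTFFVGGNFKLNG\n"
        )
        assert defs[0].label == "D1" and defs[0].kind == "beta"

    def test_malformed_range_names_the_row(self):
        with pytest.raises(ValueError, match="D7.*range"):
            p.parse_substructure_table(TABLE_HEADER + "D7,beta,8896,AKWVILGHS\n")

    def test_non_amino_acid_character_rejected(self):
        with pytest.raises(ValueError, match="D1"):
            p.parse_substructure_table(TABLE_HEADER + "D1,beta,1-3,AXZ\n")

    def test_audit_flags_only_the_inconsistent_row(self):
        defs = p.default_substructure_table()
        audit = p.audit_definitions(defs)
        assert [a["label"] for a in audit] == ["D10"]
        assert audit[0]["sequence_length"] == 11 and audit[0]["range_size"] == 119
        # flagged, not repaired: the printed range is kept verbatim
        d10 = next(d for d in defs if d.label == "D10")
        assert (d10.start, d10.end) == (12, 130)

    def test_inconsistent_row_warns_but_parses(self):
        with pytest.warns(UserWarning, match="D10"):
            p.parse_substructure_table(TABLE_HEADER + "D10,beta,12-130,GVGVILCIGET\n")


class TestReadStructure:
    def test_generator_reader_round_trip(self):
        spec = p.SyntheticStructureSpec(sequence="GAV")
        res = p.read_structure(p.generate_synthetic_structure(spec, seed=0), "A")
        assert [r.code for r in res] == ["GLY", "ALA", "VAL"]
        assert all(r.calpha is not None for r in res)

    def test_hydrogens_and_hetatm_excluded(self):
        pdb = (
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  H   GLY A   1       0.500   0.800   0.000  1.00  0.00           H\n"
            "ATOM      4  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C\n"
            "ATOM      5  O   GLY A   1       1.500   2.500   0.000  1.00  0.00           O\n"
            "HETATM    6  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O\n"
            "END\n"
        )
        res = p.read_structure(pdb, "A")
        assert len(res) == 1
        names = [a[0] for a in res[0].atoms]
        assert "H" not in names and set(names) == {"N", "CA", "C", "O"}

    def test_absent_chain_error_lists_available(self):
        pdb = p.generate_synthetic_structure(p.SyntheticStructureSpec(sequence="GG"), 0)
        with pytest.raises(ValueError, match=r"chain 'Z'.*\['A'\]"):
            p.read_structure(pdb, "Z")

    def test_no_atom_records_is_a_format_error(self):
        with pytest.raises(ValueError):
            p.read_structure("REMARK nothing here\nEND\n", "A")


class TestResidueDistance:
    def test_3_4_5_triangle_under_every_metric(self):
        r1 = single_atom_residue(1, xyz=(0, 0, 0))
        r2 = single_atom_residue(2, xyz=(3, 4, 0))
        for metric in ("calpha", "centroid", "center_of_mass", "all_atom"):
            assert p.residue_distance(r1, r2, metric) == pytest.approx(5.0)

    def test_identity_distance_zero(self):
        r = single_atom_residue(1, xyz=(1, 2, 3))
        assert p.residue_distance(r, r, "calpha") == 0.0

    def test_centroid_vs_all_atom_two_atom_residue(self):
        r1 = p.ResidueRecord(
            chain="A", index=1, icode="", code="GLY",
            atoms=(("CA", "C", (0.0, 0.0, 0.0)), ("C", "C", (2.0, 0.0, 0.0))),
        )
        r2 = single_atom_residue(2, xyz=(10, 0, 0))
        assert p.residue_distance(r1, r2, "centroid") == pytest.approx(9.0)
        assert p.residue_distance(r1, r2, "all_atom") == pytest.approx(8.0)

    def test_missing_calpha_identifies_residue(self):
        r = single_atom_residue(7, name="CB")
        with pytest.raises(ValueError, match="GLY7"):
            p.residue_distance(r, single_atom_residue(2), "calpha")

    def test_calpha_equals_centroid_on_ca_only_residues(self):
        rng = np.random.default_rng(3)
        residues = [single_atom_residue(i, xyz=tuple(rng.uniform(0, 20, 3))) for i in range(5)]
        for i in range(4):
            a = p.residue_distance(residues[i], residues[i + 1], "calpha")
            b = p.residue_distance(residues[i], residues[i + 1], "centroid")
            assert a == pytest.approx(b, abs=0)


class TestContactMap:
    def test_colinear_chain_is_a_path_at_7A(self, colinear_residues):
        cm = p.build_contact_map(colinear_residues, "calpha", 7.0)
        assert cm.pairs() == {(i, i + 1) for i in range(1, 15)}
        assert all(e.count == 1 for e in cm.entries.values())

    def test_tiny_threshold_gives_empty_map(self, colinear_residues):
        cm = p.build_contact_map(colinear_residues, "calpha", 0.5)
        assert cm.pairs() == set()

    def test_8A_adds_second_neighbors(self, colinear_residues):
        cm = p.build_contact_map(colinear_residues, "calpha", 8.0)
        want = {(i, i + 1) for i in range(1, 15)} | {(i, i + 2) for i in range(1, 14)}
        assert cm.pairs() == want

    def test_symmetric_under_residue_order_reversal(self, colinear_residues):
        fwd = p.build_contact_map(colinear_residues, "calpha", 8.0)
        rev = p.build_contact_map(list(reversed(colinear_residues)), "calpha", 8.0)
        assert fwd.pairs() == rev.pairs()
        assert {k: v.count for k, v in fwd.entries.items()} == {
            k: v.count for k, v in rev.entries.items()
        }

    def test_threshold_monotonicity(self):
        spec = p.SyntheticStructureSpec(sequence="G" * 25, mode="coil")
        res = p.read_structure(p.generate_synthetic_structure(spec, seed=5), "A")
        small = p.build_contact_map(res, "calpha", 6.0)
        large = p.build_contact_map(res, "calpha", 9.0)
        assert small.pairs() <= large.pairs()
        for k, e in small.entries.items():
            assert large.entries[k].count >= e.count

    def test_fewer_than_two_residues_empty_not_error(self):
        assert p.build_contact_map([single_atom_residue(1)], "calpha", 7.0).pairs() == set()

    def test_stored_pairs_respect_threshold_and_count(self, colinear_residues):
        cm = p.build_contact_map(colinear_residues, "calpha", 8.0)
        for entry in cm.entries.values():
            assert entry.min_distance <= cm.threshold
            assert entry.count >= 1

    def test_side_chain_count_metric_drops_glycine_contacts(self):
        spec = p.SyntheticStructureSpec(sequence="AGA", sidechains=True)
        res = p.read_structure(p.generate_synthetic_structure(spec, seed=0), "A")
        cm = p.build_contact_map(res, "calpha", 7.0, count_metric="side_chain")
        # contacts with the glycine have no side-chain witness and are dropped
        assert (1, 2) not in cm and (2, 3) not in cm


class TestSyntheticGenerator:
    def test_colinear_spacing_recovered(self, colinear_residues):
        d = [
            p.residue_distance(colinear_residues[i], colinear_residues[i + 1], "calpha")
            for i in range(len(colinear_residues) - 1)
        ]
        assert d == pytest.approx([3.8] * 14, abs=1e-3)

    def test_deterministic_given_seed(self):
        spec = p.SyntheticStructureSpec(sequence="G" * 30, mode="coil")
        assert p.generate_synthetic_structure(spec, 1) == p.generate_synthetic_structure(spec, 1)

    def test_different_seeds_differ_same_length(self):
        spec = p.SyntheticStructureSpec(sequence="G" * 30, mode="coil")
        a, b = (p.generate_synthetic_structure(spec, s) for s in (1, 2))
        assert a != b
        assert len(p.read_structure(a, "A")) == len(p.read_structure(b, "A")) == 30

    def test_unknown_residue_code_rejected(self):
        with pytest.raises(ValueError, match="Z"):
            p.SyntheticStructureSpec(sequence="GAZ")

    def test_round_trip_preserves_coordinates_to_pdb_precision(self):
        spec = p.SyntheticStructureSpec(sequence="G" * 10, mode="helix")
        res = p.read_structure(p.generate_synthetic_structure(spec, 0), "A")
        t = np.deg2rad(100.0) * np.arange(10)
        want = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(10)])
        got = np.vstack([r.calpha for r in res])
        assert np.allclose(got, want, atol=5e-4)

    def test_sidechain_atoms_near_calpha(self):
        spec = p.SyntheticStructureSpec(sequence="AAA", sidechains=True)
        res = p.read_structure(p.generate_synthetic_structure(spec, 0), "A")
        for r in res:
            names = [a[0] for a in r.atoms]
            assert "CB" in names
            cb = r.coords(names={"CB"})[0]
            assert np.linalg.norm(cb - r.calpha) <= 1.6


def test_contact_map_key_is_unordered():
    assert ContactMap.key(5, 2) == ContactMap.key(2, 5) == (2, 5)
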