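import pytest

from raseff.errors import AmbiguousChainError, ChainNotFoundError, MalformedInputError
from raseff.structure_io import chain_sequence, enumerate_chain_pairs, parse_structure
from raseff.synthetic_data import PlantedContactSpec, complex_to_pdb, make_toy_complex

MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLU A   2       5.000   0.000   0.000  1.00  0.00           N
ATOM      4  CA  GLU A   2       6.400   0.000   0.000  1.00  0.00           C
TER
ATOM      5  N   ALA B   1      20.000   0.000   0.000  1.00  0.00           N
ATOM      6  CA  ALA B   1      21.400   0.000   0.000  1.00  0.00           C
TER
END
"""


class TestParseStructure:
    def test_counts_residues_per_chain(self):
        cx = parse_structure(MINIMAL_PDB, "A", "B")
        assert len(cx.ras_chain) == 2
        assert len(cx.effector_chain) == 1
        assert chain_sequence(cx.ras_chain) == "GE"

    def test_missing_chain_raises(self):
        with pytest.raises(ChainNotFoundError):
            parse_structure(MINIMAL_PDB, "Z", "B")

    def test_empty_text_raises(self):
        with pytest.raises(MalformedInputError):
            parse_structure("", "A", "B")

    def test_author_numbering_preserved(self):
        shifted = MINIMAL_PDB.replace("GLU A   2", "GLU A  77")
        cx = parse_structure(shifted, "A", "B")
        assert [r.number for r in cx.ras_chain] == [1, 77]

    def test_hydrogens_waters_and_ligands_removed(self):
        decorated = MINIMAL_PDB.replace(
            "TER\nEND",
            "HETATM  90  O   HOH A 100      9.000   9.000   9.000  1.00  0.00           O\n"
            "HETATM  91  MG   MG A 101      8.000   8.000   8.000  1.00  0.00          MG\n"
            "ATOM    92  H   ALA B   1      21.000   1.000   0.000  1.00  0.00           H\n"
            "TER\nEND",
        )
        cx = parse_structure(decorated, "A", "B")
        assert len(cx.ras_chain) == 2  # no water/ion residues
        names = [a.name for r in cx.effector_chain for a in r.atoms]
        assert "H" not in names

    def test_selenomethionine_kept_as_methionine(self):
        text = MINIMAL_PDB.replace(
            "ATOM      3  N   GLU A   2",
            "HETATM    3  N   MSE A   2",
        ).replace("ATOM      4  CA  GLU A   2", "HETATM    4  CA  MSE A   2")
        cx = parse_structure(text, "A", "B")
        assert chain_sequence(cx.ras_chain) == "GM"

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA  ALA B   1      20.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        cx = parse_structure(text, "A", "B")
        (atom,) = cx.ras_chain[0].atoms
        assert atom.coord[0] == pytest.approx(9.0)  # occupancy 0.60 wins

    def test_altloc_tie_breaks_to_smallest_id(self):
        text = (
            "ATOM      1  CA BGLY A   1       9.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA AGLY A   1       0.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      3  CA  ALA B   1      20.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        cx = parse_structure(text, "A", "B")
        (atom,) = cx.ras_chain[0].atoms
        assert atom.altloc == "A"

    def test_roundtrip_preserves_coordinates(self):
        pdb, _ = make_toy_complex(
            [PlantedContactSpec(1, 2, 3.5, "mm")], (5, 5)
        )
        cx = parse_structure(pdb, "A", "B", structure_id="toy")
        again = parse_structure(complex_to_pdb(cx), "A", "B", structure_id="toy")
        for c1, c2 in zip(cx.ras_chain + cx.effector_chain,
                          again.ras_chain + again.effector_chain):
            assert c1.key == c2.key
            for a1, a2 in zip(c1.atoms, c2.atoms):
                assert a1.name == a2.name
                assert a1.coord == pytest.approx(a2.coord, abs=1e-3)

    def test_reserialization_idempotent(self):
        pdb, _ = make_toy_complex([PlantedContactSpec(0, 0, 3.9, "ss")], (4, 4))
        cx = parse_structure(pdb, "A", "B")
        once = complex_to_pdb(cx)
        twice = complex_to_pdb(parse_structure(once, "A", "B"))
        assert once == twice


class TestEnumerateChainPairs:
    RAS_SEQ = "WGEDSVHAAKL"
    EFF_SEQ = "MKLQRTPPY"

    def _two_copy_pdb(self):
        # chains A,C RAS-like and B,D effector-like (two complexes per cell)
        pdb1, _ = make_toy_complex([], (len(self.RAS_SEQ), len(self.EFF_SEQ)),
                                   ras_seq=self.RAS_SEQ, eff_seq=self.EFF_SEQ)
        pdb2 = pdb1.replace(" A ", " C ").replace(" B ", " D ")
        body1 = pdb1.replace("END\n", "")
        return body1 + pdb2

    def test_single_pair(self):
        pdb, _ = make_toy_complex([], (len(self.RAS_SEQ), len(self.EFF_SEQ)),
                                  ras_seq=self.RAS_SEQ, eff_seq=self.EFF_SEQ)
        pairs = enumerate_chain_pairs(
            pdb, {"HRAS": self.RAS_SEQ}, {"CRAF": self.EFF_SEQ}
        )
        assert pairs == [("A", "B", ("HRAS", "CRAF"))]

    def test_two_copies_with_pairing_list(self):
        pairs = enumerate_chain_pairs(
            self._two_copy_pdb(),
            {"HRAS": self.RAS_SEQ},
            {"CRAF": self.EFF_SEQ},
            pairing=[("A", "B"), ("C", "D")],
        )
        assert [(p[0], p[1]) for p in pairs] == [("A", "B"), ("C", "D")]

    def test_two_copies_without_pairing_flags_all_combinations(self):
        with pytest.warns(UserWarning, match="pairing list"):
            pairs = enumerate_chain_pairs(
                self._two_copy_pdb(), {"HRAS": self.RAS_SEQ}, {"CRAF": self.EFF_SEQ}
            )
        assert [(p[0], p[1]) for p in pairs] == [
            ("A", "B"), ("A", "D"), ("C", "B"), ("C", "D")
        ]

    def test_no_match_returns_empty_list(self):
        pdb, _ = make_toy_complex([], (4, 4))
        assert enumerate_chain_pairs(pdb, {"HRAS": "WWWWYYYY"}, {"CRAF": "PPPPQQQQ"}) == []

    def test_chain_matching_both_sides_is_ambiguous(self):
        pdb, _ = make_toy_complex([], (len(self.RAS_SEQ), len(self.EFF_SEQ)),
                                  ras_seq=self.RAS_SEQ, eff_seq=self.EFF_SEQ)
        with pytest.raises(AmbiguousChainError):
            enumerate_chain_pairs(
                pdb, {"HRAS": self.RAS_SEQ}, {"CRAF": self.RAS_SEQ}
            )
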