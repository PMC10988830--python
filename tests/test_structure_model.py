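"""Structure container, PDB I/O, preparation and neighborhoods."""

import numpy as np
import pytest

from gefscan import chem
from gefscan.builder import build_peptide, side_chain_complete
from gefscan.prepare import build_all_atom_model, count_hbonds
from gefscan.structure_model import (
    AtomRecord,
    ComplexPartition,
    Residue,
    StructureModel,
    read_pdb,
    select_neighborhood,
    write_pdb,
)

PDB_TWO_CHAINS = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.984   2.841   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.030   1.580   0.000  1.00  0.00           O
ATOM      9  N   SER A   3       6.230   3.806   0.000  1.00  0.00           N
ATOM     10  CA  SER A   3       7.686   3.770   0.000  1.00  0.00           C
ATOM     11  C   SER A   3       8.237   5.190   0.000  1.00  0.00           C
ATOM     12  O   SER A   3       7.479   6.160   0.000  1.00  0.00           O
TER
ATOM     13  N   ALA B   1       0.000   0.000  20.000  1.00  0.00           N
ATOM     14  CA  ALA B   1       1.458   0.000  20.000  1.00  0.00           C
ATOM     15  C   ALA B   1       2.009   1.420  20.000  1.00  0.00           C
ATOM     16  O   ALA B   1       1.251   2.390  20.000  1.00  0.00           O
ATOM     17  N   GLY B   2       3.332   1.536  20.000  1.00  0.00           N
ATOM     18  CA  GLY B   2       3.984   2.841  20.000  1.00  0.00           C
ATOM     19  C   GLY B   2       5.504   2.693  20.000  1.00  0.00           C
ATOM     20  O   GLY B   2       6.030   1.580  20.000  1.00  0.00           O
ATOM     21  N   GLY B   3       6.230   3.806  20.000  1.00  0.00           N
ATOM     22  CA  GLY B   3       7.686   3.770  20.000  1.00  0.00           C
ATOM     23  C   GLY B   3       8.237   5.190  20.000  1.00  0.00           C
ATOM     24  O   GLY B   3       7.479   6.160  20.000  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB ASER A   1       2.000  -1.000   1.000  0.40  0.00           C
ATOM      6  CB BSER A   1       2.000  -1.000  -1.000  0.60  0.00           C
ATOM      7  OG ASER A   1       3.300  -1.200   1.200  0.40  0.00           O
ATOM      8  OG BSER A   1       3.300  -1.200  -1.200  0.60  0.00           O
END
"""

PDB_DUPLICATE = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   1       1.400   0.100   0.000  1.00  0.00           C
END
"""


class TestReadPdb:
    def test_two_chain_fixture(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(PDB_TWO_CHAINS)
        st = read_pdb(p)
        assert st.chain_ids == ["A", "B"]
        assert len(st.residues()) == 6
        assert st.get("A", 3).aa3 == "SER"

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        st = read_pdb(p)
        cb = st.get("A", 1).atom("CB")
        # conformer B has occupancy 0.60 and sits at z = -1
        assert cb.pos[2] == pytest.approx(-1.0)
        assert any("altloc" in k for k in st.metadata)

    def test_duplicate_atom_is_hard_error(self, tmp_path):
        p = tmp_path / "dup.pdb"
        p.write_text(PDB_DUPLICATE)
        with pytest.raises(ValueError, match="duplicate atom"):
            read_pdb(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError):
            read_pdb(p)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pdb(tmp_path / "nope.pdb")

    def test_waters_dropped_by_default(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text(
            PDB_TWO_CHAINS.replace(
                "END",
                "HETATM   25  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O\nEND",
            )
        )
        st = read_pdb(p)
        assert all(r.aa3 != "HOH" for r in st.residues())


def test_roundtrip_preserves_identity_and_coordinates(tmp_path):
    st = build_all_atom_model(build_peptide("GLKDS", conformation="helix"))
    p = tmp_path / "rt.pdb"
    write_pdb(st, p)
    back = read_pdb(p)
    orig = {(r.rid, a.name): a.pos for r in st.residues() for a in r.atoms}
    got = {(r.rid, a.name): a.pos for r in back.residues() for a in r.atoms}
    assert orig.keys() == got.keys()
    for k in orig:
        assert np.allclose(orig[k], got[k], atol=1.5e-3)


class TestNeighborhood:
    @staticmethod
    def _ca_only(chain, seq, xyz):
        return Residue(chain, seq, "", "GLY", [AtomRecord("CA", "C", np.asarray(xyz, float))])

    def test_distance_boundary(self):
        st = StructureModel(
            [
                ("A", [self._ca_only("A", 1, [0, 0, 0])]),
                ("B", [self._ca_only("B", 1, [7.9, 0, 0]), self._ca_only("B", 2, [8.1, 0, 0])]),
            ]
        )
        got = select_neighborhood(st, ("A", 1, ""), 8.0)
        assert ("B", 1, "") in got
        assert ("B", 2, "") not in got
        assert ("A", 1, "") in got  # site always included

    def test_isolated_residue(self):
        st = StructureModel([("A", [self._ca_only("A", 1, [0, 0, 0])])])
        assert select_neighborhood(st, ("A", 1, ""), 8.0) == [("A", 1, "")]

    def test_monotone_in_radius(self, helix12):
        prev = set()
        for r in (3.0, 5.0, 8.0, 12.0):
            cur = set(select_neighborhood(helix12, ("A", 6, ""), r))
            assert prev <= cur
            prev = cur

    def test_unknown_site(self, helix12):
        with pytest.raises(KeyError):
            select_neighborhood(helix12, ("Z", 1, ""), 8.0)

    def test_default_radius_is_8A(self, helix12):
        import inspect

        sig = inspect.signature(select_neighborhood)
        assert sig.parameters["radius"].default == 8.0


class TestPrepare:
    def test_idempotent(self):
        st = build_all_atom_model(build_peptide("GNKSQ", conformation="helix"))
        st2 = build_all_atom_model(st)
        a = {(r.rid, a.name): a.pos for r in st.residues() for a in r.atoms}
        b = {(r.rid, a.name): a.pos for r in st2.residues() for a in r.atoms}
        assert a.keys() == b.keys()
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_no_flippable_residues_heavy_atoms_unchanged(self):
        raw = build_peptide("GALVS", conformation="helix")
        st = build_all_atom_model(raw)
        for r_raw, r_prep in zip(raw.residues(), st.residues()):
            for atom in r_raw.atoms:
                if atom.element == "H":
                    continue
                assert np.allclose(atom.pos, r_prep.pos(atom.name))
        # hydrogens were added
        assert any(a.element == "H" for r in st.residues() for a in r.atoms)

    def test_missing_side_chain_rebuilt(self):
        raw = build_peptide("GKG", conformation="helix")
        lys = raw.get("A", 2)
        for name in ("CD", "CE", "NZ"):
            lys.remove_atom(name)
        assert not side_chain_complete(lys)
        st = build_all_atom_model(raw)
        assert side_chain_complete(st.get("A", 2))
        assert ("A", 2, "") in st.metadata["rebuilt_side_chains"]

    def test_missing_backbone_errors(self):
        raw = build_peptide("GKG", conformation="helix")
        raw.get("A", 2).remove_atom("CA")
        with pytest.raises(ValueError, match="CA"):
            build_all_atom_model(raw)

    def test_unknown_residue_errors_unless_skipped(self):
        raw = build_peptide("GAG", conformation="helix")
        raw.get("A", 2).aa3 = "XYZ"
        with pytest.raises(ValueError, match="unknown residue"):
            build_all_atom_model(raw)
        st = build_all_atom_model(raw, skip_unknown=True)
        assert st.prepared

    def test_asn_flip_gains_hydrogen_bond(self):
        # a carbonyl acceptor is placed 3 A beyond where ND2 would sit after
        # the amide flip: only the flipped orientation can donate to it.
        # chi2 = 90 keeps OD1/ND2 symmetric about the backbone so the H-bond
        # alone decides the flip.
        import copy

        from gefscan.builder import rotate_chi_by

        def align(a, b):
            a = a / np.linalg.norm(a)
            b = b / np.linalg.norm(b)
            v = np.cross(a, b)
            c = float(a @ b)
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            return np.eye(3) + vx + vx @ vx * (1 / (1 + c))

        asn_chain = build_peptide("N", conformation="extended", chain_id="A",
                                  chis={0: (-60.0, 90.0)})
        asn = asn_chain.get("A", 1)
        tmp = copy.deepcopy(asn)
        rotate_chi_by(tmp, 2, 180.0)
        nd2_flipped = tmp.pos("ND2").copy()
        cg = asn.pos("CG")
        u = nd2_flipped - cg
        u /= np.linalg.norm(u)
        target_o = nd2_flipped + 3.0 * u
        probe = build_peptide("G", conformation="extended", chain_id="B")
        g = probe.get("B", 1)
        rot = align(g.pos("C") - g.pos("O"), u)
        o0 = g.pos("O").copy()
        for a in g.atoms:
            a.pos = rot @ (a.pos - o0) + target_o
        st = StructureModel(asn_chain.chains + probe.chains)
        unflipped = build_all_atom_model(st, flip_his_asn_gln=False)
        flipped = build_all_atom_model(st)
        assert ("A", 1, "") in flipped.metadata.get("flipped_side_chains", [])
        assert count_hbonds(flipped) >= count_hbonds(unflipped) + 1


def test_partition_validation(dimer):
    with pytest.raises(ValueError, match="overlap"):
        ComplexPartition({"A"}, {"A", "B"})
    with pytest.raises(ValueError):
        ComplexPartition(set(), {"B"})
    part = ComplexPartition({"A"}, {"B"})
    part.validate_against(dimer.structure)
    with pytest.raises(ValueError, match="cover"):
        ComplexPartition({"A"}, {"C"}).validate_against(dimer.structure)
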