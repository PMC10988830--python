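"""Chemical reference tables: amino-acid codes, idealized side-chain
internal-coordinate templates, chi-angle definitions, intra-residue
connectivity, polar-hydrogen templates and nonbonded atom parameters.

Side-chain heavy atoms are described by NeRF internal coordinates
``(name, element, (a, b, c), bond, angle, torsion)``: the atom is bonded to
``c`` with the given bond length (A) and angle at ``c`` (deg); the torsion
``a-b-c-X`` is either a fixed value in degrees or ``("chi", k, offset)``
meaning chi_k plus a constant offset.  Bond lengths and angles are standard
idealized values; aromatic rings are built atom-by-atom from these internal
coordinates, which closes the rings to within a few hundredths of an
Angstrom - adequate for an empirical scoring function.
"""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# ---------------------------------------------------------------------------
# chi-angle definitions (atom-name quadruples, in order chi1..chi4)
# ---------------------------------------------------------------------------
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "A": [],
    "G": [],
    "S": [("N", "CA", "CB", "OG")],
    "C": [("N", "CA", "CB", "SG")],
    "T": [("N", "CA", "CB", "OG1")],
    "V": [("N", "CA", "CB", "CG1")],
    "P": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

N_CHI = {aa: len(v) for aa, v in CHI_ATOMS.items()}

# ---------------------------------------------------------------------------
# side-chain heavy-atom templates (beyond CB; CB itself is placed separately)
# ---------------------------------------------------------------------------
Chi = tuple  # ("chi", k, offset)

SIDE_CHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "A": [],
    "G": [],
    "S": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "C": [("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
    "T": [("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1, 0.0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0))],
    "V": [("CG1", "C", ("N", "CA", "CB"), 1.527, 110.7, ("chi", 1, 0.0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.7, ("chi", 1, -122.0))],
    "L": [("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.524, 110.7, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.524, 110.7, ("chi", 2, 122.6))],
    "I": [("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
          ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.9, ("chi", 2, 0.0))],
    "M": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
          ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
          ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.6, ("chi", 3, 0.0))],
    # proline: CD is placed off the backbone nitrogen so the pyrrolidine
    # ring closes by construction; the soft CG-CD closure is a bonded
    # (excluded) pair.  One rigid pucker only.
    "P": [("CG", "C", ("N", "CA", "CB"), 1.495, 104.5, ("chi", 1, 0.0)),
          ("CD", "C", ("CB", "CA", "N"), 1.487, 104.1, -39.3)],
    "F": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.372, 120.0, 0.0)],
    "Y": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.372, 120.0, 0.0),
          ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "W": [("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, ("chi", 2, 180.0)),
          ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
          ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
          ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
          ("CZ3", "C", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
          ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.400, 117.5, 0.0)],
    "D": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
          ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0))],
    "N": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.7, ("chi", 1, 0.0)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
          ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0))],
    "E": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
          ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0))],
    "Q": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.7, ("chi", 2, 0.0)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
          ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0))],
    "K": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
          ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 3, 0.0)),
          ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 4, 0.0))],
    "R": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
          ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3, 0.0)),
          ("CZ", "C", ("CG", "CD", "NE"), 1.330, 124.2, ("chi", 4, 0.0)),
          ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
          ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "H": [("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1, 0.0)),
          ("ND1", "N", ("CA", "CB", "CG"), 1.371, 122.7, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.356, 129.1, ("chi", 2, 180.0)),
          ("CE1", "C", ("CB", "CG", "ND1"), 1.319, 109.3, 180.0),
          ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
}

# CB placement: bonded to CA, improper torsion vs N and C giving L-chirality
CB_INTERNAL = (("N", "C", "CA"), 1.530, 110.5, -122.6)

# ring-closure bonds not implied by the template parent chain
RING_CLOSURE_BONDS: dict[str, list[tuple[str, str]]] = {
    "F": [("CZ", "CE2")],
    "Y": [("CZ", "CE2")],
    "W": [("NE1", "CE2"), ("CZ3", "CH2")],
    "H": [("CE1", "NE2")],
    "P": [("CG", "CD")],
}

# ---------------------------------------------------------------------------
# polar hydrogens (placed by build_all_atom_model)
# ---------------------------------------------------------------------------
# (name, (a, b, c), bond, angle, torsion) -- same NeRF convention
POLAR_H_TEMPLATES: dict[str, list[tuple]] = {
    "S": [("HG", ("CA", "CB", "OG"), 0.96, 109.5, 180.0)],
    "T": [("HG1", ("CA", "CB", "OG1"), 0.96, 109.5, 180.0)],
    "Y": [("HH", ("CE1", "CZ", "OH"), 0.96, 109.5, 180.0)],
    "C": [("HG", ("CA", "CB", "SG"), 1.34, 96.0, 180.0)],
    "N": [("HD21", ("CB", "CG", "ND2"), 1.01, 120.0, 0.0),
          ("HD22", ("CB", "CG", "ND2"), 1.01, 120.0, 180.0)],
    "Q": [("HE21", ("CG", "CD", "NE2"), 1.01, 120.0, 0.0),
          ("HE22", ("CG", "CD", "NE2"), 1.01, 120.0, 180.0)],
    "W": [("HE1", ("CG", "CD1", "NE1"), 1.01, 125.0, 180.0)],
    # His hydrogen depends on the tautomer; handled explicitly in preparation
}
HIS_TAUTOMER_H = {
    "NE2": ("HE2", ("CG", "CD2", "NE2"), 1.01, 125.6, 180.0),
    "ND1": ("HD1", ("CB", "CG", "ND1"), 1.01, 125.6, 180.0),
}

# parent of each polar hydrogen (the donor heavy atom)
H_PARENT = {
    "HG": {"S": "OG", "C": "SG"}, "HG1": {"T": "OG1"}, "HH": {"Y": "OH"},
    "HD21": {"N": "ND2"}, "HD22": {"N": "ND2"},
    "HE21": {"Q": "NE2"}, "HE22": {"Q": "NE2"},
    "HE1": {"W": "NE1"}, "HE2": {"H": "NE2"}, "HD1": {"H": "ND1"},
    "H": None,  # backbone amide H, parent N
}

# ---------------------------------------------------------------------------
# hydrogen-bond donors / acceptors (heavy atoms, per one-letter residue type)
# ---------------------------------------------------------------------------
# donor atom -> antecedent (base) atom used for the angular criterion
SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "S": {"OG": "CB"}, "T": {"OG1": "CB"}, "Y": {"OH": "CZ"},
    "C": {"SG": "CB"},
    "N": {"ND2": "CG"}, "Q": {"NE2": "CD"}, "W": {"NE1": "CD1"},
    "H": {"ND1": "CG", "NE2": "CD2"},
    "K": {"NZ": "CE"}, "R": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
}
SIDECHAIN_ACCEPTORS: dict[str, dict[str, str]] = {
    "S": {"OG": "CB"}, "T": {"OG1": "CB"}, "Y": {"OH": "CZ"},
    "D": {"OD1": "CG", "OD2": "CG"}, "E": {"OE1": "CD", "OE2": "CD"},
    "N": {"OD1": "CG"}, "Q": {"OE1": "CD"},
    "H": {"ND1": "CG", "NE2": "CD2"},
}

# formal-charge model: only ionized side-chain groups carry charge
PARTIAL_CHARGES: dict[tuple[str, str], float] = {
    ("D", "OD1"): -0.5, ("D", "OD2"): -0.5,
    ("E", "OE1"): -0.5, ("E", "OE2"): -0.5,
    ("K", "NZ"): 1.0,
    ("R", "NH1"): 0.5, ("R", "NH2"): 0.5,
}

# ---------------------------------------------------------------------------
# per-element nonbonded parameters
# ---------------------------------------------------------------------------
# Lennard-Jones: Rmin/2 (A) and well depth epsilon (kcal/mol).
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "C": (1.95, 0.12),
    "N": (1.75, 0.16),
    "O": (1.70, 0.20),
    "S": (2.00, 0.25),
    "H": (0.00, 0.00),  # polar H are geometric markers only, no LJ
}

# Gaussian-exclusion desolvation parameters per element:
# (dG_free kcal/mol, atomic volume A^3).  Positive dG_free = hydrophobic
# (burial favorable), negative = polar (burial penalized).
SOLVATION_PARAMS: dict[str, tuple[float, float]] = {
    "C": (0.55, 14.7),
    "N": (-4.0, 11.2),
    "O": (-4.5, 10.8),
    "S": (0.50, 14.7),
    "H": (0.0, 0.0),
}
SOLVATION_LAMBDA = 3.5  # correlation length, A

COULOMB_CONSTANT = 332.0636  # kcal/mol * A / e^2


def heavy_atom_names(aa1: str) -> list[str]:
    """Complete heavy-atom name list for a residue type (backbone + side chain)."""
    names = list(BACKBONE_ATOMS)
    if aa1 != "G":
        names.append("CB")
    names.extend(t[0] for t in SIDE_CHAIN_TEMPLATES[aa1])
    return names
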