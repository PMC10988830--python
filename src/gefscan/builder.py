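"""Side-chain construction from internal-coordinate templates."""

from __future__ import annotations

import numpy as np

from . import chem
from .geometry import dihedral, place_atom, rotation_about_axis
from .structure_model import AtomRecord, Residue

__all__ = [
    "place_cb",
    "build_side_chain",
    "measure_chis",
    "rotate_chi_by",
    "backbone_complete",
    "side_chain_complete",
    "build_peptide",
]

# ideal backbone geometry (A, deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.1
PHI_PSI = {"helix": (-57.0, -47.0), "extended": (-139.0, 135.0)}


def backbone_complete(res: Residue) -> bool:
    return all(res.has_atom(n) for n in chem.BACKBONE_ATOMS)


def side_chain_complete(res: Residue) -> bool:
    """True if every heavy atom of the residue's template is present."""
    aa1 = res.aa1
    if aa1 is None:
        return True  # non-standard residues are taken as-is
    return all(res.has_atom(n) for n in chem.heavy_atom_names(aa1))


def place_cb(res: Residue) -> np.ndarray:
    (a, b, c), bond, angle, tor = chem.CB_INTERNAL
    return place_atom(res.pos(a), res.pos(b), res.pos(c), bond, angle, tor)


def build_side_chain(res: Residue, aa1: str, chis: list[float] | tuple[float, ...]) -> None:
    """Replace the residue's side chain (and type) with an idealized one.

    Backbone atoms (N, CA, C, O and the amide H if present) are untouched.
    ``chis`` must supply one angle per rotatable bond of ``aa1``.
    """
    if aa1 not in chem.AA1_TO_3:
        raise ValueError(f"unknown amino acid {aa1!r}")
    nchi = chem.N_CHI[aa1]
    chis = list(chis)
    if len(chis) != nchi:
        raise ValueError(f"{aa1} needs {nchi} chi angles, got {len(chis)}")
    keep = set(chem.BACKBONE_ATOMS) | {"H"}
    res.atoms = [a for a in res.atoms if a.name in keep]
    res.aa3 = chem.AA1_TO_3[aa1]
    if aa1 == "G":
        return
    res.atoms.append(AtomRecord("CB", "C", place_cb(res)))
    for name, element, (a, b, c), bond, angle, tor in chem.SIDE_CHAIN_TEMPLATES[aa1]:
        if isinstance(tor, tuple):
            _, k, offset = tor
            tor_val = chis[k - 1] + offset
        else:
            tor_val = tor
        pos = place_atom(res.pos(a), res.pos(b), res.pos(c), bond, angle, tor_val)
        res.atoms.append(AtomRecord(name, element, pos))


def measure_chis(res: Residue) -> list[float]:
    """Chi angles (degrees) measured from current coordinates."""
    aa1 = res.aa1
    if aa1 is None:
        raise ValueError(f"cannot measure chis of non-standard residue {res.aa3}")
    out = []
    for quad in chem.CHI_ATOMS[aa1]:
        out.append(dihedral(*(res.pos(n) for n in quad)))
    return out


def rotate_chi_by(res: Residue, chi_index: int, delta_deg: float) -> None:
    """Rotate all atoms distal to the chi_index-th rotatable bond in place.

    Used for amide/imidazole flips (delta = 180) so crystal bond lengths and
    angles are preserved exactly; a double flip restores the input bitwise.
    """
    aa1 = res.aa1
    quad = chem.CHI_ATOMS[aa1][chi_index - 1]
    axis_from, axis_to = res.pos(quad[1]), res.pos(quad[2])
    rot = rotation_about_axis(axis_to - axis_from, delta_deg)
    moving = _atoms_distal_to(aa1, quad[2])
    for a in res.atoms:
        if a.name in moving:
            a.pos = axis_to + rot @ (a.pos - axis_to)


def _atoms_distal_to(aa1: str, pivot: str) -> set[str]:
    """Heavy atoms strictly beyond `pivot` along the side-chain tree."""
    order = [t[0] for t in chem.SIDE_CHAIN_TEMPLATES[aa1]]
    if pivot == "CB":
        return set(order)
    i = order.index(pivot)
    return set(order[i + 1:])


def build_peptide(
    sequence: str,
    conformation: str | list[tuple[float, float]] = "extended",
    chain_id: str = "A",
    start_seq: int = 1,
    chis: dict[int, tuple[float, ...]] | None = None,
    library=None,
) -> "StructureModel":
    """Construct an ideal-geometry peptide from scratch.

    ``conformation`` is "helix", "extended", or an explicit per-residue
    (phi, psi) list.  Side chains are built at each residue's most probable
    library rotamer unless overridden through ``chis`` (keyed by 0-based
    residue index).  Returns an unprepared StructureModel with one chain.
    """
    from .structure_model import StructureModel

    if isinstance(conformation, str):
        phi_psi = [PHI_PSI[conformation]] * len(sequence)
    else:
        phi_psi = list(conformation)
        if len(phi_psi) != len(sequence):
            raise ValueError("need one (phi, psi) pair per residue")
    if library is None:
        from .rotamers import default_library

        library = default_library()
    chis = chis or {}
    residues: list[Residue] = []
    prev_n = prev_ca = prev_c = None
    for i, aa1 in enumerate(sequence):
        if aa1 not in chem.AA1_TO_3:
            raise ValueError(f"unknown residue letter {aa1!r}")
        phi, psi = phi_psi[i]
        res = Residue(chain_id, start_seq + i, "", chem.AA1_TO_3[aa1])
        if i == 0:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([_B_N_CA, 0.0, 0.0])
            ang = np.radians(180.0 - _A_N_CA_C)
            c = ca + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
        else:
            n = place_atom(prev_n, prev_ca, prev_c, _B_C_N, _A_CA_C_N,
                           phi_psi[i - 1][1])
            ca = place_atom(prev_ca, prev_c, n, _B_N_CA, _A_C_N_CA, 180.0)
            c = place_atom(prev_c, n, ca, _B_CA_C, _A_N_CA_C, phi)
        o = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi - 180.0)
        res.atoms = [
            AtomRecord("N", "N", n),
            AtomRecord("CA", "C", ca),
            AtomRecord("C", "C", c),
            AtomRecord("O", "O", o),
        ]
        rot_chis = chis.get(i, library.most_probable(aa1).chis)
        build_side_chain(res, aa1, rot_chis)
        residues.append(res)
        prev_n, prev_ca, prev_c = n, ca, c
    return StructureModel([(chain_id, residues)], {"source": "build_peptide"})
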