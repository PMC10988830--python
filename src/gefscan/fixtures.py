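"""Synthetic toy structures with machine-checkable ground truth.

Everything here is generated from ideal geometry in code - no external
structure file is ever needed.  Three families:

* ``make_toy_dimer`` - two short peptides with a controlled number of
  cross-chain contacts; ground-truth cross-partition energies come from an
  independent scalar brute-force pair loop.
* ``make_rotamer_puzzle`` - a row of leucines whose spacing is chosen (by
  deterministic search at generation time) so that the jointly optimal
  rotamer assignment differs from the per-residue greedy one; ground truth
  is the enumerated global optimum.
* ``make_surface_helix`` - an ideal alpha-helix whose mid-chain residues
  are fully solvent exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import build_peptide
from .energy import EnergyModel, binding_energy, folded_energy
from .geometry import rotation_about_axis
from .prepare import build_all_atom_model
from .structure_model import ComplexPartition, ResidueId, StructureModel

__all__ = [
    "FixtureSpec",
    "ToyDimer",
    "RotamerPuzzle",
    "make_toy_dimer",
    "make_rotamer_puzzle",
    "make_surface_helix",
    "brute_force_cross_energy",
    "dimer_model",
]


@dataclass
class FixtureSpec:
    kind: str  # toy_dimer | rotamer_puzzle | surface_helix
    n_residues_per_chain: int = 3
    seed: int = 0
    params: dict = field(default_factory=dict)

    def build(self):
        if self.kind == "toy_dimer":
            return make_toy_dimer(seed=self.seed, **self.params)
        if self.kind == "rotamer_puzzle":
            return make_rotamer_puzzle(seed=self.seed, **self.params)
        if self.kind == "surface_helix":
            return make_surface_helix(n_residues=self.n_residues_per_chain, **self.params)
        raise ValueError(f"unknown fixture kind {self.kind!r}")


@dataclass
class ToyDimer:
    structure: StructureModel
    partition: ComplexPartition
    model: EnergyModel
    ground_truth: dict


@dataclass
class RotamerPuzzle:
    structure: StructureModel
    flexible: list[ResidueId]
    model: EnergyModel
    optimum_energy: float
    optimum_assignment: tuple[int, ...]
    greedy_assignment: tuple[int, ...]
    greedy_energy: float


def dimer_model(cutoff: float = 4.6) -> EnergyModel:
    """vdW-only scoring model used for the dimer fixtures; the short cutoff
    makes the designed contact the only scored cross-chain pair."""
    m = EnergyModel.default()
    m.weights = {t: 0.0 for t in m.weights}
    m.weights["vdw"] = 1.0
    m.cutoff = cutoff
    return m


def make_toy_dimer(
    n_contacts: int = 1,
    separation: float | None = None,
    seed: int = 0,
    cutoff: float = 4.6,
) -> ToyDimer:
    """Two Gly-Leu-Gly strands whose leucine tips meet head-on.

    With ``n_contacts=1`` the Leu CD1-CD1 pair sits at the Lennard-Jones
    optimum (or at ``separation`` if given) and is the only cross-chain
    pair inside the scoring cutoff.  ``n_contacts=0`` places the chains
    beyond the cutoff entirely.
    """
    if n_contacts not in (0, 1):
        raise ValueError("toy dimer supports 0 or 1 designed contacts")
    model = dimer_model(cutoff)
    rmin_cc = 2.0 * model.vdw_params["C"][0]
    if separation is None:
        separation = rmin_cc if n_contacts == 1 else cutoff + 6.0

    # leucines are built at (180, 180), which is also their intra-chain
    # optimum here, so repacking does not abandon the designed contact
    leu_chis = {1: (180.0, 180.0)}
    a = build_peptide("GLG", conformation="extended", chain_id="A", chis=leu_chis)
    # chain B is chain A rotated 180 degrees about an axis perpendicular to
    # both the Leu tip direction and the backbone, pivoted at the tip atom,
    # then translated outward: the two CD1 tips meet head-on while both
    # backbones extend away from the interface.
    leu = a.get("A", 2)
    tip = leu.pos("CD1")
    u = tip - leu.pos("CB")
    u /= np.linalg.norm(u)
    bb = a.get("A", 3).pos("CA") - a.get("A", 1).pos("CA")
    bb /= np.linalg.norm(bb)
    w = np.cross(u, bb)
    w /= np.linalg.norm(w)
    rot = rotation_about_axis(w, 180.0)
    b = build_peptide("GLG", conformation="extended", chain_id="B", chis=leu_chis)
    for res in b.residues():
        for at in res.atoms:
            at.pos = rot @ (at.pos - tip) + tip + separation * u

    st = StructureModel(a.chains + b.chains, {"source": f"toy_dimer(seed={seed})"})
    st = build_all_atom_model(st)
    partition = ComplexPartition({"A"}, {"B"})

    # verify the design: exactly n_contacts cross pairs inside the cutoff
    pairs = _cross_pairs_within(st, partition, model.cutoff)
    if n_contacts == 1:
        if len(pairs) != 1 or pairs[0][:2] != ("CD1", "CD1"):
            raise RuntimeError(f"degenerate dimer geometry: contacts {pairs}")
    elif pairs:
        raise RuntimeError(f"degenerate dimer geometry: unexpected contacts {pairs}")

    truth = brute_force_cross_energy(st, partition, model)
    truth["n_contacts"] = len(pairs)
    truth["contact_distance"] = pairs[0][2] if pairs else None
    return ToyDimer(st, partition, model, truth)


def _cross_pairs_within(st, partition, cutoff):
    recs = [r for r in st.residues() if r.chain_id in partition.receptor_chains]
    parts = [r for r in st.residues() if r.chain_id in partition.partner_chains]
    found = []
    for ra in recs:
        for aa in ra.heavy_atoms():
            for rb in parts:
                for ab in rb.heavy_atoms():
                    d = float(np.linalg.norm(aa.pos - ab.pos))
                    if d < cutoff:
                        found.append((aa.name, ab.name, d))
    return found


def brute_force_cross_energy(
    structure: StructureModel, partition: ComplexPartition, model: EnergyModel
) -> dict:
    """Independent scalar-loop oracle for the cross-partition energy.

    Walks every receptor-atom/partner-atom pair with plain Python floats
    (no shared code with the vectorized evaluator) and sums the weighted
    vdW, electrostatic, desolvation and H-bond terms.  Cross-chain pairs
    are never bonded, so no exclusions apply.
    """
    import math

    from . import chem

    rec = [r for r in structure.residues() if r.chain_id in partition.receptor_chains]
    par = [r for r in structure.residues() if r.chain_id in partition.partner_chains]
    vdw = elec = solv = 0.0
    for ra in rec:
        for atom_a in ra.heavy_atoms():
            rh_a, eps_a = model.vdw_params[atom_a.element]
            dg_a, vol_a = model.solvation_params[atom_a.element]
            q_a = chem.PARTIAL_CHARGES.get((ra.aa1, atom_a.name), 0.0)
            for rb in par:
                for atom_b in rb.heavy_atoms():
                    d = max(math.dist(atom_a.pos, atom_b.pos), 0.05)
                    if d >= model.cutoff:
                        continue
                    rh_b, eps_b = model.vdw_params[atom_b.element]
                    rmin = rh_a + rh_b
                    eps = math.sqrt(eps_a * eps_b)
                    if eps > 0:
                        r0 = model.cap_fraction * rmin
                        if d < r0:
                            x6 = (1.0 / model.cap_fraction) ** 6
                            e0 = eps * (x6 * x6 - 2 * x6)
                            slope = (12.0 * eps / r0) * (x6 - x6 * x6)
                            vdw += e0 + slope * (d - r0)
                        else:
                            x6 = (rmin / d) ** 6
                            vdw += eps * (x6 * x6 - 2 * x6)
                    q_b = chem.PARTIAL_CHARGES.get((rb.aa1, atom_b.name), 0.0)
                    if q_a and q_b:
                        elec += chem.COULOMB_CONSTANT * q_a * q_b / (
                            model.dielectric_coeff * d * d
                        )
                    dg_b, vol_b = model.solvation_params[atom_b.element]
                    lam = model.solvation_lambda
                    pref = 2.0 * math.pi ** 1.5 * lam
                    solv += -(dg_a / (pref * d * d)) * math.exp(
                        -(((d - rh_a) / lam) ** 2)
                    ) * vol_b
                    solv += -(dg_b / (pref * d * d)) * math.exp(
                        -(((d - rh_b) / lam) ** 2)
                    ) * vol_a
    hb = _brute_force_cross_hbonds(structure, partition, model)
    w = model.weights
    total = (
        w.get("vdw", 0) * vdw
        + w.get("elec", 0) * elec
        + w.get("solvation", 0) * solv
        + w.get("hbond", 0) * hb
    )
    return {
        "cross_energy": total,
        "vdw": w.get("vdw", 0) * vdw,
        "elec": w.get("elec", 0) * elec,
        "solvation": w.get("solvation", 0) * solv,
        "hbond": w.get("hbond", 0) * hb,
    }


def _brute_force_cross_hbonds(structure, partition, model) -> float:
    import math

    from . import chem

    def participants(residues):
        donors, acceptors = [], []
        for r in residues:
            aa1 = r.aa1
            if aa1 is None:
                continue
            if aa1 != "P" and r.has_atom("N") and r.has_atom("CA"):
                donors.append((r.pos("N"), r.pos("CA")))
            if r.has_atom("O") and r.has_atom("C"):
                acceptors.append((r.pos("O"), r.pos("C")))
            for atom, base in chem.SIDECHAIN_DONORS.get(aa1, {}).items():
                if r.has_atom(atom) and r.has_atom(base):
                    donors.append((r.pos(atom), r.pos(base)))
            for atom, base in chem.SIDECHAIN_ACCEPTORS.get(aa1, {}).items():
                if r.has_atom(atom) and r.has_atom(base):
                    acceptors.append((r.pos(atom), r.pos(base)))
        return donors, acceptors

    def angle(p, q, r):
        u, v = p - q, r - q
        c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    rec = [r for r in structure.residues() if r.chain_id in partition.receptor_chains]
    par = [r for r in structure.residues() if r.chain_id in partition.partner_chains]
    total = 0.0
    for side_a, side_b in ((rec, par), (par, rec)):
        donors, _ = participants(side_a)
        _, acceptors = participants(side_b)
        for dpos, dbase in donors:
            for apos, abase in acceptors:
                d = math.dist(dpos, apos)
                if d > model.hb_max_dist or d < 1.5:
                    continue
                if angle(dbase, dpos, apos) < model.hb_min_angle:
                    continue
                if angle(abase, apos, dpos) < model.hb_min_angle:
                    continue
                ramp = min(
                    1.0,
                    (model.hb_max_dist - d) / (model.hb_max_dist - model.hb_opt_dist),
                )
                total -= model.hb_strength * ramp
    return total


# ---------------------------------------------------------------------------
# rotamer puzzles
# ---------------------------------------------------------------------------

def make_rotamer_puzzle(
    n_flexible: int = 2,
    coupling: str = "pairwise_clash",
    seed: int = 0,
    model: EnergyModel | None = None,
) -> RotamerPuzzle:
    """Serine residues on separate one-residue chains, each starting at its
    most probable rotamer.

    With ``coupling="pairwise_clash"`` the first two chains face each other
    so that a hydroxyl-hydroxyl hydrogen bond forms only for one specific
    rotamer pair: the per-residue greedy choice misses it and is strictly
    worse than the joint optimum.  With ``coupling="none"`` the chains sit
    far apart and greedy equals optimal.  Ground truth is the enumerated
    global optimum, computed at generation time; generation fails rather
    than returning an uncoupled "clash" puzzle.
    """
    from .conformational_sampler import enumerate_rotamers
    from .rotamers import default_library

    if n_flexible < 1:
        raise ValueError("need at least one flexible residue")
    if coupling not in ("none", "pairwise_clash"):
        raise ValueError(f"unknown coupling {coupling!r}")
    model = model or EnergyModel()
    lib = default_library()

    st = _serine_puzzle_structure(n_flexible, coupling)
    flexible = [r.rid for r in st.residues()]
    opt_st, opt_e = enumerate_rotamers(st, flexible, model, lib)
    opt_assign = _assignment_of(opt_st, flexible, lib)
    greedy_assign = _greedy_assignment(st, flexible, model, lib)
    greedy_e = _energy_of_assignment(st, flexible, greedy_assign, model, lib)
    puzzle = RotamerPuzzle(st, flexible, model, opt_e, opt_assign, greedy_assign, greedy_e)
    if coupling == "pairwise_clash" and n_flexible >= 2:
        if greedy_assign == opt_assign or greedy_e <= opt_e + 0.05:
            raise RuntimeError("degenerate puzzle: greedy choice already optimal")
    return puzzle


def _serine_puzzle_structure(n: int, coupling: str, contact: float = 2.95) -> StructureModel:
    from .builder import build_side_chain
    from .rotamers import default_library

    lib = default_library()
    chains = []
    a = build_peptide("S", conformation="extended", chain_id="A", chis={0: (180.0,)})
    chains.extend(a.chains)
    ser = a.get("A", 1)
    tip = ser.pos("OG")
    u = tip - ser.pos("CB")
    u /= np.linalg.norm(u)
    bb = ser.pos("C") - ser.pos("N")
    bb /= np.linalg.norm(bb)
    w = np.cross(u, bb)
    w /= np.linalg.norm(w)
    for i in range(1, n):
        cid = chr(ord("A") + i)
        c = build_peptide("S", conformation="extended", chain_id=cid, chis={0: (180.0,)})
        if i == 1 and coupling == "pairwise_clash":
            # face chain A so the chi=180/chi=180 hydroxyls meet at H-bond range
            rot = rotation_about_axis(w, 180.0)
            for res in c.residues():
                for at in res.atoms:
                    at.pos = rot @ (at.pos - tip) + tip + contact * u
        else:
            # spectators (or all chains, for coupling="none"): well separated
            for res in c.residues():
                for at in res.atoms:
                    at.pos = at.pos + i * 14.0 * w
        chains.extend(c.chains)
    st = StructureModel(chains, {"source": f"serine_puzzle(n={n}, coupling={coupling})"})
    for r in st.residues():
        build_side_chain(r, "S", lib.most_probable("S").chis)
    return build_all_atom_model(st)


def _assignment_of(st, flexible, lib) -> tuple[int, ...]:
    """Index of the library rotamer nearest each residue's current chis."""
    from .builder import measure_chis

    out = []
    for rid in flexible:
        res = st.get(*rid)
        chis = measure_chis(res)
        best_k, best_d = 0, float("inf")
        for k, rot in enumerate(lib.rotamers(res.aa1)):
            d = sum(
                min(abs(c - t), 360 - abs(c - t)) for c, t in zip(chis, rot.chis)
            )
            if d < best_d:
                best_k, best_d = k, d
        out.append(best_k)
    return tuple(out)


def _energy_of_assignment(st, flexible, assignment, model, lib) -> float:
    from .builder import build_side_chain

    work = st.copy()
    for rid, k in zip(flexible, assignment):
        res = work.get(*rid)
        build_side_chain(res, res.aa1, lib.rotamers(res.aa1)[k].chis)
    work.prepared = True
    return folded_energy(work, model).total


def _greedy_assignment(st, flexible, model, lib) -> tuple[int, ...]:
    """Optimize each residue independently, everything else at its input
    (most-probable) rotamer."""
    from .conformational_sampler import enumerate_rotamers

    out = []
    for rid in flexible:
        opt_st, _ = enumerate_rotamers(st, [rid], model, lib)
        out.append(_assignment_of(opt_st, [rid], lib)[0])
    return tuple(out)


def make_surface_helix(n_residues: int = 12, sequence: str | None = None) -> StructureModel:
    """An ideal poly-Ala alpha-helix (prepared); mid-chain side chains are
    fully solvent exposed, so surface substitutions there should be close
    to neutral in stability."""
    seq = sequence or "A" * n_residues
    st = build_peptide(seq, conformation="helix", chain_id="A")
    return build_all_atom_model(st)
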