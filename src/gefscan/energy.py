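"""Empirical all-atom free-energy function.

Terms (all pairwise-decomposable, kcal/mol):

* ``vdw`` - 6-12 Lennard-Jones on heavy atoms with per-element Rmin/epsilon
  (Lorentz-Berthelot mixing), hard 9 A cutoff and a linear continuation at
  short range so clashes stay finite and monotonically repulsive.
* ``hbond`` - geometric donor/acceptor term on heavy atoms: full strength at
  D...A <= 3.0 A fading linearly to zero at 3.5 A, gated by angular cutoffs
  at both donor and acceptor.
* ``elec`` - Coulomb between formally charged side-chain groups with a
  distance-dependent dielectric eps(r) = 4r.
* ``solvation`` - pairwise Gaussian-exclusion desolvation (Lazaridis-Karplus
  form): burying hydrophobic atoms is rewarded, burying polar atoms is
  penalized.  A pairwise form is used (rather than an explicit surface
  area) so that every term decomposes over atom pairs, which the scoped /
  incremental evaluation contract requires.
* ``torsion`` - a small three-fold strain penalty on side-chain chi angles.

Bonded exclusions: 1-2 and 1-3 pairs are skipped, 1-4 pairs are scaled.
Hydrogens are geometric markers only and carry no nonbonded parameters.

The unfolded-state reference is a per-residue free energy table; the energy
of an unfolded chain is the sum of its residues' entries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import chem
from .structure_model import ComplexPartition, Residue, StructureModel

__all__ = [
    "EnergyModel",
    "EnergyBreakdown",
    "System",
    "build_system",
    "folded_energy",
    "unfolded_energy",
    "binding_energy",
    "extract_chains",
]

TERM_NAMES = ("vdw", "hbond", "elec", "solvation", "torsion")

_SCHEMA_VERSION = 1


@dataclass
class EnergyModel:
    """Term weights plus all physical parameters of the energy function."""

    weights: dict = field(default_factory=lambda: {t: 1.0 for t in TERM_NAMES})
    vdw_params: dict = field(default_factory=lambda: dict(chem.VDW_PARAMS))
    cutoff: float = 9.0
    scale_14: float = 0.5
    cap_fraction: float = 0.6  # linear LJ continuation below cap_fraction*Rmin
    hb_max_dist: float = 3.5
    hb_opt_dist: float = 3.0
    hb_min_angle: float = 90.0  # base-donor-acceptor and base-acceptor-donor, deg
    hb_strength: float = 1.5
    dielectric_coeff: float = 4.0  # eps(r) = coeff * r
    solvation_params: dict = field(default_factory=lambda: dict(chem.SOLVATION_PARAMS))
    solvation_lambda: float = chem.SOLVATION_LAMBDA
    torsion_k: float = 0.25
    unfolded_reference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, w in self.weights.items():
            if t not in TERM_NAMES:
                raise ValueError(f"unknown energy term {t!r}")
            if not math.isfinite(w):
                raise ValueError(f"weight for {t} must be finite")

    def validate_reference(self) -> None:
        missing = [aa for aa in chem.STANDARD_AA1 if aa not in self.unfolded_reference]
        if missing:
            raise ValueError(f"unfolded reference table missing entries for {missing}")

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema_version": _SCHEMA_VERSION,
            "weights": self.weights,
            "vdw_params": {k: list(v) for k, v in self.vdw_params.items()},
            "cutoff": self.cutoff,
            "scale_14": self.scale_14,
            "cap_fraction": self.cap_fraction,
            "hb_max_dist": self.hb_max_dist,
            "hb_opt_dist": self.hb_opt_dist,
            "hb_min_angle": self.hb_min_angle,
            "hb_strength": self.hb_strength,
            "dielectric_coeff": self.dielectric_coeff,
            "solvation_params": {k: list(v) for k, v in self.solvation_params.items()},
            "solvation_lambda": self.solvation_lambda,
            "torsion_k": self.torsion_k,
            "unfolded_reference": self.unfolded_reference,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnergyModel":
        doc = json.loads(Path(path).read_text())
        ver = doc.pop("schema_version", None)
        if ver != _SCHEMA_VERSION:
            raise ValueError(f"unsupported energy model schema version {ver}")
        doc["vdw_params"] = {k: tuple(v) for k, v in doc["vdw_params"].items()}
        doc["solvation_params"] = {k: tuple(v) for k, v in doc["solvation_params"].items()}
        return cls(**doc)

    @classmethod
    def default(cls) -> "EnergyModel":
        """The bundled default profile, including the calibrated
        unfolded-state reference table."""
        model = cls()
        ref_file = resources.files("gefscan.data").joinpath("unfolded_reference.json")
        if ref_file.is_file():
            model.unfolded_reference = json.loads(ref_file.read_text())
        return model


@dataclass
class EnergyBreakdown:
    """Weighted per-term energies; total is their exact sum."""

    total: float
    terms: dict

    @classmethod
    def from_terms(cls, raw: dict, weights: dict) -> "EnergyBreakdown":
        weighted = {t: weights.get(t, 0.0) * raw.get(t, 0.0) for t in TERM_NAMES}
        return cls(total=sum(weighted.values()), terms=weighted)


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------

class System:
    """Flattened arrays + topology for fast repeated evaluation.

    Holds references to the residues it was built from; ``refresh_residue``
    re-reads one residue's coordinates after a side-chain move.
    """

    def __init__(self) -> None:
        self.pos = np.zeros((0, 3))
        self.rminh = np.zeros(0)
        self.eps = np.zeros(0)
        self.charge = np.zeros(0)
        self.dgfree = np.zeros(0)
        self.vol = np.zeros(0)
        self.res_of = np.zeros(0, dtype=int)
        self.excl = np.zeros((0, 0), dtype=np.int8)
        self.residues: list[Residue] = []
        self.res_atom_idx: list[np.ndarray] = []
        self.donors: list[tuple[int, int]] = []       # (donor, base)
        self.acceptors: list[tuple[int, int]] = []    # (acceptor, base)
        self.chi_quads: list[tuple[int, tuple[int, int, int, int]]] = []
        self.atom_key: dict[tuple[int, str], int] = {}

    @property
    def n_atoms(self) -> int:
        return len(self.pos)

    def atoms_of(self, res_indices) -> np.ndarray:
        if not len(self.res_atom_idx):
            return np.zeros(0, dtype=int)
        parts = [self.res_atom_idx[i] for i in res_indices]
        return np.concatenate(parts) if parts else np.zeros(0, dtype=int)

    def refresh_residue(self, res_index: int) -> None:
        res = self.residues[res_index]
        for i in self.res_atom_idx[res_index]:
            # atoms are keyed by name; heavy-atom sets are fixed during repack
            name = self._names[i]
            self.pos[i] = res.pos(name)

    _names: list[str]


def build_system(structure: StructureModel, model: EnergyModel) -> System:
    sys = System()
    residues = structure.residues()
    names: list[str] = []
    pos, rminh, eps, charge, dgfree, vol, res_of = [], [], [], [], [], [], []
    bonds: list[tuple[int, int]] = []
    sys.residues = residues
    for ri, res in enumerate(residues):
        idx_here: list[int] = []
        aa1 = res.aa1
        for a in res.atoms:
            if a.element == "H":
                continue
            i = len(pos)
            sys.atom_key[(ri, a.name)] = i
            names.append(a.name)
            idx_here.append(i)
            pos.append(a.pos)
            rh, ep = model.vdw_params.get(a.element, (1.8, 0.1))
            rminh.append(rh)
            eps.append(ep)
            dg, v = model.solvation_params.get(a.element, (0.0, 0.0))
            dgfree.append(dg)
            vol.append(v)
            charge.append(chem.PARTIAL_CHARGES.get((aa1, a.name), 0.0) if aa1 else 0.0)
            res_of.append(ri)
        sys.res_atom_idx.append(np.array(idx_here, dtype=int))
        if aa1 is None:
            # non-standard group kept as rigid background: exclude intra pairs
            for x in idx_here:
                for y in idx_here:
                    if x < y:
                        bonds.append((x, y))
            continue
        # intra-residue bonds from the template tree
        def _bond(n1: str, n2: str) -> None:
            k1, k2 = sys.atom_key.get((ri, n1)), sys.atom_key.get((ri, n2))
            if k1 is not None and k2 is not None:
                bonds.append((k1, k2))

        _bond("N", "CA")
        _bond("CA", "C")
        _bond("C", "O")
        _bond("CA", "CB")
        for name, _el, (_a, _b, c), *_ in chem.SIDE_CHAIN_TEMPLATES[aa1]:
            _bond(name, c)
        for n1, n2 in chem.RING_CLOSURE_BONDS.get(aa1, []):
            _bond(n1, n2)
        # hydrogen-bond participants (heavy-atom criterion)
        def _add(group: list, atom: str, base: str) -> None:
            ka, kb = sys.atom_key.get((ri, atom)), sys.atom_key.get((ri, base))
            if ka is not None and kb is not None:
                group.append((ka, kb))

        if aa1 != "P":
            _add(sys.donors, "N", "CA")
        _add(sys.acceptors, "O", "C")
        for atom, base in chem.SIDECHAIN_DONORS.get(aa1, {}).items():
            _add(sys.donors, atom, base)
        for atom, base in chem.SIDECHAIN_ACCEPTORS.get(aa1, {}).items():
            _add(sys.acceptors, atom, base)
        for quad in chem.CHI_ATOMS[aa1]:
            ks = [sys.atom_key.get((ri, n)) for n in quad]
            if all(k is not None for k in ks):
                sys.chi_quads.append((ri, tuple(ks)))
    # peptide bonds between consecutive residues of the same chain
    offset = 0
    for _cid, chain_res in structure.chains:
        for j in range(len(chain_res) - 1):
            ri, rj = offset + j, offset + j + 1
            kc = sys.atom_key.get((ri, "C"))
            kn = sys.atom_key.get((rj, "N"))
            if kc is not None and kn is not None:
                if np.linalg.norm(np.asarray(pos[kc]) - np.asarray(pos[kn])) < 2.0:
                    bonds.append((kc, kn))
        offset += len(chain_res)

    n = len(pos)
    sys.pos = np.array(pos) if n else np.zeros((0, 3))
    sys.rminh = np.array(rminh)
    sys.eps = np.array(eps)
    sys.charge = np.array(charge)
    sys.dgfree = np.array(dgfree)
    sys.vol = np.array(vol)
    sys.res_of = np.array(res_of, dtype=int)
    sys._names = names
    # exclusion matrix: 1 = skip (1-2/1-3), 2 = 1-4 scaling
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    excl = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in adj[i]:
            excl[i, j] = 1
        for j in adj[i]:
            for k in adj[j]:
                if k != i:
                    excl[i, k] = 1
    for i in range(n):
        onethree = {k for j in adj[i] for k in adj[j] if k != i}
        for j in onethree:
            for k in adj[j]:
                if k != i and excl[i, k] == 0:
                    excl[i, k] = 2
                    excl[k, i] = 2
    np.fill_diagonal(excl, 1)
    sys.excl = np.maximum(excl, excl.T)
    return sys


# ---------------------------------------------------------------------------
# term evaluation
# ---------------------------------------------------------------------------

def _lj_matrix(model: EnergyModel, d: np.ndarray, rmin: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Capped, truncated Lennard-Jones on a distance matrix."""
    out = np.zeros_like(d)
    live = (eps > 0) & (d < model.cutoff)
    if not np.any(live):
        return out
    r0 = model.cap_fraction * rmin
    capped = live & (d < r0)
    smooth = live & ~capped
    x6 = (rmin[smooth] / d[smooth]) ** 6
    out[smooth] = eps[smooth] * (x6 * x6 - 2.0 * x6)
    if np.any(capped):
        x06 = (1.0 / model.cap_fraction) ** 6
        e0 = eps[capped] * (x06 * x06 - 2.0 * x06)
        slope = (12.0 * eps[capped] / r0[capped]) * (x06 - x06 * x06)
        out[capped] = e0 + slope * (d[capped] - r0[capped])
    return out


def _nb_terms(sys: System, model: EnergyModel, ia: np.ndarray, ib: np.ndarray) -> dict:
    """Raw (unweighted) vdw/elec/solvation sums over the pair block ia x ib.

    If ``ia is ib`` each unordered pair is counted once; otherwise the two
    index sets must be disjoint.
    """
    raw = {"vdw": 0.0, "elec": 0.0, "solvation": 0.0}
    if len(ia) == 0 or len(ib) == 0:
        return raw
    diff = sys.pos[ia][:, None, :] - sys.pos[ib][None, :, :]
    # clamp coincident atoms to a tiny distance: the capped LJ then yields a
    # large finite repulsion instead of NaN/zero
    d = np.maximum(np.sqrt(np.sum(diff * diff, axis=-1)), 0.05)
    excl = sys.excl[np.ix_(ia, ib)]
    if ia is ib:
        keep = np.triu(np.ones_like(d, dtype=bool), k=1)
    else:
        keep = np.ones_like(d, dtype=bool)
    keep &= excl != 1
    scale = np.where(excl == 2, model.scale_14, 1.0)
    inrange = keep & (d < model.cutoff)
    if not np.any(inrange):
        return raw
    # vdw
    rmin = sys.rminh[ia][:, None] + sys.rminh[ib][None, :]
    eps = np.sqrt(sys.eps[ia][:, None] * sys.eps[ib][None, :])
    lj = _lj_matrix(model, np.where(inrange, d, np.inf), rmin, eps)
    raw["vdw"] = float(np.sum(lj * scale * inrange))
    # electrostatics (formal charges only)
    qq = sys.charge[ia][:, None] * sys.charge[ib][None, :]
    qmask = inrange & (qq != 0)
    if np.any(qmask):
        raw["elec"] = float(
            np.sum(
                chem.COULOMB_CONSTANT
                * qq[qmask]
                * scale[qmask]
                / (model.dielectric_coeff * d[qmask] ** 2)
            )
        )
    # pairwise desolvation
    lam = model.solvation_lambda
    pref = 2.0 * np.pi ** 1.5 * lam
    gi = sys.dgfree[ia][:, None]
    gj = sys.dgfree[ib][None, :]
    vi = sys.vol[ia][:, None]
    vj = sys.vol[ib][None, :]
    ri = sys.rminh[ia][:, None]
    rj = sys.rminh[ib][None, :]
    smask = inrange & ((gi != 0) | (gj != 0))
    if np.any(smask):
        dd = np.where(smask, d, 1.0)
        e_ij = -(gi / (pref * dd ** 2)) * np.exp(-(((dd - ri) / lam) ** 2)) * vj
        e_ji = -(gj / (pref * dd ** 2)) * np.exp(-(((dd - rj) / lam) ** 2)) * vi
        raw["solvation"] = float(np.sum((e_ij + e_ji) * smask))
    return raw


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond_matrix(sys: System, model: EnergyModel) -> np.ndarray:
    """(n_donors x n_acceptors) matrix of raw H-bond energies (<= 0)."""
    nd, na = len(sys.donors), len(sys.acceptors)
    if nd == 0 or na == 0:
        return np.zeros((nd, na))
    don = np.array([d for d, _ in sys.donors], dtype=int)
    dbase = np.array([b for _, b in sys.donors], dtype=int)
    acc = np.array([a for a, _ in sys.acceptors], dtype=int)
    abase = np.array([b for _, b in sys.acceptors], dtype=int)
    dp, ap = sys.pos[don], sys.pos[acc]
    diff = ap[None, :, :] - dp[:, None, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    ok = (dist <= model.hb_max_dist) & (dist >= 1.5)
    ok &= sys.res_of[don][:, None] != sys.res_of[acc][None, :]
    cosmin = np.cos(np.radians(model.hb_min_angle))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = sys.pos[dbase] - dp
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cos_d = np.einsum("ij,ikj->ik", u, diff / np.maximum(dist, 1e-9)[:, :, None])
        ok &= cos_d <= cosmin  # angle at donor >= cutoff
        v = sys.pos[abase] - ap
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        cos_a = np.einsum("kj,ikj->ik", v, -diff / np.maximum(dist, 1e-9)[:, :, None])
        ok &= cos_a <= cosmin  # angle at acceptor >= cutoff
    ramp = np.clip(
        (model.hb_max_dist - dist) / (model.hb_max_dist - model.hb_opt_dist), 0.0, 1.0
    )
    return np.where(ok, -model.hb_strength * ramp, 0.0)


def _hbond_term(sys: System, model: EnergyModel, scope_res: set[int] | None) -> float:
    """Raw hydrogen-bond sum; restricted to pairs touching ``scope_res``."""
    m = _hbond_matrix(sys, model)
    if m.size == 0:
        return 0.0
    if scope_res is not None:
        don = np.array([d for d, _ in sys.donors], dtype=int)
        acc = np.array([a for a, _ in sys.acceptors], dtype=int)
        in_scope = np.zeros(len(sys.residues) + 1, dtype=bool)
        for r in scope_res:
            in_scope[r] = True
        keep = in_scope[sys.res_of[don]][:, None] | in_scope[sys.res_of[acc]][None, :]
        m = np.where(keep, m, 0.0)
    return float(np.sum(m))


def hbond_between(sys: System, model: EnergyModel, res_a: set[int], res_b: set[int]) -> float:
    """Raw H-bond energy between two residue-index sets (both directions)."""
    m = _hbond_matrix(sys, model)
    if m.size == 0:
        return 0.0
    don = np.array([d for d, _ in sys.donors], dtype=int)
    acc = np.array([a for a, _ in sys.acceptors], dtype=int)
    da = np.isin(sys.res_of[don], list(res_a))
    db = np.isin(sys.res_of[don], list(res_b))
    aa = np.isin(sys.res_of[acc], list(res_a))
    ab = np.isin(sys.res_of[acc], list(res_b))
    keep = (da[:, None] & ab[None, :]) | (db[:, None] & aa[None, :])
    return float(np.sum(np.where(keep, m, 0.0)))


def _torsion_term(sys: System, model: EnergyModel, scope_res: set[int] | None) -> float:
    from .geometry import dihedral

    total = 0.0
    for ri, (i, j, k, l) in sys.chi_quads:
        if scope_res is not None and ri not in scope_res:
            continue
        chi = math.radians(dihedral(sys.pos[i], sys.pos[j], sys.pos[k], sys.pos[l]))
        total += model.torsion_k * (1.0 + math.cos(3.0 * chi))
    return total


def raw_terms(sys: System, model: EnergyModel, scope_res: set[int] | None = None) -> dict:
    """Unweighted term sums; with a residue-index scope, pair terms with at
    least one endpoint in scope plus local terms of scoped residues."""
    if scope_res is None:
        all_idx = np.arange(sys.n_atoms)
        raw = _nb_terms(sys, model, all_idx, all_idx)
    else:
        s_idx = sys.atoms_of(sorted(scope_res))
        mask = np.zeros(sys.n_atoms, dtype=bool)
        mask[s_idx] = True
        r_idx = np.flatnonzero(~mask)
        raw = _nb_terms(sys, model, s_idx, s_idx)
        between = _nb_terms(sys, model, s_idx, r_idx)
        for t in raw:
            raw[t] += between[t]
    raw["hbond"] = _hbond_term(sys, model, scope_res)
    raw["torsion"] = _torsion_term(sys, model, scope_res)
    return raw


# ---------------------------------------------------------------------------
# public evaluations
# ---------------------------------------------------------------------------

def _require_prepared(structure: StructureModel) -> None:
    if not structure.prepared:
        raise ValueError(
            "structure has not been prepared; run build_all_atom_model first"
        )


def folded_energy(
    structure: StructureModel,
    model: EnergyModel,
    scope: set | list | None = None,
) -> EnergyBreakdown:
    """Folded-state free energy (kcal/mol), optionally scoped.

    With ``scope`` (residue locators), returns the interaction energy of the
    scoped subset with the whole system (pairs within the subset counted
    once) plus the subset's local terms - the quantity used for incremental
    Monte-Carlo scoring.
    """
    _require_prepared(structure)
    sys = build_system(structure, model)
    scope_res: set[int] | None = None
    if scope is not None:
        wanted = set(scope)
        scope_res = {i for i, r in enumerate(sys.residues) if r.rid in wanted}
        missing = wanted - {sys.residues[i].rid for i in scope_res}
        if missing:
            raise KeyError(f"scope residues not in structure: {sorted(missing)}")
    raw = raw_terms(sys, model, scope_res)
    return EnergyBreakdown.from_terms(raw, model.weights)


def unfolded_energy(sequence: str, model: EnergyModel) -> float:
    """Unfolded-chain free energy: the sum of residue-specific reference
    energies (order-independent and additive by construction)."""
    total = 0.0
    for aa in sequence:
        if aa not in model.unfolded_reference:
            raise KeyError(f"no unfolded reference energy for residue {aa!r}")
        total += model.unfolded_reference[aa]
    return total


def extract_chains(structure: StructureModel, chain_ids) -> StructureModel:
    wanted = set(chain_ids)
    chains = [(cid, rs) for cid, rs in structure.copy().chains if cid in wanted]
    sub = StructureModel(chains, dict(structure.metadata))
    sub.prepared = structure.prepared
    return sub


def binding_energy(
    structure: StructureModel,
    partition: ComplexPartition,
    model: EnergyModel,
    repack_unbound: bool = False,
    sampler_config=None,
) -> float:
    """G(complex) - G(receptor) - G(partner), kcal/mol (favorable < 0).

    With ``repack_unbound=False`` the separated parts keep their bound-state
    conformations, and the value reduces exactly to the cross-partition
    interaction energy.  With ``repack_unbound=True`` the former interface
    residues of each part are repacked before evaluation.
    """
    _require_prepared(structure)
    partition.validate_against(structure)
    g_complex = folded_energy(structure, model).total
    parts = []
    for side in (partition.receptor_chains, partition.partner_chains):
        sub = extract_chains(structure, side)
        if repack_unbound:
            from .conformational_sampler import SamplerConfig, repack

            cfg = sampler_config or SamplerConfig()
            flex = _interface_residues(structure, partition, side, model.cutoff)
            flex = [rid for rid in flex if sub.has(rid)]
            if flex:
                sub = repack(sub, flex, model, cfg).structure
        parts.append(folded_energy(sub, model).total)
    return g_complex - parts[0] - parts[1]


def _interface_residues(structure, partition, side, cutoff) -> list:
    """Residues of ``side`` with heavy atoms within cutoff of the other side."""
    mine, other = [], []
    for r in structure.residues():
        (mine if r.chain_id in side else other).append(r)
    if not other:
        return []
    other_xyz = np.concatenate([r.heavy_coords() for r in other])
    out = []
    for r in mine:
        xyz = r.heavy_coords()
        d2 = np.sum((xyz[:, None, :] - other_xyz[None, :, :]) ** 2, axis=-1)
        if np.min(d2) <= cutoff * cutoff:
            out.append(r.rid)
    return out


# ---------------------------------------------------------------------------
# unfolded-reference calibration
# ---------------------------------------------------------------------------

def calibrate_unfolded_reference(model: EnergyModel, library=None, n_context: int = 9) -> dict:
    """Derive the per-residue unfolded reference table.

    The reference context for residue X is the midpoint of an ideal poly-Ala
    helix with X substituted in: the entry is the minimum (over library
    rotamers of X) of X's scoped energy there.  With this table, a fully
    solvent-exposed substitution on a helix surface has a near-zero
    stability ddG by construction, which anchors the ddG scale.
    """
    from .builder import build_peptide, build_side_chain
    from .prepare import build_all_atom_model
    from .rotamers import default_library

    lib = library or default_library()
    table: dict[str, float] = {}
    mid_i = n_context // 2
    for aa in chem.STANDARD_AA1:
        st = build_peptide("A" * n_context, conformation="helix")
        st = build_all_atom_model(st)
        mid = st.residues()[mid_i]
        best = math.inf
        for rot in lib.rotamers(aa):
            build_side_chain(mid, aa, rot.chis)
            st.prepared = True
            e = folded_energy(st, model, scope=[mid.rid]).total
            best = min(best, e)
        table[aa] = round(best, 6)
    return table
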