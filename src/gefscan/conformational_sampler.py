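"""Point mutations and side-chain packing.

``repack`` runs biased-probability Metropolis Monte Carlo: each move picks a
flexible residue uniformly and proposes one of its rotamers with probability
proportional to the library prior, accepting on the Metropolis criterion
under an annealed reduced temperature.  The best state visited is returned.
``enumerate_rotamers`` is the exact counterpart: exhaustive minimization
over the discrete rotamer grid via the standard self/pair energy-table
decomposition, usable whenever the combinatorial product is small.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import chem
from .builder import build_side_chain
from .energy import (
    EnergyModel,
    _nb_terms,
    build_system,
    folded_energy,
    hbond_between,
    raw_terms,
)
from .rotamers import RotamerLibrary, default_library
from .structure_model import ResidueId, StructureModel

__all__ = [
    "SamplerConfig",
    "PackResult",
    "mutate_residue",
    "repack",
    "enumerate_rotamers",
]


@dataclass
class SamplerConfig:
    """Monte-Carlo settings.

    ``n_steps=None`` means 2000 proposals per flexible residue.  The default
    temperature schedule anneals geometrically from 3.0 to 0.3 (reduced
    units).  Convergence is declared when the best energy improves by less
    than ``convergence_tol_kcal`` over ``convergence_window`` consecutive
    steps.
    """

    radius_A: float = 8.0
    n_steps: int | None = None
    temperature_schedule: tuple[float, float] = (3.0, 0.3)
    seed: int = 0
    convergence_window: int = 500
    convergence_tol_kcal: float = 0.01
    steps_per_residue: int = 2000
    log_moves: bool = False

    def __post_init__(self) -> None:
        if self.n_steps is not None and self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        hi, lo = self.temperature_schedule
        if hi <= 0 or lo <= 0 or lo > hi:
            raise ValueError("temperatures must be positive and non-increasing")

    def resolve_steps(self, n_flexible: int) -> int:
        return self.n_steps if self.n_steps is not None else self.steps_per_residue * max(
            1, n_flexible
        )


@dataclass
class PackResult:
    structure: StructureModel
    energy: float
    accepted_moves: int
    converged: bool
    seed: int
    n_steps: int = 0
    moves: list | None = field(default=None, repr=False)


def mutate_residue(
    structure: StructureModel,
    site: ResidueId,
    target_aa: str,
    library: RotamerLibrary | None = None,
) -> StructureModel:
    """Return a copy with the site residue replaced by ``target_aa`` built at
    its most probable rotamer; backbone atoms are untouched."""
    if target_aa not in chem.AA1_TO_3:
        raise ValueError(f"unknown amino acid {target_aa!r}")
    if not structure.has(site):
        raise KeyError(f"unknown site {site}")
    lib = library or default_library()
    st = structure.copy()
    res = st.get(*site)
    build_side_chain(res, target_aa, lib.most_probable(target_aa).chis)
    if structure.prepared:
        from .prepare import _add_polar_hydrogens

        _add_polar_hydrogens(st)
    return st


def _movable(structure: StructureModel, flexible, library: RotamerLibrary):
    """Flexible residues that actually have rotameric freedom."""
    out = []
    for rid in sorted(set(flexible)):
        if not structure.has(rid):
            raise KeyError(f"flexible residue {rid} not in structure")
        res = structure.get(*rid)
        if res.aa1 is None:
            raise ValueError(f"cannot repack non-standard residue {res.aa3} at {rid}")
        if len(library.rotamers(res.aa1)) > 1:
            out.append(rid)
    return out


def _scoped_energy(sys, model: EnergyModel, ri: int) -> float:
    raw = raw_terms(sys, model, scope_res={ri})
    return sum(model.weights.get(t, 0.0) * v for t, v in raw.items())


def repack(
    structure: StructureModel,
    flexible,
    model: EnergyModel,
    config: SamplerConfig | None = None,
    library: RotamerLibrary | None = None,
) -> PackResult:
    """Biased-probability Monte-Carlo side-chain optimization.

    Only side chains of ``flexible`` residues move; backbones are bitwise
    untouched.  Fully reproducible for a given ``config.seed``.
    """
    config = config or SamplerConfig()
    lib = library or default_library()
    st = structure.copy()
    movable = _movable(st, flexible, lib)
    if not movable:
        e = folded_energy(st, model).total
        return PackResult(st, e, 0, True, config.seed, 0, [] if config.log_moves else None)

    sys = build_system(st, model)
    rid_to_ri = {r.rid: i for i, r in enumerate(sys.residues)}
    move_ris = [rid_to_ri[rid] for rid in movable]
    rots = {ri: lib.rotamers(sys.residues[ri].aa1) for ri in move_ris}
    cum = {ri: np.cumsum([r.prob for r in rots[ri]]) for ri in move_ris}

    n_steps = config.resolve_steps(len(move_ris))
    t_hi, t_lo = config.temperature_schedule
    temps = t_hi * (t_lo / t_hi) ** (np.arange(n_steps) / max(1, n_steps - 1))
    rng = np.random.default_rng(config.seed)

    e_total = folded_energy(st, model).total
    best_e = e_total
    best_snapshot = {ri: np.array([a.pos for a in sys.residues[ri].atoms]) for ri in move_ris}
    best_atoms = {ri: [a.name for a in sys.residues[ri].atoms] for ri in move_ris}
    accepted = 0
    last_improve = 0
    converged = False
    log: list = [] if config.log_moves else None
    steps_run = 0

    for step in range(n_steps):
        steps_run = step + 1
        ri = move_ris[int(rng.integers(len(move_ris)))]
        u = rng.random()
        k = int(np.searchsorted(cum[ri], u * cum[ri][-1], side="right"))
        k = min(k, len(rots[ri]) - 1)
        res = sys.residues[ri]
        old_atoms = [(a.name, a.element, a.pos.copy()) for a in res.atoms]
        e_old = _scoped_energy(sys, model, ri)
        build_side_chain(res, res.aa1, rots[ri][k].chis)
        sys.refresh_residue(ri)
        e_new = _scoped_energy(sys, model, ri)
        delta = e_new - e_old
        if delta <= 0 or rng.random() < math.exp(-delta / temps[step]):
            accepted += 1
            e_total += delta
            if log is not None:
                log.append((res.rid, k))
            if e_total < best_e - 1e-12:
                if e_total < best_e - config.convergence_tol_kcal:
                    last_improve = step
                best_e = e_total
                for rj in move_ris:
                    rr = sys.residues[rj]
                    best_snapshot[rj] = np.array([a.pos for a in rr.atoms])
                    best_atoms[rj] = [a.name for a in rr.atoms]
        else:
            from .structure_model import AtomRecord

            res.atoms = [AtomRecord(n, el, p) for n, el, p in old_atoms]
            sys.refresh_residue(ri)
        if step - last_improve >= config.convergence_window:
            converged = True
            break

    # restore the best-visited state
    from .structure_model import AtomRecord

    for ri in move_ris:
        res = sys.residues[ri]
        elements = {a.name: a.element for a in res.atoms}
        res.atoms = [
            AtomRecord(n, elements.get(n, n[0]), p)
            for n, p in zip(best_atoms[ri], best_snapshot[ri])
        ]
    if structure.prepared:
        from .prepare import _add_polar_hydrogens

        _add_polar_hydrogens(st)
    energy = folded_energy(st, model).total
    return PackResult(st, energy, accepted, converged, config.seed, steps_run, log)


def enumerate_rotamers(
    structure: StructureModel,
    flexible,
    model: EnergyModel,
    library: RotamerLibrary | None = None,
    max_combinations: int = 10**6,
) -> tuple[StructureModel, float]:
    """Exact global minimum over the discrete rotamer grid.

    Uses the standard self/pair energy-table decomposition so the full
    product is enumerated as table sums; errors out when the combinatorial
    bound is exceeded (use ``repack`` instead)."""
    lib = library or default_library()
    st = structure.copy()
    movable = _movable(st, flexible, lib)
    if not movable:
        return st, folded_energy(st, model).total

    n_comb = 1
    for rid in movable:
        n_comb *= len(lib.rotamers(st.get(*rid).aa1))
        if n_comb > max_combinations:
            raise ValueError(
                f"rotamer combinations exceed bound ({max_combinations}); use repack"
            )

    sys = build_system(st, model)
    rid_to_ri = {r.rid: i for i, r in enumerate(sys.residues)}
    flex_ri = [rid_to_ri[rid] for rid in movable]
    flex_set = set(flex_ri)
    rots = {ri: lib.rotamers(sys.residues[ri].aa1) for ri in flex_ri}
    static_res = {i for i in range(len(sys.residues)) if i not in flex_set}
    static_idx = sys.atoms_of(sorted(static_res)) if static_res else np.zeros(0, dtype=int)

    def weighted(raw: dict) -> float:
        return sum(model.weights.get(t, 0.0) * v for t, v in raw.items())

    def set_rotamer(ri: int, k: int) -> None:
        res = sys.residues[ri]
        build_side_chain(res, res.aa1, rots[ri][k].chis)
        sys.refresh_residue(ri)

    from .energy import _torsion_term

    # static-static contribution (nb pairs, hbond among static, static torsions)
    e_static = weighted(_nb_terms(sys, model, static_idx, static_idx))
    e_static += model.weights.get("hbond", 0.0) * _static_hbond(sys, model, flex_set)
    e_static += model.weights.get("torsion", 0.0) * _torsion_term(sys, model, static_res)

    # self tables
    self_e: dict[int, list[float]] = {}
    for ri in flex_ri:
        own = sys.res_atom_idx[ri]
        vals = []
        for k in range(len(rots[ri])):
            set_rotamer(ri, k)
            raw = _nb_terms(sys, model, own, own)
            between = _nb_terms(sys, model, own, static_idx)
            e = weighted(raw) + weighted(between)
            e += model.weights.get("hbond", 0.0) * hbond_between(sys, model, {ri}, static_res)
            e += model.weights.get("torsion", 0.0) * _torsion_term(sys, model, {ri})
            vals.append(e)
        self_e[ri] = vals

    # pair tables
    pair_e: dict[tuple[int, int], np.ndarray] = {}
    for a, b in itertools.combinations(flex_ri, 2):
        tbl = np.zeros((len(rots[a]), len(rots[b])))
        for ka in range(len(rots[a])):
            set_rotamer(a, ka)
            for kb in range(len(rots[b])):
                set_rotamer(b, kb)
                e = weighted(_nb_terms(sys, model, sys.res_atom_idx[a], sys.res_atom_idx[b]))
                e += model.weights.get("hbond", 0.0) * hbond_between(sys, model, {a}, {b})
                tbl[ka, kb] = e
        pair_e[(a, b)] = tbl

    best = None
    best_e = math.inf
    for combo in itertools.product(*(range(len(rots[ri])) for ri in flex_ri)):
        e = e_static
        for ri, k in zip(flex_ri, combo):
            e += self_e[ri][k]
        for idx_a in range(len(flex_ri)):
            for idx_b in range(idx_a + 1, len(flex_ri)):
                key = (flex_ri[idx_a], flex_ri[idx_b])
                e += pair_e[key][combo[idx_a], combo[idx_b]]
        if e < best_e - 1e-12:
            best_e = e
            best = combo
    for ri, k in zip(flex_ri, best):
        set_rotamer(ri, k)
    if structure.prepared:
        from .prepare import _add_polar_hydrogens

        _add_polar_hydrogens(st)
    # report the directly evaluated energy of the reconstructed optimum
    return st, folded_energy(st, model).total


def _static_hbond(sys, model: EnergyModel, flex_set: set[int]) -> float:
    from .energy import _hbond_matrix

    m = _hbond_matrix(sys, model)
    if m.size == 0:
        return 0.0
    don = np.array([d for d, _ in sys.donors], dtype=int)
    acc = np.array([a for a, _ in sys.acceptors], dtype=int)
    d_static = ~np.isin(sys.res_of[don], list(flex_set))
    a_static = ~np.isin(sys.res_of[acc], list(flex_set))
    keep = d_static[:, None] & a_static[None, :]
    return float(np.sum(np.where(keep, m, 0.0)))
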