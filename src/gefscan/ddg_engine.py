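"""Per-mutation free-energy changes.

For a mutation m at site s:

* stability: ddG = (G_folded^mut - G_unfolded^mut) - (G_folded^WT - G_unfolded^WT),
  where the unfolded chain energy is a sum of residue-specific reference
  energies, so every term except the mutated residue's cancels and the
  difference reduces to the single-entry swap ref[mut] - ref[wt].
* binding: ddG = G_binding^mut - G_binding^WT on the two-partner complex.

Positive values are destabilizing / binding-disruptive.  Both states are
prepared identically: side chains in the repacking shell (default 8 A
around the site) are first set to their most probable rotamers, then
optimized by the same Monte-Carlo run with the same seed, so an identity
"mutation" yields exactly zero by construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import chem
from .conformational_sampler import SamplerConfig, mutate_residue, repack
from .builder import build_side_chain
from .energy import EnergyBreakdown, EnergyModel, binding_energy, extract_chains, folded_energy
from .rotamers import default_library
from .structure_model import ComplexPartition, ResidueId, StructureModel, select_neighborhood

__all__ = [
    "MutationSpec",
    "DdgResult",
    "ddg_stability",
    "ddg_binding",
    "compute_ddg",
    "scan",
    "derive_seed",
    "read_mutations_tsv",
    "write_results_tsv",
]


@dataclass(frozen=True)
class MutationSpec:
    chain_id: str
    seq_num: int
    wt_aa: str
    mut_aa: str
    icode: str = ""
    label: str = ""
    wt_codon: str | None = None
    mut_codon: str | None = None

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in chem.AA1_TO_3:
                raise ValueError(f"unknown amino acid {aa!r}")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.wt_aa}{self.seq_num}{self.mut_aa}"
            )

    @property
    def site(self) -> ResidueId:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def is_identity(self) -> bool:
        return self.wt_aa == self.mut_aa


@dataclass
class DdgResult:
    mutation: MutationSpec
    ddg_stability: float
    ddg_binding: float
    breakdown_wt: EnergyBreakdown
    breakdown_mut: EnergyBreakdown
    seed: int
    converged: bool


def derive_seed(run_seed: int, label: str) -> int:
    """Deterministic per-mutation seed (stable across processes)."""
    return zlib.crc32(f"{run_seed}:{label}".encode()) & 0x7FFFFFFF


def _check_wt(structure: StructureModel, mutation: MutationSpec) -> None:
    res = structure.get(*mutation.site)
    if res.aa1 != mutation.wt_aa:
        raise ValueError(
            f"{mutation.label}: structure has {res.aa1} at "
            f"{mutation.chain_id}{mutation.seq_num}, expected {mutation.wt_aa}"
        )


def _canonicalize(st: StructureModel, rids, library) -> None:
    """Set every standard side chain in ``rids`` to its most probable
    rotamer, giving WT and mutant runs a common, seed-independent start."""
    for rid in rids:
        res = st.get(*rid)
        if res.aa1 is not None and chem.N_CHI[res.aa1] > 0:
            build_side_chain(res, res.aa1, library.most_probable(res.aa1).chis)
    from .prepare import _add_polar_hydrogens

    _add_polar_hydrogens(st)


def _packed_states(
    structure: StructureModel,
    mutation: MutationSpec,
    model: EnergyModel,
    sampler: SamplerConfig,
    library=None,
):
    """Repacked WT and mutant complexes plus sampler convergence flags."""
    if not structure.prepared:
        raise ValueError("structure must be prepared (build_all_atom_model)")
    _check_wt(structure, mutation)
    lib = library or default_library()
    shell = select_neighborhood(structure, mutation.site, sampler.radius_A)

    wt = structure.copy()
    _canonicalize(wt, shell, lib)
    wt_pack = repack(wt, shell, model, sampler, lib)

    mut = mutate_residue(structure, mutation.site, mutation.mut_aa, lib)
    _canonicalize(mut, shell, lib)
    mut_pack = repack(mut, shell, model, sampler, lib)
    return wt_pack, mut_pack


def compute_ddg(
    structure: StructureModel,
    partition: ComplexPartition | None,
    mutation: MutationSpec,
    model: EnergyModel,
    sampler: SamplerConfig | None = None,
    stability_scope: str = "complex",
    repack_unbound: bool = False,
    library=None,
) -> DdgResult:
    """Stability and (if a partition is given) binding ddG for one mutation."""
    sampler = sampler or SamplerConfig()
    wt_pack, mut_pack = _packed_states(structure, mutation, model, sampler, library)

    if stability_scope == "receptor" and partition is not None:
        wt_st = extract_chains(wt_pack.structure, partition.receptor_chains)
        mut_st = extract_chains(mut_pack.structure, partition.receptor_chains)
        bd_wt = folded_energy(wt_st, model)
        bd_mut = folded_energy(mut_st, model)
    else:
        bd_wt = folded_energy(wt_pack.structure, model)
        bd_mut = folded_energy(mut_pack.structure, model)
    # all unfolded-reference entries except the mutated residue's cancel
    ref = model.unfolded_reference
    for aa in (mutation.wt_aa, mutation.mut_aa):
        if aa not in ref:
            raise KeyError(f"no unfolded reference energy for {aa!r}")
    d_stab = (bd_mut.total - ref[mutation.mut_aa]) - (bd_wt.total - ref[mutation.wt_aa])

    d_bind = 0.0
    if partition is not None:
        b_wt = binding_energy(
            wt_pack.structure, partition, model,
            repack_unbound=repack_unbound, sampler_config=sampler,
        )
        b_mut = binding_energy(
            mut_pack.structure, partition, model,
            repack_unbound=repack_unbound, sampler_config=sampler,
        )
        d_bind = b_mut - b_wt
    if mutation.is_identity:
        # identical states by construction; clamp numerical echo to exact zero
        assert abs(d_stab) < 1e-9 and abs(d_bind) < 1e-9
        d_stab = 0.0
        d_bind = 0.0
    return DdgResult(
        mutation=mutation,
        ddg_stability=d_stab,
        ddg_binding=d_bind,
        breakdown_wt=bd_wt,
        breakdown_mut=bd_mut,
        seed=sampler.seed,
        converged=wt_pack.converged and mut_pack.converged,
    )


def ddg_stability(
    structure: StructureModel,
    mutation: MutationSpec,
    model: EnergyModel,
    sampler: SamplerConfig | None = None,
    **kw,
) -> float:
    return compute_ddg(structure, None, mutation, model, sampler, **kw).ddg_stability


def ddg_binding(
    structure: StructureModel,
    partition: ComplexPartition,
    mutation: MutationSpec,
    model: EnergyModel,
    sampler: SamplerConfig | None = None,
    **kw,
) -> float:
    return compute_ddg(structure, partition, mutation, model, sampler, **kw).ddg_binding


def scan(
    structure: StructureModel,
    partition: ComplexPartition | None,
    sites,
    targets,
    model: EnergyModel,
    sampler: SamplerConfig | None = None,
    **kw,
) -> list[DdgResult]:
    """Cartesian site x target scan, identities skipped; each mutation gets
    a deterministic seed derived from the run seed and its label, so a scan
    reproduces single-mutation calls exactly."""
    sites = list(sites)
    targets = list(targets)
    if not sites or not targets:
        raise ValueError("scan needs at least one site and one target amino acid")
    sampler = sampler or SamplerConfig()
    run_seed = sampler.seed
    results: list[DdgResult] = []
    jobs = []
    for rid in sites:
        res = structure.get(*rid)
        for t in sorted(set(targets)):
            if t == res.aa1:
                continue
            jobs.append((rid, res.aa1, t))
    jobs.sort(key=lambda j: (j[0][0], j[0][1], j[0][2], j[2]))
    for rid, wt_aa, t in jobs:
        spec = MutationSpec(rid[0], rid[1], wt_aa, t, icode=rid[2])
        cfg = SamplerConfig(
            radius_A=sampler.radius_A,
            n_steps=sampler.n_steps,
            temperature_schedule=sampler.temperature_schedule,
            seed=derive_seed(run_seed, spec.label),
            convergence_window=sampler.convergence_window,
            convergence_tol_kcal=sampler.convergence_tol_kcal,
            steps_per_residue=sampler.steps_per_residue,
        )
        results.append(compute_ddg(structure, partition, spec, model, cfg, **kw))
    return results


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_mutations_tsv(path: str | Path) -> list[MutationSpec]:
    """Columns: chain, pos, wt, mut and optionally wt_codon, mut_codon."""
    out = []
    lines = Path(path).read_text().strip().splitlines()
    for ln in lines:
        if not ln.strip() or ln.startswith("#") or ln.lower().startswith("chain"):
            continue
        f = ln.split("\t")
        if len(f) < 4:
            raise ValueError(f"malformed mutation line: {ln!r}")
        spec = MutationSpec(
            chain_id=f[0], seq_num=int(f[1]), wt_aa=f[2], mut_aa=f[3],
            wt_codon=f[4] if len(f) > 4 else None,
            mut_codon=f[5] if len(f) > 5 else None,
        )
        out.append(spec)
    return out


def write_results_tsv(results: list[DdgResult], path: str | Path) -> None:
    rows = ["label\tddg_stability\tddg_binding\tconverged\tseed"]
    for r in results:
        rows.append(
            f"{r.mutation.label}\t{r.ddg_stability:.4f}\t{r.ddg_binding:.4f}"
            f"\t{str(r.converged).lower()}\t{r.seed}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
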