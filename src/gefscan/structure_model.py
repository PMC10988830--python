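"""All-atom structure container, PDB I/O, and mutation-site neighborhoods.

The in-memory model is a light hierarchy (StructureModel -> chains ->
Residue -> AtomRecord) holding author numbering, insertion codes and
coordinates in Angstrom.  PDB files are read and written through gemmi;
alternate locations are resolved to the highest-occupancy conformer at
read time so the rest of the package never sees alt-loc ambiguity.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import chem

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "ComplexPartition",
    "ResidueId",
    "read_pdb",
    "write_pdb",
    "select_neighborhood",
    "build_all_atom_model",
]

#: residue locator: (chain_id, seq_num, insertion_code)
ResidueId = tuple[str, int, str]

_KNOWN_ELEMENTS = {"H", "C", "N", "O", "S", "P", "SE", "FE", "MG", "ZN", "MN", "CA", "NA", "CL", "K"}


@dataclass
class AtomRecord:
    """A single atom: PDB name, element symbol and position in Angstrom."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.element.upper() not in _KNOWN_ELEMENTS:
            raise ValueError(f"atom {self.name}: unrecognized element {self.element!r}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    aa3: str
    atoms: list[AtomRecord] = field(default_factory=list)
    his_tautomer: str = "NE2"  # protonated imidazole nitrogen, His only

    @property
    def aa1(self) -> str | None:
        """One-letter code, or None for a non-standard residue."""
        return chem.AA3_TO_1.get(self.aa3)

    @property
    def is_standard(self) -> bool:
        return self.aa3 in chem.AA3_TO_1

    @property
    def rid(self) -> ResidueId:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def pos(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"residue {self.chain_id}{self.seq_num}: no atom {name}")
        return a.pos

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None

    def remove_atom(self, name: str) -> None:
        self.atoms = [a for a in self.atoms if a.name != name]

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.heavy_atoms()])

    def validate(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"duplicate atom(s) {dup} in residue {self.aa3} "
                f"{self.chain_id}{self.seq_num}{self.icode}"
            )


class StructureModel:
    """An all-atom protein (complex) model keyed by author numbering."""

    def __init__(self, chains: list[tuple[str, list[Residue]]], metadata: dict | None = None):
        self.chains: list[tuple[str, list[Residue]]] = chains
        self.metadata: dict = metadata or {}
        self.prepared: bool = False
        self._index: dict[ResidueId, Residue] = {}
        self.reindex()

    def reindex(self) -> None:
        self._index = {}
        for _cid, residues in self.chains:
            for r in residues:
                if r.rid in self._index:
                    raise ValueError(f"duplicate residue id {r.rid}")
                self._index[r.rid] = r

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def residues(self) -> list[Residue]:
        return [r for _cid, rs in self.chains for r in rs]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, rs in self.chains:
            if cid == chain_id:
                return rs
        raise KeyError(f"no chain {chain_id!r}")

    def get(self, chain_id: str, seq_num: int, icode: str = "") -> Residue:
        try:
            return self._index[(chain_id, seq_num, icode)]
        except KeyError:
            raise KeyError(f"no residue {chain_id}/{seq_num}{icode}") from None

    def has(self, rid: ResidueId) -> bool:
        return rid in self._index

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa1 or "X" for r in self.chain(chain_id))

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "StructureModel":
        m = StructureModel(_copy.deepcopy(self.chains), _copy.deepcopy(self.metadata))
        m.prepared = self.prepared
        return m

    def __repr__(self) -> str:
        return (
            f"<StructureModel {len(self.chains)} chains, "
            f"{len(self.residues())} residues, {self.n_atoms} atoms>"
        )


@dataclass(frozen=True)
class ComplexPartition:
    """The two sides of a binding interface (e.g. GEF domain vs GTPase)."""

    receptor_chains: frozenset[str]
    partner_chains: frozenset[str]

    def __init__(self, receptor_chains, partner_chains):
        object.__setattr__(self, "receptor_chains", frozenset(receptor_chains))
        object.__setattr__(self, "partner_chains", frozenset(partner_chains))
        if not self.receptor_chains or not self.partner_chains:
            raise ValueError("both partition sides must be non-empty")
        if self.receptor_chains & self.partner_chains:
            raise ValueError("partition sides overlap: "
                             f"{sorted(self.receptor_chains & self.partner_chains)}")

    def validate_against(self, structure: StructureModel) -> None:
        scored = set(structure.chain_ids)
        covered = self.receptor_chains | self.partner_chains
        if covered != scored:
            raise ValueError(
                f"partition {sorted(covered)} does not cover structure chains {sorted(scored)}"
            )

    def swapped(self) -> "ComplexPartition":
        return ComplexPartition(self.partner_chains, self.receptor_chains)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, keep_hetero: bool = False) -> StructureModel:
    """Read a PDB file into a StructureModel.

    Waters and other HETATM groups are dropped unless ``keep_hetero``;
    alternate locations are resolved to the highest-occupancy conformer
    (ties broken by alphabetical alt-loc id) and the choice is recorded in
    ``metadata["altloc_resolved"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no atoms found")
    model = st[0]
    chains: list[tuple[str, list[Residue]]] = []
    altloc_log: list[str] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            is_aa = res.name in chem.AA3_TO_1
            if not is_aa:
                if res.is_water() or not keep_hetero:
                    continue
            icode = res.seqid.icode.strip()
            r = Residue(ch.name, res.seqid.num, icode, res.name)
            # group by atom name for alt-loc resolution
            by_name: dict[str, list] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                def _alt(g):
                    return g.altloc.replace("\x00", "").strip()

                if len(group) > 1 and all(not _alt(g) for g in group):
                    raise ValueError(
                        f"{path}: duplicate atom {name} in residue "
                        f"{res.name} {ch.name}{res.seqid.num}"
                    )
                best = sorted(group, key=lambda g: (-g.occ, _alt(g)))[0]
                if len(group) > 1:
                    altloc_log.append(
                        f"{ch.name}/{res.seqid.num}/{name}: kept altloc "
                        f"{_alt(best) or '.'} (occ {best.occ:.2f})"
                    )
                r.atoms.append(
                    AtomRecord(
                        name=name,
                        element=best.element.name.upper(),
                        pos=np.array([best.pos.x, best.pos.y, best.pos.z]),
                        occupancy=best.occ,
                        alt_loc="",
                    )
                )
            r.validate()
            if r.atoms:
                residues.append(r)
        if residues:
            chains.append((ch.name, residues))
    if not chains:
        raise ValueError(f"{path}: no parsable ATOM records")
    meta = {"source": path.name}
    if st.resolution:
        meta["resolution"] = st.resolution
    if altloc_log:
        meta["altloc_resolved"] = altloc_log
    return StructureModel(chains, meta)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write the model as a standard PDB file (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.name = str(structure.metadata.get("source", "gefscan"))
    model = gemmi.Model("1")
    for cid, residues in structure.chains:
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.aa3
            gr.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
            gr.het_flag = "A" if r.is_standard else "H"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occupancy
                gr.add_atom(ga)
            ch.add_residue(gr)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# neighborhoods
# ---------------------------------------------------------------------------

def select_neighborhood(
    structure: StructureModel, site: ResidueId, radius: float = 8.0
) -> list[ResidueId]:
    """All residues with any heavy atom within ``radius`` (A) of any heavy
    atom of the site residue, the site included; sorted by (chain, seq_num,
    icode).  The 8 A default is the repacking shell around a mutation.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not structure.has(site):
        raise KeyError(f"unknown site {site}")
    site_res = structure.get(*site)
    site_xyz = site_res.heavy_coords()
    out = {site}
    for r in structure.residues():
        if r.rid in out or not r.heavy_atoms():
            continue
        xyz = r.heavy_coords()
        d2 = np.sum((xyz[:, None, :] - site_xyz[None, :, :]) ** 2, axis=-1)
        if np.min(d2) <= radius * radius:
            out.add(r.rid)
    return sorted(out)


# build_all_atom_model lives in the preparation module; re-exported here so
# the structure-handling surface is importable from one place.
from .prepare import build_all_atom_model  # noqa: E402,F401
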