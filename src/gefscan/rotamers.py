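"""Compact backbone-independent rotamer library.

Each amino acid maps to a list of (chi tuple in degrees, prior probability).
The default library is a curated, deliberately small set built around the
canonical gauche-/trans/gauche+ chi preferences, ordered by decreasing
prior; it trades coverage for enumerability, which keeps the exhaustive
oracle usable in tests.  Libraries can be serialized to / loaded from JSON
(``{"L": [{"chi": [-60, 180], "p": 0.55}, ...], ...}``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import chem

__all__ = ["Rotamer", "RotamerLibrary", "default_library"]


@dataclass(frozen=True)
class Rotamer:
    chis: tuple[float, ...]
    prob: float


_DEFAULT: dict[str, list[tuple[tuple[float, ...], float]]] = {
    "A": [((), 1.0)],
    "G": [((), 1.0)],
    "S": [((-60.0,), 0.45), ((180.0,), 0.33), ((60.0,), 0.22)],
    "C": [((-60.0,), 0.52), ((180.0,), 0.31), ((60.0,), 0.17)],
    "T": [((60.0,), 0.48), ((-60.0,), 0.45), ((180.0,), 0.07)],
    "V": [((180.0,), 0.62), ((-60.0,), 0.28), ((60.0,), 0.10)],
    "P": [((23.8, 0.0), 1.0)],  # single rigid pucker; ring closes on CG-CD
    "L": [((-60.0, 180.0), 0.55), ((180.0, 60.0), 0.27),
          ((180.0, 180.0), 0.10), ((-60.0, 60.0), 0.08)],
    "I": [((-60.0, 180.0), 0.58), ((-60.0, -60.0), 0.14),
          ((180.0, 180.0), 0.15), ((60.0, 180.0), 0.13)],
    "M": [((-60.0, 180.0, 180.0), 0.28), ((-60.0, 180.0, -60.0), 0.22),
          ((-60.0, 180.0, 60.0), 0.16), ((180.0, 180.0, 180.0), 0.14),
          ((180.0, 60.0, 60.0), 0.10), ((60.0, 180.0, 180.0), 0.10)],
    "F": [((-60.0, 90.0), 0.44), ((180.0, 80.0), 0.33),
          ((60.0, 90.0), 0.13), ((-60.0, -30.0), 0.10)],
    "Y": [((-60.0, 90.0), 0.44), ((180.0, 80.0), 0.33),
          ((60.0, 90.0), 0.13), ((-60.0, -30.0), 0.10)],
    "W": [((-60.0, 100.0), 0.32), ((-60.0, -90.0), 0.26),
          ((180.0, -105.0), 0.20), ((180.0, 90.0), 0.12),
          ((60.0, -90.0), 0.10)],
    "D": [((-60.0, -20.0), 0.42), ((180.0, 10.0), 0.33),
          ((-60.0, 60.0), 0.14), ((60.0, -20.0), 0.11)],
    "N": [((-60.0, -30.0), 0.38), ((180.0, 30.0), 0.27),
          ((-60.0, 120.0), 0.16), ((60.0, -20.0), 0.11),
          ((180.0, -80.0), 0.08)],
    "H": [((-60.0, -75.0), 0.36), ((180.0, 75.0), 0.26),
          ((-60.0, 100.0), 0.20), ((60.0, -75.0), 0.18)],
    "E": [((-60.0, 180.0, -10.0), 0.32), ((180.0, 180.0, 0.0), 0.24),
          ((-60.0, -60.0, -10.0), 0.18), ((180.0, 60.0, 0.0), 0.14),
          ((60.0, 180.0, 0.0), 0.12)],
    "Q": [((-60.0, 180.0, 20.0), 0.32), ((180.0, 180.0, 0.0), 0.24),
          ((-60.0, -60.0, -40.0), 0.18), ((180.0, 60.0, 0.0), 0.14),
          ((60.0, 180.0, 20.0), 0.12)],
    "K": [((-60.0, 180.0, 180.0, 180.0), 0.30),
          ((180.0, 180.0, 180.0, 180.0), 0.22),
          ((-60.0, 180.0, 180.0, -60.0), 0.14),
          ((-60.0, 180.0, -60.0, 180.0), 0.12),
          ((180.0, 180.0, 60.0, 180.0), 0.08),
          ((-60.0, -60.0, 180.0, 180.0), 0.08),
          ((60.0, 180.0, 180.0, 180.0), 0.06)],
    "R": [((-60.0, 180.0, 180.0, 180.0), 0.26),
          ((180.0, 180.0, 180.0, 180.0), 0.20),
          ((-60.0, 180.0, -65.0, 175.0), 0.16),
          ((-60.0, 180.0, 65.0, 85.0), 0.12),
          ((180.0, 180.0, 65.0, 85.0), 0.10),
          ((-60.0, -65.0, 180.0, 180.0), 0.09),
          ((60.0, 180.0, 180.0, 180.0), 0.07)],
}


class RotamerLibrary:
    def __init__(self, table: dict[str, list[Rotamer]]):
        self.table: dict[str, list[Rotamer]] = {}
        for aa, rots in table.items():
            if aa not in chem.AA1_TO_3:
                raise ValueError(f"unknown amino acid {aa!r}")
            nchi = chem.N_CHI[aa]
            total = sum(r.prob for r in rots)
            if not rots or total <= 0:
                raise ValueError(f"{aa}: empty rotamer list")
            norm = [Rotamer(tuple(r.chis), r.prob / total) for r in rots]
            for r in norm:
                if len(r.chis) != nchi:
                    raise ValueError(
                        f"{aa}: rotamer {r.chis} has {len(r.chis)} chis, expected {nchi}"
                    )
            self.table[aa] = norm

    def rotamers(self, aa1: str) -> list[Rotamer]:
        try:
            return self.table[aa1]
        except KeyError:
            raise KeyError(f"no rotamers for amino acid {aa1!r}") from None

    def most_probable(self, aa1: str) -> Rotamer:
        return max(self.rotamers(aa1), key=lambda r: r.prob)

    def priors(self, aa1: str) -> list[float]:
        return [r.prob for r in self.rotamers(aa1)]

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            aa: [{"chi": list(r.chis), "p": r.prob} for r in rots]
            for aa, rots in self.table.items()
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RotamerLibrary":
        doc = json.loads(Path(path).read_text())
        return cls(
            {
                aa: [Rotamer(tuple(e["chi"]), float(e["p"])) for e in rots]
                for aa, rots in doc.items()
            }
        )


def default_library() -> RotamerLibrary:
    return RotamerLibrary(
        {aa: [Rotamer(c, p) for c, p in rots] for aa, rots in _DEFAULT.items()}
    )
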