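"""Variant classification, codon substitution probabilities and filtering.

The classifier applies a 3 kcal/mol threshold to the two predicted energy
changes, checking stability first: a variant with ddG_stability >= 3 is
called stability-deleterious even if its binding ddG also crosses the
threshold (a destabilized domain cannot present a competent interface);
otherwise ddG_binding >= 3 makes it binding-deleterious, and anything else
is benign.

Codon substitution probabilities can come from a generic per-site
independent 4x4 base-substitution model, or from the bundled lookup table
of published per-variant values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Classification",
    "VariantAnnotation",
    "CodonModel",
    "ReferenceVariant",
    "classify",
    "codon_probability",
    "filter_by_probability",
    "load_reference_tables",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 3.0

BASES = "ACGT"

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class Classification:
    label: str
    category: str  # stability_deleterious | binding_deleterious | benign
    ddg_stability: float
    ddg_binding: float
    threshold_kcal: float = DEFAULT_THRESHOLD

    @property
    def is_deleterious(self) -> bool:
        return self.category != "benign"


@dataclass(frozen=True)
class VariantAnnotation:
    label: str
    wt_codon: str
    mut_codon: str
    probability: float

    def __post_init__(self) -> None:
        for codon in (self.wt_codon, self.mut_codon):
            if len(codon) != 3 or any(b not in BASES for b in codon):
                raise ValueError(f"invalid codon {codon!r}")
        if not (0.0 < self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside (0, 1]")

    @property
    def base_replacement(self) -> str:
        return f"{self.wt_codon}→{self.mut_codon}"


@dataclass(frozen=True)
class ReferenceVariant:
    annotation: VariantAnnotation
    table: str  # "binding" or "stability"
    ddg_stability: float
    ddg_binding: float
    prediction: str  # printed label: Deleterious / Benign


@dataclass
class CodonModel:
    """Per-site independent base-substitution model.

    ``matrix[i, j]`` is the probability that base i is observed as base j at
    one codon position (rows sum to 1; the diagonal is the stay
    probability).  ``mode="lookup"`` consults the bundled published values
    by variant label instead.
    """

    matrix: np.ndarray = field(default_factory=lambda: CodonModel.uniform_matrix(0.01))
    mode: str = "per_site_independent"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.mode not in ("per_site_independent", "lookup"):
            raise ValueError(f"unknown codon model mode {self.mode!r}")
        if self.matrix.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("substitution probabilities must lie in [0, 1]")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("substitution matrix rows must sum to 1")

    @staticmethod
    def uniform_matrix(mu: float) -> np.ndarray:
        """Uniform single-base mutation rate mu, split evenly over the three
        alternative bases."""
        m = np.full((4, 4), mu / 3.0)
        np.fill_diagonal(m, 1.0 - mu)
        return m

    @classmethod
    def lookup(cls) -> "CodonModel":
        return cls(mode="lookup")


def classify(
    ddg_stability: float,
    ddg_binding: float,
    threshold: float = DEFAULT_THRESHOLD,
    label: str = "",
) -> Classification:
    """Threshold rule on the (stability, binding) ddG pair; stability is
    checked first so a variant crossing both thresholds is reported as a
    stability mutant."""
    if not (math.isfinite(ddg_stability) and math.isfinite(ddg_binding)):
        raise ValueError("ddG inputs must be finite")
    if ddg_stability >= threshold:
        category = "stability_deleterious"
    elif ddg_binding >= threshold:
        category = "binding_deleterious"
    else:
        category = "benign"
    return Classification(label, category, ddg_stability, ddg_binding, threshold)


def codon_probability(wt_codon: str, mut_codon: str, model: CodonModel | None = None) -> float:
    """Probability of observing ``mut_codon`` given ``wt_codon``.

    In per-site mode the three positions are independent, so the result is
    the product of the per-position matrix entries.  In lookup mode the
    bundled published value for the matching variant is returned.
    """
    model = model or CodonModel()
    for codon in (wt_codon, mut_codon):
        if len(codon) != 3 or any(b not in BASES for b in codon):
            raise ValueError(f"invalid codon {codon!r}")
    if model.mode == "lookup":
        for rv in load_reference_tables():
            ann = rv.annotation
            if ann.wt_codon == wt_codon and ann.mut_codon == mut_codon:
                return ann.probability
        raise KeyError(f"no published probability for {wt_codon}→{mut_codon}")
    p = 1.0
    for bw, bm in zip(wt_codon, mut_codon):
        p *= float(model.matrix[BASES.index(bw), BASES.index(bm)])
    return p


def lookup_probability(label: str) -> float:
    """Published codon substitution probability for a bundled variant label."""
    for rv in load_reference_tables():
        if rv.annotation.label == label:
            return rv.annotation.probability
    raise KeyError(f"no published probability for variant {label!r}")


def filter_by_probability(
    annotations: list[VariantAnnotation], min_p: float
) -> list[VariantAnnotation]:
    """Keep annotations with probability strictly greater than ``min_p``;
    input order is preserved."""
    if not (0.0 < min_p <= 1.0):
        raise ValueError("min_p must lie in (0, 1]")
    return [a for a in annotations if a.probability > min_p]


def load_reference_tables() -> list[ReferenceVariant]:
    """The bundled 10-variant reference table (5 interface rows, 5 domain
    rows), sanity-checked: codons must translate to the variant's amino
    acids and the threshold rule must reproduce every printed prediction."""
    text = resources.files("gefscan.data").joinpath("reference_variants.tsv").read_text()
    rows: list[ReferenceVariant] = []
    header: list[str] | None = None
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        if header is None:
            header = ln.split("\t")
            continue
        rec = dict(zip(header, ln.split("\t")))
        ann = VariantAnnotation(
            label=rec["label"],
            wt_codon=rec["wt_codon"],
            mut_codon=rec["mut_codon"],
            probability=float(rec["probability"]),
        )
        wt_aa, mut_aa = rec["label"][0], rec["label"][-1]
        if CODON_TABLE[ann.wt_codon] != wt_aa or CODON_TABLE[ann.mut_codon] != mut_aa:
            raise ValueError(f"reference data corrupt: codons of {ann.label} do not translate")
        rv = ReferenceVariant(
            annotation=ann,
            table=rec["table"],
            ddg_stability=float(rec["ddg_stability"]),
            ddg_binding=float(rec["ddg_binding"]),
            prediction=rec["prediction"],
        )
        got = classify(rv.ddg_stability, rv.ddg_binding).is_deleterious
        want = rv.prediction == "Deleterious"
        if got != want:
            raise ValueError(f"reference data corrupt: {ann.label} classification mismatch")
        rows.append(rv)
    if len(rows) != 10:
        raise ValueError(f"reference data corrupt: expected 10 variants, found {len(rows)}")
    return rows
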