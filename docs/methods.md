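# Methods

## Scope and model

`gefscan` estimates the effect of a point substitution on (i) fold
stability and (ii) partner binding of a two-chain protein complex, and
turns the two numbers into a deleterious/benign call. The method follows
the standard empirical-ΔΔG recipe: build the mutant side chain on the
fixed backbone, re-optimize all side chains in a shell around the site,
and difference the resulting free energies against an identically treated
wild-type baseline.

The published force fields behind this family of protocols are
proprietary; the energy function here is the package's own documented
parameterization, built from standard terms. Consequently no numeric
agreement with any published per-variant ΔΔG table is claimed or tested —
the published values ship only as reference data for the classification
and bookkeeping stages, which are exact.

## Energy function

All terms are heavy-atom, pairwise-decomposable, in kcal/mol:

* **van der Waals** — 6–12 Lennard-Jones with per-element Rmin/2 and well
  depth (C 1.95/0.12, N 1.75/0.16, O 1.70/0.20, S 2.00/0.25),
  Lorentz–Berthelot mixing, hard cutoff 9 Å. Below 0.6·Rmin the potential
  continues linearly with the slope at the switch point, so clashes are
  finite, monotone and optimizable. Interatomic distances are clamped at
  0.05 Å so even coincident atoms score a large finite repulsion.
* **Hydrogen bonds** — geometric term on donor/acceptor heavy atoms: full
  strength (−1.5) at D···A ≤ 3.0 Å fading linearly to zero at 3.5 Å,
  gated by ≥ 90° angles at both the donor and the acceptor (measured
  against each atom's covalent antecedent). Explicit hydrogens are placed
  during preparation but are *not* scored; the heavy-atom angular
  criterion makes the term insensitive to proton placement and usable
  before hydrogens exist (needed when scoring amide flips).
* **Electrostatics** — Coulomb with distance-dependent dielectric
  ε(r) = 4r between formally charged groups only (Asp/Glu carboxylates
  −0.5 per O, Lys NZ +1, Arg NH1/NH2 +0.5).
* **Solvation** — pairwise Gaussian-exclusion desolvation
  (Lazaridis–Karplus form) with per-element ΔG_free and volumes
  (hydrophobic C/S positive: burial rewarded; polar N/O negative: burial
  penalized), correlation length 3.5 Å. A surface-area term was
  considered and rejected: SASA is not pairwise-decomposable, and the
  module contract requires that a scoped evaluation equal the subset's
  interaction energy with everything and that rigid binding energies
  reduce exactly to the cross-partition pair sum. The pairwise form keeps
  those identities exact.
* **Torsional strain** — a small three-fold penalty k(1 + cos 3χ),
  k = 0.25, per side-chain rotatable bond.

Bonded exclusions: 1-2 and 1-3 pairs skipped, 1-4 scaled by 0.5. Bond
topology comes from the residue templates (including ring-closure bonds
and the proline CD–N bond), never from distances, so a clashing rotamer
cannot silently "bond" to its neighbor. Weights, radii, cutoffs and the
reference table are all data on the `EnergyModel` (JSON-serializable,
schema-versioned), so recalibration never touches code.

## Unfolded-state reference

The unfolded chain's free energy is modeled as a sum of per-residue
reference energies; in the stability difference all terms except the
mutated residue's cancel, which the implementation exploits analytically
(a single-entry swap, verified in tests against the naive full-sequence
sums). The bundled table was calibrated once, by construction rather than
fitting: the entry for residue X is X's scoped energy at the midpoint of
an ideal 9-residue poly-Ala helix, minimized over library rotamers. This
anchors the scale so that a fully solvent-exposed substitution on a helix
surface has ΔΔG_stability ≈ 0 (observed |ΔΔG| ≤ 0.04 kcal/mol on a
12-residue helix). The table is regenerated by
`gefscan.energy.calibrate_unfolded_reference` and shipped as versioned
data (`data/unfolded_reference.json`).

## Side-chain construction and preparation

Side chains are built from idealized internal coordinates (NeRF) on the
existing backbone frame; rings close to within a few hundredths of an
Ångström, adequate for this scoring function. Proline is special-cased:
CD is placed off the backbone nitrogen with internal coordinates measured
from the reference pyrrolidine geometry, so the ring closes by
construction, and it carries a single rigid pucker in the rotamer library.

Preparation (`build_all_atom_model`) validates backbones, rebuilds any
incomplete side chain from its most probable rotamer (flagged in
metadata), tests Asn/Gln amide and His imidazole orientations in both
flip states — applied as rigid 180° rotations that preserve the deposited
bond geometry — keeping the state with the lower local vdW + H-bond
energy (ties keep the incoming orientation, which makes preparation
idempotent), and finally places polar hydrogens by ideal geometry
(backbone amides, hydroxyls/thiols, amide NH2, Trp NE1, the chosen His
tautomer; charged amines are treated implicitly by the heavy-atom H-bond
criterion). Alternate locations are resolved at read time to the
highest-occupancy conformer, ties broken alphabetically. Waters and other
hetero groups are excluded by default; a flag retains them as rigid,
internally unscored background.

## Rotamer library and sampling

The backbone-independent library is deliberately compact: curated chi
combinations around the canonical gauche/trans wells with plausible
priors (1–7 rotamers per residue type), normalized to sum to one. The
choice trades coverage for enumerability — every repacking problem used
in validation can also be solved exactly by exhaustive enumeration, which
keeps the Monte-Carlo sampler falsifiable against a true global optimum.

`repack` is Metropolis Monte Carlo in which a move picks a flexible
residue uniformly and proposes one of its rotamers with probability
proportional to the library prior (the "biased probability" scheme);
proposals are scored incrementally through the scoped energy. Defaults:
2000 proposals per flexible residue, reduced temperature annealed
geometrically from 3.0 to 0.3, convergence declared when the best energy
fails to improve by 0.01 kcal/mol over 500 consecutive steps (the run
then stops early; all randomness flows from one integer seed, and equal
-energy ties resolve to the first state visited). The sampler returns the
best state visited, re-evaluated by a full energy call so the reported
energy is exactly the returned structure's energy. Chi angles move only
on the rotamer grid — no continuous minimization — which is what makes
the enumeration oracle exact; continuous refinement would be an
extension, not a default.

`enumerate_rotamers` uses the standard self/pair energy-table
decomposition, enumerates the full product (bounded, default 10⁶), and
returns the reconstructed optimum scored by a direct energy call.

## ΔΔG protocol

For each mutation: the 8 Å heavy-atom neighborhood of the site defines
the flexible shell. Both the wild-type baseline and the mutant are first
*canonicalized* — every flexible side chain set to its most probable
rotamer — then repacked with the same seed. Canonicalizing the wild type
(rather than keeping crystal side chains) removes crystal-contact bias,
makes the comparison symmetric, and gives identity mutations a bitwise
identical pipeline on both sides, hence ΔΔG ≡ 0 exactly. Stability is
evaluated on the full complex by default (`stability_scope="receptor"`
restricts it to one side). Binding energy defaults to rigid unbound
states — the separated partners keep their bound-state conformations, so
ΔG_binding reduces exactly to the cross-partition interaction energy; a
`repack_unbound` flag instead repacks the former interface residues of
each separated partner first. Scans derive one seed per mutation from the
run seed and the mutation label (CRC32), so a scan reproduces
single-mutation calls exactly and parallelizes trivially.

Sign conventions: positive ΔΔG is destabilizing / binding-disruptive;
a favorable binding energy is negative (G(AB) − G(A) − G(B)).

## Classification, codon probabilities, evaluation

The classifier applies the 3 kcal/mol threshold with stability checked
first. The precedence matters for exactly one bundled variant (G1453W,
above threshold on both axes), which is thereby reported as a stability
mutant, matching its published label; the prose selection heuristic
("high on one axis, < 3 on the other") was a screening rule, not a
classifier, and that variant itself violates it. The threshold is
inclusive (≥ 3); the boundary is not exercised by the reference panel.

Codon substitution probabilities: the published per-variant values ship
as a lookup table (their upstream rate model is not recoverable), and a
generic per-site-independent 4×4 base-substitution model (rows sum to 1,
probability of a codon change = product over the three positions) is
provided for new variants with user-supplied rates. The accessibility
filter keeps variants with P strictly greater than the cutoff
(default 3 × 10⁻⁴).

Evaluation counts a predicted-deleterious variant as confirmed when the
experimental outcome is loss-of-function *or* dominant-negative — a
dominant negative is a stronger-than-predicted disruption, not a miss —
and a predicted-benign variant as confirmed by a WT-like outcome. On the
bundled 10-variant panel this yields 6/8 = 75% deleterious success and
8/10 = 80% overall accuracy. Orthogonal assay outcomes (co-IP, FRET) are
not part of the headline numbers.

## Synthetic systems and what they do (and do not) show

All validation runs on ideal-geometry structures generated in code:

* **toy dimer** — two Gly-Leu-Gly strands whose leucine tips meet head-on
  at the Lennard-Jones optimum; under the fixture's vdW-only model the
  designed CD1–CD1 pair is the only scored cross-chain contact, so the
  binding energy has a closed form. The leucines are built at their
  intra-chain optimal rotamer so repacking preserves the design.
* **rotamer puzzle** — facing serines whose hydroxyls H-bond only in one
  specific rotamer pair: the greedy per-residue choice misses it, the
  joint optimum finds it, and generation fails rather than emit a puzzle
  without genuine coupling.
* **surface helix** — ideal poly-Ala α-helix; mid-chain side chains are
  fully exposed, giving the near-zero surface-mutation control.

These systems exercise the machinery (exactness, oracle agreement,
antisymmetry, locality, determinism) at desk scale. They do not emulate
real protein environments — no buried polar networks, no waters, no
backbone relaxation — so passing tests demonstrates correctness of the
implementation, not predictive accuracy on real variants; the latter is
represented only by the bundled reference panel and its outcome labels.

Problem sizes were chosen so the full suite and the acceptance script
each run in about a minute on one CPU: helices of 8–12 residues, dimers
of 6, puzzles of 2–3 flexible residues (9–27 combinations against the
exact oracle).

## Numerical choices and degenerate inputs

Energies are float64 throughout; term totals are exact weighted sums
(checked to 1e-9). Identity mutations short-circuit to exactly 0 after an
internal consistency assertion (< 1e-9). Empty flexible sets return the
input unchanged and converged. Duplicate atoms in a residue are a hard
error naming the residue; missing backbone atoms and unknown residue
types are hard errors (the latter downgradable to "keep as rigid
background"). The pipeline stages outputs in a temporary directory and
moves them into place only on success, so a failed run never overwrites a
previous one.

## Known limitations

Backbone is rigid everywhere (limited backbone adjustment is plausible
future work). The rotamer library is coarse; grid-only chi angles bias
against tightly packed native-like minima. The charge model ignores His
protonation charge states and termini. The solvation term is a burial
model, not a surface model, so cavity and shape effects are approximate.
Binding with `repack_unbound=True` repacks only former-interface side
chains, not the rest of the unbound chains. Numbering between a protein
reference sequence and a deposited structure is supplied by the user
(`numbering_offset` in the pipeline config); the package does not attempt
to infer it.
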