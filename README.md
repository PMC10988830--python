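# gefscan

Structure-based prediction and triage of missense variants at
protein–protein interfaces.

Rare missense variants in interface-forming domains — the motivating case
is the catalytic GEF1/DH1 domain of TRIO, which binds and activates the
small GTPase RAC1 — are hard to interpret from sequence alone: a variant
can break function by destabilizing the domain fold or by disrupting
partner binding, and the two mechanisms call for different follow-up
experiments. `gefscan` takes an all-atom structure of a two-partner
complex and a list of candidate substitutions and, for each one, estimates
both free-energy changes, classifies the variant, annotates how likely the
underlying codon change is, and scores a panel of predictions against
experimental outcome labels. It is aimed at structural bioinformaticians
and variant-curation groups who want a transparent, fully reproducible
energy-based triage step next to sequence-based predictors.

## Model

For a mutation at one site, with side chains within 8 Å of the site
re-optimized by biased-probability Monte Carlo over a rotamer library:

```
ΔΔG_stability = (ΔG_folded^mut − ΔG_unfolded^mut) − (ΔG_folded^WT − ΔG_unfolded^WT)
ΔΔG_binding   = ΔG_binding^mut − ΔG_binding^WT,   ΔG_binding = G(AB) − G(A) − G(B)
```

Positive values are destabilizing / binding-disruptive. The unfolded-state
free energy is a sum of residue-specific reference energies, so in
`ΔΔG_stability` every term except the mutated residue's cancels
analytically. The folded-state energy is an empirical all-atom function
(capped 6–12 van der Waals, geometric hydrogen bonds, screened Coulomb,
pairwise desolvation, rotamer strain); see `docs/methods.md` for the exact
terms, parameters, and their rationale.

Variants are classified with a 3 kcal/mol threshold, stability checked
first: `ΔΔG_stability ≥ 3` → stability-deleterious, else
`ΔΔG_binding ≥ 3` → binding-deleterious, else benign. A per-site codon
substitution model (or a bundled table of published per-variant values)
supplies the probability filter `P > 0.0003` used to restrict attention to
mutationally accessible variants.

## Worked example

Everything below runs on synthetic structures generated by the package —
no downloads. Build a toy two-chain complex with a single designed
leucine–leucine contact, then score the mutation that removes it:

```
$ gefscan fixtures make --kind toy_dimer --seed 7 --out dimer.pdb
$ printf 'chain\tpos\twt\tmut\nA\t2\tL\tG\n' > muts.tsv
$ cat > config.json <<EOF
{"structure": "dimer.pdb", "mutations": "muts.tsv",
 "receptor_chains": ["A"], "partner_chains": ["B"], "seed": 4}
EOF
$ gefscan run --config config.json --outdir out
$ cat out/results.tsv
label   ddg_stability   ddg_binding     converged       seed
L2G     -29.4733        0.4224  true    1901921656
```

Under the fixture's own vdW-only scoring model the binding change is
exactly +0.12 kcal/mol — the negated energy of the one designed contact —
which the test suite checks against a hand-computed closed form; under the
full default energy function shown here, burying and unburying polar atoms
contributes too. The classification and accuracy stages reproduce the
published 10-variant reference panel:

```
$ gefscan eval
{
 "n_deleterious_predicted": 8,
 "n_deleterious_confirmed": 6,
 "deleterious_success_rate": 0.75,
 "n_total": 10,
 "n_correct": 8,
 "overall_accuracy": 0.8
}
```

i.e. 6 of 8 variants predicted deleterious were confirmed by paired-neuron
electrophysiology (75%), and 8 of 10 calls were correct overall (80%).
Codon probabilities come from the bundled published values or a generic
per-site model:

```
$ gefscan codon --wt-codon GAG --mut-codon TGG --lookup
0.00037
```

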