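"""Stability and binding ddG: exactness, oracles, locality, scans."""

import numpy as np
import pytest

from gefscan.conformational_sampler import SamplerConfig
from gefscan.ddg_engine import (
    MutationSpec,
    compute_ddg,
    ddg_binding,
    ddg_stability,
    derive_seed,
    read_mutations_tsv,
    scan,
    write_results_tsv,
    _packed_states,
)
from gefscan.energy import folded_energy, unfolded_energy

CFG = SamplerConfig(seed=17)


class TestStability:
    def test_identity_mutation_exactly_zero(self, helix12, default_model):
        r = compute_ddg(helix12, None, MutationSpec("A", 6, "A", "A"), default_model, CFG)
        assert r.ddg_stability == 0.0
        assert r.ddg_binding == 0.0

    def test_surface_substitutions_near_neutral(self, helix12, default_model):
        # the unfolded reference is anchored so that solvent-exposed helix
        # substitutions are close to zero
        for aa in ("S", "L", "G"):
            v = ddg_stability(helix12, MutationSpec("A", 6, "A", aa), default_model, CFG)
            assert abs(v) < 0.5

    def test_unrelievable_buried_clash_is_destabilizing(self, buried_site, default_model):
        v = ddg_stability(buried_site, MutationSpec("A", 6, "A", "W"), default_model, CFG)
        assert v > 3.0

    def test_wt_mismatch_reports_expected_and_found(self, helix12, default_model):
        with pytest.raises(ValueError, match="expected"):
            ddg_stability(helix12, MutationSpec("A", 6, "W", "G"), default_model, CFG)

    def test_forward_backward_antisymmetry(self, helix12, default_model):
        for aa in ("L", "S"):
            spec = MutationSpec("A", 6, "A", aa)
            fwd = ddg_stability(helix12, spec, default_model, CFG)
            _wt, mut_pack = _packed_states(helix12, spec, default_model, CFG)
            back = MutationSpec("A", 6, aa, "A")
            bwd = ddg_stability(mut_pack.structure, back, default_model, CFG)
            assert abs(fwd + bwd) <= 0.5

    def test_single_entry_swap_matches_naive_full_sum(self, helix12, default_model):
        # Eq.-level check: the analytic single-residue reference swap equals
        # the difference of full unfolded-chain sums over both sequences
        spec = MutationSpec("A", 6, "A", "W")
        _wt, mut_pack = _packed_states(helix12, spec, default_model, CFG)
        wt_pack, _ = _packed_states(helix12, spec, default_model, CFG)
        seq_wt = helix12.sequence("A")
        seq_mut = seq_wt[:5] + "W" + seq_wt[6:]
        naive = (
            folded_energy(mut_pack.structure, default_model).total
            - unfolded_energy(seq_mut, default_model)
        ) - (
            folded_energy(wt_pack.structure, default_model).total
            - unfolded_energy(seq_wt, default_model)
        )
        fast = ddg_stability(helix12, spec, default_model, CFG)
        assert fast == pytest.approx(naive, abs=1e-6)

    def test_breakdown_consistency(self, helix12, default_model):
        spec = MutationSpec("A", 6, "A", "L")
        r = compute_ddg(helix12, None, spec, default_model, CFG)
        ref = default_model.unfolded_reference
        recomputed = (r.breakdown_mut.total - ref["L"]) - (r.breakdown_wt.total - ref["A"])
        assert r.ddg_stability == pytest.approx(recomputed, abs=1e-6)

    def test_bit_reproducible(self, helix12, default_model):
        spec = MutationSpec("A", 6, "A", "L")
        a = compute_ddg(helix12, None, spec, default_model, CFG)
        b = compute_ddg(helix12, None, spec, default_model, CFG)
        assert a.ddg_stability == b.ddg_stability
        assert a.breakdown_mut.terms == b.breakdown_mut.terms


class TestBinding:
    def test_removing_the_only_contact(self, dimer):
        # Leu -> Gly removes the single designed cross-chain contact, so the
        # binding ddG equals the negated WT cross-pair energy (-(-eps))
        eps = dimer.model.vdw_params["C"][1]
        v = ddg_binding(dimer.structure, dimer.partition,
                        MutationSpec("A", 2, "L", "G"), dimer.model, CFG)
        assert v == pytest.approx(eps, abs=1e-3)

    def test_mutation_far_from_interface_is_local(self, dimer):
        v = ddg_binding(dimer.structure, dimer.partition,
                        MutationSpec("A", 1, "G", "S"), dimer.model, CFG)
        assert abs(v) <= 0.1

    def test_identity_zero(self, dimer):
        v = ddg_binding(dimer.structure, dimer.partition,
                        MutationSpec("B", 2, "L", "L"), dimer.model, CFG)
        assert v == 0.0


class TestScan:
    def test_counting_skips_identities(self, dimer):
        results = scan(
            dimer.structure, dimer.partition,
            [("A", 2, ""), ("B", 2, "")], ["L", "G"],
            dimer.model, SamplerConfig(seed=23, n_steps=150),
        )
        # 2 sites x 2 targets with both sites Leu -> 2 identities skipped
        assert len(results) == 2
        labels = [r.mutation.label for r in results]
        assert labels == sorted(labels)

    def test_scan_reproduces_single_calls(self, dimer):
        cfg = SamplerConfig(seed=23, n_steps=150)
        results = scan(dimer.structure, dimer.partition, [("A", 2, "")], ["G"],
                       dimer.model, cfg)
        single_cfg = SamplerConfig(seed=derive_seed(23, "L2G"), n_steps=150)
        single = compute_ddg(dimer.structure, dimer.partition,
                             MutationSpec("A", 2, "L", "G"), dimer.model, single_cfg)
        assert results[0].ddg_binding == single.ddg_binding
        assert results[0].ddg_stability == single.ddg_stability

    def test_empty_inputs_rejected(self, dimer):
        with pytest.raises(ValueError):
            scan(dimer.structure, dimer.partition, [], ["G"], dimer.model)
        with pytest.raises(ValueError):
            scan(dimer.structure, dimer.partition, [("A", 2, "")], [], dimer.model)


def test_mutation_tsv_roundtrip(tmp_path):
    p = tmp_path / "muts.tsv"
    p.write_text("chain\tpos\twt\tmut\twt_codon\tmut_codon\nA\t2\tL\tG\tCTG\tGGG\nB\t2\tL\tW\n")
    specs = read_mutations_tsv(p)
    assert [s.label for s in specs] == ["L2G", "L2W"]
    assert specs[0].wt_codon == "CTG"
    assert specs[1].wt_codon is None


def test_results_tsv_format(tmp_path, dimer):
    r = compute_ddg(dimer.structure, dimer.partition,
                    MutationSpec("A", 2, "L", "G"), dimer.model,
                    SamplerConfig(seed=3, n_steps=100))
    out = tmp_path / "res.tsv"
    write_results_tsv([r], out)
    lines = out.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["label", "ddg_stability", "ddg_binding", "converged", "seed"]
    assert lines[1].startswith("L2G\t")
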