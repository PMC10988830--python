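"""Mutation construction and Monte-Carlo repacking vs the exact oracle."""

import numpy as np
import pytest

from gefscan import chem
from gefscan.builder import build_peptide
from gefscan.conformational_sampler import (
    SamplerConfig,
    enumerate_rotamers,
    mutate_residue,
    repack,
)
from gefscan.energy import EnergyModel, folded_energy
from gefscan.fixtures import make_rotamer_puzzle
from gefscan.prepare import build_all_atom_model
from gefscan.rotamers import default_library


def _heavy_names(res):
    return sorted(a.name for a in res.atoms if a.element != "H")


class TestMutateResidue:
    def test_identity_keeps_backbone_reidealizes_side_chain(self, helix12):
        mut = mutate_residue(helix12, ("A", 6, ""), "A")
        for name in chem.BACKBONE_ATOMS:
            assert np.array_equal(helix12.get("A", 6).pos(name), mut.get("A", 6).pos(name))
        assert _heavy_names(mut.get("A", 6)) == sorted(chem.heavy_atom_names("A"))

    def test_to_glycine_strips_side_chain(self, helix12):
        mut = mutate_residue(helix12, ("A", 6, ""), "G")
        assert _heavy_names(mut.get("A", 6)) == sorted(chem.heavy_atom_names("G"))
        assert not mut.get("A", 6).has_atom("CB")

    def test_ala_to_trp_atom_bookkeeping(self, helix12):
        n_before = len(helix12.get("A", 6).heavy_atoms())
        mut = mutate_residue(helix12, ("A", 6, ""), "W")
        n_after = len(mut.get("A", 6).heavy_atoms())
        expected_delta = len(chem.heavy_atom_names("W")) - len(chem.heavy_atom_names("A"))
        assert n_after - n_before == expected_delta
        assert mut.get("A", 6).aa3 == "TRP"

    def test_unknown_site_and_amino_acid(self, helix12):
        with pytest.raises(KeyError):
            mutate_residue(helix12, ("A", 99, ""), "W")
        with pytest.raises(ValueError):
            mutate_residue(helix12, ("A", 6, ""), "Z")

    def test_original_structure_untouched(self, helix12):
        before = [a.pos.copy() for a in helix12.get("A", 6).atoms]
        mutate_residue(helix12, ("A", 6, ""), "W")
        after = [a.pos for a in helix12.get("A", 6).atoms]
        assert all(np.array_equal(b, a) for b, a in zip(before, after))


class TestRepack:
    def test_empty_flexible_set_is_identity(self, helix12, default_model):
        res = repack(helix12, [], default_model, SamplerConfig(seed=1))
        assert res.converged
        assert res.accepted_moves == 0
        assert res.energy == pytest.approx(
            folded_energy(helix12, default_model).total, abs=1e-9
        )

    def test_matches_exhaustive_oracle(self, puzzle):
        res = repack(puzzle.structure, puzzle.flexible, puzzle.model, SamplerConfig(seed=2))
        assert res.energy <= puzzle.greedy_energy
        assert abs(res.energy - puzzle.optimum_energy) <= SamplerConfig().convergence_tol_kcal

    def test_oracle_never_above_repack(self, puzzle):
        for seed in (0, 1, 2):
            res = repack(puzzle.structure, puzzle.flexible, puzzle.model,
                         SamplerConfig(seed=seed))
            assert puzzle.optimum_energy <= res.energy + 1e-9

    def test_same_seed_bitwise_identical(self, puzzle):
        r1 = repack(puzzle.structure, puzzle.flexible, puzzle.model, SamplerConfig(seed=5))
        r2 = repack(puzzle.structure, puzzle.flexible, puzzle.model, SamplerConfig(seed=5))
        assert r1.energy == r2.energy
        assert r1.accepted_moves == r2.accepted_moves
        for ra, rb in zip(r1.structure.residues(), r2.structure.residues()):
            for a, b in zip(ra.atoms, rb.atoms):
                assert np.array_equal(a.pos, b.pos)

    def test_different_seeds_agree_within_tolerance(self, puzzle):
        energies = [
            repack(puzzle.structure, puzzle.flexible, puzzle.model,
                   SamplerConfig(seed=s)).energy
            for s in (3, 11, 42)
        ]
        spread = max(energies) - min(energies)
        assert spread <= SamplerConfig().convergence_tol_kcal

    def test_backbone_bit_identical(self, puzzle):
        res = repack(puzzle.structure, puzzle.flexible, puzzle.model, SamplerConfig(seed=9))
        for before, after in zip(puzzle.structure.residues(), res.structure.residues()):
            for name in chem.BACKBONE_ATOMS:
                assert np.array_equal(before.pos(name), after.pos(name))

    def test_result_energy_consistent_with_folded_energy(self, puzzle):
        res = repack(puzzle.structure, puzzle.flexible, puzzle.model, SamplerConfig(seed=4))
        assert res.energy == pytest.approx(
            folded_energy(res.structure, puzzle.model).total, abs=1e-6
        )

    def test_accepted_moves_bounded_by_steps(self, puzzle):
        res = repack(puzzle.structure, puzzle.flexible, puzzle.model,
                     SamplerConfig(seed=1, n_steps=200))
        assert res.accepted_moves <= res.n_steps <= 200

    def test_prior_bias_under_flat_energy(self):
        # with all weights zero every proposal is accepted, so rotamer visit
        # frequencies must follow the library priors
        from scipy.stats import chisquare

        st = build_all_atom_model(build_peptide("S", conformation="extended"))
        flat = EnergyModel()
        flat.weights = {t: 0.0 for t in flat.weights}
        cfg = SamplerConfig(seed=13, n_steps=4000, convergence_window=10**9, log_moves=True)
        res = repack(st, [("A", 1, "")], flat, cfg)
        lib = default_library()
        priors = np.array(lib.priors("S"))
        counts = np.zeros(len(priors))
        for _rid, k in res.moves:
            counts[k] += 1
        _stat, p = chisquare(counts, priors * counts.sum())
        assert p > 1e-3


class TestEnumerateRotamers:
    def test_single_residue_is_argmin(self, default_model):
        from gefscan.builder import build_side_chain

        st = build_all_atom_model(build_peptide("GSG", conformation="helix"))
        lib = default_library()
        best_direct = np.inf
        for rot in lib.rotamers("S"):
            work = st.copy()
            build_side_chain(work.get("A", 2), "S", rot.chis)
            work.prepared = True
            best_direct = min(best_direct, folded_energy(work, default_model).total)
        _st_opt, e_opt = enumerate_rotamers(st, [("A", 2, "")], default_model, lib)
        assert e_opt == pytest.approx(best_direct, abs=1e-9)

    def test_combinatorial_bound_enforced(self, puzzle):
        with pytest.raises(ValueError, match="bound"):
            enumerate_rotamers(
                puzzle.structure, puzzle.flexible, puzzle.model, max_combinations=2
            )

    def test_coupled_puzzle_beats_greedy(self, puzzle):
        assert puzzle.optimum_assignment != puzzle.greedy_assignment
        assert puzzle.greedy_energy > puzzle.optimum_energy + 0.05

    def test_uncoupled_puzzle_greedy_is_optimal(self):
        p = make_rotamer_puzzle(2, "none")
        assert p.optimum_assignment == p.greedy_assignment
        assert p.greedy_energy == pytest.approx(p.optimum_energy, abs=1e-9)
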