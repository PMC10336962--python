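"""Bead-necklace Monte Carlo: potentials, moves, sampling, diagnostics."""

import math

import numpy as np
import pytest

from idpbench.bead_necklace import (
    MonteCarloEngine,
    SimulationConfig,
    bond_energy,
    bond_force_constant_kT,
    convergence_report,
    counterion_rdf,
    debye_parameters,
    pair_energy,
    radius_of_gyration,
    run_simulation,
    statistical_inefficiency,
    total_energy,
    _min_image,
)
from idpbench.synthetic import harmonic_bond_moment


class TestDebyeParameters:
    def test_zero_salt_means_zero_kappa(self):
        _, kappa = debye_parameters(0.0)
        assert kappa == 0.0

    def test_bjerrum_length_in_water_at_room_temperature(self):
        bjerrum, _ = debye_parameters(0.0, 298.0, 78.4)
        assert bjerrum == pytest.approx(7.15, abs=0.05)

    def test_debye_length_at_physiological_salt(self):
        _, kappa = debye_parameters(150.0, 298.0, 78.4)
        assert 1.0 / kappa == pytest.approx(7.85, abs=0.1)

    def test_nonphysical_permittivity_rejected(self):
        with pytest.raises(ValueError):
            debye_parameters(100.0, relative_permittivity=-1.0)


class TestPairEnergy:
    def test_neutral_ion_pair_is_zero(self):
        cfg = SimulationConfig()
        assert pair_energy("ion-ion", 0, 0, 6.0, cfg) == 0.0

    def test_chain_contact_attraction_depth(self):
        # the uniform short-range well is -0.6 kT at closest contact (4 A)
        cfg = SimulationConfig()
        assert pair_energy("chain-chain", 0, 0, 4.0, cfg) == pytest.approx(-0.6)

    def test_overlap_flag(self):
        cfg = SimulationConfig()
        assert math.isinf(pair_energy("chain-chain", 0, 0, 3.9, cfg))

    def test_reduces_to_bare_coulomb_without_screening_or_size(self):
        cfg = SimulationConfig(salt_mM=0.0, bead_radius=1e-9, ion_radius=1e-9,
                               attraction_contact=0.0)
        bjerrum, _ = debye_parameters(0.0, cfg.temperature_K, cfg.relative_permittivity)
        r = 10.0
        assert pair_energy("ion-ion", 1, 1, r, cfg) == pytest.approx(bjerrum / r, rel=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            pair_energy("bead-bead", 0, 0, 5.0, SimulationConfig())


class TestBondEnergy:
    def test_zero_at_equilibrium_and_symmetric(self):
        cfg = SimulationConfig()
        assert bond_energy(4.1, cfg) == 0.0
        assert bond_energy(4.6, cfg) == pytest.approx(bond_energy(3.6, cfg))

    def test_force_constant_conversion(self):
        # 0.4 N/m is about 0.97 kT/A^2 at 298 K
        assert bond_force_constant_kT(0.4, 298.0) == pytest.approx(0.972, abs=0.002)

    def test_one_angstrom_stretch(self):
        cfg = SimulationConfig()
        assert bond_energy(5.1, cfg) == pytest.approx(0.486, abs=0.002)


@pytest.fixture(scope="module")
def charged_engine():
    cfg = SimulationConfig(salt_mM=50.0, n_equil_cycles=0, n_prod_cycles=0, seed=5)
    return MonteCarloEngine([1, 0, -1, 0] * 5, cfg)


class TestEnergyBookkeeping:
    def test_total_energy_matches_brute_force_double_loop(self, charged_engine):
        """Independent O(N^2) re-summation of every pair and bond term."""
        eng = charged_engine
        cfg = eng.config
        state = eng.snapshot()
        u = 0.0
        coords = np.vstack([state.chain_coords, state.counterion_coords])
        charges = np.concatenate([state.per_bead_charge, state.counterion_charges])
        n = state.n_beads
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                d = _min_image(coords[i] - coords[j], eng.box)
                r = float(np.linalg.norm(d))
                if i < n and j < n:
                    kind = "chain-chain"
                elif i >= n and j >= n:
                    kind = "ion-ion"
                else:
                    kind = "chain-ion"
                u += pair_energy(kind, int(charges[i]), int(charges[j]), r, cfg)
        for i in range(n - 1):
            u += bond_energy(float(np.linalg.norm(coords[i + 1] - coords[i])), cfg)
        assert total_energy(state, cfg) == pytest.approx(u, abs=1e-8)
        assert eng.full_energy() == pytest.approx(u, abs=1e-8)

    def test_incremental_du_matches_full_recomputation(self, charged_engine):
        """100 random proposals: incremental dU vs before/after full energies."""
        eng = charged_engine
        checked = 0
        while checked < 100:
            move = eng._move_names[int(eng.rng.integers(len(eng._move_names)))]
            kind, payload, du, _ = eng.propose_move(move)
            if kind == "noop":
                continue
            before = eng.full_energy()
            old = eng.coords.copy()
            eng._apply(kind, payload)
            after = eng.full_energy()
            eng.coords = old
            if math.isfinite(du):
                assert after - before == pytest.approx(du, abs=1e-8)
            else:
                assert math.isinf(after)
            checked += 1

    def test_energy_ledger_drift(self):
        cfg = SimulationConfig(salt_mM=50.0, n_equil_cycles=0, n_prod_cycles=0, seed=7)
        eng = MonteCarloEngine([1, -1, 0, 1, 0, -1] * 3, cfg)
        eng.run_cycles(600)
        assert abs(eng.energy - eng.full_energy()) < 1e-6

    def test_overlap_flagged_in_total_energy(self, charged_engine):
        state = charged_engine.snapshot()
        state.chain_coords = state.chain_coords.copy()
        state.chain_coords[1] = state.chain_coords[0] + [3.9, 0, 0]
        assert math.isinf(total_energy(state, charged_engine.config))


class TestMetropolis:
    def test_zero_du_always_accepted(self, charged_engine):
        assert all(charged_engine.metropolis_accept(0.0) for _ in range(100))

    def test_overlap_always_rejected(self, charged_engine):
        assert not any(charged_engine.metropolis_accept(math.inf) for _ in range(100))

    def test_acceptance_frequency_at_one_kT(self):
        """P(accept | dU = 1 kT) = exp(-1) within 3 sigma over 1e5 trials."""
        cfg = SimulationConfig(n_equil_cycles=0, n_prod_cycles=0, seed=9)
        eng = MonteCarloEngine([0, 0, 0], cfg)
        trials = 100_000
        acc = sum(eng.metropolis_accept(1.0) for _ in range(trials))
        p = math.exp(-1.0)
        sigma = math.sqrt(p * (1 - p) / trials)
        assert acc / trials == pytest.approx(p, abs=3 * sigma)


class TestMoves:
    def test_slither_keeps_bead_count_and_charge_sequence(self):
        """Charges stay attached to residue indices; only geometry relabels."""
        cfg = SimulationConfig(salt_mM=50.0, n_equil_cycles=0, n_prod_cycles=0, seed=21)
        q = [1, 0, -1, 0, 0, 1, 0, 0]
        eng = MonteCarloEngine(q, cfg)
        before = eng.charge[: eng.n].copy()
        for _ in range(50):
            kind, payload, du, du_acc = eng.propose_move("slither")
            if eng.metropolis_accept(du_acc):
                eng._apply(kind, payload)
                eng.energy += du
        assert eng.n == len(q)
        assert np.array_equal(eng.charge[: eng.n], before)

    def test_pivot_preserves_bond_lengths(self):
        cfg = SimulationConfig(n_equil_cycles=0, n_prod_cycles=0, seed=22)
        eng = MonteCarloEngine([0] * 12, cfg)
        bonds_before = np.linalg.norm(np.diff(eng.coords[: eng.n], axis=0), axis=1)
        for _ in range(20):
            kind, payload, du, _ = eng.propose_move("pivot")
            if kind != "noop":
                eng._apply(kind, payload)
        bonds_after = np.linalg.norm(np.diff(eng.coords[: eng.n], axis=0), axis=1)
        assert np.allclose(bonds_before, bonds_after, atol=1e-9)

    def test_pivot_and_slither_disabled_for_dimers(self):
        cfg = SimulationConfig(n_equil_cycles=0, n_prod_cycles=0, seed=23)
        eng = MonteCarloEngine([0, 0], cfg)
        assert "pivot" not in eng._move_names
        assert "slither" not in eng._move_names
        eng.run_cycles(10)  # still samples with the remaining moves


class TestRunSimulation:
    def test_identical_seed_gives_bit_identical_series(self):
        cfg = SimulationConfig(salt_mM=100.0, n_equil_cycles=50, n_prod_cycles=200,
                               sample_interval=10, seed=77)
        q = [1, 0, -1, 0, 0, 1]
        a = run_simulation(q, cfg)
        b = run_simulation(q, cfg)
        assert np.array_equal(a.rg_series, b.rg_series)
        assert np.array_equal(a.energy_series, b.energy_series)

    def test_electroneutrality_at_setup_and_conserved(self, salt_runs):
        for trajs in salt_runs.values():
            for traj in trajs:
                for fr in traj.frames[::20]:
                    total = fr.per_bead_charge.sum() + fr.counterion_charges.sum()
                    assert total == 0

    def test_counterion_count_matches_chain_charges(self, hst5_run):
        fr = hst5_run.frames[0]
        assert fr.n_ions == np.count_nonzero(fr.per_bead_charge)

    def test_hard_core_never_violated_in_sampled_frames(self, salt_runs):
        """Every sampled pair distance >= 4 A under minimum image."""
        from idpbench.bead_necklace import box_side_for

        for trajs in salt_runs.values():
            for traj in trajs:
                box = box_side_for(traj.frames[0].n_beads, traj.config)
                for fr in traj.frames[::25]:
                    coords = np.vstack([fr.chain_coords, fr.counterion_coords])
                    d = _min_image(coords[:, None, :] - coords[None, :, :], box)
                    r = np.sqrt(np.einsum("abj,abj->ab", d, d))
                    iu = np.triu_indices(len(coords), k=1)
                    assert r[iu].min() >= 4.0 - 1e-9

    def test_phantom_limit_matches_ideal_chain(self, phantom_run):
        """With interactions off, <Ree^2> = (N-1) <b^2> from quadrature."""
        ree2 = np.mean(
            [np.sum((f.chain_coords[-1] - f.chain_coords[0]) ** 2) for f in phantom_run.frames]
        )
        b2 = harmonic_bond_moment(4.1, 0.4, 298.0, order=2)
        assert ree2 == pytest.approx(9 * b2, rel=0.05)

    def test_salt_screening_compacts_a_polyelectrolyte(self, salt_runs):
        """Mean Rg at 0 mM exceeds mean Rg at 150 mM beyond pooled errors."""
        rep0 = convergence_report([t.rg_series for t in salt_runs[0.0]])
        rep150 = convergence_report([t.rg_series for t in salt_runs[150.0]])
        gap = rep0.pooled_mean - rep150.pooled_mean
        err = math.hypot(rep0.pooled_stderr, rep150.pooled_stderr)
        assert gap > 3 * err
        assert gap > 0

    def test_rg_definition_unweighted_over_chain(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)


class TestCounterionRdf:
    def test_zero_density_below_contact(self, hst5_run):
        edges, density, _ = counterion_rdf(hst5_run, bin_width=0.5)
        below = edges[:-1] < 4.0 - 0.5
        assert np.all(density[below] == 0.0)

    def test_counts_conserved(self, hst5_run):
        _, _, counts = counterion_rdf(hst5_run, bin_width=1.0)
        fr = hst5_run.frames[0]
        assert counts.sum() == fr.n_ions * len(hst5_run.frames)

    def test_opposite_ions_sit_closer_to_a_charged_chain(self, hst5_run):
        """Histatin 5 is net positive: its negative counterions accumulate
        nearer the chain than the co-ion positives."""

        def mean_min_distance(charge):
            edges, density, counts = counterion_rdf(hst5_run, bin_width=0.5, charge=charge)
            centers = (edges[:-1] + edges[1:]) / 2
            return np.average(centers, weights=counts)

        assert mean_min_distance(-1) < mean_min_distance(+1)

    def test_requires_frames_and_ions(self, hst5_run):
        import dataclasses

        short = dataclasses.replace(hst5_run, frames=hst5_run.frames[:5])
        with pytest.raises(ValueError, match="10 frames"):
            counterion_rdf(short)


class TestConvergenceDiagnostics:
    def test_constant_series_zero_error_no_flags(self):
        rep = convergence_report([np.full(100, 13.0), np.full(100, 13.0)])
        assert rep.pooled_stderr == 0.0
        assert rep.flagged == []

    def test_offset_replicate_is_flagged(self, rng):
        base = 20.0 + 0.1 * rng.standard_normal(500)
        trapped = 30.0 + 0.1 * rng.standard_normal(500)
        rep = convergence_report([base, trapped])
        assert len(rep.flagged) == 2  # both deviate from the pooled mean

    def test_statistical_inefficiency_of_ar1(self, rng):
        """g = (1+phi)/(1-phi) for an AR(1) process, here phi = 0.8 -> g = 9."""
        phi, n = 0.8, 40_000
        x = np.empty(n)
        x[0] = 0.0
        noise = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + noise[t]
        g = statistical_inefficiency(x)
        expected = (1 + phi) / (1 - phi)
        assert g == pytest.approx(expected, rel=0.2)

    def test_white_noise_inefficiency_near_one(self, rng):
        g = statistical_inefficiency(rng.standard_normal(20_000))
        assert g == pytest.approx(1.0, abs=0.2)


class TestConfigValidation:
    def test_box_smaller_than_contour_rejected(self):
        cfg = SimulationConfig(box_side=10.0, n_equil_cycles=0, n_prod_cycles=0)
        with pytest.raises(ValueError, match="contour"):
            MonteCarloEngine([0] * 10, cfg)

    def test_single_bead_weight_required(self):
        with pytest.raises(ValueError, match="single_bead"):
            SimulationConfig(move_weights={"single_bead": 0.0, "pivot": 1.0})

    def test_negative_salt_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(salt_mM=-1.0)
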