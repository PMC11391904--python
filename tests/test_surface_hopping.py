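"""FSSH mechanics: integrators, hop statistics, ensembles, kinetics."""

import numpy as np
import pytest

from namdnn import units
from namdnn.data import StateSpace
from namdnn.hopping import (HopRecord, SHConfig, SHState, attempt_hop,
                            ensemble_populations, fit_sequential_kinetics,
                            hop_probabilities, propagate_coefficients,
                            run_ensemble, run_trajectory,
                            sequential_populations, velocity_verlet_step)
from namdnn.models import (make_avoided_crossing_1d, make_conical_2d,
                           sample_initial_conditions)

S2 = StateSpace(2)


class TestVelocityVerlet:
    def _state(self, vel):
        return SHState(positions=np.zeros((1, 3)),
                       velocities=np.array([vel]),
                       masses=np.array([1800.0]), active_state=0,
                       coefficients=np.array([1.0, 0.0]))

    def test_zero_force_gives_uniform_linear_motion(self):
        s = self._state([0.01, 0.0, -0.02])
        zero = lambda pos: np.zeros((1, 3))
        for _ in range(10):
            s = velocity_verlet_step(s, zero, 10.0)
        assert np.allclose(s.positions, s.velocities * 100.0, rtol=1e-14)

    def test_harmonic_oscillator_symplectic_over_1000_steps(self):
        # velocity Verlet is symplectic: the energy error oscillates with
        # bounded amplitude O((w dt)^2) and shows no secular drift, so the
        # energy at full periods returns to the initial value much more
        # tightly than the instantaneous bound
        m, k = 1800.0, 0.05
        omega = np.sqrt(k / m)
        period = 2 * np.pi / omega
        dt = period / 100
        forces = lambda pos: -k * pos
        s = self._state([0.0, 0.0, 0.0])
        s.positions[0, 0] = 0.4
        e0 = 0.5 * k * 0.4 ** 2

        def energy(st):
            return st.kinetic_energy() + 0.5 * k * float(
                np.sum(st.positions ** 2))

        bound = 0.0
        for _ in range(1000):   # ten full periods
            s = velocity_verlet_step(s, forces, dt)
            bound = max(bound, abs(energy(s) - e0))
        assert abs(energy(s) - e0) / e0 < 1e-5     # secular drift
        assert bound / e0 < 1e-2                   # oscillating bound

    def test_time_reversibility(self):
        k = 0.02
        forces = lambda pos: -k * pos
        s = self._state([0.005, -0.002, 0.001])
        s.positions[:] = [[0.3, -0.1, 0.2]]
        start = s.positions.copy()
        for _ in range(50):
            s = velocity_verlet_step(s, forces, 8.0)
        s.velocities *= -1
        for _ in range(50):
            s = velocity_verlet_step(s, forces, 8.0)
        assert np.max(np.abs(s.positions - start)) <= 1e-10

    def test_nonfinite_forces_abort_with_geometry(self):
        s = self._state([0.0, 0.0, 0.0])
        bad = lambda pos: np.full((1, 3), np.nan)
        with pytest.raises(RuntimeError, match="non-finite"):
            velocity_verlet_step(s, bad, 1.0)


class TestCoefficientPropagation:
    def test_zero_coupling_pure_phase_evolution(self):
        c0 = np.array([np.sqrt(0.5), np.sqrt(0.5)], dtype=complex)
        e = np.array([0.0, 0.1])
        vc = np.zeros((2, 2))
        c1 = propagate_coefficients(c0, (e, e), (vc, vc), dt=1.0)
        assert np.allclose(np.abs(c1), np.abs(c0), atol=1e-12)
        rel_phase = np.angle(c1[1]) - np.angle(c1[0])
        assert rel_phase == pytest.approx(-0.1, abs=1e-12)

    def test_norm_conserved_over_many_random_steps(self):
        rng = np.random.default_rng(0)
        c = np.array([0.6 + 0.3j, 0.2 - 0.1j, 0.0 + 0.0j])
        c /= np.linalg.norm(c)
        for _ in range(200):
            e0, e1 = rng.normal(size=3), rng.normal(size=3)
            w = rng.normal(size=(3, 3)) * 0.05
            vc0, vc1 = w - w.T, (w - w.T) * rng.uniform()
            c = propagate_coefficients(c, (e0, e1), (vc0, vc1), dt=5.0,
                                       n_substeps=8)
            assert abs(np.sum(np.abs(c) ** 2) - 1.0) <= 1e-8

    def test_two_level_rabi_oscillation_matches_closed_form(self):
        w = 0.02
        vc = np.array([[0.0, w], [-w, 0.0]])
        zero = np.zeros(2)
        c = np.array([1.0 + 0j, 0.0])
        total_t, steps = 50.0, 100
        for _ in range(steps):
            c = propagate_coefficients(c, (zero, zero), (vc, vc),
                                       dt=total_t / steps, n_substeps=10)
        # d/dt (c0, c1) = (-w c1, +w c0): rotation by angle w t
        assert abs(c[0].real - np.cos(w * total_t)) <= 1e-6
        assert abs(c[1].real - np.sin(w * total_t)) <= 1e-6


class TestHopProbabilities:
    def test_zero_couplings_give_zero_probabilities(self):
        c = np.array([0.8, 0.6j])
        g = hop_probabilities(c, 0, np.zeros((2, 2)), dt=10.0)
        assert np.all(g == 0)

    def test_negative_flux_clamped_and_active_zero(self):
        c = np.array([np.sqrt(0.5), np.sqrt(0.5)], dtype=complex)
        vc = np.array([[0.0, -0.3], [0.3, 0.0]])   # flux into the active
        g = hop_probabilities(c, 0, vc, dt=1.0)
        assert g[0] == 0.0 and g[1] == 0.0

    def test_probabilities_normalized_when_flux_exceeds_one(self):
        c = np.array([0.1, np.sqrt(1 - 0.01)], dtype=complex)
        vc = np.array([[0.0, 50.0], [-50.0, 0.0]])
        g = hop_probabilities(c, 0, vc, dt=1.0)
        assert g.sum() <= 1.0 + 1e-12

    def test_tiny_active_population_warns(self):
        c = np.array([1e-9, 1.0], dtype=complex)
        with pytest.warns(RuntimeWarning):
            g = hop_probabilities(c, 0, np.ones((2, 2)), dt=1.0)
        assert np.all(g == 0)


class TestAttemptHop:
    def _state(self, vel_x, active=0):
        return SHState(positions=np.zeros((1, 3)),
                       velocities=np.array([[vel_x, 0.0, 0.0]]),
                       masses=np.array([2000.0]), active_state=active,
                       coefficients=np.array([1.0, 0.0], dtype=complex))

    def test_zero_probabilities_give_no_hop(self):
        s = self._state(0.01)
        rng = np.random.default_rng(0)
        new, rec = attempt_hop(s, np.zeros(2), np.array([0.0, 0.1]),
                               np.ones((1, 1, 3)), S2, rng)
        assert rec.outcome == "none" and new.active_state == 0

    def test_downhill_hop_gains_exact_kinetic_energy(self):
        s = self._state(0.002, active=1)
        energies = np.array([0.09, 0.1])      # hop down by 0.01 Ha
        nacs = np.zeros((1, 1, 3))
        nacs[0, 0, 0] = 1.0
        rng = np.random.default_rng(1)
        new, rec = attempt_hop(s, np.array([1.0, 0.0]), energies, nacs, S2,
                               rng)
        assert rec.outcome == "accepted" and new.active_state == 0
        gain = new.kinetic_energy() - s.kinetic_energy()
        assert gain == pytest.approx(0.01, abs=1e-9)

    def test_frustrated_uphill_hop_keeps_energy_and_state(self):
        s = self._state(1e-4, active=0)
        energies = np.array([0.0, 0.5])
        nacs = np.zeros((1, 1, 3))
        nacs[0, 0, 0] = 1.0
        rng = np.random.default_rng(2)
        new, rec = attempt_hop(s, np.array([0.0, 1.0]), energies, nacs, S2,
                               rng)
        assert rec.outcome == "frustrated" and new.active_state == 0
        assert new.kinetic_energy() == pytest.approx(s.kinetic_energy(),
                                                     rel=1e-12)

    def test_reflection_policy_reverses_component_conserving_energy(self):
        s = self._state(1e-4, active=0)
        energies = np.array([0.0, 0.5])
        nacs = np.zeros((1, 1, 3))
        nacs[0, 0, 0] = 1.0
        rng = np.random.default_rng(3)
        new, rec = attempt_hop(s, np.array([0.0, 1.0]), energies, nacs, S2,
                               rng, frustrated_hop="reflect")
        assert rec.outcome == "frustrated"
        assert new.velocities[0, 0] == pytest.approx(-1e-4, rel=1e-12)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            HopRecord(0.0, 0, 1, 1.5, 0.2, "accepted")


class TestTrajectories:
    def test_single_state_harmonic_surface_small_drift_no_hops(self):
        # zero coupling: the lower adiabat is a pure harmonic well
        m = make_conical_2d(c=0.0, delta=0.05)
        pos, vel = sample_initial_conditions(m, 1, seed=2)
        cfg = SHConfig(t_max_fs=100.0, dt_fs=0.5, initial_state=0, seed=0)
        log = run_trajectory(m, (pos[0], vel[0]), cfg)
        assert not log.hops
        drift = np.max(np.abs(log.total_energy - log.total_energy[0]))
        assert drift < 1e-5
        assert log.valid

    def test_zero_coupling_population_stays_on_initial_state(self):
        m = make_conical_2d(c=0.0, delta=0.05)
        pos, vel = sample_initial_conditions(m, 4, seed=3)
        cfg = SHConfig(t_max_fs=50.0, dt_fs=0.5, initial_state=1, seed=1)
        logs = run_ensemble(m, pos, vel, m.masses, cfg)
        for log in logs:
            assert np.all(log.active == 1)
            assert np.allclose(log.coeff_populations[:, 1], 1.0, atol=1e-8)

    def test_same_seed_reproduces_hop_records(self, ci2d):
        pos, vel = sample_initial_conditions(ci2d, 3, seed=5)
        cfg = SHConfig(t_max_fs=60.0, initial_state=1, seed=9)
        a = run_ensemble(ci2d, pos, vel, ci2d.masses, cfg)
        b = run_ensemble(ci2d, pos, vel, ci2d.masses, cfg)
        ra = [(h.time, h.from_state, h.to_state, h.random_draw, h.outcome)
              for log in a for h in log.hops]
        rb = [(h.time, h.from_state, h.to_state, h.random_draw, h.outcome)
              for log in b for h in log.hops]
        assert ra == rb and len({la.valid_until for la in a}) >= 1

    def test_coefficient_norm_conserved_every_step(self, ci2d):
        pos, vel = sample_initial_conditions(ci2d, 2, seed=6)
        cfg = SHConfig(t_max_fs=50.0, initial_state=1, seed=2,
                       decoherence="none")
        logs = run_ensemble(ci2d, pos, vel, ci2d.masses, cfg)
        for log in logs:
            norms = log.coeff_populations.sum(axis=1)
            assert np.max(np.abs(norms - 1.0)) <= 1e-8

    def test_hop_statistics_consistent_with_coefficient_transfer(self):
        # fewest-switches self-consistency: for a single clean passage
        # through a localized coupling region (flat surfaces, no recrossing,
        # no frustrated hops, no decoherence) the fraction of trajectories
        # that switched surface equals the coefficient population transfer
        class FlatCrossing:
            n_states = 2
            gap = 1e-4
            amp = 0.8
            sigma = 0.3

            def evaluate(self, positions):
                B = positions.shape[0]
                x = positions[:, 0, 0]
                e = np.zeros((B, 2))
                e[:, 1] = self.gap
                f = np.zeros((B, 2, 1, 3))
                nac = np.zeros((B, 1, 1, 3))
                nac[:, 0, 0, 0] = self.amp * np.exp(
                    -0.5 * (x / self.sigma) ** 2)
                return e, f, nac

        n = 1000
        masses = np.array([2000.0])
        pos = np.zeros((n, 1, 3))
        pos[:, 0, 0] = -2.0
        vel = np.zeros((n, 1, 3))
        vel[:, 0, 0] = 1e-3            # KE well above the gap
        t_total_fs = (4.0 / 1e-3) / units.FS
        cfg = SHConfig(t_max_fs=t_total_fs, dt_fs=0.25, initial_state=1,
                       seed=4, decoherence="none")
        logs = run_ensemble(FlatCrossing(), pos, vel, masses, cfg)
        assert all(log.valid for log in logs)
        hop_fraction = np.mean([log.active[-1] == 0 for log in logs])
        coeff_transfer = np.mean([log.coeff_populations[-1, 0]
                                  for log in logs])
        assert 0.05 < coeff_transfer < 0.95    # non-trivial transfer
        assert hop_fraction == pytest.approx(coeff_transfer, abs=0.02)


class TestEnsembleAnalysis:
    def _fake_log(self, times, active, valid_until=None):
        T = len(times)
        return type("L", (), {})() if False else \
            __import__("namdnn.hopping", fromlist=["TrajectoryLog"]
                       ).TrajectoryLog(
                times=np.asarray(times, float),
                active=np.asarray(active, int),
                energies=np.zeros((T, 2)),
                coeff_populations=np.zeros((T, 2)),
                total_energy=np.zeros(T), hops=[],
                valid_until=T if valid_until is None else valid_until)

    def test_all_on_ground_state(self):
        t = np.arange(3.0)
        logs = [self._fake_log(t, [0, 0, 0]) for _ in range(5)]
        _, pops, se, n = ensemble_populations(logs)
        assert np.allclose(pops[:, 0], 1.0) and np.all(n == 5)
        assert np.allclose(se[:, 0], 0.0)

    def test_single_hop_steps_population(self):
        t = np.arange(3.0)
        logs = [self._fake_log(t, [1, 1, 1]), self._fake_log(t, [1, 0, 0])]
        _, pops, _, _ = ensemble_populations(logs)
        assert np.allclose(pops[:, 1], [1.0, 0.5, 0.5])

    def test_invalid_trajectories_masked_out(self):
        t = np.arange(4.0)
        logs = [self._fake_log(t, [1, 1, 1, 1]),
                self._fake_log(t, [1, 0, 0, 0], valid_until=2)]
        _, pops, _, n = ensemble_populations(logs)
        assert list(n) == [2, 2, 1, 1]
        assert pops[2, 1] == 1.0    # only the valid trajectory counts

    def test_no_valid_trajectories_yields_nan(self):
        t = np.arange(2.0)
        logs = [self._fake_log(t, [0, 0], valid_until=0)]
        _, pops, _, n = ensemble_populations(logs)
        assert np.isnan(pops).all() and np.all(n == 0)


class TestSequentialKinetics:
    def test_two_step_lifetimes_recovered_within_one_percent(self):
        t = np.linspace(0, 200, 401)
        pops = sequential_populations(t, [1 / 50.0, 1 / 20.0])
        fit = fit_sequential_kinetics(pops, t, 3)
        assert fit["lifetimes"][1] == pytest.approx(20.0, rel=0.01)
        assert fit["lifetimes"][0] == pytest.approx(50.0, rel=0.01)

    def test_single_step_decay(self):
        t = np.linspace(0, 100, 201)
        pops = sequential_populations(t, [1 / 35.0])
        fit = fit_sequential_kinetics(pops, t, 2)
        assert fit["lifetimes"][0] == pytest.approx(35.0, rel=1e-6)

    def test_zero_rate_flags_infinite_lifetime(self):
        t = np.linspace(0, 100, 51)
        pops = np.zeros((51, 2))
        pops[:, 1] = 1.0
        fit = fit_sequential_kinetics(pops, t, 2)
        assert fit["tau_infinite"] and np.isinf(fit["lifetimes"]).all()

    def test_flat_but_mixed_populations_not_identifiable(self):
        t = np.linspace(0, 100, 51)
        pops = np.full((51, 2), 0.5)
        with pytest.raises(ValueError, match="identifiable"):
            fit_sequential_kinetics(pops, t, 2)

    def test_time_unit_rescaling_rescales_rates(self):
        t = np.linspace(0, 200, 401)
        pops = sequential_populations(t, [1 / 40.0])
        f1 = fit_sequential_kinetics(pops, t, 2)
        f2 = fit_sequential_kinetics(pops, t * units.FS, 2)
        assert f2["lifetimes"][0] == pytest.approx(
            f1["lifetimes"][0] * units.FS, rel=1e-9)


class TestSHConfigAndState:
    def test_validation(self):
        with pytest.raises(ValueError):
            SHConfig(dt_fs=0.0)
        with pytest.raises(ValueError):
            SHConfig(decoherence="magic")
        with pytest.raises(ValueError):
            SHState(np.zeros((1, 3)), np.zeros((1, 3)), np.ones(1), 0,
                    np.array([0.5, 0.5]))   # norm != 1

    def test_default_time_step_and_horizon(self):
        cfg = SHConfig()
        assert cfg.dt_fs == 0.5 and cfg.t_max_fs == 100.0
        assert cfg.n_steps == 200
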