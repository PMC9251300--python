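"""Finite-volume column solver: fluxes, stability, conservation, determinism."""

from dataclasses import replace

import numpy as np
import pytest

import cyanoagg as ca
from cyanoagg.environment import EnvironmentProfile, synthetic_profile
from cyanoagg.transport import (
    ConfigurationError,
    NumericalConfig,
    SimulationState,
    advective_diffusive_flux,
    face_values,
    initial_condition,
    stability_check,
    step,
)
from cyanoagg.diagnostics import appearance_time, mass_audit

from conftest import HIGH


def constant_env(nz, dz, T=20.0, D=1e-4, eps=0.0):
    z = (np.arange(nz) + 0.5) * dz
    return EnvironmentProfile(
        z_nodes=z, T=np.full(nz, T), Dz=np.full(nz, D), eps=np.full(nz, eps),
        label="uniform",
    )


class TestInitialCondition:
    def test_mixed_layer_seeding(self, table25, scaled_cfg):
        state = initial_condition(scaled_cfg, table25)
        assert mass_audit(state.n, scaled_cfg.dz) == pytest.approx(
            scaled_cfg.n0 * scaled_cfg.h_ML
        )
        assert np.all(state.n[1:] == 0.0)
        below = scaled_cfg.z_nodes > scaled_cfg.h_ML
        assert np.all(state.n[0, below] == 0.0)

    def test_full_column_when_hml_equals_depth(self, table25, scaled_cfg):
        cfg = replace(scaled_cfg, h_ML=scaled_cfg.z_max)
        state = initial_condition(cfg, table25)
        assert np.all(state.n[0] == cfg.n0)

    def test_neutral_density_start(self, table25, scaled_cfg):
        env = synthetic_profile(scaled_cfg.z_nodes, regime="high_wind")
        state = initial_condition(scaled_cfg, table25, env)
        assert np.all(state.rho_cell == pytest.approx(float(env.rho_w[0])))


class TestUpwindFaces:
    def test_sinking_takes_shallower_node(self):
        n = np.array([1.0, 2.0, 3.0, 4.0])
        w_face = np.full(5, 1e-4)
        np.testing.assert_array_equal(face_values(n, w_face)[1:-1], [1.0, 2.0, 3.0])

    def test_floating_takes_deeper_node(self):
        n = np.array([1.0, 2.0, 3.0, 4.0])
        w_face = np.full(5, -1e-4)
        np.testing.assert_array_equal(face_values(n, w_face)[1:-1], [2.0, 3.0, 4.0])

    def test_uniform_field_indifferent_to_direction(self, rng):
        n = np.full(6, 7.5)
        w_face = rng.normal(size=7)
        assert np.all(face_values(n, w_face)[1:-1] == 7.5)


class TestFluxes:
    def test_uniform_no_advection_all_zero(self):
        q = advective_diffusive_flux(np.full(5, 3.0), np.full(6, 1e-3), np.zeros(6), 0.2)
        np.testing.assert_array_equal(q, 0.0)

    def test_linear_profile_fickian_flux(self):
        dz = 0.25
        n = 10.0 + 4.0 * (np.arange(4) + 0.5) * dz  # slope 4 per meter
        q = advective_diffusive_flux(n, np.full(5, 2e-3), np.zeros(5), dz)
        np.testing.assert_allclose(q[1:-1], -2e-3 * 4.0, rtol=1e-12)

    def test_boundary_faces_always_zero(self, rng):
        n = rng.random(8)
        q = advective_diffusive_flux(n, rng.random(9), rng.normal(size=9), 0.5)
        assert q[0] == 0.0 and q[-1] == 0.0


class TestStability:
    def test_diffusion_number_pass(self, table25):
        cfg = NumericalConfig(dz=0.2, dt=10.0, z_max=10.0)
        env = constant_env(50, 0.2, D=1e-3)
        rep = stability_check(cfg, env, w_max=0.0)
        assert rep.diffusion_number == pytest.approx(0.25)
        assert rep.ok

    def test_diffusion_number_fail(self):
        cfg = NumericalConfig(dz=0.2, dt=10.0, z_max=10.0)
        env = constant_env(50, 0.2, D=5e-3)
        rep = stability_check(cfg, env, w_max=0.0)
        assert rep.diffusion_number == pytest.approx(1.25)
        with pytest.raises(ConfigurationError, match="diffusion number"):
            rep.raise_if_unstable()

    def test_courant_number(self):
        cfg = NumericalConfig(dz=0.2, dt=10.0, z_max=10.0)
        env = constant_env(50, 0.2, D=1e-4)
        rep = stability_check(cfg, env, w_max=1e-3)
        assert rep.courant_number == pytest.approx(0.05)
        assert rep.ok

    def test_default_scheme_stable_for_both_regimes(self, table101):
        cfg = NumericalConfig()  # dz = 0.2 m, dt = 10 s
        for regime in ("high_wind", "low_wind"):
            env = synthetic_profile(cfg.z_nodes, regime=regime)
            assert stability_check(cfg, env, table=table101).ok


class TestStep:
    def test_uniform_state_is_steady_without_reaction(self, table25):
        cfg = NumericalConfig(dz=0.5, dt=30.0, z_max=10.0, h_ML=10.0, n0=1e7)
        env = constant_env(cfg.nz, cfg.dz, D=1e-4)
        state = initial_condition(cfg, table25, env)
        out = step(state, env, table25, cfg, include_advection=False, include_reaction=False)
        np.testing.assert_allclose(out.n, state.n, rtol=1e-14)

    def test_pulse_advection_matches_brute_force_oracle(self, table25):
        """Pure advection of a pulse on a 5-cell grid agrees with a literal
        loop-based upwind update, step by step."""
        cfg = NumericalConfig(dz=1.0, dt=500.0, z_max=5.0, h_ML=1.0, n0=1e6,
                              rho_cell0=1065.0)
        env = constant_env(cfg.nz, cfg.dz, D=1e-9)  # diffusion negligible
        state = initial_condition(cfg, table25, env)

        n_ref = state.n.copy()
        rho_ref = state.rho_cell.copy()
        s = state
        for istep in range(3):
            s = step(s, env, table25, cfg, include_reaction=False)
            # oracle: density update first (dark light field), then per class,
            # per cell, upwind fluxes with zero boundaries
            I = ca.light_at_depth(cfg.z_nodes, istep * cfg.dt)
            rho_ref = ca.update_cell_density(rho_ref, I, cfg.dt)
            w_all = ca.velocity_profiles(rho_ref, env, table25)
            K, nz = n_ref.shape
            n_next = n_ref.copy()
            for k in range(K):
                q = np.zeros(nz + 1)
                for f in range(1, nz):
                    wf = 0.5 * (w_all[k, f - 1] + w_all[k, f])
                    upwind = n_ref[k, f - 1] if wf >= 0 else n_ref[k, f]
                    q[f] = -1e-9 * (n_ref[k, f] - n_ref[k, f - 1]) / cfg.dz + wf * upwind
                for i in range(nz):
                    n_next[k, i] = n_ref[k, i] + cfg.dt / cfg.dz * (q[i] - q[i + 1])
            n_ref = n_next
            np.testing.assert_allclose(s.n, n_ref, rtol=1e-12, atol=1e-300)

        # the sinking pulse deepened: center of mass moved down
        z = cfg.z_nodes
        com0 = np.sum(z * state.n[0]) / np.sum(state.n[0])
        com3 = np.sum(z * s.n[0]) / np.sum(s.n[0])
        assert com3 > com0

    def test_mass_conserved_with_reaction(self, table25, scaled_cfg):
        env = synthetic_profile(scaled_cfg.z_nodes, regime="high_wind")
        state = initial_condition(scaled_cfg, table25, env)
        m0 = mass_audit(state.n, scaled_cfg.dz)
        for _ in range(5):
            state = step(state, env, table25, scaled_cfg)
        assert mass_audit(state.n, scaled_cfg.dz) == pytest.approx(m0, rel=1e-10)

    def test_reaction_substepping_preserves_positivity(self, table25):
        # concentrations high enough that one explicit step would overshoot
        cfg = NumericalConfig(dz=0.5, dt=30.0, z_max=10.0, h_ML=3.0, n0=5e10)
        env = synthetic_profile(cfg.z_nodes, regime="high_wind")
        state = initial_condition(cfg, table25, env)
        m0 = mass_audit(state.n, cfg.dz)
        for _ in range(3):
            state = step(state, env, table25, cfg)
        assert state.n.min() >= 0.0
        assert mass_audit(state.n, cfg.dz) == pytest.approx(m0, rel=1e-10)

    def test_substepping_can_be_refused(self, table25):
        cfg = NumericalConfig(dz=0.5, dt=30.0, z_max=10.0, h_ML=3.0, n0=5e10,
                              auto_substep=False)
        env = synthetic_profile(cfg.z_nodes, regime="high_wind")
        state = initial_condition(cfg, table25, env)
        with pytest.raises(ConfigurationError, match="auto_substep"):
            step(state, env, table25, cfg)


class TestDiffusionAccuracy:
    @staticmethod
    def _decay_error(dz, dt, table):
        """Relative error of the numerical decay rate of a cosine mode under
        pure diffusion with no-flux boundaries (analytic rate D (pi/H)^2)."""
        H, D = 10.0, 1e-4
        cfg = NumericalConfig(dz=dz, dt=dt, z_max=H, h_ML=H, n0=1.0)
        env = constant_env(cfg.nz, dz, D=D)
        state = initial_condition(cfg, table, env)
        mode0 = np.cos(np.pi * cfg.z_nodes / H)
        state.n[0] = 100.0 + 10.0 * mode0
        t_end = 2.0e4
        for _ in range(int(t_end / dt)):
            state = step(state, env, table, cfg,
                         include_advection=False, include_reaction=False)
        amp = np.sum(state.n[0] * mode0) / np.sum(mode0 * mode0)
        rate = -np.log(amp / 10.0) / t_end
        exact = D * (np.pi / H) ** 2
        return abs(rate - exact) / exact

    def test_decay_rate_converges_under_refinement(self, table25):
        coarse = self._decay_error(0.5, 100.0, table25)
        fine = self._decay_error(0.25, 50.0, table25)
        assert fine < coarse
        assert fine < 0.01  # within 1% of the analytic rate already when refined


class TestRunSimulation:
    def test_zero_horizon_records_only_initial_condition(self, table25, scaled_cfg):
        cfg = replace(scaled_cfg, t_end=0.0)
        series, state = ca.run_simulation(cfg, HIGH, table25)
        assert series.times.tolist() == [0.0]
        assert state.t == 0.0

    def test_reruns_are_byte_identical(self, table25, scaled_cfg, tmp_path):
        cfg = replace(scaled_cfg, t_end=0.5 * 86400.0, n0=2.3e8)
        a, state_a = ca.run_simulation(cfg, HIGH, table25)
        b, state_b = ca.run_simulation(cfg, HIGH, table25)
        assert np.array_equal(a.N, b.N)
        assert np.array_equal(state_a.n, state_b.n)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa)
        b.to_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_off_grid_profile_rejected(self, table25, scaled_cfg):
        bad = synthetic_profile((np.arange(10) + 0.5) * 1.0, regime="high_wind")
        with pytest.raises(ValueError, match="not on the model grid"):
            ca.run_simulation(scaled_cfg, HIGH, table25, profiles={"high_wind": bad})

    def test_advection_off_keeps_appearance_time(self, dense_run_high, dense_run_noadv,
                                                  table25):
        """Zeroing the buoyant velocity barely moves the appearance time of
        the largest class (transport redistributes, aggregation creates)."""
        tau_adv = appearance_time(dense_run_high[0], table25.k_max)
        tau_still = appearance_time(dense_run_noadv[0], table25.k_max)
        assert tau_adv is not None and tau_still is not None
        assert abs(tau_still - tau_adv) / tau_adv < 0.2

    def test_grid_refinement_shifts_appearance_modestly(self, dense_cfg, table25,
                                                        dense_run_high):
        """Halving dz and dt moves the appearance time of the largest class
        by only a few percent at these scaled conditions (first-order scheme;
        the shift is bounded, not sign-constrained, at this problem size)."""
        tau_coarse = appearance_time(dense_run_high[0], table25.k_max)
        fine, _ = ca.run_simulation(dense_cfg.refined(2), HIGH, table25)
        tau_fine = appearance_time(fine, table25.k_max)
        assert tau_fine is not None
        assert abs(tau_fine - tau_coarse) / tau_coarse < 0.25
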