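"""Generator: forcing-free limits, kinematics, uptake bookkeeping, ground truth."""

import numpy as np
import pytest
import xarray as xr

from dvmflux import IWComponent, ScenarioConfig, generate_scenario
from dvmflux.config import ConfigError
from dvmflux.synthetic import apply_uptake, dvm_center_depth, dvm_trajectory

from conftest import quiet_config


def still_config(**overrides):
    """No waves, no advection, no uptake, no noise."""
    base = dict(iw_components=[], spice_amplitude=0.0, uptake_mode="none",
                span_days=2.0)
    base.update(overrides)
    return quiet_config(**base)


class TestGenerateScenario:
    def test_no_forcing_gives_time_constant_fields(self):
        profiles, truth = generate_scenario(still_config())
        for var in ("sigma_theta", "nitrate", "temperature", "salinity"):
            field = profiles[var].values
            assert np.allclose(field, field[:, :1]), var
        assert np.allclose(truth["nloss_true"].values, 0.0)

    def test_uniform_layer_loss_budget(self):
        # 6 mmol m-3 d-1 in a 10-m layer for 2.5 d with saturating nitrate:
        # peak loss = rate x time, depth integral = rate x time x thickness
        cfg = quiet_config(
            iw_components=[], spice_amplitude=0.0, span_days=2.5,
            uptake_mode="prescribed", uptake_zmin=23.0, uptake_zmax=33.0,
            uptake_max=6.0, half_saturation=1e-4, nitrate_offset=40.0,
        )
        _, truth = generate_scenario(cfg)
        final = truth["nloss_true"].values[:, -1]
        z = truth["depth"].values
        assert np.max(final) == pytest.approx(15.0, rel=1e-3)
        assert np.trapezoid(final, z) == pytest.approx(150.0, rel=1e-3)

    def test_seeded_runs_are_identical(self):
        cfg = ScenarioConfig(span_days=1.0, seed=42)
        p1, t1 = generate_scenario(cfg)
        p2, t2 = generate_scenario(cfg)
        xr.testing.assert_identical(p1, p2)
        xr.testing.assert_identical(t1, t2)

    def test_displacement_peak_to_trough_matches_amplitude(self):
        cfg = quiet_config(uptake_mode="none",
                           iw_components=[IWComponent(amplitude=10.0)])
        _, truth = generate_scenario(cfg)
        eta = truth["displacement"].values
        span = eta.max() - eta.min()
        assert span == pytest.approx(20.0, rel=0.05)

    def test_nloss_is_trapezoid_integral_of_rho(self, bloom_run):
        _, truth = bloom_run
        t = truth["time"].values
        rho = truth["rho_true"].values
        nloss = truth["nloss_true"].values
        inc = 0.5 * (rho[:, :-1] + rho[:, 1:]) * np.diff(t)[None, :]
        rebuilt = np.concatenate(
            [np.zeros((rho.shape[0], 1)), np.cumsum(inc, axis=1)], axis=1
        )
        assert np.allclose(rebuilt, nloss, rtol=1e-9, atol=1e-12)
        assert np.all(np.diff(nloss, axis=1) >= -1e-12)

    def test_rho_zero_outside_active_range(self, bloom_run):
        _, truth = bloom_run
        z = truth["depth"].values
        cfg = ScenarioConfig()
        outside = (z < cfg.uptake_zmin) | (z >= cfg.uptake_zmax)
        assert np.allclose(truth["rho_true"].values[outside], 0.0)

    def test_total_removed_equals_integrated_rho(self):
        # volume of nitrate removed must equal the depth-time integral of the
        # recorded rate within discretisation error
        cfg = quiet_config(iw_components=[], spice_amplitude=0.0,
                           span_days=4.0)
        profiles, truth = generate_scenario(cfg)
        n = truth["nitrate_true"].values
        removed = n[:, 0] - n[:, -1]
        z = truth["depth"].values
        total_removed = np.trapezoid(removed, z)
        total_rho = np.trapezoid(truth["nloss_true"].values[:, -1], z)
        assert total_rho == pytest.approx(total_removed, rel=0.005)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(sigma_step=-2.0).validate()  # density inversion
        with pytest.raises(ConfigError):
            ScenarioConfig(dvm_floor_depth=200.0).validate()
        with pytest.raises(ConfigError):
            ScenarioConfig(descent_speed_um_s=-1.0).validate()


class TestDVMKinematics:
    def test_noon_before_first_descent_is_residence_depth(self):
        cfg = ScenarioConfig()
        assert dvm_center_depth(0.5, cfg) == pytest.approx(2.0)

    def test_linear_descent_kinematics(self):
        # 10 h after the 18:00 start at 380 um/s: 2 + 0.00038 * 36000 m
        cfg = ScenarioConfig(dvm_floor_depth=30.0)
        t = 18.0 / 24.0 + 10.0 / 24.0
        assert dvm_center_depth(t, cfg) == pytest.approx(15.68, abs=0.05)

    def test_zero_speed_layer_stays_put(self):
        cfg = ScenarioConfig(descent_speed_um_s=0.0, ascent_speed_um_s=0.0)
        t = np.linspace(0, 3, 200)
        assert np.allclose(dvm_trajectory(t, cfg), cfg.residence_depth)

    def test_trajectory_bounded_by_residence_and_floor(self):
        cfg = ScenarioConfig()
        t = np.linspace(0, 14, 2000)
        z = dvm_trajectory(t, cfg)
        assert z.min() >= cfg.residence_depth - 1e-9
        assert z.max() <= cfg.dvm_floor_depth + 1e-9
        assert z.max() == pytest.approx(cfg.dvm_floor_depth)  # floor reached


class TestApplyUptake:
    def setup_method(self):
        self.cfg = ScenarioConfig(uptake_mode="biomass", uptake_zmin=0.0,
                                  uptake_zmax=50.0, half_saturation=0.05)
        self.z = np.arange(0.0, 50.0)
        self.t = np.linspace(0.0, 1.0, 97)

    def test_zero_biomass_leaves_nitrate_unchanged(self):
        n0 = np.full((self.z.size, self.t.size), 12.0)
        n, rho, nloss = apply_uptake(n0, np.zeros_like(n0), self.t, self.z,
                                     self.cfg)
        assert np.array_equal(n, n0)
        assert np.allclose(rho, 0.0) and np.allclose(nloss, 0.0)

    def test_zero_nitrate_stays_zero(self):
        n0 = np.zeros((self.z.size, self.t.size))
        biomass = np.full_like(n0, 20.0)
        n, rho, _ = apply_uptake(n0, biomass, self.t, self.z, self.cfg)
        assert np.all(n >= 0) and np.allclose(n, 0.0)
        assert np.allclose(rho, 0.0)

    def test_negative_nitrate_rejected(self):
        n0 = np.full((self.z.size, self.t.size), -1.0)
        with pytest.raises(ValueError):
            apply_uptake(n0, np.zeros_like(n0), self.t, self.z, self.cfg)

    def test_saturating_drawdown_matches_fine_euler_oracle(self):
        # dN/dt = -6 N/(N+k), N0 = 20 >> k: after one day N ~ 14
        cfg = ScenarioConfig(uptake_mode="prescribed", uptake_zmin=0.0,
                             uptake_zmax=50.0, uptake_max=6.0,
                             half_saturation=0.05)
        t = np.arange(0.0, 1.0 + 1e-9, 1.0 / (24 * 60))  # 1-min steps
        n0 = np.full((self.z.size, t.size), 20.0)
        biomass = np.full_like(n0, 20.0)
        n, _, nloss = apply_uptake(n0, biomass, t, self.z, cfg)

        # independent fine-step Euler oracle
        nk, dt = 20.0, 1.0 / (24 * 3600)
        for _ in range(24 * 3600):
            nk -= 6.0 * nk / (nk + 0.05) * dt
        assert n[5, -1] == pytest.approx(nk, abs=0.02)
        assert n[5, -1] == pytest.approx(14.0, abs=0.1)
        assert nloss[5, -1] == pytest.approx(20.0 - nk, abs=0.02)
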