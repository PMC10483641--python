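"""Rate fitting, gridding, loss-field integration and error propagation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from dvmflux import AnalysisConfig, NitrateLossModel
from dvmflux.budget import (_BinRates, depth_integrate, fit_rate, grid_rates,
                            integrate_loss)
from dvmflux.units import convert_flux_units, round_sigfigs, umps_to_m_per_h

from conftest import analyse, recovery_config


class TestFitRate:
    def test_no_change_gives_zero_rate(self):
        r, _ = fit_rate([10.0, 10.0], [0.0, 1.0])
        assert r == 0.0

    def test_halving_closed_form(self):
        r, _ = fit_rate([10.0, 5.0], [0.0, 1.0])
        assert r == np.log(0.5) / 1.0  # machine-precision identity

    def test_exact_exponential_multipoint(self):
        t = np.array([0.0, 1.0, 2.0])
        n = 8.0 * np.exp(-0.5 * t)
        r, se = fit_rate(n, t)
        assert r == pytest.approx(-0.5, abs=1e-12)

    def test_pair_se_delta_method(self):
        r, se = fit_rate([10.0, 5.0], [0.0, 2.0], se=[0.3, 0.3])
        expect = np.hypot(0.3 / 10.0, 0.3 / 5.0) / 2.0
        assert se == pytest.approx(expect)

    def test_below_detection_refused(self):
        with pytest.raises(ValueError):
            fit_rate([0.4, 5.0], [0.0, 1.0], detection_limit=0.5)


class TestGridRates:
    def _grid(self, estimates, **cfg_kw):
        cfg = AnalysisConfig(**cfg_kw)
        tg = np.arange(0.0, 2.0, cfg.dt_days)
        df = pd.DataFrame(estimates,
                          columns=["sigma_bin", "t_mid", "r", "se",
                                   "dt", "n_points"])
        return grid_rates(df, tg, cfg), tg

    def test_single_estimate_fills_its_window(self):
        out, _ = self._grid([(25.0, 1.0, -0.2, 0.05, 0.5, 2)])
        br = out[25.0]
        assert br.valid.sum() == 1
        assert br.r[br.valid][0] == pytest.approx(-0.2)

    def test_equal_se_estimates_average(self):
        out, _ = self._grid([(25.0, 1.0, -0.2, 0.1, 0.5, 2),
                             (25.0, 1.001, -0.4, 0.1, 0.5, 2)])
        br = out[25.0]
        assert br.r[br.valid][0] == pytest.approx(-0.3)

    def test_gap_longer_than_limit_stays_flagged(self):
        out, tg = self._grid([(25.0, 0.1, -0.2, 0.1, 0.5, 2),
                              (25.0, 1.9, -0.2, 0.1, 0.5, 2)],
                             gap_limit_days=0.5)
        br = out[25.0]
        assert br.valid.sum() == 2  # nothing interpolated across 1.8 d
        out2, _ = self._grid([(25.0, 0.1, -0.2, 0.1, 0.5, 2),
                              (25.0, 1.9, -0.4, 0.1, 0.5, 2)],
                             gap_limit_days=2.0)
        br2 = out2[25.0]
        # interior interpolated, but no extrapolation beyond the estimates
        interior = slice(np.flatnonzero(br2.valid)[0],
                         np.flatnonzero(br2.valid)[-1] + 1)
        assert br2.valid[interior].all()
        assert not br2.valid[0] and not br2.valid[-1]
        mid = br2.r[len(tg) // 2]
        assert -0.4 < mid < -0.2  # interpolated between the two estimates


def make_loss_inputs(r_value, n0, nt, dt, se_est=0.05):
    """One-bin _BinRates with a single estimate driving every time step."""
    time_grid = np.arange(nt) * dt
    W = np.ones((nt, 1))
    br = _BinRates(25.0, np.full(nt, r_value), np.ones(nt, dtype=bool),
                   W, np.array([se_est]))
    iso = xr.Dataset(
        {
            "nitrate": (("sigma_bin", "time"), [[n0] * nt]),
            "valid": (("sigma_bin", "time"), [[True] * nt]),
        },
        coords={"sigma_bin": [25.0], "time": time_grid,
                "mean_depth": ("sigma_bin", [30.0])},
    )
    return {25.0: br}, iso, time_grid


class TestIntegrateLoss:
    def test_zero_rate_null_dynamics(self):
        cfg = AnalysisConfig(dt_days=0.01)
        br, iso, tg = make_loss_inputs(0.0, 10.0, 50, 0.01)
        loss = integrate_loss(br, iso, tg, cfg)
        assert np.allclose(loss["nhat"].values, 10.0)
        assert np.allclose(loss["rho"].values, 0.0)
        assert np.allclose(loss["nloss"].values, 0.0)

    def test_constant_decay_closed_form(self):
        # r = -0.1 d-1, N0 = 10, over 1 day: Nloss = 10 (1 - e^-0.1)
        dt = 1.0 / (24 * 60)
        nt = 24 * 60 + 1
        cfg = AnalysisConfig(dt_days=dt)
        br, iso, tg = make_loss_inputs(-0.1, 10.0, nt, dt)
        loss = integrate_loss(br, iso, tg, cfg)
        assert loss["nloss"].values[0, -1] == pytest.approx(
            10.0 * (1 - np.exp(-0.1)), abs=1e-4)

    def test_nloss_is_exact_trapezoid_of_rho(self):
        cfg = AnalysisConfig(dt_days=0.01)
        br, iso, tg = make_loss_inputs(-0.3, 12.0, 200, 0.01)
        loss = integrate_loss(br, iso, tg, cfg)
        rho = loss["rho"].values[0]
        nloss = loss["nloss"].values[0]
        rebuilt = np.concatenate(
            [[0.0], np.cumsum(0.5 * (rho[:-1] + rho[1:]) * 0.01)])
        assert np.allclose(rebuilt, nloss, rtol=1e-12, atol=1e-12)

    def test_se_scales_with_estimate_uncertainty(self):
        cfg = AnalysisConfig(dt_days=0.01)
        br1, iso, tg = make_loss_inputs(-0.2, 10.0, 100, 0.01, se_est=0.05)
        br2, _, _ = make_loss_inputs(-0.2, 10.0, 100, 0.01, se_est=0.10)
        l1 = integrate_loss(br1, iso, tg, cfg)
        l2 = integrate_loss(br2, iso, tg, cfg)
        ratio = l2["rate_se"].values / l1["rate_se"].values
        assert np.allclose(ratio, 2.0)


class TestDepthIntegrate:
    def _loss(self, depths, values, var="nloss"):
        n = len(depths)
        nt = np.shape(values)[-1] if np.ndim(values) > 1 else 1
        vals = np.broadcast_to(np.asarray(values, dtype=float).reshape(n, -1),
                               (n, nt)).copy()
        ds = xr.Dataset(
            {
                var: (("sigma_bin", "time"), vals),
                var + "_se": (("sigma_bin", "time"), np.zeros_like(vals)),
                "cell_valid": (("sigma_bin", "time"),
                               np.ones_like(vals, dtype=bool)),
                "loss_valid": (("sigma_bin", "time"),
                               np.ones_like(vals, dtype=bool)),
            },
            coords={"sigma_bin": 25.0 + 0.02 * np.arange(n),
                    "time": np.arange(nt, dtype=float),
                    "mean_depth": ("sigma_bin", np.asarray(depths, float))},
        )
        return ds

    def test_constant_integrand(self):
        ds = self._loss(np.arange(0.0, 34.0), np.ones(34))
        out = depth_integrate(ds, "nloss", 0.0, 33.0)
        assert out["value"].iloc[0] == pytest.approx(33.0)

    def test_rectangular_sublayer(self):
        depths = np.arange(0.0, 41.0)
        rho = np.where((depths >= 20) & (depths < 30), 6.0, 0.0)
        ds = self._loss(depths, rho, var="rho")
        out = depth_integrate(ds, "rho", 0.0, 40.0)
        assert out["value"].iloc[0] == pytest.approx(60.0)

    def test_triangular_profile(self):
        depths = np.arange(0.0, 41.0)
        tri = np.clip(12.0 * (1 - np.abs(depths - 25.0) / 10.0), 0.0, None)
        ds = self._loss(depths, tri)
        out = depth_integrate(ds, "nloss", 0.0, 40.0)
        assert out["value"].iloc[0] == pytest.approx(120.0)

    def test_mostly_flagged_step_is_flagged(self):
        ds = self._loss(np.arange(0.0, 34.0), np.ones(34))
        ds["loss_valid"].values[5:, 0] = False
        out = depth_integrate(ds, "nloss", 0.0, 33.0)
        assert bool(out["flagged"].iloc[0])


class TestRecovery:
    def test_loss_field_matches_ground_truth(self, recovery_run):
        # uniform 6 mmol m-3 d-1 in the 23-33 m layer: relative RMSE of the
        # recovered Nloss field < 25% at default sensor noise
        res = recovery_run["results"]
        truth = recovery_run["truth"]
        loss = res.loss
        md = loss["mean_depth"].values
        tg = loss["time"].values
        true_nl = truth["nloss_true"].values
        z = truth["depth"].values
        tt = truth["time"].values
        est = loss["nloss"].values
        ok = loss["loss_valid"].values
        interp = np.empty_like(est)
        for i, d in enumerate(md):
            prof = np.array([np.interp(d, z, true_nl[:, j])
                             for j in range(tt.size)])
            interp[i] = np.interp(tg, tt, prof)
        sel = ok & (interp > 0.1)
        rmse = np.sqrt(np.mean((est[sel] - interp[sel]) ** 2))
        scale = np.sqrt(np.mean(interp[sel] ** 2))
        assert rmse / scale < 0.25

    def test_noise_halving_halves_rate_uncertainty(self):
        medians = []
        for noise in (0.3, 0.15):
            cfg = recovery_config(span_days=1.5, noise_nitrate=noise)
            from dvmflux import generate_scenario

            profiles, _ = generate_scenario(cfg)
            acfg = AnalysisConfig(nitrate_se=noise)
            _, _, res = analyse(profiles, acfg)
            medians.append(np.median(res.estimates["se"]))
        ratio = medians[1] / medians[0]
        assert ratio == pytest.approx(0.5, abs=0.05)


class TestUnits:
    def test_flux_conversion_matches_molar_mass(self):
        assert round_sigfigs(convert_flux_units(31.0), 3) == 434.0
        assert round_sigfigs(convert_flux_units(4.0), 3) == 56.0
        assert convert_flux_units(0.0) == 0.0

    def test_flux_se_converts_identically(self):
        v, s = convert_flux_units(31.0, 4.0)
        assert round_sigfigs(s, 3) == 56.0

    def test_speed_conversion(self):
        assert round_sigfigs(umps_to_m_per_h(380.0), 2) == 1.4
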