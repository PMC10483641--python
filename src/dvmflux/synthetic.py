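"""Synthetic moored-profiler ocean with known ground truth.

The generator builds a two-week, 1-m x 15-min depth-time record emulating a
dense dinoflagellate bloom over a stratified coastal water column:

* a stable background density profile heaved by internal waves (the whole
  tracer column is displaced with the isopycnals, which is exactly the
  assumption the isopycnal transform downstream relies on);
* an oscillating along-isopycnal advection signal expressed as
  density-compensated spice anomalies, so the same water parcels reappear
  periodically at the virtual mooring;
* nitrate tied to temperature through the climatological line, minus the
  accumulated biological uptake;
* a Gaussian chlorophyll layer performing light-anchored diel vertical
  migration (descent from the residence depth at the configured local hour,
  at the configured swimming speed, down to the nitracline floor);
* saturating nitrate uptake where the layer overlaps the active depth range,
  with the chlorophyll standing stock growing in proportion to the nitrogen
  taken up (fixed Chl:N yield);
* i.i.d. Gaussian sensor noise added last.

Everything biological and advective is constructed in a *material* vertical
coordinate ``zeta`` that rides the internal-wave displacement; the output
fields are then mapped to the fixed (Eulerian) depth grid.  Ground truth
(displacement, true uptake rate, true cumulative loss, noiseless spice, layer
trajectory) is recorded on the material grid, which coincides with the
mean-isopycnal-depth axis used by the analysis.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .config import ConfigError, ScenarioConfig

__all__ = [
    "generate_scenario",
    "dvm_center_depth",
    "dvm_trajectory",
    "apply_uptake",
    "isopycnal_displacement",
]


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def dvm_trajectory(times_days: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    """Depth of the migrating layer centre at each time (material frame).

    State machine: the layer resides at ``residence_depth`` during the day,
    starts descending at ``descent_start_hour`` local time at the configured
    speed, keeps descending (across day boundaries if needed) until it reaches
    ``dvm_floor_depth``, dwells there until the next ``day_start_hour``, then
    ascends at ``ascent_speed_um_s`` back to the residence depth.

    Times are days since local midnight of day 0.
    """
    times_days = np.asarray(times_days, dtype=float)
    if times_days.ndim == 0:
        return dvm_trajectory(times_days[None], cfg)[0]
    t_end = float(times_days.max())
    dt = 30.0 / 86400.0  # 30-s internal step
    n = int(np.ceil(t_end / dt)) + 2
    tt = np.arange(n) * dt
    v_down = cfg.descent_speed_um_s * 1e-6 * 86400.0  # m/day
    v_up = cfg.ascent_speed_um_s * 1e-6 * 86400.0

    pos = np.empty(n)
    mode = "reside"
    z = cfg.residence_depth
    for i, t in enumerate(tt):
        hour = (t % 1.0) * 24.0
        if mode == "reside":
            if _crossed(tt, i, cfg.descent_start_hour):
                mode = "descend"
        if mode == "descend":
            z = min(z + v_down * dt, cfg.dvm_floor_depth)
            if z >= cfg.dvm_floor_depth:
                mode = "dwell"
        elif mode == "dwell":
            if _crossed(tt, i, cfg.day_start_hour):
                mode = "ascend"
        elif mode == "ascend":
            z = max(z - v_up * dt, cfg.residence_depth)
            if z <= cfg.residence_depth:
                mode = "reside"
        pos[i] = z
    return np.interp(times_days, tt, pos)


def _crossed(tt: np.ndarray, i: int, hour: float) -> bool:
    """Did local time cross ``hour`` during the step ending at tt[i]?"""
    if i == 0:
        return False
    h0 = (tt[i - 1] % 1.0) * 24.0
    h1 = (tt[i] % 1.0) * 24.0
    if h0 <= h1:
        return h0 < hour <= h1
    return hour > h0 or hour <= h1  # wrapped past midnight


def dvm_center_depth(t_days, cfg: ScenarioConfig):
    """Layer-centre depth (m) at local time(s) ``t_days`` since midnight day 0."""
    return dvm_trajectory(np.asarray(t_days, dtype=float), cfg)


# ---------------------------------------------------------------------------
# internal waves and spice
# ---------------------------------------------------------------------------

def isopycnal_displacement(cfg: ScenarioConfig, zeta: np.ndarray,
                           t_days: np.ndarray) -> np.ndarray:
    """Vertical displacement eta(zeta, t) in metres (positive = deeper).

    Sum of the configured wave constituents, each with a first-baroclinic
    sine mode shape vanishing at the surface and the bottom of the grid.
    """
    eta = np.zeros((zeta.size, t_days.size))
    mode = np.sin(np.pi * zeta / cfg.depth_max)
    for comp in cfg.iw_components:
        omega = 2.0 * np.pi / (comp.period_hours / 24.0)
        eta += comp.amplitude * np.outer(mode, np.sin(omega * t_days + comp.phase))
    return eta


def _spice_anomaly(cfg: ScenarioConfig, zeta: np.ndarray, t_days: np.ndarray):
    """Density-compensated (dT, dS) oscillation carrying the spice signal.

    alpha*dT = beta*dS keeps density unchanged while the linear spice
    alpha*T + beta*S oscillates with amplitude ``spice_amplitude``.
    """
    omega = 2.0 * np.pi / (cfg.advection_period_hours / 24.0)
    osc = np.sin(omega * t_days)[None, :] * np.ones((zeta.size, 1))
    d_t = cfg.spice_amplitude / (2.0 * cfg.eos_alpha) * osc
    d_s = cfg.spice_amplitude / (2.0 * cfg.eos_beta) * osc
    return d_t, d_s


# ---------------------------------------------------------------------------
# uptake
# ---------------------------------------------------------------------------

def _active_mask(zeta: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    """Half-open uptake range [zmin, zmax): a 10-m layer covers 10 m of grid."""
    return ((zeta >= cfg.uptake_zmin) & (zeta < cfg.uptake_zmax)).astype(float)


def _uptake_rate(n: np.ndarray, biomass: np.ndarray, active: np.ndarray,
                 cfg: ScenarioConfig) -> np.ndarray:
    """Instantaneous volumetric uptake (mmol N m-3 d-1) for one time step."""
    if cfg.uptake_mode == "none":
        return np.zeros_like(n)
    sat = np.where(n > 0, n / (n + cfg.half_saturation), 0.0)
    if cfg.uptake_mode == "prescribed":
        overlap = 1.0
    else:  # biomass-limited
        overlap = np.clip(biomass / cfg.biomass_ref, 0.0, 1.0)
    return cfg.uptake_max * sat * overlap * active


def apply_uptake(nitrate_adv: np.ndarray, biomass: np.ndarray,
                 t_days: np.ndarray, zeta: np.ndarray, cfg: ScenarioConfig):
    """Apply biological uptake to an advected nitrate field.

    Parameters
    ----------
    nitrate_adv : (nz, nt) array
        Nitrate the water would carry in the absence of biology (the
        advective component; may vary in time through spice).
    biomass : (nz, nt) array
        Chlorophyll standing stock (mg m-3) controlling the uptake overlap.
    t_days, zeta : 1-D arrays
        Time (days) and material depth (m) grids.

    Returns
    -------
    nitrate : (nz, nt) array
        Advective nitrate minus accumulated loss, floored at zero.
    rho_true : (nz, nt) array
        Instantaneous uptake rate actually applied (mmol N m-3 d-1).
    nloss_true : (nz, nt) array
        Trapezoidal time integral of ``rho_true`` (mmol N m-3).
    """
    nitrate_adv = np.asarray(nitrate_adv, dtype=float)
    if np.any(nitrate_adv < 0):
        raise ValueError("negative input nitrate")
    nz, nt = nitrate_adv.shape
    active = _active_mask(zeta, cfg)

    rho = np.zeros((nz, nt))
    loss = np.zeros(nz)  # Euler-accumulated loss, used for the nitrate state
    nitrate = np.empty((nz, nt))
    for i in range(nt):
        n_now = np.maximum(nitrate_adv[:, i] - loss, 0.0)
        nitrate[:, i] = n_now
        rho[:, i] = _uptake_rate(n_now, biomass[:, i], active, cfg)
        if i < nt - 1:
            dt = t_days[i + 1] - t_days[i]
            loss = loss + rho[:, i] * dt  # monotone: uptake stops at exhaustion
    dt_arr = np.diff(t_days)
    nloss = np.zeros((nz, nt))
    if nt > 1:
        increments = 0.5 * (rho[:, :-1] + rho[:, 1:]) * dt_arr[None, :]
        nloss[:, 1:] = np.cumsum(increments, axis=1)
    return nitrate, rho, nloss


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def generate_scenario(cfg: ScenarioConfig) -> tuple[xr.Dataset, xr.Dataset]:
    """Generate a profiler-like dataset plus its ground truth.

    Returns ``(profiles, truth)``: ``profiles`` is a CF-style depth x time
    Dataset of noisy sensor fields on the fixed grid; ``truth`` carries the
    noise-free material-frame fields the recovery tests score against.
    """
    cfg.validate()
    zeta = np.arange(0.0, cfg.depth_max + cfg.dz / 2, cfg.dz)
    t = np.arange(0.0, cfg.span_days + 1e-9, cfg.dt_minutes / (24 * 60.0))
    nz, nt = zeta.size, t.size
    rng = np.random.default_rng(cfg.seed)

    # background + spice (material frame)
    t_bg = cfg.background_temperature(zeta)
    sigma_bg = cfg.background_sigma(zeta)
    s_bg = cfg.salinity_from_t_sigma(t_bg, sigma_bg)
    d_t, d_s = _spice_anomaly(cfg, zeta, t)
    temp_m = t_bg[:, None] + d_t
    sal_m = s_bg[:, None] + d_s
    sigma_m = cfg.sigma_from_t_s(temp_m, sal_m)   # == sigma_bg by construction
    spice_true = (cfg.eos_alpha * temp_m + cfg.eos_beta * sal_m)

    # advective nitrate component: climatological function of temperature
    nitrate_adv = cfg.climatological_nitrate(temp_m)

    # migrating layer + uptake with Chl:N growth feedback
    z_c = dvm_trajectory(t, cfg)
    shape = np.exp(-0.5 * ((zeta[:, None] - z_c[None, :]) / cfg.layer_sigma) ** 2)
    # conserve layer mass where the Gaussian is truncated at the surface:
    # organisms pile up against the boundary instead of vanishing
    norm = cfg.layer_sigma * np.sqrt(2.0 * np.pi)
    mass = np.trapezoid(shape, zeta, axis=0) / norm
    shape = shape / mass[None, :]
    active = _active_mask(zeta, cfg)

    amp = np.empty(nt)
    rho = np.zeros((nz, nt))
    loss = np.zeros(nz)
    nitrate_m = np.empty((nz, nt))
    integ_rho = np.zeros(nt)  # instantaneous column uptake, mmol N m-2 d-1
    cum_column = 0.0          # mmol N m-2 taken up so far
    for i in range(nt):
        amp[i] = cfg.chl_amplitude + cfg.chl_per_n * cum_column / norm
        biomass_i = amp[i] * shape[:, i]
        n_now = np.maximum(nitrate_adv[:, i] - loss, 0.0)
        nitrate_m[:, i] = n_now
        rho[:, i] = _uptake_rate(n_now, biomass_i, active, cfg)
        integ_rho[i] = np.trapezoid(rho[:, i], zeta)
        if i < nt - 1:
            dt = t[i + 1] - t[i]
            loss = loss + rho[:, i] * dt
            cum_column += 0.5 * (integ_rho[i] + np.trapezoid(
                _uptake_rate(np.maximum(nitrate_adv[:, i + 1] - loss, 0.0),
                             amp[i] * shape[:, i + 1], active, cfg), zeta)) * dt
    nloss_true = np.zeros((nz, nt))
    if nt > 1:
        inc = 0.5 * (rho[:, :-1] + rho[:, 1:]) * np.diff(t)[None, :]
        nloss_true[:, 1:] = np.cumsum(inc, axis=1)

    chl_m = cfg.chl_background + amp[None, :] * shape

    # map material fields onto the fixed depth grid through the IW heaving
    eta = isopycnal_displacement(cfg, zeta, t)
    fields_m = {
        "temperature": temp_m,
        "salinity": sal_m,
        "nitrate": nitrate_m,
        "chl": chl_m,
    }
    fields_e = {k: np.empty((nz, nt)) for k in fields_m}
    for i in range(nt):
        z_of_zeta = zeta + eta[:, i]
        for k, fm in fields_m.items():
            fields_e[k][:, i] = np.interp(zeta, z_of_zeta, fm[:, i])

    chl_e = fields_e["chl"]
    bb_e = cfg.bb_dark + cfg.bb_per_chl * chl_e

    # light: diurnal surface cycle attenuated by water + chlorophyll
    hour = (t % 1.0) * 24.0
    daylen = cfg.day_end_hour - cfg.day_start_hour
    solar = np.sin(np.pi * (hour - cfg.day_start_hour) / daylen)
    par0 = cfg.par_surface_max * np.clip(solar, 0.0, None)
    kd = cfg.kd_water + cfg.kd_chl * chl_e
    tau = np.zeros((nz, nt))
    tau[1:, :] = np.cumsum(0.5 * (kd[:-1, :] + kd[1:, :]) * cfg.dz, axis=0)
    par = par0[None, :] * np.exp(-tau)

    # fluorescence with non-photochemical quenching where light is strong
    quench = np.ones_like(par)
    lit = par > cfg.npq_par_threshold
    quench[lit] = 1.0 - cfg.npq_strength * (1.0 - cfg.npq_par_threshold / par[lit])
    fluor = chl_e * quench

    # irradiance channels split the PAR signal with fixed spectral fractions
    nch = cfg.n_irradiance_channels
    fracs = np.linspace(1.5, 0.5, nch)
    fracs /= fracs.sum()
    channels = par[None, :, :] * fracs[:, None, None]

    # sensor noise, added after ground truth is frozen
    temp_n = fields_e["temperature"] + rng.normal(0, cfg.noise_t, (nz, nt))
    sal_n = fields_e["salinity"] + rng.normal(0, cfg.noise_s, (nz, nt))
    nitr_n = fields_e["nitrate"] + rng.normal(0, cfg.noise_nitrate, (nz, nt))
    fluor_n = fluor + rng.normal(0, cfg.noise_chl, (nz, nt))
    bb_n = bb_e + rng.normal(0, cfg.noise_bb, (nz, nt))
    sigma_n = cfg.sigma_from_t_s(temp_n, sal_n)

    coords = {"depth": ("depth", zeta, {"units": "m", "positive": "down"}),
              "time": ("time", t,
                       {"units": "days",
                        "long_name": "days since deployment (local midnight)"})}
    profiles = xr.Dataset(
        {
            "temperature": (("depth", "time"), temp_n, {"units": "degC"}),
            "salinity": (("depth", "time"), sal_n, {"units": "1"}),
            "sigma_theta": (("depth", "time"), sigma_n, {"units": "kg m-3"}),
            "nitrate": (("depth", "time"), nitr_n, {"units": "mmol m-3"}),
            "chl_fluor": (("depth", "time"), fluor_n, {"units": "mg m-3"}),
            "backscatter": (("depth", "time"), bb_n, {"units": "m-1 sr-1"}),
            "irradiance": (("channel", "depth", "time"), channels,
                           {"units": "relative"}),
        },
        coords={**coords, "channel": np.arange(nch)},
        attrs={
            "local_midnight_offset_days": 0.0,
            "title": "synthetic moored-profiler bloom scenario",
            "seed": cfg.seed,
        },
    )
    truth = xr.Dataset(
        {
            "displacement": (("depth", "time"), eta, {"units": "m"}),
            "rho_true": (("depth", "time"), rho, {"units": "mmol N m-3 d-1"}),
            "nloss_true": (("depth", "time"), nloss_true, {"units": "mmol N m-3"}),
            "spice_true": (("depth", "time"), spice_true, {"units": "kg m-3"}),
            "nitrate_true": (("depth", "time"), nitrate_m, {"units": "mmol m-3"}),
            "chl_true": (("depth", "time"), chl_m, {"units": "mg m-3"}),
            "layer_depth": (("time",), z_c, {"units": "m"}),
            "chl_amplitude": (("time",), amp, {"units": "mg m-3"}),
            "column_uptake": (("time",), integ_rho,
                              {"units": "mmol N m-2 d-1"}),
        },
        coords=coords,
        attrs={"frame": "material (mean-isopycnal depth)"},
    )
    return profiles, truth
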