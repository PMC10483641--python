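"""Configuration objects for the synthetic ocean and the analysis chain.

Two dataclasses hold every tunable: :class:`ScenarioConfig` for the synthetic
profiler scenario and :class:`AnalysisConfig` for the analysis stages.
:class:`RunConfig` bundles both with run-level options (stage toggles, seed,
output paths) and round-trips to YAML.  Loading is strict: unknown keys raise
:class:`ConfigError` before any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class IWComponent:
    """One internal-wave constituent heaving the water column.

    ``amplitude`` is the displacement amplitude in metres at the maximum of the
    vertical mode shape, so the peak-to-trough isopycnal excursion is twice the
    amplitude.  ``period_hours`` is the wave period; the default is the
    semidiurnal internal tide.
    """

    amplitude: float = 10.0
    period_hours: float = 12.42
    phase: float = 0.0


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic moored-profiler scenario.

    Defaults emulate the observed bloom conditions: 100 m of water profiled at
    1-m / 15-min resolution for two weeks, ~20 m peak-to-trough internal-wave
    displacements, an 18-h along-isopycnal advection cycle expressed as
    density-compensated spice anomalies, a chlorophyll layer descending at
    380 um/s from 18:00 local, and saturating nitrate uptake in the
    subeuphotic layer.
    """

    # grids
    depth_max: float = 100.0          # m
    dz: float = 1.0                   # m
    span_days: float = 14.0
    dt_minutes: float = 15.0

    # background hydrography (material/mean-isopycnal coordinate)
    sigma_surface: float = 24.40      # kg m-3, potential density anomaly at z=0
    sigma_gradient: float = 0.008     # kg m-3 per m, linear part
    sigma_step: float = 0.50          # kg m-3, tanh pycnocline step
    pycnocline_depth: float = 24.0    # m
    pycnocline_width: float = 7.0     # m
    t_surface: float = 19.0           # degC
    t_gradient: float = 0.02          # degC per m, linear part
    t_step: float = 8.0               # degC, total tanh decrease across pycnocline

    # linear equation of state sigma = sigma_c - alpha (T - T_c) + beta (S - S_c)
    eos_alpha: float = 0.20           # kg m-3 per degC
    eos_beta: float = 0.78            # kg m-3 per salinity unit
    eos_t_ref: float = 14.0
    eos_s_ref: float = 33.4
    eos_sigma_ref: float = 25.2

    # climatological nitrate-temperature line (valid below the cutoff)
    clim_slope: float = -5.9          # mmol m-3 per degC
    clim_intercept: float = 80.94     # mmol m-3
    nitrate_offset: float = 0.0       # mmol m-3 added everywhere (scenario dial)

    # internal waves
    iw_components: list[IWComponent] = field(
        default_factory=lambda: [IWComponent()]
    )

    # along-isopycnal advection expressed as an oscillating spice anomaly
    advection_period_hours: float = 18.0
    spice_amplitude: float = 0.04     # kg m-3, peak spice anomaly

    # diel vertical migration of the chlorophyll layer (material frame)
    residence_depth: float = 2.0      # m, daytime depth of the layer centre
    descent_speed_um_s: float = 380.0
    ascent_speed_um_s: float = 1520.0
    descent_start_hour: float = 18.0  # local time
    dvm_floor_depth: float = 30.0     # m, nitracline depth the descent stops at
    layer_sigma: float = 3.0          # m, Gaussian half-width of the layer

    # nitrate uptake
    uptake_mode: str = "biomass"      # "biomass" | "prescribed" | "none"
    uptake_max: float = 6.0           # mmol N m-3 d-1
    uptake_zmin: float = 20.0         # m, active range (material frame)
    uptake_zmax: float = 40.0
    half_saturation: float = 0.5      # mmol m-3
    biomass_ref: float = 8.0          # mg Chl m-3 at which uptake saturates

    # biology / optics
    chl_background: float = 0.3       # mg m-3
    chl_amplitude: float = 8.0        # mg m-3, initial layer peak
    chl_per_n: float = 0.19           # mg Chl per mmol N taken up
    bb_dark: float = 1.0e-4           # m-1 sr-1
    bb_per_chl: float = 2.0e-3        # m-1 sr-1 per mg m-3
    par_surface_max: float = 2000.0   # umol photons m-2 s-1 (relative units)
    kd_water: float = 0.12            # m-1 (turbid coastal water)
    kd_chl: float = 0.035             # m-1 per mg m-3
    day_start_hour: float = 6.0
    day_end_hour: float = 18.0
    n_irradiance_channels: int = 3
    npq_strength: float = 0.4         # fractional daytime fluorescence quenching
    npq_par_threshold: float = 100.0  # PAR above which quenching acts

    # sensor noise (1 SD, i.i.d. Gaussian per gridded sample)
    noise_nitrate: float = 0.3        # mmol m-3
    noise_chl: float = 0.1            # mg m-3
    noise_t: float = 0.002            # degC
    noise_s: float = 0.002
    noise_bb: float = 2.0e-5          # m-1 sr-1

    seed: int = 0

    def validate(self) -> None:
        if self.dz <= 0 or self.dt_minutes <= 0 or self.span_days <= 0:
            raise ConfigError("grid steps and span must be positive")
        if self.descent_speed_um_s < 0 or self.ascent_speed_um_s < 0:
            raise ConfigError("migration speeds must be non-negative")
        if self.dvm_floor_depth > self.depth_max:
            raise ConfigError("DVM layer floor deeper than the depth grid")
        if self.residence_depth > self.dvm_floor_depth:
            raise ConfigError("residence depth must be above the DVM floor")
        # background density must be strictly increasing with depth
        import numpy as np

        z = np.arange(0.0, self.depth_max + self.dz, self.dz)
        sig = self.background_sigma(z)
        if not np.all(np.diff(sig) > 0):
            raise ConfigError("background density is not strictly increasing")
        if self.uptake_mode not in ("biomass", "prescribed", "none"):
            raise ConfigError(f"unknown uptake_mode {self.uptake_mode!r}")

    # -- background profiles (material coordinate zeta, positive down) --
    def background_sigma(self, z):
        import numpy as np

        step = 0.5 * self.sigma_step * (
            1.0 + np.tanh((z - self.pycnocline_depth) / self.pycnocline_width)
        )
        return self.sigma_surface + self.sigma_gradient * z + step

    def background_temperature(self, z):
        import numpy as np

        step = 0.5 * self.t_step * (
            1.0 + np.tanh((z - self.pycnocline_depth) / self.pycnocline_width)
        )
        return self.t_surface - self.t_gradient * z - step

    def salinity_from_t_sigma(self, t, sigma):
        """Invert the linear EOS for salinity."""
        return self.eos_s_ref + (
            sigma - self.eos_sigma_ref + self.eos_alpha * (t - self.eos_t_ref)
        ) / self.eos_beta

    def sigma_from_t_s(self, t, s):
        return (
            self.eos_sigma_ref
            - self.eos_alpha * (t - self.eos_t_ref)
            + self.eos_beta * (s - self.eos_s_ref)
        )

    def climatological_nitrate(self, t):
        """Clipped climatological nitrate as a function of temperature."""
        import numpy as np

        return np.clip(self.clim_slope * t + self.clim_intercept, 0.0, None) + (
            self.nitrate_offset
        )


@dataclass
class AnalysisConfig:
    """Parameters of the analysis stages.

    Defaults reproduce the study constants: 0.02 kg m-3 density bins,
    0.005 kg m-3 spice bins, 0.25 degC x 1 mmol m-3 climatology bins and the
    0-33 m depth-integration range.
    """

    # sensor processing
    despike_window: int = 5
    despike_nmad: float = 5.0
    detection_limit: float = 0.5       # mmol m-3
    nitrate_se: float = 0.3            # mmol m-3, assumed sensor precision (1 SD)
    npq_par_threshold: float = 100.0
    npq_scaling_layer: float = 5.0     # m below the quenching depth used for ratio
    par_weights: Sequence[float] | None = None  # None -> equal weights
    par_reference_depth: float = 0.0   # m, reference for the 1% light level
    turbidity_gain: float = 200.0      # NTU per (m-1 sr-1)
    turbidity_offset: float = 1.0e-4   # m-1 sr-1 dark offset

    # isopycnal mapping
    density_bin_width: float = 0.02    # kg m-3
    max_inversion: float = 0.05        # kg m-3; larger inversions flag a profile

    # water-mass tracking
    spice_bin_width: float = 0.005     # kg m-3
    spice_mode: str = "linear"         # "linear" (alpha'T + beta'S)
    spice_alpha: float = 0.20          # kg m-3 per degC
    spice_beta: float = 0.78           # kg m-3 per salinity unit
    merge_gap_steps: int = 2           # grid steps bridged inside one visit
    max_pair_gap_days: float = 2.0
    min_pair_dt_days: float = 2.0 / 24.0  # a reappearance needs real absence
    min_visit_samples: int = 1

    # nitrate budget
    dt_days: float = 15.0 / (24 * 60)  # uniform iteration step (native grid)
    gap_limit_days: float = 1.0        # longest gap filled by interpolation
    zmin: float = 0.0                  # m, depth-integration range
    zmax: float = 33.0

    # climatology
    t_bin: float = 0.25                # degC
    n_bin: float = 1.0                 # mmol m-3
    t_cutoff: float = 14.0             # degC, fit validity limit
    clim_window_days: float = 1.0      # early window used as in-record baseline

    # bloom metrics
    corr_bin_days: float = 1.0         # averaging window for gain/loss series
    centroid_quantile: float = 0.75
    descent_fit_start_hours: float = 2.0  # after descent start
    ratio_mode: str = "molar_n_per_mass_chl"

    def validate(self) -> None:
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise ConfigError("despike window must be odd and >= 3")
        if self.density_bin_width <= 0 or self.spice_bin_width <= 0:
            raise ConfigError("bin widths must be positive")
        if self.dt_days <= 0:
            raise ConfigError("dt must be positive")
        if self.zmax <= self.zmin:
            raise ConfigError("depth-integration range is empty")
        if self.spice_mode not in ("linear", "polynomial"):
            raise ConfigError(f"unknown spice_mode {self.spice_mode!r}")


@dataclass
class RunConfig:
    """Full pipeline run: scenario + analysis + orchestration options."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate",
            "preprocess",
            "isopycnal",
            "track",
            "nitrate-loss",
            "climatology",
            "report",
        ]
    )
    input_path: str | None = None      # NetCDF input when simulate is off
    seed: int | None = None            # overrides scenario.seed when given
    log_level: str = "INFO"

    def validate(self) -> None:
        self.scenario.validate()
        self.analysis.validate()
        known = {
            "simulate", "preprocess", "isopycnal", "track",
            "nitrate-loss", "climatology", "report",
        }
        bad = [s for s in self.stages if s not in known]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        if "simulate" not in self.stages and self.input_path is None:
            raise ConfigError("need input_path when the simulate stage is off")

    def config_hash(self) -> str:
        payload = json.dumps(_as_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_dict(v) for v in obj]
    return obj


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {type(data)}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if key == "scenario":
            value = _from_dict(ScenarioConfig, value)
        elif key == "analysis":
            value = _from_dict(AnalysisConfig, value)
        elif key == "iw_components":
            value = [
                v if isinstance(v, IWComponent) else _from_dict(IWComponent, v)
                for v in value
            ]
        kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (strict keys)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_dict(RunConfig, data)
    cfg.validate()
    return cfg


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_dict(ScenarioConfig, data)
    cfg.validate()
    return cfg


def save_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(cfg), fh, sort_keys=False)
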