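"""Shared fixtures: synthetic scenarios reused across the suite.

The heavier runs (full two-week no-uptake record, uniform-layer recovery
scenario, end-to-end pipeline) are generated once per session.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from dvmflux import (AnalysisConfig, NitrateLossModel, RunConfig,
                     ScenarioConfig, generate_scenario, run_pipeline)
from dvmflux.isopycnal import to_isopycnal
from dvmflux.sensors import preprocess

warnings.filterwarnings("ignore", message="Mean of empty slice")


def quiet_config(**overrides) -> ScenarioConfig:
    """Scenario with every noise source off."""
    base = dict(noise_nitrate=0.0, noise_chl=0.0, noise_t=0.0,
                noise_s=0.0, noise_bb=0.0)
    base.update(overrides)
    return ScenarioConfig(**base)


def recovery_config(**overrides) -> ScenarioConfig:
    """Uniform 6 mmol N m-3 d-1 uptake in a 10-m layer over 2.5 days.

    Nitrate is offset high so the whole column stays far above both the
    half-saturation constant and the detection limit: the realised uptake is
    saturating (~6 everywhere in the layer) and every isopycnal yields pairs.
    """
    base = dict(uptake_mode="prescribed", uptake_zmin=23.0, uptake_zmax=33.0,
                uptake_max=6.0, half_saturation=0.05, nitrate_offset=18.0,
                span_days=2.5)
    base.update(overrides)
    return ScenarioConfig(**base)


def analyse(profiles, config: AnalysisConfig | None = None):
    """profiles -> (clean, iso, fitted results)."""
    config = config or AnalysisConfig()
    clean = preprocess(profiles, config)
    iso = to_isopycnal(clean, config)
    model = NitrateLossModel(iso, config=config)
    return clean, iso, model.fit()


@pytest.fixture(scope="session")
def bloom_run():
    """Default two-week bloom scenario (profiles, truth)."""
    return generate_scenario(ScenarioConfig())


@pytest.fixture(scope="session")
def no_uptake_run():
    """Default IWs + advection + noise, but no biology removing nitrate."""
    cfg = ScenarioConfig(uptake_mode="none")
    profiles, truth = generate_scenario(cfg)
    clean, iso, results = analyse(profiles)
    return dict(cfg=cfg, profiles=profiles, truth=truth,
                clean=clean, iso=iso, results=results)


@pytest.fixture(scope="session")
def recovery_run():
    """Uniform-layer uptake scenario with the full analysis chain applied."""
    cfg = recovery_config()
    profiles, truth = generate_scenario(cfg)
    clean, iso, results = analyse(profiles)
    return dict(cfg=cfg, profiles=profiles, truth=truth,
                clean=clean, iso=iso, results=results)


@pytest.fixture(scope="session")
def pipeline_summary(tmp_path_factory):
    """Summary of a full default-configuration pipeline run."""
    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(RunConfig(), out), out
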