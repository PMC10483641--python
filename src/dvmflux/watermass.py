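"""Water-parcel identification by spice and reappearance pairing.

On a single isopycnal, water masses are distinguished by spice (the
temperature–salinity combination orthogonal to density).  Oscillating
along-isopycnal currents sweep the same parcels repeatedly past a mooring;
points falling in the same spice bin (default width 0.005 kg m-3) on an
isopycnal are taken to be the same water mass, and successive visits of a
parcel provide pairs of nitrate observations whose difference is free of
horizontal-advection artefacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .config import AnalysisConfig

__all__ = ["compute_spice", "spice_bin_labels", "find_reappearance_pairs"]


def compute_spice(temperature, salinity, cfg: AnalysisConfig | None = None):
    """Spice (kg m-3) from temperature and salinity.

    The default ``linear`` formulation is the density-orthogonal linear
    combination ``alpha' T + beta' S`` with the configured expansion
    coefficients; warm/salty water is spicier than cool/fresh water on the
    same isopycnal.  Cells with missing T or S come back NaN.
    """
    cfg = cfg or AnalysisConfig()
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if cfg.spice_mode == "linear":
        return cfg.spice_alpha * t + cfg.spice_beta * s
    raise NotImplementedError(
        "polynomial spice formulation requires a TEOS-10 library"
    )


def spice_bin_labels(spice: np.ndarray, width: float = 0.005,
                     origin: float = 0.0) -> np.ndarray:
    """Deterministic integer bin label per cell; NaN maps to the minimum int."""
    lab = np.floor((np.asarray(spice, dtype=float) - origin) / width)
    lab = np.where(np.isfinite(lab), lab, np.iinfo(np.int64).min)
    return lab.astype(np.int64)


def find_reappearance_pairs(iso: xr.Dataset,
                            cfg: AnalysisConfig | None = None,
                            spice_origin: float = 0.0) -> pd.DataFrame:
    """Extract nitrate observation pairs from water-mass reappearances.

    For every (density bin, spice bin) key, contiguous occurrences —
    allowing gaps up to ``merge_gap_steps`` grid steps — are collapsed into
    single *visits* (time: median, nitrate: mean over the samples, SE:
    assumed sensor precision / sqrt(n)).  Consecutive visits of a key form
    pairs; pairs closer than ``min_pair_dt_days`` (noise jitter across a bin
    edge is not a reappearance), farther than ``max_pair_gap_days``, or with
    either value below the detection limit are discarded.

    Returns a DataFrame with columns ``sigma_bin, spice_bin, t1, t2, dt,
    n1, n2, se1, se2, m1, m2`` (m* = samples per visit).
    """
    cfg = cfg or AnalysisConfig()
    spice = compute_spice(iso["temperature"].values, iso["salinity"].values, cfg)
    labels = spice_bin_labels(spice, cfg.spice_bin_width, spice_origin)
    nitrate = iso["nitrate"].values
    valid = iso["valid"].values & np.isfinite(nitrate)
    t = iso["time"].values
    bins = iso["sigma_bin"].values
    sentinel = np.iinfo(np.int64).min

    rows = []
    for b in range(bins.size):
        lab = np.where(valid[b], labels[b], sentinel)
        for key in np.unique(lab):
            if key == sentinel:
                continue
            idx = np.flatnonzero(lab == key)
            if idx.size < cfg.min_visit_samples:
                continue
            # split into visits where the gap exceeds the merge threshold
            breaks = np.flatnonzero(np.diff(idx) > cfg.merge_gap_steps + 1)
            visits = np.split(idx, breaks + 1)
            collapsed = []
            for v in visits:
                if v.size < cfg.min_visit_samples:
                    continue
                collapsed.append((
                    float(np.median(t[v])),
                    float(np.mean(nitrate[b, v])),
                    cfg.nitrate_se / np.sqrt(v.size),
                    v.size,
                ))
            for (t1, n1, se1, m1), (t2, n2, se2, m2) in zip(collapsed,
                                                            collapsed[1:]):
                dt = t2 - t1
                if dt < cfg.min_pair_dt_days or dt > cfg.max_pair_gap_days:
                    continue
                if n1 < cfg.detection_limit or n2 < cfg.detection_limit:
                    continue
                rows.append((bins[b], int(key), t1, t2, dt,
                             n1, n2, se1, se2, m1, m2))
    return pd.DataFrame(
        rows,
        columns=["sigma_bin", "spice_bin", "t1", "t2", "dt",
                 "n1", "n2", "se1", "se2", "m1", "m2"],
    )
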