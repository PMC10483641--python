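"""Sensor stream processing: nitrate QC, quenching correction, PAR, turbidity.

These are the standard cleaning steps between raw optical/chemical sensor
output and the gridded fields the analysis consumes.  Each routine is a
documented conventional choice (running-median/MAD despiking, a
backscatter-ratio non-photochemical-quenching correction, configurable
spectral weights for PAR, affine turbidity scaling) exposed behind config
switches so alternatives can be substituted.

Flag conventions (integer masks alongside the data):

====  =========================
0     good
1     despiked (value replaced)
2     below detection limit (value set to 0; excluded from log-space fits)
3     unusable / missing
4     quenching-corrected
5     correction skipped (no backscatter signal)
====  =========================
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .config import AnalysisConfig

FLAG_GOOD = 0
FLAG_DESPIKED = 1
FLAG_BELOW_DETECTION = 2
FLAG_UNUSABLE = 3
FLAG_NPQ_CORRECTED = 4
FLAG_NPQ_SKIPPED = 5

__all__ = [
    "despike",
    "burst_average",
    "qc_nitrate",
    "correct_npq",
    "compute_par",
    "near_surface_par",
    "euphotic_depth",
    "estimate_turbidity",
    "preprocess",
]


def despike(values: np.ndarray, window: int = 5, nmad: float = 5.0):
    """Replace running-median outliers by the local median.

    A sample is a spike when its residual from the centred running median
    exceeds ``nmad`` times the median absolute residual of the series.
    Returns ``(cleaned, spike_mask)``.  Idempotent: residuals of an already
    cleaned series no longer exceed the threshold.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = np.asarray(values, dtype=float)
    if x.size < window:
        return x.copy(), np.zeros(x.size, dtype=bool)
    from scipy.ndimage import median_filter

    med = median_filter(x, size=window, mode="nearest")
    resid = x - med
    mad = np.median(np.abs(resid))
    spikes = np.abs(resid) > nmad * mad
    cleaned = np.where(spikes, med, x)
    return cleaned, spikes


def burst_average(depths: np.ndarray, values: np.ndarray, dz: float = 1.0):
    """Average burst samples into depth cells of width ``dz``.

    Returns ``(cell_depths, means, counts)`` for occupied cells, cell centres
    at ``(k + 0.5) * dz``.
    """
    depths = np.asarray(depths, dtype=float)
    values = np.asarray(values, dtype=float)
    idx = np.floor(depths / dz).astype(int)
    out_z, out_v, out_n = [], [], []
    for k in np.unique(idx):
        sel = idx == k
        out_z.append((k + 0.5) * dz)
        out_v.append(values[sel].mean())
        out_n.append(int(sel.sum()))
    return np.array(out_z), np.array(out_v), np.array(out_n)


def qc_nitrate(values: np.ndarray, cfg: AnalysisConfig | None = None):
    """Quality-control one nitrate profile.

    Despikes with the running-median/MAD rule, then flags values below the
    detection limit (``FLAG_BELOW_DETECTION``), setting them to 0 for display;
    downstream log-space fitting excludes them.  Returns ``(cleaned, flags)``.
    A profile whose samples are all flagged is unusable.
    """
    cfg = cfg or AnalysisConfig()
    x = np.asarray(values, dtype=float)
    flags = np.zeros(x.size, dtype=np.int8)
    bad = ~np.isfinite(x)
    flags[bad] = FLAG_UNUSABLE
    cleaned = x.copy()
    good = ~bad
    if good.sum() >= cfg.despike_window:
        # iterate the median/MAD rule to a fixed point so QC is idempotent
        work = x[good]
        gflags = flags[good]
        for _ in range(20):
            work, spikes = despike(work, cfg.despike_window, cfg.despike_nmad)
            gflags[spikes] = FLAG_DESPIKED
            if not spikes.any():
                break
        cleaned[good] = work
        flags[good] = gflags
    below = good & (cleaned < cfg.detection_limit)
    cleaned[below] = 0.0
    flags[below] = FLAG_BELOW_DETECTION
    return cleaned, flags


def correct_npq(chl: np.ndarray, par: np.ndarray, backscatter: np.ndarray,
                depth: np.ndarray, is_day: np.ndarray,
                cfg: AnalysisConfig | None = None):
    """Correct daytime fluorescence for non-photochemical quenching.

    For each daytime profile, fluorescence above the quenching depth (the
    deepest depth where PAR still exceeds ``npq_par_threshold``) is replaced
    by backscatter scaled with that profile's chl:backscatter ratio evaluated
    just below the quenching depth.  The correction never reduces the
    measured value; nighttime profiles pass through untouched.  Returns
    ``(corrected, flags)`` with flags per cell.
    """
    cfg = cfg or AnalysisConfig()
    chl = np.asarray(chl, dtype=float)
    out = chl.copy()
    flags = np.zeros(chl.shape, dtype=np.int8)
    for j in range(chl.shape[1]):
        if not is_day[j]:
            continue
        lit = par[:, j] > cfg.npq_par_threshold
        if not lit.any():
            continue
        z_q = depth[lit].max()
        scale_sel = (depth > z_q) & (depth <= z_q + cfg.npq_scaling_layer)
        bb_ref = backscatter[scale_sel, j]
        chl_ref = chl[scale_sel, j]
        if bb_ref.size == 0 or np.all(bb_ref <= 0):
            flags[depth <= z_q, j] = FLAG_NPQ_SKIPPED
            continue
        ratio = chl_ref.sum() / bb_ref.sum()
        above = depth <= z_q
        proxy = backscatter[above, j] * ratio
        corrected = np.maximum(chl[above, j], proxy)
        changed = corrected > chl[above, j]
        out[above, j] = corrected
        col = flags[above, j]
        col[changed] = FLAG_NPQ_CORRECTED
        flags[above, j] = col
    return out, flags


def compute_par(channels: np.ndarray, weights=None):
    """PAR as a weighted sum of irradiance channels.

    ``channels`` has the channel axis first.  ``weights=None`` uses equal
    weights normalised to one (so n identical channels give back the channel
    value); explicit weights are applied as given.
    """
    channels = np.asarray(channels, dtype=float)
    nch = channels.shape[0]
    if nch == 0:
        raise ValueError("need at least one irradiance channel")
    if weights is None:
        weights = np.full(nch, 1.0 / nch)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.size != nch:
            raise ValueError("one weight per channel required")
    return np.tensordot(weights, channels, axes=1)


def near_surface_par(par: np.ndarray, depth: np.ndarray, at: float = 2.0):
    """PAR time series at the grid cell nearest the requested depth."""
    i = int(np.argmin(np.abs(np.asarray(depth) - at)))
    return np.asarray(par)[i]


def euphotic_depth(par_profile: np.ndarray, depth: np.ndarray,
                   reference_depth: float = 0.0, fraction: float = 0.01):
    """Depth of the 1% light level.

    Shallowest depth where PAR drops below ``fraction`` of its value at the
    reference depth, interpolated linearly in log(PAR) between grid cells
    (exact for exponential attenuation).  Scaling the whole profile by a
    positive constant leaves the result unchanged.

    Returns ``(depth_m, resolved)``; when the profile never drops below the
    threshold the grid bottom is returned with ``resolved=False``.
    """
    par = np.asarray(par_profile, dtype=float)
    depth = np.asarray(depth, dtype=float)
    i_ref = int(np.argmin(np.abs(depth - reference_depth)))
    p_ref = par[i_ref]
    if not (p_ref > 0):
        raise ValueError("PAR must be positive at the reference depth")
    threshold = fraction * p_ref
    below = (par < threshold) & (depth >= depth[i_ref])
    if not below.any():
        return float(depth[-1]), False
    j = int(np.argmax(below))  # first crossing
    if j == 0:
        return float(depth[0]), True
    p0, p1 = par[j - 1], par[j]
    if p1 <= 0 or p0 <= 0:
        return float(depth[j]), True
    f = (np.log(p0) - np.log(threshold)) / (np.log(p0) - np.log(p1))
    return float(depth[j - 1] + f * (depth[j] - depth[j - 1])), True


def estimate_turbidity(backscatter: np.ndarray, cfg: AnalysisConfig | None = None):
    """Affine turbidity proxy from optical backscatter.

    turbidity = gain * (backscatter - dark offset), clipped at zero; clipped
    cells are flagged.  Returns ``(turbidity, flags)``.
    """
    cfg = cfg or AnalysisConfig()
    bb = np.asarray(backscatter, dtype=float)
    raw = cfg.turbidity_gain * (bb - cfg.turbidity_offset)
    flags = np.where(raw < 0, FLAG_BELOW_DETECTION, FLAG_GOOD).astype(np.int8)
    return np.clip(raw, 0.0, None), flags


def preprocess(profiles: xr.Dataset, cfg: AnalysisConfig | None = None) -> xr.Dataset:
    """Run the full sensor chain on a gridded profile dataset.

    Adds ``par``, ``turbidity``, corrected ``chl`` and per-variable flag
    fields; nitrate is despiked and detection-limited per profile.
    """
    cfg = cfg or AnalysisConfig()
    ds = profiles.copy(deep=True)
    depth = ds["depth"].values
    t = ds["time"].values

    par = compute_par(ds["irradiance"].values, cfg.par_weights)
    ds["par"] = (("depth", "time"), par, {"units": "relative"})

    nitr = ds["nitrate"].values
    nflags = np.zeros(nitr.shape, dtype=np.int8)
    for j in range(nitr.shape[1]):
        nitr[:, j], nflags[:, j] = qc_nitrate(nitr[:, j], cfg)
    ds["nitrate"] = (("depth", "time"), nitr, {"units": "mmol m-3"})
    ds["nitrate_flag"] = (("depth", "time"), nflags)

    hour = (t % 1.0) * 24.0
    is_day = (hour >= 6.0) & (hour < 18.0)
    chl, cflags = correct_npq(ds["chl_fluor"].values, par,
                              ds["backscatter"].values, depth, is_day, cfg)
    ds["chl"] = (("depth", "time"), chl, {"units": "mg m-3"})
    ds["chl_flag"] = (("depth", "time"), cflags)

    turb, tflags = estimate_turbidity(ds["backscatter"].values, cfg)
    ds["turbidity"] = (("depth", "time"), turb, {"units": "NTU"})
    ds["turbidity_flag"] = (("depth", "time"), tflags)
    ds.attrs["preprocessed"] = 1
    return ds
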