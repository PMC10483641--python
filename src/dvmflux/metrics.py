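"""Bloom diagnostics: integrated biomass, loss–gain correlation, descent speed.

These connect the nitrate budget back to the organisms: depth-integrated
chlorophyll and turbidity track standing stock, their increases should be
proportional to the integrated nitrate loss if the loss is biological, the
descent speed of the chlorophyll layer identifies the migration, and the
N:Chl yield closes the elemental budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .config import AnalysisConfig

__all__ = [
    "integrate_biomass",
    "correlate_gain_loss",
    "DescentTrack",
    "estimate_descent_speed",
    "n_to_chl_ratio",
]


def integrate_biomass(iso: xr.Dataset, var: str = "chl",
                      zmin: float = 0.0, zmax: float = 33.0,
                      min_valid_fraction: float = 0.5,
                      pad_edges: bool = True) -> pd.DataFrame:
    """Trapezoidal depth integral of a field over the mean-isopycnal axis.

    With ``pad_edges`` (default), the integrand is extended to the exact
    ``[zmin, zmax]`` bounds with its edge values: the density axis cannot
    resolve the weakly stratified surface layer, but the biomass it carries
    is real and would otherwise be clipped out of the integral.

    Returns ``time, value, n_bins, flagged`` (flagged when more than half of
    the in-range bins are invalid at that time step).
    """
    depth = iso["mean_depth"].values
    sel = np.flatnonzero((depth >= zmin) & (depth <= zmax) & np.isfinite(depth))
    if sel.size < 2:
        raise ValueError("fewer than two bins in the integration range")
    order = sel[np.argsort(depth[sel])]
    z = depth[order]
    vals = iso[var].values[order]
    valid = iso["valid"].values[order] if "valid" in iso else np.isfinite(vals)
    t = iso["time"].values
    out = []
    for j in range(t.size):
        ok = valid[:, j] & np.isfinite(vals[:, j])
        if ok.sum() < 2:
            out.append((t[j], np.nan, int(ok.sum()), True))
            continue
        zz, vv = z[ok], vals[ok, j]
        if pad_edges:
            if zz[0] > zmin:
                zz = np.concatenate([[zmin], zz])
                vv = np.concatenate([[vv[0]], vv])
            if zz[-1] < zmax:
                zz = np.concatenate([zz, [zmax]])
                vv = np.concatenate([vv, [vv[-1]]])
        out.append((
            t[j],
            float(np.trapezoid(vv, zz)),
            int(ok.sum()),
            ok.mean() < min_valid_fraction,
        ))
    return pd.DataFrame(out, columns=["time", "value", "n_bins", "flagged"])


def correlate_gain_loss(loss_series, gain_series):
    """Pearson correlation between integrated loss and biomass increase.

    Both inputs are aligned series (arrays or DataFrames with ``value`` /
    ``flagged`` columns); the gain series should already be expressed as the
    increase relative to the window start.  Returns ``(R, p, n)``.
    """
    x = _values(loss_series)
    y = _values(gain_series)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least three paired points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance series; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def _values(series):
    if isinstance(series, pd.DataFrame):
        v = series["value"].to_numpy(dtype=float)
        if "flagged" in series:
            v = np.where(series["flagged"].to_numpy(), np.nan, v)
        return v
    return np.asarray(series, dtype=float)


@dataclass
class DescentTrack:
    """Tracked descent of the chlorophyll layer over one migration window."""

    times: np.ndarray       # days
    depths: np.ndarray      # m, thresholded-centroid depth
    speed_um_s: float
    speed_se_um_s: float
    window: tuple[float, float]


def estimate_descent_speed(iso: xr.Dataset, window: tuple[float, float],
                           cfg: AnalysisConfig | None = None,
                           var: str = "chl") -> DescentTrack:
    """Descent speed of the chlorophyll layer from its thresholded centroid.

    For each profile in the window, the layer depth is the centroid (on the
    mean-isopycnal-depth axis) of the chlorophyll *excess* above the
    profile's ``centroid_quantile`` quantile — subtracting the threshold
    baseline keeps the near-uniform background from biasing the centroid
    toward mid-column.  An ordinary least-squares line of depth against time
    gives the speed.  Multiplying the field by a positive constant leaves
    the track unchanged.
    """
    cfg = cfg or AnalysisConfig()
    t = iso["time"].values
    depth = iso["mean_depth"].values
    chl = iso[var].values
    valid = iso["valid"].values if "valid" in iso else np.isfinite(chl)
    sel = np.flatnonzero((t >= window[0]) & (t <= window[1]))
    times, depths = [], []
    for j in sel:
        ok = valid[:, j] & np.isfinite(chl[:, j]) & np.isfinite(depth)
        if ok.sum() < 4:
            continue
        prof = chl[ok, j]
        z = depth[ok]
        thresh = np.quantile(prof, cfg.centroid_quantile)
        excess = np.clip(prof - thresh, 0.0, None)
        if np.count_nonzero(excess) < 2:
            continue
        times.append(t[j])
        depths.append(float(np.sum(z * excess) / np.sum(excess)))
    if len(times) < 5:
        raise ValueError("fewer than five usable track points")
    times = np.asarray(times)
    depths = np.asarray(depths)
    res = stats.linregress(times, depths)
    to_um_s = 1e6 / 86400.0  # m/day -> um/s
    return DescentTrack(times, depths, float(res.slope * to_um_s),
                        float(res.stderr * to_um_s), window)


def n_to_chl_ratio(total_nloss: float, total_chl_increase: float,
                   mode: str = "molar_n_per_mass_chl"):
    """Ratio of integrated nitrate loss to integrated chlorophyll increase.

    ``molar_n_per_mass_chl`` divides mmol N m-2 by mg Chl m-2; the
    ``mass_per_mass`` mode multiplies by the molar mass of nitrogen first.
    Returns ``(ratio, mode)``; a non-positive chlorophyll increase refuses
    the estimate.
    """
    if total_nloss <= 0 or total_chl_increase <= 0:
        raise ValueError("both totals must be positive")
    ratio = total_nloss / total_chl_increase
    if mode == "mass_per_mass":
        from .units import MOLAR_MASS_N

        ratio *= MOLAR_MASS_N
    elif mode != "molar_n_per_mass_chl":
        raise ValueError(f"unknown mode {mode!r}")
    return float(ratio), mode
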