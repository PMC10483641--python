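"""Remapping depth-coordinate fields onto uniform potential-density bins.

Internal waves heave tracers up and down with the isopycnals; interpolating
every profile onto a fixed set of density bins (default spacing
0.02 kg m-3) and plotting against the time-mean depth of each bin removes
that vertical motion.  A tracer carried on isopycnals becomes stationary in
these coordinates; the residual time variability is what the biology and the
along-isopycnal advection put there.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .config import AnalysisConfig

__all__ = ["density_bin_centers", "to_isopycnal", "mean_isopycnal_depth"]

_DEFAULT_VARS = ("temperature", "salinity", "nitrate", "chl", "turbidity")


def density_bin_centers(sigma_min: float, sigma_max: float,
                        width: float = 0.02) -> np.ndarray:
    """Uniform density-bin centres covering [sigma_min, sigma_max]."""
    lo = np.floor(sigma_min / width) * width
    hi = np.ceil(sigma_max / width) * width
    edges = np.arange(lo, hi + width / 2, width)
    return 0.5 * (edges[:-1] + edges[1:])


def to_isopycnal(ds: xr.Dataset, cfg: AnalysisConfig | None = None,
                 bin_centers: np.ndarray | None = None,
                 variables=None) -> xr.Dataset:
    """Interpolate each profile onto uniform density bins.

    Per profile, density is sorted non-decreasing (weak inversions are
    reordered; profiles with inversions larger than ``cfg.max_inversion``
    are flagged unusable) and every variable — including depth itself — is
    linearly interpolated onto the bin centres.  Bins outside the profile's
    observed density range are invalid.

    Returns a Dataset with dims ``(sigma_bin, time)``, the per-cell
    instantaneous depth ``depth_iso``, a boolean ``valid`` mask and the
    per-bin time-mean depth ``mean_depth``.
    """
    cfg = cfg or AnalysisConfig()
    sigma = ds["sigma_theta"].values
    depth = ds["depth"].values
    t = ds["time"].values
    nt = t.size
    if bin_centers is None:
        finite = np.isfinite(sigma)
        bin_centers = density_bin_centers(
            sigma[finite].min(), sigma[finite].max(), cfg.density_bin_width
        )
    nb = bin_centers.size
    variables = [v for v in (variables or _DEFAULT_VARS) if v in ds]

    out = {v: np.full((nb, nt), np.nan) for v in variables}
    depth_iso = np.full((nb, nt), np.nan)
    valid = np.zeros((nb, nt), dtype=bool)
    profile_ok = np.ones(nt, dtype=bool)

    for j in range(nt):
        x = sigma[:, j]
        good = np.isfinite(x)
        if good.sum() < 2:
            profile_ok[j] = False
            continue
        xg, zg = x[good], depth[good]
        drop = np.max(np.maximum.accumulate(xg) - xg)
        if drop > cfg.max_inversion:
            profile_ok[j] = False
            continue
        order = np.argsort(xg, kind="stable")
        xs, zs = xg[order], zg[order]
        in_range = (bin_centers >= xs[0]) & (bin_centers <= xs[-1])
        depth_iso[in_range, j] = np.interp(bin_centers[in_range], xs, zs)
        for v in variables:
            vals = ds[v].values[good, j][order]
            out[v][in_range, j] = np.interp(bin_centers[in_range], xs, vals)
        valid[in_range, j] = True

    iso = xr.Dataset(
        {v: (("sigma_bin", "time"), out[v], dict(ds[v].attrs)) for v in variables},
        coords={
            "sigma_bin": ("sigma_bin", bin_centers, {"units": "kg m-3"}),
            "time": ("time", t, dict(ds["time"].attrs)),
        },
        attrs={
            "density_bin_width": cfg.density_bin_width,
            "local_midnight_offset_days": ds.attrs.get(
                "local_midnight_offset_days", 0.0
            ),
        },
    )
    iso["depth_iso"] = (("sigma_bin", "time"), depth_iso, {"units": "m"})
    iso["valid"] = (("sigma_bin", "time"), valid)
    iso["profile_ok"] = (("time",), profile_ok)
    iso["mean_depth"] = (
        ("sigma_bin",),
        mean_isopycnal_depth(depth_iso, valid),
        {"units": "m", "long_name": "time-mean isopycnal depth"},
    )
    return iso


def mean_isopycnal_depth(depth_iso: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Time-mean depth per density bin over its valid occurrences.

    Bins never observed come back NaN and are excluded from the vertical
    axis downstream.
    """
    depth_iso = np.asarray(depth_iso, dtype=float)
    counts = valid.sum(axis=1)
    sums = np.where(valid, depth_iso, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
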