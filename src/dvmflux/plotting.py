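"""Diagnostic figures for loss fields and integrated series."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_loss_field", "plot_integrated_series"]


def plot_loss_field(results, var: str = "nloss", ax=None):
    """Pcolor of a loss-field variable against time and mean isopycnal depth."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    loss = results.loss
    depth = loss["mean_depth"].values
    order = np.argsort(depth)
    pcm = ax.pcolormesh(loss["time"].values, depth[order],
                        loss[var].values[order], shading="nearest")
    ax.invert_yaxis()
    ax.set_xlabel("time (days)")
    ax.set_ylabel("mean isopycnal depth (m)")
    label = loss[var].attrs.get("units", "")
    plt.colorbar(pcm, ax=ax, label=f"{var} ({label})")
    return ax


def plot_integrated_series(series, ax=None, label=None):
    """Depth-integrated series with its error band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ok = ~series["flagged"]
    t = series.loc[ok, "time"]
    v = series.loc[ok, "value"]
    ax.plot(t, v, label=label)
    if "se" in series:
        s = series.loc[ok, "se"]
        ax.fill_between(t, v - s, v + s, alpha=0.3)
    ax.set_xlabel("time (days)")
    if label:
        ax.legend()
    return ax
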