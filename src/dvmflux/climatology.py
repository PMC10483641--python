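"""Nitrate–temperature climatology: binned PDFs, line fit, deficit.

Below about 14 degC the nitrate–temperature relation of these coastal waters
is a remarkably stable straight line; binning observations into
0.25 degC x 1 mmol m-3 cells and fitting the cold-water branch gives a
climatological prediction against which a bloom-period nitrate *deficit* can
be measured cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .config import AnalysisConfig

__all__ = [
    "TNPDF",
    "build_tn_pdf",
    "fit_climatology_line",
    "nitrate_deficit",
    "ClimatologyModel",
    "ClimatologyResults",
]


@dataclass
class TNPDF:
    """Per-temperature-bin probability density of nitrate.

    ``pdf[i, j]`` is the probability of nitrate bin ``j`` given temperature
    bin ``i`` (each nonempty temperature column sums to one).  ``t_mean`` and
    ``n_mean`` are the per-column means of the raw samples — the regression
    below uses these, not the bin centres, so a noise-free linear relation is
    recovered exactly.
    """

    t_edges: np.ndarray
    n_edges: np.ndarray
    pdf: np.ndarray        # (n_t_bins, n_n_bins)
    counts: np.ndarray     # (n_t_bins,)
    t_mean: np.ndarray
    n_mean: np.ndarray

    @property
    def t_centers(self):
        return 0.5 * (self.t_edges[:-1] + self.t_edges[1:])

    @property
    def n_centers(self):
        return 0.5 * (self.n_edges[:-1] + self.n_edges[1:])


def build_tn_pdf(t_samples, n_samples, t_bin: float = 0.25,
                 n_bin: float = 1.0) -> TNPDF:
    """2-D histogram of paired (T, N) samples, column-normalised per T bin."""
    t = np.asarray(t_samples, dtype=float).ravel()
    n = np.asarray(n_samples, dtype=float).ravel()
    ok = np.isfinite(t) & np.isfinite(n)
    t, n = t[ok], n[ok]
    if t.size == 0:
        raise ValueError("no samples")
    t_edges = np.arange(np.floor(t.min() / t_bin) * t_bin,
                        t.max() + t_bin, t_bin)
    n_edges = np.arange(min(0.0, np.floor(n.min() / n_bin) * n_bin),
                        n.max() + n_bin, n_bin)
    hist, t_edges, n_edges = np.histogram2d(t, n, bins=[t_edges, n_edges])
    counts = hist.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pdf = np.where(counts[:, None] > 0, hist / counts[:, None], np.nan)
    idx = np.clip(np.digitize(t, t_edges) - 1, 0, counts.size - 1)
    t_mean = np.full(counts.size, np.nan)
    n_mean = np.full(counts.size, np.nan)
    for i in range(counts.size):
        sel = idx == i
        if sel.any():
            t_mean[i] = t[sel].mean()
            n_mean[i] = n[sel].mean()
    return TNPDF(t_edges, n_edges, pdf, counts, t_mean, n_mean)


class ClimatologyModel:
    """Weighted linear model of nitrate against temperature (cold branch)."""

    def __init__(self, t_samples, n_samples,
                 config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        self.pdf = build_tn_pdf(t_samples, n_samples,
                                self.config.t_bin, self.config.n_bin)

    def fit(self, t_cutoff: float | None = None) -> "ClimatologyResults":
        """Count-weighted least squares of per-bin mean N on per-bin mean T."""
        cfg = self.config
        cutoff = cfg.t_cutoff if t_cutoff is None else t_cutoff
        p = self.pdf
        use = (p.counts > 0) & (p.t_mean < cutoff)
        if use.sum() < 2:
            raise ValueError("fewer than two usable temperature bins below cutoff")
        x = p.t_mean[use]
        y = p.n_mean[use]
        w = p.counts[use]
        res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        return ClimatologyResults(
            model=self,
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            t_cutoff=cutoff,
            n_bins=int(use.sum()),
            rsquared=float(res.rsquared),
        )


@dataclass
class ClimatologyResults:
    """Fitted climatological nitrate–temperature line."""

    model: ClimatologyModel
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    t_cutoff: float
    n_bins: int
    rsquared: float

    def predict(self, t):
        """Climatological nitrate at temperature ``t`` (clipped at zero)."""
        return np.clip(self.slope * np.asarray(t, dtype=float)
                       + self.intercept, 0.0, None)

    def deficit(self, t, n):
        """Per-observation nitrate deficit relative to climatology.

        ``max(0, predicted(T) - N)``; undefined (NaN) at or above the fit's
        validity cutoff rather than zero.
        """
        t = np.asarray(t, dtype=float)
        n = np.asarray(n, dtype=float)
        d = np.maximum(self.predict(t) - n, 0.0)
        return np.where(t < self.t_cutoff, d, np.nan)

    def summary(self) -> str:
        return "\n".join([
            "Climatological nitrate-temperature fit",
            "=" * 48,
            f"N = {self.slope:.4f} T + {self.intercept:.4f}"
            f"   (T < {self.t_cutoff:g} degC)",
            f"slope SE     {self.slope_se:.4f}   intercept SE "
            f"{self.intercept_se:.4f}",
            f"T bins used  {self.n_bins}   weighted R^2 {self.rsquared:.4f}",
        ])


def fit_climatology_line(t_samples, n_samples, t_cutoff: float = 14.0,
                         config: AnalysisConfig | None = None
                         ) -> ClimatologyResults:
    """Functional wrapper: build the PDF and fit the cold-branch line."""
    return ClimatologyModel(t_samples, n_samples, config).fit(t_cutoff)


def nitrate_deficit(t, n, fit: ClimatologyResults):
    """Deficit of each observation relative to a fitted climatology line."""
    return fit.deficit(t, n)
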