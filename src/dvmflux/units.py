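"""Small unit helpers used across the package."""

from __future__ import annotations

import math

MOLAR_MASS_N = 14.007  # g mol-1

__all__ = ["MOLAR_MASS_N", "convert_flux_units", "umps_to_m_per_h",
           "round_sigfigs"]


def convert_flux_units(flux_mmol_m2_d: float, se: float | None = None):
    """Convert a nitrogen flux from mmol N m-2 d-1 to mg N m-2 d-1.

    Multiplies by the molar mass of nitrogen (14.007 g mol-1); a standard
    error converts identically.  Returns the value, or ``(value, se)`` when
    an SE is given.
    """
    value = flux_mmol_m2_d * MOLAR_MASS_N
    if se is None:
        return value
    return value, se * MOLAR_MASS_N


def umps_to_m_per_h(speed_um_s: float) -> float:
    """Convert a swimming speed from micrometres per second to metres per hour."""
    return speed_um_s * 1e-6 * 3600.0


def round_sigfigs(x: float, sig: int = 3) -> float:
    """Round to the given number of significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
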