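"""Worm-like chain elasticity: Marko-Siggia interpolation and segment fitting.

The tether stretch preceding each unbinding event is described by the
Marko-Siggia interpolation formula

    F(x) = (k_B T / Lp) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ],

with persistence length Lp and contour length Lc.  F is strictly increasing
in x and diverges as x -> Lc.  Units: nm, pN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.stats import linregress

from .constants import T_DEFAULT, thermal_energy

__all__ = [
    "wlc_force",
    "wlc_stiffness",
    "wlc_extension",
    "WlcFit",
    "fit_wlc_segment",
]


def wlc_force(extension, persistence_length: float, contour_length: float,
              temperature: float = T_DEFAULT):
    """Marko-Siggia WLC force (pN) at the given extension(s) in nm.

    Raises for extensions outside [0, Lc); the model diverges at the contour
    length and is undefined beyond it.
    """
    if persistence_length <= 0 or contour_length <= 0:
        raise ValueError("persistence and contour length must be positive")
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0) or np.any(x >= contour_length):
        raise ValueError(
            f"extension must lie in [0, Lc={contour_length}); got range "
            f"[{x.min() if x.size else 'empty'}, {x.max() if x.size else 'empty'}]"
        )
    kbt = thermal_energy(temperature)
    t = x / contour_length
    out = (kbt / persistence_length) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)
    return float(out) if np.isscalar(extension) else out


def _wlc_force_capped(x, persistence_length, contour_length, kbt, cap=0.9990):
    """Evaluation helper for fitting: clips x/Lc into [0, cap] so that the
    optimizer can probe trial contour lengths below the data range without
    overflowing."""
    t = np.clip(np.asarray(x, dtype=float) / contour_length, 0.0, cap)
    return (kbt / persistence_length) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)


def wlc_stiffness(extension, persistence_length: float, contour_length: float,
                  temperature: float = T_DEFAULT):
    """dF/dx of the Marko-Siggia force, pN/nm."""
    kbt = thermal_energy(temperature)
    t = np.asarray(extension, dtype=float) / contour_length
    out = (kbt / persistence_length) * (
        0.5 / (contour_length * (1.0 - t) ** 3) + 1.0 / contour_length
    )
    return float(out) if np.isscalar(extension) else out


def wlc_extension(force: float, persistence_length: float, contour_length: float,
                  temperature: float = T_DEFAULT) -> float:
    """Invert the Marko-Siggia relation: extension (nm) at a given force (pN)."""
    if force < 0:
        raise ValueError("force must be non-negative")
    if force == 0:
        return 0.0
    lo, hi = 0.0, contour_length * (1.0 - 1e-12)
    return brentq(
        lambda x: wlc_force(x, persistence_length, contour_length, temperature) - force,
        lo, hi, xtol=1e-12,
    )


@dataclass
class WlcFit:
    """Result of fitting a stretch segment preceding a rupture."""

    persistence_length: float  # nm
    contour_length: float      # nm
    rupture_force: float       # pN, raw force at the last point before the drop
    apparent_loading_rate: float  # pN/s
    fit_quality: float         # R^2 clipped to [0, 1]; 0 marks a failed fit


def fit_wlc_segment(separation, force, time=None, temperature: float = T_DEFAULT,
                    loading_fraction: float = 0.1, min_loading_points: int = 5) -> WlcFit:
    """Least-squares WLC fit of a stretch segment.

    ``separation``/``force``/``time`` are the tip-sample separation (nm),
    force (pN) and time (s) samples of the segment ending at the last point
    before the force drop.  The apparent loading rate is the slope of a
    linear force-vs-time fit over the final ``loading_fraction`` of the
    segment (at least ``min_loading_points`` points).

    Non-convergence is not an exception: the event comes back with
    ``fit_quality = 0`` and NaN parameters.
    """
    sep = np.asarray(separation, dtype=float)
    f = np.asarray(force, dtype=float)
    if sep.shape != f.shape:
        raise ValueError("separation and force must have equal length")
    keep = sep >= 0
    sep, f = sep[keep], f[keep]
    if time is not None:
        t = np.asarray(time, dtype=float)[keep]
    else:
        t = None
    if sep.size < 8:
        raise ValueError(f"segment needs >= 8 non-negative-separation points, got {sep.size}")

    rupture_force = float(f[-1])
    rate = _loading_rate(t, f, loading_fraction, min_loading_points)

    trend = linregress(sep, f)
    if trend.slope <= 0:
        return WlcFit(np.nan, np.nan, rupture_force, rate, 0.0)

    kbt = thermal_energy(temperature)
    smax = sep.max()
    lc_lo, lc_hi = 1.02 * smax, 25.0 * smax

    def model(x, lp, lc):
        return _wlc_force_capped(x, lp, lc, kbt)

    try:
        popt, _ = curve_fit(
            model, sep, f,
            p0=(0.4, min(max(1.3 * smax, lc_lo * 1.01), lc_hi * 0.99)),
            bounds=((0.01, lc_lo), (50.0, lc_hi)),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return WlcFit(np.nan, np.nan, rupture_force, rate, 0.0)

    resid = f - model(sep, *popt)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot <= 0:
        quality = 0.0
    else:
        quality = float(np.clip(1.0 - float(np.sum(resid**2)) / ss_tot, 0.0, 1.0))
    return WlcFit(float(popt[0]), float(popt[1]), rupture_force, rate, quality)


def _loading_rate(time, force, fraction, min_points) -> float:
    if time is None or len(force) < min_points:
        return float("nan")
    n = max(min_points, int(np.ceil(fraction * len(force))))
    tt, ff = time[-n:], force[-n:]
    if np.ptp(tt) <= 0:
        return float("nan")
    return float(np.polyfit(tt, ff, 1)[0])
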