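"""AFM force-curve processing: baseline/contact correction and rupture mining.

Sign convention: tensile (adhesive) force on the tether is positive, the
compressive indentation force in the contact region is negative.  A rupture
therefore appears as a sharp *negative step* — the force drops back toward
zero when the bond breaks.

Detection follows a smoothing / peak-coincidence scheme: the retract trace is
smoothed with a moving average; candidate ruptures are step-like drops whose
magnitude exceeds a noise-scaled threshold in BOTH the raw and the smoothed
trace, and whose locations in the two traces coincide within the smoothing
window.  The stretch preceding each candidate is then WLC-fitted, and events
are classified specific when the fit is good and the rupture distance is
consistent with the PEG-linker contour length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .constants import T_DEFAULT
from .wlc import WlcFit, fit_wlc_segment

__all__ = [
    "ForceCurve",
    "RuptureEvent",
    "correct_baseline_and_contact",
    "to_tip_separation",
    "RuptureDetector",
    "detect_rupture_events",
    "classify_specific",
    "events_to_frame",
]

#: Nominal contour length (nm) of the 5 kDa PEG tether used to couple the
#: peptide to the tip; anchors the specificity distance window.
PEG_CONTOUR_NM = 35.0


@dataclass
class ForceCurve:
    """One AFM retract trace.

    time (s) and piezo_position (nm, increasing away from the surface) are
    monotone; force is deflection times spring constant, in pN.
    """

    time: np.ndarray
    piezo_position: np.ndarray
    force: np.ndarray
    spring_constant: float  # pN/nm
    retraction_speed: float  # nm/s
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.piezo_position = np.asarray(self.piezo_position, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if not (n == self.piezo_position.size == self.force.size):
            raise ValueError(f"curve {self.curve_id!r}: series lengths differ")
        if n < 16:
            raise ValueError(f"curve {self.curve_id!r}: needs >= 16 samples, got {n}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"curve {self.curve_id!r}: time not strictly increasing")
        if self.spring_constant <= 0 or self.retraction_speed <= 0:
            raise ValueError(
                f"curve {self.curve_id!r}: spring constant and retraction speed must be positive"
            )

    def __len__(self) -> int:
        return self.time.size


@dataclass
class RuptureEvent:
    """A detected unbinding event and its WLC characterization."""

    rupture_force: float           # pN
    rupture_distance: float        # nm, tip-sample separation at rupture
    apparent_loading_rate: float   # pN/s
    contour_length: float          # nm
    persistence_length: float      # nm
    fit_quality: float             # [0, 1]
    specific: bool = False
    index: int = field(default=-1, repr=False)  # sample index of the last pre-drop point


def correct_baseline_and_contact(curve: ForceCurve, baseline_fraction: float = 0.3
                                 ) -> tuple[ForceCurve, float]:
    """Remove a linear baseline and shift the piezo origin to the contact point.

    A straight line is fitted to the far-from-surface tail (the final
    ``baseline_fraction`` of the retract) and subtracted everywhere.  The
    contact point is where the corrected force leaves the compressive contact
    branch — the zero crossing terminating the initial negative (indentation)
    region; curves with no compressive branch get the contact at the first
    sample.  Returns the corrected curve and the contact position (nm, in the
    original piezo coordinates).
    """
    n = len(curve)
    n_tail = int(round(baseline_fraction * n))
    if n_tail < 8:
        raise ValueError(
            f"baseline tail of {n_tail} samples (< 8); increase baseline_fraction"
        )
    z = curve.piezo_position
    f = curve.force
    coeff = np.polyfit(z[-n_tail:], f[-n_tail:], 1)
    corrected = f - np.polyval(coeff, z)

    sigma = _noise_sigma(corrected[-n_tail:])
    threshold = max(5.0 * sigma, 10.0)
    compressive = np.flatnonzero(corrected < -threshold)
    if compressive.size == 0:
        contact = float(z[0])
    else:
        j = int(compressive[-1])
        # walk forward to the zero crossing that ends the contact branch
        after = np.flatnonzero(corrected[j:] >= 0.0)
        if after.size == 0:
            contact = float(z[-1])
        else:
            k = j + int(after[0])
            if k > 0 and corrected[k] != corrected[k - 1]:
                # linear interpolation of the crossing
                frac = -corrected[k - 1] / (corrected[k] - corrected[k - 1])
                contact = float(z[k - 1] + frac * (z[k] - z[k - 1]))
            else:
                contact = float(z[k])

    shifted = replace(
        curve,
        time=curve.time.copy(),
        piezo_position=z - contact,
        force=corrected,
    )
    return shifted, contact


def to_tip_separation(curve: ForceCurve) -> np.ndarray:
    """Tip-sample separation (nm) of a baseline-corrected curve.

    The cantilever deflects toward the surface under tether tension, so
    separation = piezo displacement - force / spring constant.
    """
    return curve.piezo_position - curve.force / curve.spring_constant


def _noise_sigma(values: np.ndarray) -> float:
    """Robust noise scale from first differences (MAD-based)."""
    d = np.diff(np.asarray(values, dtype=float))
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / (0.6745 * np.sqrt(2.0)))


class RuptureDetector(BaseEstimator):
    """Smoothing / peak-coincidence rupture detector.

    Parameters
    ----------
    window : int
        Moving-average window (samples) used both for smoothing and for the
        pre/post step statistic.
    nsigma : float
        Threshold in units of the noise scale of the step statistic.
    min_drop : float
        Absolute floor (pN) on the step size, guarding low-noise curves.
    baseline_fraction : float
        Fraction of the retract tail used for the noise estimate.
    loading_fraction : float
        Final fraction of each stretch segment used for the loading-rate fit.
    contact_exclusion : float
        Near-surface zone (nm) excluded from the WLC fit when enough of the
        segment lies beyond it.  Non-specific contact adhesion lives within
        ~10 nm of the surface while the tether force there is negligible, so
        excluding the zone keeps contact peaks from corrupting the fit.
    quality_threshold, distance_window, linker_contour
        Specificity rule: fit quality >= threshold and rupture distance within
        ``distance_window`` times the nominal linker contour length.
    """

    def __init__(self, window: int = 15, nsigma: float = 6.0, min_drop: float = 20.0,
                 baseline_fraction: float = 0.3, loading_fraction: float = 0.1,
                 contact_exclusion: float = 10.0,
                 quality_threshold: float = 0.8,
                 distance_window: tuple = (0.5, 1.5),
                 linker_contour: float = PEG_CONTOUR_NM,
                 temperature: float = T_DEFAULT):
        self.window = window
        self.nsigma = nsigma
        self.min_drop = min_drop
        self.baseline_fraction = baseline_fraction
        self.loading_fraction = loading_fraction
        self.contact_exclusion = contact_exclusion
        self.quality_threshold = quality_threshold
        self.distance_window = distance_window
        self.linker_contour = linker_contour
        self.temperature = temperature

    # -- detection -------------------------------------------------------
    def detect(self, curve: ForceCurve) -> list[RuptureEvent]:
        """Detect ruptures on a baseline-corrected curve."""
        f = curve.force
        n = f.size
        w = max(3, int(self.window))
        smoothed = uniform_filter1d(f, size=w, mode="nearest")

        n_tail = max(8, int(round(self.baseline_fraction * n)))
        sigma = _noise_sigma(f[-n_tail:])

        drop_raw = _step_statistic(f, w)
        drop_sm = _step_statistic(smoothed, w)
        threshold = max(self.nsigma * sigma * np.sqrt(2.0 / w), self.min_drop)

        peaks_raw, _ = find_peaks(drop_raw, height=threshold, distance=w)
        peaks_sm, _ = find_peaks(drop_sm, height=0.8 * threshold, distance=w)
        if peaks_raw.size == 0 or peaks_sm.size == 0:
            return []
        # correlation criterion: raw and smoothed step locations must coincide
        candidates = [
            int(p) for p in peaks_raw
            if np.min(np.abs(peaks_sm - p)) <= w
        ]

        separation = to_tip_separation(curve)
        events: list[RuptureEvent] = []
        prev_idx = 0
        for idx in sorted(candidates):
            # refine the edge: the rupture is the sharpest raw single-sample
            # drop near the step-statistic peak
            lo = max(idx - w, 1)
            hi = min(idx + w, n - 1)
            idx = lo + 1 + int(np.argmin(f[lo + 1:hi + 1] - f[lo:hi]))
            last = idx - 1
            if last <= prev_idx or f[last] <= 0:
                prev_idx = idx
                continue
            seg = slice(max(prev_idx, 0), idx)
            prev_idx = idx
            event = self._characterize(curve, separation, seg, last)
            if event is not None:
                events.append(event)
        return events

    def _characterize(self, curve, separation, seg, last) -> "RuptureEvent | None":
        sep_seg = separation[seg]
        f_seg = curve.force[seg]
        t_seg = curve.time[seg]
        rupture_distance = float(separation[last])
        if rupture_distance <= 0:
            return None
        beyond = sep_seg >= self.contact_exclusion
        if beyond.sum() >= 8:
            sep_seg, f_seg, t_seg = sep_seg[beyond], f_seg[beyond], t_seg[beyond]
        try:
            fit = fit_wlc_segment(
                sep_seg, f_seg, time=t_seg, temperature=self.temperature,
                loading_fraction=self.loading_fraction,
            )
        except ValueError:
            fit = WlcFit(np.nan, np.nan, float(curve.force[last]), np.nan, 0.0)
        if not np.isfinite(fit.apparent_loading_rate):
            # short (near-contact) segment: rate from the final raw points
            tail = slice(max(seg.stop - 8, seg.start), seg.stop)
            tt, ff = curve.time[tail], curve.force[tail]
            if tt.size >= 3 and np.ptp(tt) > 0:
                fit.apparent_loading_rate = float(np.polyfit(tt, ff, 1)[0])
        if not (np.isfinite(fit.apparent_loading_rate) and fit.apparent_loading_rate > 0):
            # a genuine adhesive release loads the bond; reject slope artifacts
            return None
        event = RuptureEvent(
            rupture_force=float(curve.force[last]),
            rupture_distance=rupture_distance,
            apparent_loading_rate=fit.apparent_loading_rate,
            contour_length=fit.contour_length,
            persistence_length=fit.persistence_length,
            fit_quality=fit.fit_quality,
            index=last,
        )
        event.specific = classify_specific(
            event,
            quality_threshold=self.quality_threshold,
            distance_window=self.distance_window,
            linker_contour=self.linker_contour,
        )
        return event

    def transform(self, curves) -> list[list[RuptureEvent]]:
        """Detect on a sequence of baseline-corrected curves."""
        return [self.detect(c) for c in curves]


def _step_statistic(values: np.ndarray, w: int) -> np.ndarray:
    """mean(values[i-w:i]) - mean(values[i:i+w]): peaks at downward steps."""
    c = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    n = values.size
    out = np.zeros(n)
    idx = np.arange(w, n - w)
    pre = (c[idx] - c[idx - w]) / w
    post = (c[idx + w] - c[idx]) / w
    out[idx] = pre - post
    return out


def detect_rupture_events(curve: ForceCurve, **params) -> list[RuptureEvent]:
    """Functional wrapper over :class:`RuptureDetector` (corrected curve in)."""
    return RuptureDetector(**params).detect(curve)


def classify_specific(event: RuptureEvent, quality_threshold: float = 0.8,
                      distance_window: tuple = (0.5, 1.5),
                      linker_contour: float = PEG_CONTOUR_NM) -> bool:
    """Specific <=> well-fitted WLC stretch rupturing at a linker-consistent
    distance (within ``distance_window`` times the nominal PEG contour)."""
    lo, hi = distance_window
    if not np.isfinite(event.fit_quality) or event.fit_quality < quality_threshold:
        return False
    if not (lo * linker_contour <= event.rupture_distance <= hi * linker_contour):
        return False
    if not np.isfinite(event.apparent_loading_rate) or event.apparent_loading_rate <= 0:
        return False
    return True


def events_to_frame(events_by_curve: dict) -> pd.DataFrame:
    """Per-curve event table (curve_id, force, distance, rate, Lc, Lp, quality, specific)."""
    rows = []
    for curve_id, events in events_by_curve.items():
        for e in events:
            rows.append(
                {
                    "curve_id": curve_id,
                    "force_pN": e.rupture_force,
                    "distance_nm": e.rupture_distance,
                    "loading_rate_pN_s": e.apparent_loading_rate,
                    "contour_length_nm": e.contour_length,
                    "persistence_length_nm": e.persistence_length,
                    "fit_quality": e.fit_quality,
                    "specific": e.specific,
                }
            )
    columns = ["curve_id", "force_pN", "distance_nm", "loading_rate_pN_s",
               "contour_length_nm", "persistence_length_nm", "fit_quality", "specific"]
    return pd.DataFrame(rows, columns=columns)
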