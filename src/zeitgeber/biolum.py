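"""Feature extraction from PER2::LUC-style bioluminescence reporter traces.

A trace is photomultiplier counts/second sampled at a uniform interval
(10 min by default) over several days.  Slow baseline drift is removed by
subtracting a centered 24-h running average; peaks and troughs of the
detrended, lightly smoothed signal yield the first-cycle peak phase,
cycle amplitudes and the mean peak-to-peak period.  An explant showing
fewer than two circadian peaks is scored arrhythmic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

HOURS = 24.0


@dataclass(frozen=True)
class BiolumTrace:
    """A bioluminescence time series.

    times are hours from culture start at uniform spacing; start_zt is the
    Zeitgeber time at which the culture was started, so absolute phase of
    an event at trace time t is (start_zt + t) mod 24.  ``valid`` marks
    samples where the running-average detrend is defined (None = all).
    """

    start_zt: float
    times: np.ndarray
    counts: np.ndarray
    detrended: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if times.size != counts.size:
            raise ValueError("times and counts must have equal length")
        if times.size < 3:
            raise ValueError("trace too short")
        dt = np.diff(times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be strictly increasing and uniformly spaced")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class BiolumFeatures:
    """Summary features of a single detrended trace."""

    peak_times: np.ndarray
    trough_times: np.ndarray
    first_peak_zt: float | None
    amplitude_cycle1: float | None
    amplitude_cycle2: float | None
    period: float | None
    rhythmic: bool
    n_peaks: int = field(default=0)


def _centered_moving_mean(x: np.ndarray, n_half: int) -> np.ndarray:
    """Moving mean over a symmetric window of 2*n_half+1 samples ('same' length)."""
    kernel = np.ones(2 * n_half + 1) / (2 * n_half + 1)
    return np.convolve(x, kernel, mode="same")


def detrend_running_average(trace: BiolumTrace, window: float = 24.0) -> BiolumTrace:
    """Subtract a centered ``window``-hour running average from the raw counts.

    The window must be an integer multiple of the sampling interval; the
    symmetric window spans window/dt + 1 samples so that constants and
    linear drift are removed exactly.  The half-window at each edge,
    where the average is undefined, is flagged invalid and excluded from
    downstream peak searches.
    """
    if trace.detrended:
        raise ValueError("trace is already detrended")
    dt = trace.dt
    ratio = window / dt
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(f"window ({window} h) must be a multiple of the sampling interval ({dt:g} h)")
    n_half = int(round(ratio)) // 2
    if trace.times.size <= 2 * n_half:
        raise ValueError("trace shorter than the detrending window")
    baseline = _centered_moving_mean(trace.counts, n_half)
    detrended = trace.counts - baseline
    valid = np.zeros(trace.times.size, dtype=bool)
    valid[n_half : trace.times.size - n_half] = True
    return replace(trace, counts=detrended, detrended=True, valid=valid)


def _refine_extremum(t: np.ndarray, y: np.ndarray, idx: int, half: int, sign: float) -> tuple[float, float]:
    """Sub-sample extremum location by a local quadratic fit around sample idx."""
    lo, hi = max(0, idx - half), min(y.size, idx + half + 1)
    tt = t[lo:hi] - t[idx]
    a, b, c = np.polyfit(tt, sign * y[lo:hi], 2)
    if a >= 0:  # not locally concave: keep the grid extremum
        return float(t[idx]), float(y[idx])
    v = float(np.clip(-b / (2 * a), tt[0], tt[-1]))
    return float(t[idx] + v), float(sign * (a * v * v + b * v + c))


def detect_extrema(
    trace: BiolumTrace,
    smooth: float = 2.0,
    min_separation: float = 16.0,
    refine_window: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Locate circadian peaks and troughs of a detrended trace.

    The valid region is smoothed with a centered ``smooth``-hour moving
    mean; peaks (troughs) are local maxima (minima) separated by at least
    ``min_separation`` hours, which restricts detection to circadian-scale
    oscillations.  Each extremum is then refined to sub-sample precision
    by the vertex of a quadratic fitted over +-``refine_window`` hours.
    Returns (peak_times, peak_values, trough_times, trough_values) in
    time order, values on the smoothed detrended scale.
    """
    if not trace.detrended:
        raise ValueError("detect_extrema expects a detrended trace")
    valid = trace.valid if trace.valid is not None else np.ones(trace.times.size, bool)
    if not valid.any():
        raise ValueError("empty valid region")
    dt = trace.dt
    n_half = max(1, int(round(smooth / dt)) // 2)
    smoothed = _centered_moving_mean(trace.counts, n_half)
    # the smoother must not touch samples where the detrend is undefined:
    # erode the valid block by the smoothing half-window on each side
    idx = np.flatnonzero(valid)
    lo, hi = idx[0] + n_half, idx[-1] - n_half
    if hi <= lo:
        raise ValueError("empty valid region after smoothing")
    valid = np.zeros_like(valid)
    valid[lo : hi + 1] = True
    t_valid = trace.times[valid]
    y_valid = smoothed[valid]
    distance = max(1, int(round(min_separation / dt)))
    half = max(1, int(round(refine_window / dt)))
    pk, _ = find_peaks(y_valid, distance=distance)
    tr, _ = find_peaks(-y_valid, distance=distance)
    peaks = [_refine_extremum(t_valid, y_valid, i, half, 1.0) for i in pk]
    troughs = [_refine_extremum(t_valid, y_valid, i, half, -1.0) for i in tr]
    pt = np.array([p[0] for p in peaks])
    pv = np.array([p[1] for p in peaks])
    tt = np.array([p[0] for p in troughs])
    tv = np.array([p[1] for p in troughs])
    return pt, pv, tt, tv


def extract_features(
    trace: BiolumTrace,
    window: float = 24.0,
    smooth: float = 2.0,
    min_separation: float = 16.0,
    refine_window: float = 3.0,
    period_span: float = 72.0,
) -> BiolumFeatures:
    """Detrend a raw trace and compute first-cycle phase, amplitudes and period.

    first_peak_zt is the Zeitgeber time of the first valid peak,
    (start_zt + peak time) mod 24.  amplitude_cycle1 is the drop from the
    first peak to the first following trough; amplitude_cycle2 the rise
    from that trough to the second peak, both on the detrended scale.
    The period is the mean of successive peak-to-peak intervals among
    peaks within the first ``period_span`` valid hours.  A trace with
    fewer than two peaks is arrhythmic and carries no period.
    """
    if not trace.detrended:
        trace = detrend_running_average(trace, window=window)
    peak_t, peak_v, trough_t, trough_v = detect_extrema(trace, smooth, min_separation, refine_window)
    n_peaks = peak_t.size
    rhythmic = n_peaks >= 2

    first_peak_zt = float((trace.start_zt + peak_t[0]) % HOURS) if n_peaks >= 1 else None

    amp1 = amp2 = None
    if n_peaks >= 1:
        after = trough_t > peak_t[0]
        if after.any():
            t1_val = trough_v[after][0]
            amp1 = float(peak_v[0] - t1_val)
            if n_peaks >= 2:
                amp2 = float(peak_v[1] - t1_val)

    period = None
    if rhythmic:
        t0 = peak_t[0]
        in_span = peak_t <= t0 + period_span
        pk_span = peak_t[in_span]
        if pk_span.size >= 2:
            period = float(np.mean(np.diff(pk_span)))
        else:
            period = float(np.mean(np.diff(peak_t[:2])))

    return BiolumFeatures(
        peak_times=peak_t,
        trough_times=trough_t,
        first_peak_zt=first_peak_zt,
        amplitude_cycle1=amp1,
        amplitude_cycle2=amp2,
        period=period,
        rhythmic=rhythmic,
        n_peaks=int(n_peaks),
    )
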