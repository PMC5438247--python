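"""Breath detection and sniff-phase assignment.

The airflow convention is negative = inhalation.  The trace is smoothed
with a second-order Savitzky-Golay filter (200 ms frames), locally
detrended in 1.5 s windows with 1 s overlap, and inhalation/exhalation
onsets are taken as the zero-crossings before and after large negative
peaks.  "Large" is defined here by peak prominence relative to the median
trough depth (the amplitude criterion is a configurable choice).

Spike phases interpolate linearly from 0 at inhalation onset to pi at
exhalation onset to 2*pi at the next inhalation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks, savgol_filter


@dataclasses.dataclass
class RespirationTrace:
    samples: np.ndarray
    sampling_rate: float = 2000.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclasses.dataclass
class BreathEvents:
    """Alternating inhalation/exhalation onset times (seconds)."""

    inhalation_onsets: np.ndarray
    exhalation_onsets: np.ndarray

    def __post_init__(self):
        self.inhalation_onsets = np.asarray(self.inhalation_onsets, float)
        self.exhalation_onsets = np.asarray(self.exhalation_onsets, float)
        for arr in (self.inhalation_onsets, self.exhalation_onsets):
            if len(arr) > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.inhalation_onsets)


def _local_detrend(x: np.ndarray, fs: float, window: float,
                   overlap: float) -> np.ndarray:
    """Subtract a linear fit in overlapping windows, averaging estimates
    where windows overlap."""
    n = len(x)
    win = max(int(round(window * fs)), 2)
    step = max(int(round((window - overlap) * fs)), 1)
    trend = np.zeros(n)
    weight = np.zeros(n)
    idx = np.arange(n)
    start = 0
    while True:
        end = min(start + win, n)
        seg = slice(start, end)
        tt = idx[seg].astype(float)
        # triangular weights: windows blend smoothly where they overlap,
        # avoiding trend discontinuities at window boundaries
        w = 1.0 - np.abs(tt - 0.5 * (start + end - 1)) / (0.5 * (end - start))
        w = np.maximum(w, 1e-3)
        if end - start >= 2:
            coef = np.polyfit(tt, x[seg], 1)
            trend[seg] += w * np.polyval(coef, tt)
        else:
            trend[seg] += w * x[seg]
        weight[seg] += w
        if end >= n:
            break
        start += step
    return x - trend / np.maximum(weight, 1e-12)


def _zero_crossing(y: np.ndarray, i: int, fs: float,
                   direction: int) -> float | None:
    """Time of the nearest sign change searching from index ``i``
    (direction -1 = backwards for the downward crossing preceding a trough,
    +1 = forwards for the upward crossing after it), interpolated linearly
    between samples."""
    j = i
    if direction < 0:
        while j > 0 and y[j] < 0:
            j -= 1
        if y[j] >= 0:
            # crossing between j and j+1
            denom = y[j + 1] - y[j]
            frac = -y[j] / denom if denom != 0 else 0.0
            return (j + frac) / fs
        return None
    while j < len(y) - 1 and y[j] < 0:
        j += 1
    if y[j] >= 0:
        denom = y[j] - y[j - 1]
        frac = (0 - y[j - 1]) / denom if denom != 0 else 0.0
        return (j - 1 + frac) / fs
    return None


def detect_breaths(trace: RespirationTrace,
                   smooth_window: float = 0.200,
                   detrend_window: float = 1.5,
                   detrend_overlap: float = 1.0,
                   peak_prominence: float = 0.5) -> BreathEvents:
    """Detect inhalation and exhalation onsets from an airflow trace.

    Parameters
    ----------
    smooth_window : float
        Savitzky-Golay frame length in seconds (order 2).
    detrend_window, detrend_overlap : float
        Local linear detrending window and overlap, seconds.
    peak_prominence : float
        Troughs with prominence below ``peak_prominence`` times the median
        trough depth are ignored.

    Returns empty events when no negative peaks are found (e.g. a constant
    trace); raises ``ValueError`` when the trace is shorter than one
    smoothing frame.
    """
    fs = trace.sampling_rate
    frame = int(round(smooth_window * fs))
    frame += (frame + 1) % 2  # savgol needs an odd window
    if len(trace.samples) < frame:
        raise ValueError("trace shorter than one smoothing frame")
    y = savgol_filter(trace.samples, frame, polyorder=2)
    if len(y) >= int(round(detrend_window * fs)):
        y = _local_detrend(y, fs, detrend_window, detrend_overlap)

    scale = max(float(np.max(np.abs(trace.samples))), 1e-30)
    if np.ptp(y) < 1e-9 * scale:  # flat (e.g. constant) trace
        return BreathEvents(np.empty(0), np.empty(0))
    troughs, props = find_peaks(-y, prominence=0.0)
    if len(troughs) == 0:
        return BreathEvents(np.empty(0), np.empty(0))
    depth = -y[troughs]
    ref = np.median(depth[depth > 0]) if np.any(depth > 0) else 0.0
    if ref <= 0:
        return BreathEvents(np.empty(0), np.empty(0))
    big = troughs[props["prominences"] >= peak_prominence * ref]

    inh, exh = [], []
    for i in big:
        t_in = _zero_crossing(y, i, fs, -1)
        t_ex = _zero_crossing(y, i, fs, +1)
        if t_in is None or t_ex is None:
            continue
        if inh and t_in <= inh[-1] + 1e-9:
            continue  # two troughs within one negative lobe
        inh.append(t_in)
        exh.append(t_ex)
    return BreathEvents(np.asarray(inh), np.asarray(exh))


def spike_phase(spike_times, events: BreathEvents) -> np.ndarray:
    """Sniff phase in [0, 2*pi) for each spike time.

    Linear interpolation: 0 at inhalation onset, pi at exhalation onset,
    approaching 2*pi at the next inhalation onset.  Spikes outside the
    event coverage get NaN.
    """
    t = np.atleast_1d(np.asarray(spike_times, float))
    inh = events.inhalation_onsets
    exh = events.exhalation_onsets
    n_pairs = min(len(inh), len(exh))
    if n_pairs == 0 or len(inh) < 2:
        return np.full(t.shape, np.nan)
    knots = np.empty(2 * n_pairs)
    knots[0::2] = inh[:n_pairs]
    knots[1::2] = exh[:n_pairs]
    unwrapped = np.empty_like(knots)
    unwrapped[0::2] = 2 * np.pi * np.arange(n_pairs)
    unwrapped[1::2] = 2 * np.pi * np.arange(n_pairs) + np.pi
    phase = np.interp(t, knots, unwrapped)
    out = np.mod(phase, 2 * np.pi)
    out[(t < inh[0]) | (t >= inh[-1])] = np.nan
    # exact inhalation onsets wrap to 0
    at_onset = np.isin(t, inh[:-1])
    out[at_onset] = 0.0
    return out


def phase_histogram(phases, bin_width_deg: float = 10.0,
                    normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of sniff phases with ``bin_width_deg`` degree bins.

    Returns ``(counts_or_fractions, bin_edges_rad)``.  NaN phases are
    dropped; an empty phase list yields an all-zero histogram.
    """
    if 360.0 % bin_width_deg != 0:
        raise ValueError("bin width must divide 360 degrees")
    n_bins = int(round(360.0 / bin_width_deg))
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    p = np.asarray(phases, float)
    p = p[np.isfinite(p)]
    hist, _ = np.histogram(p, bins=edges)
    hist = hist.astype(float)
    if normalize and hist.sum() > 0:
        hist /= hist.sum()
    return hist, edges
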