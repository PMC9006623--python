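"""Per-ROA trace extraction, event detection, and transient kinetics.

Each ROA is summarised by the unweighted mean ΔF/F0 of its pixels at every
frame.  Events are local maxima of that trace above a field-of-view-wide
floor ``mu + detect_k * sigma``, where ``mu`` and ``sigma`` are the mean and
standard deviation pooled over every sample of every ROA trace in the FOV.
The same (mu, sigma) pair defines the signal-strength bands used for
classification:

* ``sub``:  a < mu + sigma (below the lowest band)
* ``low``:  mu + sigma <= a <= mu + 2 sigma
* ``mid``:  mu + 2 sigma < a <= mu + 3 sigma
* ``high``: a > mu + 3 sigma

Kinetic parameters follow the FWHM convention: an event's duration is the
full width at half its peak amplitude, its start/end are the linearly
interpolated half-maximum crossings nearest the peak, rise time runs from
start to the 90%-of-peak crossing, decay time from the falling 90% crossing
to the end, and integrated fluorescence is the trapezoidal integral of the
trace between start and end (units ΔF/F0·s).  A crossing that runs into the
recording edge, or into the valley shared with a neighbouring event, is
clamped there and the event flagged as censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .baseline import DffStack
from .core import ParameterError
from .roa_detect import ROAMap

STRENGTH_CLASSES = ("sub", "low", "mid", "high")


@dataclass
class ROATrace:
    """Mean ΔF/F0 of one ROA per frame."""

    roa_id: int
    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ParameterError("values and times must have equal length")


@dataclass
class StrengthThresholds:
    """Pooled mean and SD of all ROA-trace samples in one field of view."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")


@dataclass
class CaEvent:
    """One detected calcium transient and its kinetic parameters (seconds)."""

    roa_id: int
    peak_frame: int
    peak_time: float
    amplitude: float
    t_start: float
    t_end: float
    duration: float
    rise_time: float
    decay_time: float
    integrated_fluorescence: float
    strength_class: str = "sub"
    censored: bool = False


def extract_traces(dff: DffStack, roa_map: ROAMap) -> list[ROATrace]:
    """Mean ΔF/F0 over each ROA's pixels, one trace per ROA.

    Boundary pixels contribute only to the region they are assigned to.
    """
    labels = roa_map.labels
    n = roa_map.n_roas
    if n == 0:
        return []
    T = dff.n_frames
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    sums = np.zeros((T, n))
    data2 = dff.data.reshape(T, -1)
    for k in range(1, n + 1):
        idx = np.nonzero(flat == k)[0]
        sums[:, k - 1] = data2[:, idx].sum(axis=1)
    means = sums / counts[None, :]
    times = dff.times
    return [ROATrace(roa_id=k + 1, values=means[:, k], times=times) for k in range(n)]


def compute_thresholds(traces: list[ROATrace]) -> StrengthThresholds:
    """Pooled mu and sigma over all samples of all ROA traces."""
    if not traces:
        raise ParameterError("compute_thresholds requires at least one trace")
    pooled = np.concatenate([t.values for t in traces])
    return StrengthThresholds(mu=float(pooled.mean()), sigma=float(pooled.std()))


def detect_events(
    trace: ROATrace, thr: StrengthThresholds, detect_k: float = 1.0
) -> list[int]:
    """Frame indices of event peaks in one ROA trace, ordered by time.

    Peaks are local maxima with value >= ``mu + detect_k * sigma`` and
    prominence >= sigma; maxima closer than 2 frames merge into the higher.
    """
    height = thr.mu + detect_k * thr.sigma
    peaks, _ = find_peaks(
        trace.values, height=height, prominence=thr.sigma if thr.sigma > 0 else None,
        distance=2,
    )
    return [int(p) for p in peaks]


def classify_strength(amplitude: float, thr: StrengthThresholds) -> str:
    """Assign the signal-strength band of an amplitude (closed/open edges as above)."""
    mu, s = thr.mu, thr.sigma
    if amplitude > mu + 3 * s:
        return "high"
    if amplitude > mu + 2 * s:
        return "mid"
    if amplitude >= mu + s:
        return "low"
    return "sub"


def _cross_left(v: np.ndarray, t: np.ndarray, peak: int, level: float, lo: int):
    """Nearest interpolated crossing of ``level`` left of ``peak``, not before ``lo``."""
    for i in range(peak - 1, lo - 1, -1):
        if v[i] < level <= v[i + 1]:
            f = (level - v[i]) / (v[i + 1] - v[i])
            return t[i] + f * (t[i + 1] - t[i]), False
    return t[lo], True


def _cross_right(v: np.ndarray, t: np.ndarray, peak: int, level: float, hi: int):
    """Nearest interpolated crossing of ``level`` right of ``peak``, not past ``hi``."""
    for i in range(peak, hi):
        if v[i] >= level > v[i + 1]:
            f = (v[i] - level) / (v[i] - v[i + 1])
            return t[i] + f * (t[i + 1] - t[i]), False
    return t[hi], True


def _trace_value_at(v: np.ndarray, t: np.ndarray, x: float) -> float:
    return float(np.interp(x, t, v))


def _refine_peak(v: np.ndarray, t: np.ndarray, p: int) -> tuple[float, float]:
    """Sub-frame peak estimate by quadratic interpolation through 3 samples.

    The continuous transient maximum generally falls between frames; the
    parabola through ``(p-1, p, p+1)`` corrects the resulting sampling bias
    of the amplitude.  At the trace edges, on degenerate curvature, or for
    exactly symmetric neighbours the sample value itself is returned.
    """
    if p <= 0 or p >= len(v) - 1:
        return float(v[p]), float(t[p])
    a, b, c = float(v[p - 1]), float(v[p]), float(v[p + 1])
    denom = a - 2 * b + c
    if denom >= 0:  # not a concave vertex
        return b, float(t[p])
    delta = 0.5 * (a - c) / denom
    if not -0.5 <= delta <= 0.5:
        return b, float(t[p])
    amp = b - 0.25 * (a - c) * delta
    dt = t[p + 1] - t[p]
    return float(max(amp, b)), float(t[p] + delta * dt)


def event_metrics(
    trace: ROATrace,
    peak_frame: int,
    left_bound: int = 0,
    right_bound: int | None = None,
) -> CaEvent:
    """Compute all kinetic parameters of one detected peak.

    ``left_bound``/``right_bound`` restrict the crossing search (used to
    separate overlapping events at the inter-peak minimum); a crossing not
    reached inside the window is clamped to the window edge and the event
    marked censored.
    """
    v, t = trace.values, trace.times
    if right_bound is None:
        right_bound = len(v) - 1
    if v[peak_frame] <= 0:
        raise ParameterError("rejected peak: amplitude must be > 0")
    amplitude, peak_time = _refine_peak(v, t, peak_frame)
    half = amplitude / 2.0
    lvl90 = 0.9 * amplitude

    t_start, cens_l = _cross_left(v, t, peak_frame, half, left_bound)
    t_end, cens_r = _cross_right(v, t, peak_frame, half, right_bound)

    # 90% crossings searched between the half-max crossings and the peak.
    t90_pre, _ = _cross_left(v, t, peak_frame, lvl90, left_bound)
    t90_post, _ = _cross_right(v, t, peak_frame, lvl90, right_bound)
    t90_pre = max(t90_pre, t_start)
    t90_post = min(t90_post, t_end)

    duration = t_end - t_start
    rise = t90_pre - t_start
    decay = t_end - t90_post

    # Trapezoidal integral of the trace over [t_start, t_end], with linearly
    # interpolated endpoint values.
    i0 = int(np.searchsorted(t, t_start, side="right"))
    i1 = int(np.searchsorted(t, t_end, side="left"))
    xs = np.concatenate([[t_start], t[i0:i1], [t_end]])
    ys = np.concatenate(
        [[_trace_value_at(v, t, t_start)], v[i0:i1], [_trace_value_at(v, t, t_end)]]
    )
    integral = float(np.trapezoid(ys, xs))

    return CaEvent(
        roa_id=trace.roa_id,
        peak_frame=int(peak_frame),
        peak_time=peak_time,
        amplitude=amplitude,
        t_start=float(t_start),
        t_end=float(t_end),
        duration=float(duration),
        rise_time=float(rise),
        decay_time=float(decay),
        integrated_fluorescence=integral,
        censored=bool(cens_l or cens_r),
    )


def analyze_trace(
    trace: ROATrace, thr: StrengthThresholds, detect_k: float = 1.0
) -> list[CaEvent]:
    """Detect and fully characterise every event in one ROA trace.

    Neighbouring events are separated at the inter-peak minimum; a missing
    half-max crossing on the shared side is clamped there and censored.
    """
    peaks = detect_events(trace, thr, detect_k)
    v = trace.values
    events = []
    for j, p in enumerate(peaks):
        lo = 0
        hi = len(v) - 1
        if j > 0:
            prev = peaks[j - 1]
            lo = prev + int(np.argmin(v[prev : p + 1]))
        if j < len(peaks) - 1:
            nxt = peaks[j + 1]
            hi = p + int(np.argmin(v[p : nxt + 1]))
        ev = event_metrics(trace, p, lo, hi)
        ev.strength_class = classify_strength(ev.amplitude, thr)
        events.append(ev)
    return events


def roa_frequency(event_times: np.ndarray | list[float]) -> float | None:
    """Mean signal frequency (min^-1) of one ROA, or ``None`` with < 2 events.

    Defined as the reciprocal of the mean inter-peak interval, expressed per
    minute: ``60 / mean(diff(peak times in s))``.
    """
    times = np.asarray(event_times, dtype=float)
    if times.size < 2:
        return None
    intervals = np.diff(np.sort(times))
    return float(60.0 / intervals.mean())
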