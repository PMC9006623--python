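"""Field-of-view level aggregation of ROAs and events.

The FOV summary carries the spatial density of ROAs and of signals
(reported per 10^-3 μm^-2), the split of active ROAs into single-signal and
multi-signal fractions, the coincidence index, and per-metric FOV medians.

The coincidence index measures concerted activity: a ROA counts as active
at frame ``i`` when the frame time ``i * frame_interval`` falls inside the
FWHM window ``[t_start, t_end]`` of any of its events (alternatively within
one frame of an event peak), and the index is the mean over frames of the
fraction of ROAs active, hence lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .event_analysis import CaEvent, roa_frequency
from .roa_detect import ROAMap

DENSITY_UNIT = 1e3  # densities are reported in 10^-3 per μm²


@dataclass
class FOVSummary:
    """Aggregate statistics of one field of view."""

    fov_area: float  # μm²
    n_roas: int
    n_signals: int
    roa_density: float  # 10^-3 / μm²
    signal_density: float  # 10^-3 / μm²
    frac_single: float  # fraction of active ROAs with exactly one signal
    frac_multi: float  # fraction of active ROAs with more than one signal
    coincidence_index: float | None
    medians: dict[str, float] = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "fov_area_um2": self.fov_area,
            "n_roas": self.n_roas,
            "n_signals": self.n_signals,
            "roa_density_1e-3_per_um2": self.roa_density,
            "signal_density_1e-3_per_um2": self.signal_density,
            "frac_single": self.frac_single,
            "frac_multi": self.frac_multi,
            "coincidence_index": self.coincidence_index,
            "medians": self.medians,
            "provenance": list(self.provenance),
        }
        return d


def _active_matrix(
    events: list[CaEvent],
    n_roas: int,
    n_frames: int,
    frame_interval: float,
    window: str = "fwhm",
) -> np.ndarray:
    """Boolean (n_roas, n_frames) activity matrix."""
    active = np.zeros((n_roas, n_frames), dtype=bool)
    times = np.arange(n_frames) * frame_interval
    for ev in events:
        if window == "fwhm":
            lo, hi = ev.t_start, ev.t_end
        else:  # 'peak': within one frame of the peak
            lo = ev.peak_time - frame_interval
            hi = ev.peak_time + frame_interval
        active[ev.roa_id - 1] |= (times >= lo) & (times <= hi)
    return active


def coincidence_index(
    events: list[CaEvent],
    n_roas: int,
    n_frames: int,
    frame_interval: float,
    window: str = "fwhm",
) -> float | None:
    """Mean over frames of (simultaneously active ROAs / total ROAs).

    Returns ``None`` when there are no ROAs (the index is undefined).
    """
    if n_roas < 1:
        return None
    active = _active_matrix(events, n_roas, n_frames, frame_interval, window)
    return float(active.sum(axis=0).mean() / n_roas)


def fov_summary(
    roa_map: ROAMap,
    events: list[CaEvent],
    image_shape: tuple[int, int],
    pixel_size: float,
    n_frames: int,
    frame_interval: float,
    active_window: str = "fwhm",
    provenance: tuple[str, ...] = (),
) -> FOVSummary:
    """Aggregate a detection run into FOV-level statistics.

    Densities are counts divided by the FOV area ``H * W * pixel_size²``,
    reported in units of 10^-3/μm².  The single/multi split is taken over
    ROAs with at least one signal, matching the convention of reporting the
    relative frequency of ROAs active once versus more than once.
    """
    H, W = image_shape
    fov_area = H * W * pixel_size**2
    n_roas = roa_map.n_roas
    n_signals = len(events)

    counts = np.zeros(n_roas + 1, dtype=int)
    for ev in events:
        counts[ev.roa_id] += 1
    active_counts = counts[1:][counts[1:] > 0]
    if active_counts.size:
        frac_single = float((active_counts == 1).mean())
        frac_multi = float((active_counts > 1).mean())
    else:
        frac_single = frac_multi = 0.0

    freqs = []
    for rid in range(1, n_roas + 1):
        f = roa_frequency([ev.peak_time for ev in events if ev.roa_id == rid])
        if f is not None:
            freqs.append(f)

    def med(vals):
        arr = np.asarray(list(vals), dtype=float)
        return float(np.median(arr)) if arr.size else float("nan")

    medians = {
        "amplitude": med(ev.amplitude for ev in events),
        "duration": med(ev.duration for ev in events),
        "rise_time": med(ev.rise_time for ev in events),
        "decay_time": med(ev.decay_time for ev in events),
        "integrated_fluorescence": med(ev.integrated_fluorescence for ev in events),
        "area": med(roa_map.areas),
        "frequency": med(freqs),
    }

    return FOVSummary(
        fov_area=fov_area,
        n_roas=n_roas,
        n_signals=n_signals,
        roa_density=n_roas / fov_area * DENSITY_UNIT,
        signal_density=n_signals / fov_area * DENSITY_UNIT,
        frac_single=frac_single,
        frac_multi=frac_multi,
        coincidence_index=coincidence_index(
            events, n_roas, n_frames, frame_interval, active_window
        ),
        medians=medians,
        provenance=provenance,
    )
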