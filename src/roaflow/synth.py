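"""Synthetic two-photon calcium movies with ground truth.

The generator emulates GCaMP3 recordings of glial activity: a flat basal
fluorescence with slow polynomial photobleaching, stationary active regions
(connected pixel blobs of realistic area), calcium transients with a linear
rise and an exponential decay whose full width at half maximum matches a
sampled duration, Poisson shot noise on the photon counts, and Gaussian
read noise.  Default amplitudes (0.10-0.30 ΔF/F0), durations (5-10 s FWHM),
per-region rates (~1 min^-1) and region areas (10-180 μm² for the "astro"
profile, 5-60 μm² for "micro") sit inside the ranges reported for
spontaneous astroglial and microglial activity in spinal cord recordings.

The "astro" profile additionally injects occasional multi-region coincident
events (concerted waves), the qualitative hallmark that the coincidence
index is designed to pick up; "micro" activity is sparser and uncoordinated.

Every random choice derives from a single seed split into independent
streams for structure (footprints, event times) and noise, so the noise can
be switched off without changing the implanted events (``clean_twin``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import MovieStack, ParameterError

_LN2 = float(np.log(2.0))


@dataclass
class SynthConfig:
    """Parameters of the synthetic movie generator."""

    shape: tuple[int, int, int] = (300, 256, 256)  # T, H, W
    pixel_size: float = 0.5  # μm
    frame_interval: float = 1.0  # s
    baseline_level: float = 100.0  # counts
    bleach: float = -0.10  # fractional drift over the recording
    bleach_degree: int = 1  # polynomial degree of the drift, <= 2
    read_noise_sd: float = 1.5  # counts
    cell_profile: str = "astro"  # "astro" | "micro"
    n_regions: int = 20
    events_per_region: float = 1.0  # Poisson rate, min^-1
    amplitude_range: tuple[float, float] = (0.1, 0.3)  # ΔF/F0
    duration_range: tuple[float, float] = (5.0, 10.0)  # s, FWHM
    area_range: tuple[float, float] | None = None  # μm²; profile default if None
    rise_fraction: float = 0.4  # rise time / FWHM duration
    wave_rate: float = 0.2  # "astro" coincident-wave rate, min^-1
    wave_fraction: float = 0.3  # fraction of regions recruited per wave
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_profile not in ("astro", "micro"):
            raise ParameterError("cell_profile must be 'astro' or 'micro'")
        if self.area_range is None:
            self.area_range = (10.0, 180.0) if self.cell_profile == "astro" else (5.0, 60.0)
        for name, rng in (
            ("amplitude_range", self.amplitude_range),
            ("duration_range", self.duration_range),
            ("area_range", self.area_range),
        ):
            if not (0 < rng[0] <= rng[1]):
                raise ParameterError(f"{name} must be positive and ordered")
        if self.bleach_degree > 2 or self.bleach_degree < 0:
            raise ParameterError("bleach_degree must be 0, 1, or 2")
        if not 0 < self.rise_fraction < 1:
            raise ParameterError("rise_fraction must lie in (0, 1)")
        T, H, W = self.shape
        fov_area = H * W * self.pixel_size**2
        if self.area_range[1] > fov_area:
            raise ParameterError("region area exceeds the field of view")


@dataclass
class RegionTruth:
    region_id: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    centroid: tuple[float, float]
    area_um2: float


@dataclass
class EventTruth:
    region_id: int
    onset_time: float  # s
    peak_time: float  # s
    amplitude: float  # ΔF/F0
    fwhm: float  # s


@dataclass
class GroundTruth:
    regions: list[RegionTruth] = field(default_factory=list)
    events: list[EventTruth] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


def _grow_blob(rng: np.random.Generator, center, k, forbidden, shape):
    """Grow a connected blob of exactly ``k`` pixels by weighted accretion.

    Candidate frontier pixels are weighted by the squared count of already
    included neighbours, which keeps blobs compact but irregular.  Returns
    None if the frontier exhausts before reaching ``k`` pixels.
    """
    H, W = shape
    cy, cx = center
    if forbidden[cy, cx]:
        return None
    included = {(cy, cx)}
    frontier: dict[tuple[int, int], int] = {}

    def push_neighbors(y, x):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                ny, nx = y + dy, x + dx
                if 0 <= ny < H and 0 <= nx < W and not forbidden[ny, nx]:
                    p = (ny, nx)
                    if p not in included:
                        frontier[p] = frontier.get(p, 0) + 1

    push_neighbors(cy, cx)
    while len(included) < k:
        if not frontier:
            return None
        cands = sorted(frontier)
        w = np.array([frontier[c] ** 2 for c in cands], dtype=float)
        pick = cands[rng.choice(len(cands), p=w / w.sum())]
        del frontier[pick]
        included.add(pick)
        push_neighbors(*pick)
    return np.array(sorted(included), dtype=int)


def _place_regions(rng: np.random.Generator, cfg: SynthConfig) -> list[RegionTruth]:
    T, H, W = cfg.shape
    px2 = cfg.pixel_size**2
    occupied = np.zeros((H, W), dtype=bool)
    regions: list[RegionTruth] = []
    max_attempts = 200 * cfg.n_regions
    attempts = 0
    while len(regions) < cfg.n_regions and attempts < max_attempts:
        attempts += 1
        area = rng.uniform(*cfg.area_range)
        k = max(1, int(round(area / px2)))
        # keep centres away from the frame edge by roughly the blob radius,
        # but stay feasible on small frames (blobs are clipped at the border)
        margin = min(int(np.ceil(np.sqrt(k / np.pi))) + 2, min(H, W) // 4)
        if H - 2 * margin <= 0 or W - 2 * margin <= 0:
            raise ParameterError("region area too large for the field of view")
        cy = int(rng.integers(margin, H - margin))
        cx = int(rng.integers(margin, W - margin))
        # keep 2 px of clearance between regions so ROAs stay separable
        forbidden = ndimage.binary_dilation(occupied, iterations=2) if occupied.any() else occupied
        pixels = _grow_blob(rng, (cy, cx), k, forbidden, (H, W))
        if pixels is None:
            continue
        occupied[pixels[:, 0], pixels[:, 1]] = True
        regions.append(
            RegionTruth(
                region_id=len(regions) + 1,
                pixels=pixels,
                centroid=(float(pixels[:, 0].mean()), float(pixels[:, 1].mean())),
                area_um2=len(pixels) * px2,
            )
        )
    if len(regions) < cfg.n_regions:
        raise ParameterError(
            f"could not place {cfg.n_regions} non-overlapping regions; "
            f"placed {len(regions)}"
        )
    return regions


def _sample_events(rng: np.random.Generator, cfg: SynthConfig, n_regions: int):
    T, H, W = cfg.shape
    total_s = T * cfg.frame_interval
    total_min = total_s / 60.0
    events: list[EventTruth] = []
    for rid in range(1, n_regions + 1):
        n = rng.poisson(cfg.events_per_region * total_min)
        onsets = np.sort(rng.uniform(0.0, total_s, size=n))
        for t0 in onsets:
            events.append(_one_event(rng, cfg, rid, float(t0)))
    if cfg.cell_profile == "astro" and n_regions > 1:
        n_waves = rng.poisson(cfg.wave_rate * total_min)
        for _ in range(n_waves):
            t0 = float(rng.uniform(0.0, total_s))
            n_rec = max(2, int(round(cfg.wave_fraction * n_regions)))
            recruited = rng.choice(n_regions, size=n_rec, replace=False) + 1
            for rid in sorted(int(r) for r in recruited):
                events.append(_one_event(rng, cfg, rid, t0))
    events.sort(key=lambda e: (e.region_id, e.onset_time))
    return events


def _one_event(rng, cfg: SynthConfig, rid: int, t0: float) -> EventTruth:
    amp = float(rng.uniform(*cfg.amplitude_range))
    dur = float(rng.uniform(*cfg.duration_range))
    rise = cfg.rise_fraction * dur
    return EventTruth(
        region_id=rid, onset_time=t0, peak_time=t0 + rise, amplitude=amp, fwhm=dur
    )


def event_kernel(times: np.ndarray, ev: EventTruth, rise_fraction: float) -> np.ndarray:
    """Temporal kernel: linear rise to the peak, exponential decay.

    The decay constant is chosen so the kernel's FWHM equals the sampled
    duration: the rising half-max crossing sits at ``rise/2`` before the
    peak and the falling one at ``tau * ln 2`` after, so
    ``tau = (fwhm - rise/2) / ln 2``.
    """
    rise = rise_fraction * ev.fwhm
    tau = (ev.fwhm - rise / 2.0) / _LN2
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    up = (t >= ev.onset_time) & (t < ev.peak_time)
    out[up] = ev.amplitude * (t[up] - ev.onset_time) / rise
    down = t >= ev.peak_time
    out[down] = ev.amplitude * np.exp(-(t[down] - ev.peak_time) / tau)
    return out


def _render_clean(cfg: SynthConfig, regions, events, with_events: bool) -> np.ndarray:
    T, H, W = cfg.shape
    times = np.arange(T) * cfg.frame_interval
    u = times / times[-1] if T > 1 else np.zeros(T)
    drift = 1.0 + cfg.bleach * u**max(cfg.bleach_degree, 1) if cfg.bleach_degree > 0 else np.ones(T)
    signal = np.zeros((T, H, W))
    if with_events:
        per_region = {}
        for ev in events:
            per_region.setdefault(ev.region_id, []).append(ev)
        for reg in regions:
            evs = per_region.get(reg.region_id, [])
            if not evs:
                continue
            s = np.zeros(T)
            for ev in evs:
                s += event_kernel(times, ev, cfg.rise_fraction)
            ys, xs = reg.pixels[:, 0], reg.pixels[:, 1]
            signal[:, ys, xs] += s[:, None]
    clean = cfg.baseline_level * drift[:, None, None] * (1.0 + signal)
    return clean


def _structure(cfg: SynthConfig):
    ss = np.random.SeedSequence(cfg.rng_seed)
    s_struct, s_noise = ss.spawn(2)
    rng = np.random.default_rng(s_struct)
    regions = _place_regions(rng, cfg)
    events = _sample_events(rng, cfg, len(regions))
    return regions, events, np.random.default_rng(s_noise)


def generate_movie(config: SynthConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a noisy synthetic movie and its ground truth.

    The clean signal is ``baseline * (1 + bleach(t)) * (1 + sum of events)``;
    Poisson shot noise is applied to the counts, then Gaussian read noise,
    clipped at zero.  Identical seeds give bit-identical movies.
    """
    regions, events, noise_rng = _structure(config)
    clean = _render_clean(config, regions, events, with_events=True)
    noisy = noise_rng.poisson(clean).astype(float)
    if config.read_noise_sd > 0:
        noisy += noise_rng.normal(0.0, config.read_noise_sd, size=clean.shape)
    noisy = np.maximum(noisy, 0.0)
    stack = MovieStack(
        data=noisy,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        source_path=f"synthetic({config.cell_profile}, seed={config.rng_seed})",
        provenance=("synthetic",),
    )
    return stack, GroundTruth(regions=regions, events=events)


def clean_twin(
    config: SynthConfig, with_events: bool = False
) -> tuple[MovieStack, GroundTruth]:
    """Noise-free rendering sharing the seed-derived structure of the full movie.

    With ``with_events=False`` the result is the pure baseline x drift
    surface (the F0 recovery oracle); with ``with_events=True`` it carries
    the exact continuous transients (the kinetics oracle).
    """
    regions, events, _ = _structure(config)
    clean = _render_clean(config, regions, events, with_events=with_events)
    stack = MovieStack(
        data=clean,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        source_path=f"synthetic-clean(seed={config.rng_seed}, events={with_events})",
        provenance=("synthetic-clean",),
    )
    return stack, GroundTruth(regions=regions, events=events)


# ---------------------------------------------------------------------------
# Ground-truth evaluation helpers


def match_regions(gt: GroundTruth, labels: np.ndarray) -> dict[int, tuple[int, float]]:
    """Map each ground-truth region to the best-overlapping ROA label.

    Returns ``{region_id: (label, jaccard)}`` with label 0 when nothing
    overlaps.
    """
    out: dict[int, tuple[int, float]] = {}
    counts = np.bincount(labels.ravel())
    for reg in gt.regions:
        lab_at = labels[reg.pixels[:, 0], reg.pixels[:, 1]]
        lab_at = lab_at[lab_at > 0]
        if lab_at.size == 0:
            out[reg.region_id] = (0, 0.0)
            continue
        best, inter = 0, 0
        for lab in np.unique(lab_at):
            n = int((lab_at == lab).sum())
            if n > inter:
                best, inter = int(lab), n
        union = len(reg.pixels) + int(counts[best]) - inter
        out[reg.region_id] = (best, inter / union)
    return out


def match_events(
    gt: GroundTruth,
    detected,  # list[CaEvent]
    region_to_label: dict[int, tuple[int, float]],
    tol_s: float = 3.0,
    recording_end: float | None = None,
) -> dict:
    """Match detected events to ground truth.

    Matching proceeds in two tiers.  First, greedy one-to-one: a detected
    event matches the truth event of its ROA's region whose peak time lies
    within ``tol_s``; amplitude/duration errors are taken from these pairs
    only.  Second, a truth transient that overlaps a neighbour so closely
    that the rendered trace has a single maximum cannot be a separate
    detection, so an unmatched truth peak falling inside an already-matched
    detection's FWHM window counts as *covered* (detected as part of a
    compound event).  Recall counts matched + covered truth events;
    precision counts one-to-one matches only.

    Truth events whose peak lies beyond ``recording_end`` (seconds) never
    appear in the data and are excluded from the denominator; they are
    reported as ``n_truncated``.
    """
    by_label: dict[int, list] = {}
    for ev in detected:
        by_label.setdefault(ev.roa_id, []).append(ev)
    truth = list(gt.events)
    n_truncated = 0
    if recording_end is not None:
        n_truncated = sum(1 for t in truth if t.peak_time > recording_end)
        truth = [t for t in truth if t.peak_time <= recording_end]

    used = set()
    amp_err, dur_err, dur_abs = [], [], []
    unmatched = []
    n_matched = 0
    for tev in truth:
        lab, _ = region_to_label.get(tev.region_id, (0, 0.0))
        best = None
        if lab != 0:
            for dev in by_label.get(lab, []):
                if id(dev) in used:
                    continue
                dt = abs(dev.peak_time - tev.peak_time)
                if dt <= tol_s and (best is None or dt < best[0]):
                    best = (dt, dev)
        if best is not None:
            used.add(id(best[1]))
            n_matched += 1
            amp_err.append(abs(best[1].amplitude - tev.amplitude) / tev.amplitude)
            dur_err.append(abs(best[1].duration - tev.fwhm) / tev.fwhm)
            dur_abs.append(abs(best[1].duration - tev.fwhm))
        else:
            unmatched.append(tev)

    n_covered = 0
    for tev in unmatched:
        lab, _ = region_to_label.get(tev.region_id, (0, 0.0))
        if lab == 0:
            continue
        for dev in by_label.get(lab, []):
            if id(dev) in used and dev.t_start <= tev.peak_time <= dev.t_end:
                n_covered += 1
                break

    n_true = len(truth)
    n_det = len(detected)
    return {
        "n_true": n_true,
        "n_truncated": n_truncated,
        "n_detected": n_det,
        "n_matched": n_matched,
        "n_covered": n_covered,
        "recall": (n_matched + n_covered) / n_true if n_true else float("nan"),
        "precision": n_matched / n_det if n_det else float("nan"),
        "median_amplitude_rel_error": float(np.median(amp_err)) if amp_err else float("nan"),
        "median_duration_rel_error": float(np.median(dur_err)) if dur_err else float("nan"),
        "median_duration_abs_error_s": float(np.median(dur_abs)) if dur_abs else float("nan"),
    }
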