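"""Reading and writing of TIFF stacks and result tables."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ConfigurationError, FormatError, MovieStack, PipelineConfig
from .event_analysis import CaEvent, roa_frequency
from .fov_stats import FOVSummary
from .roa_detect import ROAMap

logger = logging.getLogger(__name__)

_MICRON_UNITS = {"um", "micron", "microns", "µm", "\\u00b5m"}


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Pixel size in μm from ImageJ metadata or TIFF resolution tags."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    px_per_unit = num / den
    ij = tif.imagej_metadata or {}
    unit = str(ij.get("unit", "")).strip().lower()
    if unit in _MICRON_UNITS:
        return den / num
    res_unit = tags.get("ResolutionUnit")
    code = getattr(res_unit, "value", None)
    code = getattr(code, "value", code)  # enum -> int
    if code == 3:  # centimetre
        return den / num * 1e4
    if code == 2:  # inch
        return den / num * 2.54e4
    return None


def _frame_interval_from_tiff(tif: tifffile.TiffFile) -> float | None:
    ij = tif.imagej_metadata or {}
    fi = ij.get("finterval")
    if fi is not None and float(fi) > 0:
        return float(fi)
    return None


def read_movie(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> MovieStack:
    """Read a multi-page grayscale TIFF time-lapse.

    Explicit ``pixel_size`` (μm) and ``frame_interval`` (s) override values
    found in the metadata; if neither source provides a value, a
    :class:`ConfigurationError` names the missing field.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            meta_px = _pixel_size_from_tiff(tif)
            meta_fi = _frame_interval_from_tiff(tif)
    except (OSError, ValueError, tifffile.TiffFileError) as e:
        raise FormatError(f"cannot read TIFF {path}: {e}") from e
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        raise FormatError(f"{path}: single-frame image, need a time-lapse stack")
    if arr.ndim == 4 and arr.shape[-1] in (3, 4):
        raise FormatError(f"{path}: RGB(A) stacks are not supported, need grayscale")
    if arr.ndim != 3:
        raise FormatError(f"{path}: unsupported stack layout with shape {arr.shape}")

    px = pixel_size if pixel_size is not None else meta_px
    fi = frame_interval if frame_interval is not None else meta_fi
    if px is None:
        raise ConfigurationError(
            f"{path}: pixel_size not in TIFF metadata; supply pixel_size explicitly"
        )
    if fi is None:
        raise ConfigurationError(
            f"{path}: frame_interval not in TIFF metadata; supply frame_interval explicitly"
        )
    return MovieStack(
        data=arr.astype(float),
        pixel_size=float(px),
        frame_interval=float(fi),
        source_path=str(path),
        provenance=("read",),
    )


def save_movie(stack: MovieStack, path: str | Path) -> None:
    """Write a stack as an ImageJ-compatible TIFF carrying the calibration."""
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={
            "unit": "micron",
            "finterval": stack.frame_interval,
            "axes": "TYX",
        },
    )


def events_to_frame(events: list[CaEvent]) -> pd.DataFrame:
    cols = [
        "roa_id", "peak_frame", "peak_time_s", "amplitude_dff", "t_start_s",
        "t_end_s", "duration_s", "rise_time_s", "decay_time_s",
        "integrated_fluorescence_dffs", "strength_class", "censored",
    ]
    rows = [
        (
            ev.roa_id, ev.peak_frame, ev.peak_time, ev.amplitude, ev.t_start,
            ev.t_end, ev.duration, ev.rise_time, ev.decay_time,
            ev.integrated_fluorescence, ev.strength_class, ev.censored,
        )
        for ev in events
    ]
    return pd.DataFrame(rows, columns=cols)


def roas_to_frame(roa_map: ROAMap, events: list[CaEvent]) -> pd.DataFrame:
    labels = roa_map.labels
    rows = []
    for k in range(1, roa_map.n_roas + 1):
        ys, xs = np.nonzero(labels == k)
        times = [ev.peak_time for ev in events if ev.roa_id == k]
        freq = roa_frequency(times)
        rows.append(
            (
                k,
                roa_map.areas[k - 1],
                len(ys),
                float(ys.mean()) if ys.size else float("nan"),
                float(xs.mean()) if xs.size else float("nan"),
                roa_map.seeds[k - 1][0],
                roa_map.seeds[k - 1][1],
                len(times),
                freq if freq is not None else float("nan"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "roa_id", "area_um2", "n_pixels", "centroid_y", "centroid_x",
            "seed_y", "seed_x", "n_signals", "frequency_per_min",
        ],
    )


def write_results(
    roa_map: ROAMap,
    events: list[CaEvent] | pd.DataFrame,
    summary: FOVSummary,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, Path]:
    """Write the standard result set into ``out_dir``.

    Files: ``events.csv`` (one row per event), ``roas.csv`` (one row per
    ROA), ``summary.json``, ``labels.tif`` (16-bit label image, 0 =
    background), and ``config.json`` when a config is given.  The label
    image round-trips losslessly.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out} is not writable: {e}") from e

    if isinstance(events, pd.DataFrame):
        raise TypeError("write_results expects the event list, not a DataFrame")
    event_list = list(events)
    events_df = events_to_frame(event_list)
    roas_df = roas_to_frame(roa_map, event_list)

    paths = {
        "events": out / "events.csv",
        "roas": out / "roas.csv",
        "summary": out / "summary.json",
        "labels": out / "labels.tif",
        "config": out / "config.json",
    }
    events_df.to_csv(paths["events"], index=False)
    roas_df.to_csv(paths["roas"], index=False)
    paths["summary"].write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    if roa_map.n_roas > np.iinfo(np.uint16).max:
        raise OverflowError("more ROAs than a 16-bit label image can hold")
    tifffile.imwrite(str(paths["labels"]), roa_map.labels.astype(np.uint16))
    if config is not None:
        config.to_json(paths["config"])
    else:
        del paths["config"]
    logger.info("write_results: %d events, %d ROAs -> %s", len(event_list), roa_map.n_roas, out)
    return paths
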