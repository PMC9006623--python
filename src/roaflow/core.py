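"""Core containers and configuration for the ROA analysis pipeline.

The pipeline operates on time-lapse fluorescence stacks ``F(t, y, x)``
acquired by two-photon laser-scanning microscopy.  A :class:`MovieStack`
couples the raw intensities with the two pieces of calibration metadata the
analysis needs throughout: the isotropic pixel size (μm) used to convert
pixel counts into areas, and the frame interval (s) used to convert frame
indices into times.  :class:`PipelineConfig` collects every tunable of the
detection procedure in one flat, serialisable record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np


class RoaflowError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RoaflowError):
    """An input file is unreadable or has the wrong layout (RGB, single frame...)."""


class ConfigurationError(RoaflowError):
    """Required calibration or configuration is missing or inconsistent."""


class ParameterError(RoaflowError, ValueError):
    """A function argument is outside its documented domain."""


class DomainError(RoaflowError, ValueError):
    """Data violate a mathematical precondition (e.g. negative intensities)."""


class PipelineError(RoaflowError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class MovieStack:
    """A fluorescence time-lapse with calibration metadata.

    Parameters
    ----------
    data
        Intensities, shape ``(T, H, W)``, arbitrary units, non-negative.
    pixel_size
        Isotropic pixel edge length in μm.
    frame_interval
        Time between consecutive frames in seconds; frame ``i`` is taken to
        start at ``i * frame_interval``.
    source_path
        Provenance string (file path or generator description).
    provenance
        Ordered names of the processing steps already applied to ``data``.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    source_path: str = ""
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"movie data must be 3-D (T, H, W), got shape {self.data.shape}"
            )
        if self.data.shape[0] < 2:
            raise FormatError("movie must contain at least 2 frames")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be > 0 μm")
        if not self.frame_interval > 0:
            raise ConfigurationError("frame_interval must be > 0 s")
        if np.nanmin(self.data) < 0:
            raise DomainError("fluorescence intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.data.shape[1]), int(self.data.shape[2])

    @property
    def times(self) -> np.ndarray:
        """Start time of each frame in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def with_data(self, data: np.ndarray, step: str | None = None) -> "MovieStack":
        """Return a copy holding ``data``, optionally appending a provenance step."""
        prov = self.provenance + ((step,) if step else ())
        return MovieStack(
            data=data,
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            source_path=self.source_path,
            provenance=prov,
        )


@dataclass
class PipelineConfig:
    """All tunables of the ROA detection pipeline.

    Defaults follow the published operating point where one is stated
    (minimum ROA area 5 μm², temporal correlation threshold 0.2) and are
    otherwise the package's own documented choices.
    """

    poly_degree: int = 3  # F0 polynomial degree; 3 absorbs slow bleaching over <=5 min
    clip_k: float = 2.0  # one-sided sigma-clip multiplier for transient exclusion
    f0_max_iter: int = 5  # max fit/exclude iterations for F0
    corr_threshold: float = 0.2  # Pearson r floor for region growing
    min_roa_area: float = 5.0  # μm²
    median_window: int = 3  # temporal median filter width, frames, odd
    denoise: bool = True  # apply the wavelet denoiser before the median filter
    seed_neighborhood: int = 3  # strict-maximum neighbourhood radius, px
    seed_range_k: float = 3.0  # seed threshold = median + k * MAD of the range map
    detect_k: float = 1.0  # event detection floor = mu + detect_k * sigma
    class_k: tuple[float, float, float] = (1.0, 2.0, 3.0)  # strength band multipliers
    connectivity: int = 8  # 4 or 8
    merge_correlated: bool = True  # merge adjacent fragments of one region
    merge_threshold: float = 0.5  # Pearson r between adjacent regions' mean traces
    grow_on_denoised: bool = False  # growth correlations on denoised vs median-only data
    grow_temporal_sigma: float = 1.5  # frames; temporal Gaussian smoothing of growth data
    active_window: str = "fwhm"  # ROA "active" definition for the coincidence index
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.poly_degree < 0:
            raise ParameterError("poly_degree must be >= 0")
        if not -1.0 <= self.corr_threshold <= 1.0:
            raise ParameterError("corr_threshold must lie in [-1, 1]")
        if not self.min_roa_area > 0:
            raise ParameterError("min_roa_area must be > 0 μm²")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ParameterError("median_window must be odd and >= 1")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.seed_neighborhood < 1:
            raise ParameterError("seed_neighborhood must be >= 1")
        if self.active_window not in ("fwhm", "peak"):
            raise ParameterError("active_window must be 'fwhm' or 'peak'")
        self.class_k = tuple(float(k) for k in self.class_k)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["class_k"] = list(self.class_k)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat JSON or YAML document."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if not isinstance(d, dict):
            raise ConfigurationError("config file must hold a flat mapping")
        return cls.from_dict(d)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
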