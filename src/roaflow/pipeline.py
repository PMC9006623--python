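"""End-to-end orchestration of the ROA detection pipeline.

``run_pipeline`` composes the stages in the documented order — wavelet
denoising, temporal median filtering, polynomial F0 estimation with
transient exclusion, ΔF/F0 normalisation, ROA detection, per-ROA event
detection and kinetics, FOV aggregation — and is a pure function of the
movie and the configuration: repeated runs are bit-identical.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import baseline, event_analysis, fov_stats, preprocess, roa_detect
from .core import MovieStack, PipelineConfig, PipelineError
from .event_analysis import CaEvent
from .fov_stats import FOVSummary
from .roa_detect import ROAMap

logger = logging.getLogger(__name__)


def run_pipeline(
    movie: MovieStack, config: PipelineConfig | None = None
) -> tuple[ROAMap, list[CaEvent], FOVSummary]:
    """Run the full analysis on one movie.

    Returns the ROA map, the list of detected events, and the FOV summary.
    Stage failures are re-raised as :class:`PipelineError` naming the stage.
    """
    if config is None:
        config = PipelineConfig()
    stage = "preprocess"
    try:
        median_only = preprocess.temporal_median_filter(movie, config.median_window)
        if config.denoise:
            work = preprocess.denoise_stack(movie, config)
            work = preprocess.temporal_median_filter(work, config.median_window)
        else:
            work = median_only
        logger.info("preprocess: provenance=%s", "|".join(work.provenance))

        stage = "baseline"
        model = baseline.estimate_f0(
            work, config.poly_degree, config.clip_k, config.f0_max_iter
        )
        dff = baseline.compute_dff(work, model)
        logger.info(
            "baseline: degree=%d, %d fallback pixels, %d invalid pixels",
            config.poly_degree,
            int(model.fallback_mask.sum()),
            int((~dff.valid_mask).sum()),
        )

        stage = "roa_detect"
        if config.grow_on_denoised or not config.denoise:
            grow_dff = dff
        else:
            # Region membership is decided on data whose noise is spatially
            # independent; spatial denoising would correlate neighbouring
            # background pixels above the growth threshold.  Temporal
            # smoothing (which leaves pixels independent) sharpens the
            # within-region correlations instead.
            grow_dff = baseline.compute_dff(median_only, model)
            if config.grow_temporal_sigma > 0:
                from scipy.ndimage import gaussian_filter1d

                grow_dff.data = gaussian_filter1d(
                    grow_dff.data, config.grow_temporal_sigma, axis=0
                )
        roa_map = roa_detect.detect_roas(dff, config, grow_dff=grow_dff)
        logger.info("roa_detect: %d ROAs kept", roa_map.n_roas)

        stage = "event_analysis"
        events: list[CaEvent] = []
        if roa_map.n_roas > 0:
            # Kinetics are measured on the unsmoothed normalised data: the
            # per-ROA pixel mean is the variance reducer, and temporal
            # smoothing would clip sampled transient peaks.
            measure_dff = baseline.compute_dff(movie, model)
            traces = event_analysis.extract_traces(measure_dff, roa_map)
            thr = event_analysis.compute_thresholds(traces)
            for trace in traces:
                events.extend(event_analysis.analyze_trace(trace, thr, config.detect_k))
        logger.info("event_analysis: %d events detected", len(events))

        stage = "fov_stats"
        summary = fov_stats.fov_summary(
            roa_map,
            events,
            movie.frame_shape,
            movie.pixel_size,
            movie.n_frames,
            movie.frame_interval,
            active_window=config.active_window,
            provenance=work.provenance,
        )
        return roa_map, events, summary
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage '{stage}' failed: {e}") from e
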