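"""Detection of stationary regions of activity (ROAs).

A ROA is a connected set of pixels whose temporal fluorescence profiles are
mutually correlated with a common local seed.  Detection proceeds in four
steps on the normalised ΔF/F0 stack:

1. **Range projection** — per-pixel ``max - min`` over time; active pixels
   stand out because a transient inflates their range.
2. **Seed finding** — strict local maxima of the range projection above a
   robust threshold (median + k x MAD of the map).
3. **Simultaneous region growing** — all seeds grow at once from a single
   global best-first frontier ordered by the Pearson correlation between a
   candidate pixel's full-length temporal profile and its claiming seed's
   profile.  Growth stops at a correlation threshold.  A pixel reached by a
   second region above threshold keeps its first (higher-correlation)
   assignment and is marked as a boundary pixel.
4. **Minimum-area filter** — regions smaller than a physical area floor
   (default 5 μm²) are discarded and labels renumbered densely.

Global best-first growth rather than per-seed sequential growth prevents
the first seed from conquering territory that correlates better with a
later seed; ties are broken by lower seed id, then row-major pixel order,
making the procedure fully deterministic.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .baseline import DffStack
from .core import ParameterError, PipelineConfig

logger = logging.getLogger(__name__)

_OFFSETS4 = ((-1, 0), (0, -1), (0, 1), (1, 0))
_OFFSETS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class ROAMap:
    """Label image of regions of activity.

    ``labels`` is ``(H, W)`` int32 with 0 background and ids ``1..K``;
    ``seeds[k]`` is the (row, col) seed of region ``k+1``; ``boundary_mask``
    marks pixels that were claimed above threshold by more than one region;
    ``areas[k]`` is region ``k+1``'s area in μm² (pixel count x pixel_size²).
    """

    labels: np.ndarray
    seeds: list[tuple[int, int]]
    boundary_mask: np.ndarray
    areas: np.ndarray
    pixel_size: float

    @property
    def n_roas(self) -> int:
        return len(self.seeds)

    def pixel_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_roas + 1)[1:]

    @classmethod
    def empty(cls, shape: tuple[int, int], pixel_size: float) -> "ROAMap":
        return cls(
            labels=np.zeros(shape, dtype=np.int32),
            seeds=[],
            boundary_mask=np.zeros(shape, dtype=bool),
            areas=np.zeros(0),
            pixel_size=pixel_size,
        )


def range_projection(dff: DffStack) -> np.ndarray:
    """Per-pixel ``max - min`` of ΔF/F0 over time; invalid pixels map to 0."""
    rng = dff.data.max(axis=0) - dff.data.min(axis=0)
    return np.where(dff.valid_mask, rng, 0.0)


def find_seeds(
    range_map: np.ndarray, neighborhood: int = 3, k: float = 3.0
) -> list[tuple[int, int]]:
    """Strict local maxima of the range map above ``median + k * MAD``.

    A pixel is a seed when it is at least as large as every other pixel in
    the square neighbourhood of radius ``neighborhood`` and exceeds the
    robust amplitude threshold.  A plateau of exactly equal maximal pixels
    (which transform-domain denoising can produce) yields a single seed at
    its row-major-first pixel; on maps with distinct values this reduces to
    the strict local maxima.  Seeds are returned in row-major order.
    """
    if neighborhood < 1:
        raise ParameterError("neighborhood must be >= 1")
    from scipy.ndimage import label, maximum_filter

    m = np.asarray(range_map, dtype=float)
    med = np.median(m)
    mad = np.median(np.abs(m - med))
    thr = med + k * mad
    size = 2 * neighborhood + 1
    footprint = np.ones((size, size), dtype=bool)
    footprint[neighborhood, neighborhood] = False
    nbr_max = maximum_filter(m, footprint=footprint, mode="constant", cval=-np.inf)
    cand = (m >= nbr_max) & (m > thr)
    # Adjacent candidates necessarily share one value; keep one per plateau.
    comp, n_comp = label(cand, structure=np.ones((3, 3), dtype=int))
    seeds: list[tuple[int, int]] = []
    seen = np.zeros(n_comp + 1, dtype=bool)
    for y, x in zip(*np.nonzero(cand)):
        c = comp[y, x]
        if not seen[c]:
            seen[c] = True
            seeds.append((int(y), int(x)))
    return seeds


def _neighbor_offsets(connectivity: int):
    if connectivity == 4:
        return _OFFSETS4
    if connectivity == 8:
        return _OFFSETS8
    raise ParameterError("connectivity must be 4 or 8")


def _pearson_to_seed(trace: np.ndarray, seed_unit: np.ndarray) -> float:
    """Pearson r between a trace and a pre-normalised (zero-mean, unit-norm) seed."""
    c = trace - trace.mean()
    n = np.linalg.norm(c)
    if n == 0:
        return np.nan
    return float(np.dot(c, seed_unit) / n)


def grow_regions(
    dff: DffStack,
    seeds: list[tuple[int, int]],
    corr_threshold: float = 0.2,
    connectivity: int = 8,
) -> ROAMap:
    """Grow all seed regions simultaneously by descending correlation.

    A single global frontier holds (candidate pixel, claiming region, r)
    entries ordered by descending Pearson r (ties: lower seed id, then
    row-major pixel).  A candidate is admitted to its claiming region iff
    ``r >= corr_threshold``; admitted pixels enqueue their unassigned
    neighbours for the same region.  A pixel already assigned to one region
    that is reached from another region above threshold stays put but is
    marked in ``boundary_mask``.  Constant (zero-variance) and invalid
    pixels are never admitted; a seed placed on such a pixel is skipped
    with a warning.
    """
    if not -1.0 <= corr_threshold <= 1.0:
        raise ParameterError("corr_threshold must lie in [-1, 1]")
    data = dff.data
    T, H, W = data.shape
    labels = np.zeros((H, W), dtype=np.int32)
    boundary = np.zeros((H, W), dtype=bool)
    offsets = _neighbor_offsets(connectivity)

    admissible = dff.valid_mask & (data.std(axis=0) > 0)

    seed_units: list[np.ndarray | None] = []
    kept_seeds: list[tuple[int, int]] = []
    for sy, sx in seeds:
        if not admissible[sy, sx]:
            logger.warning("seed at (%d, %d) lies on an invalid/constant pixel; skipped", sy, sx)
            continue
        c = data[:, sy, sx] - data[:, sy, sx].mean()
        seed_units.append(c / np.linalg.norm(c))
        kept_seeds.append((int(sy), int(sx)))

    heap: list[tuple[float, int, int, int]] = []  # (-r, region_id, y, x)

    def enqueue_neighbors(y: int, x: int, region: int) -> None:
        su = seed_units[region - 1]
        for dy, dx in offsets:
            ny, nx = y + dy, x + dx
            if not (0 <= ny < H and 0 <= nx < W):
                continue
            if not admissible[ny, nx]:
                continue
            lab = labels[ny, nx]
            r = _pearson_to_seed(data[:, ny, nx], su)
            if not (r >= corr_threshold):
                continue
            if lab == 0:
                heapq.heappush(heap, (-r, region, ny, nx))
            elif lab != region:
                boundary[ny, nx] = True

    for rid, (sy, sx) in enumerate(kept_seeds, start=1):
        if labels[sy, sx] != 0:
            boundary[sy, sx] = True  # two seeds on one pixel: later one yields
            continue
        labels[sy, sx] = rid

    for rid, (sy, sx) in enumerate(kept_seeds, start=1):
        if labels[sy, sx] == rid:
            enqueue_neighbors(sy, sx, rid)

    while heap:
        negr, region, y, x = heapq.heappop(heap)
        lab = labels[y, x]
        if lab != 0:
            if lab != region:
                boundary[y, x] = True
            continue
        labels[y, x] = region
        enqueue_neighbors(y, x, region)

    counts = np.bincount(labels.ravel(), minlength=len(kept_seeds) + 1)[1:]
    areas = counts * dff.pixel_size**2
    return ROAMap(
        labels=labels,
        seeds=kept_seeds,
        boundary_mask=boundary,
        areas=areas,
        pixel_size=dff.pixel_size,
    )


def filter_min_area(roa_map: ROAMap, min_area: float) -> ROAMap:
    """Drop ROAs below the area floor and renumber survivors densely from 1."""
    keep = roa_map.areas >= min_area
    old_ids = np.nonzero(keep)[0] + 1
    remap = np.zeros(roa_map.n_roas + 1, dtype=np.int32)
    remap[old_ids] = np.arange(1, keep.sum() + 1)
    labels = remap[roa_map.labels]
    boundary = roa_map.boundary_mask & (labels > 0)
    return ROAMap(
        labels=labels,
        seeds=[roa_map.seeds[i - 1] for i in old_ids],
        boundary_mask=boundary,
        areas=roa_map.areas[keep],
        pixel_size=roa_map.pixel_size,
    )


def merge_correlated_regions(
    roa_map: ROAMap,
    dff: DffStack,
    merge_threshold: float = 0.5,
    connectivity: int = 8,
) -> ROAMap:
    """Union adjacent regions whose mean traces correlate above threshold.

    One contiguous active area can host several local range-map maxima and
    therefore several seeds; simultaneous growth then partitions it into
    fragments that all follow the same temporal signal.  Adjacent regions
    whose *mean* traces (far less noisy than single seed pixels) have
    Pearson r >= ``merge_threshold`` are merged back into one ROA.  The
    default 0.5 demands that the majority of the temporal variance be
    shared, which fragments of one region satisfy (r -> 1 as pixel noise
    averages out) while distinct regions that merely co-activate during
    occasional concerted waves do not.  Merged regions keep the seed (and
    ordering) of their lowest original id; boundary pixels are re-derived
    as pixels adjacent to a different final region.
    """
    n = roa_map.n_roas
    if n <= 1:
        return roa_map
    labels = roa_map.labels
    pairs = set()
    for dy, dx in _neighbor_offsets(connectivity):
        a = labels[max(dy, 0) : labels.shape[0] + min(dy, 0),
                   max(dx, 0) : labels.shape[1] + min(dx, 0)]
        b = labels[max(-dy, 0) : labels.shape[0] + min(-dy, 0),
                   max(-dx, 0) : labels.shape[1] + min(-dx, 0)]
        both = (a > 0) & (b > 0) & (a != b)
        pairs.update(
            (min(int(u), int(v)), max(int(u), int(v)))
            for u, v in zip(a[both].ravel(), b[both].ravel())
        )

    parent = list(range(n + 1))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    flat = labels.ravel()
    data2 = dff.data.reshape(dff.data.shape[0], -1)
    traces = {}
    for k in range(1, n + 1):
        idx = np.nonzero(flat == k)[0]
        c = data2[:, idx].mean(axis=1)
        c = c - c.mean()
        nrm = np.linalg.norm(c)
        traces[k] = c / nrm if nrm > 0 else None

    for a, b in sorted(pairs):
        ta, tb = traces[a], traces[b]
        if ta is None or tb is None:
            continue
        if float(np.dot(ta, tb)) >= merge_threshold:
            union(a, b)

    roots = sorted({find(k) for k in range(1, n + 1)})
    remap = np.zeros(n + 1, dtype=np.int32)
    for new_id, root in enumerate(roots, start=1):
        for k in range(1, n + 1):
            if find(k) == root:
                remap[k] = new_id
    new_labels = remap[labels]
    counts = np.bincount(new_labels.ravel(), minlength=len(roots) + 1)[1:]

    # boundary = pixels adjacent to a different (final) region
    boundary = np.zeros_like(roa_map.boundary_mask)
    for dy, dx in _neighbor_offsets(connectivity):
        a_sl = (slice(max(dy, 0), new_labels.shape[0] + min(dy, 0)),
                slice(max(dx, 0), new_labels.shape[1] + min(dx, 0)))
        b_sl = (slice(max(-dy, 0), new_labels.shape[0] + min(-dy, 0)),
                slice(max(-dx, 0), new_labels.shape[1] + min(-dx, 0)))
        a = new_labels[a_sl]
        b = new_labels[b_sl]
        touch = (a > 0) & (b > 0) & (a != b)
        sub = boundary[a_sl]
        sub[touch] = True

    return ROAMap(
        labels=new_labels,
        seeds=[roa_map.seeds[root - 1] for root in roots],
        boundary_mask=boundary,
        areas=counts * roa_map.pixel_size**2,
        pixel_size=roa_map.pixel_size,
    )


def detect_roas(
    dff: DffStack, config: PipelineConfig, grow_dff: DffStack | None = None
) -> ROAMap:
    """Full ROA detection: range projection -> seeds -> growth -> merge -> area filter.

    ``grow_dff`` optionally supplies the data on which growth correlations
    are evaluated (e.g. the median-filtered-only ΔF/F0, whose noise is
    spatially independent); seeds and the range projection always come from
    ``dff``.
    """
    if grow_dff is None:
        grow_dff = dff
    rng_map = range_projection(dff)
    seeds = find_seeds(rng_map, config.seed_neighborhood, config.seed_range_k)
    logger.info("find_seeds: %d seeds", len(seeds))
    if not seeds:
        return ROAMap.empty(rng_map.shape, dff.pixel_size)
    grown = grow_regions(grow_dff, seeds, config.corr_threshold, config.connectivity)
    if config.merge_correlated:
        grown = merge_correlated_regions(
            grown, grow_dff, config.merge_threshold, config.connectivity
        )
    kept = filter_min_area(grown, config.min_roa_area)
    logger.info(
        "detect_roas: %d grown, %d kept (>= %.2f μm²), %d discarded",
        grown.n_roas,
        kept.n_roas,
        config.min_roa_area,
        grown.n_roas - kept.n_roas,
    )
    return kept
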