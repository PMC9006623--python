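"""Range projection, seed finding, and correlation-based region growing.

``oracle_grow`` is an independent brute-force implementation of the stated
growth rule: at every step it rescans all (unassigned pixel adjacent to a
region, region) pairs, computes the Pearson correlation to the claiming
seed with ``np.corrcoef``, and admits the globally best candidate
(descending r; ties by lower seed id, then row-major pixel).  Boundary
pixels are derived post-hoc: an assigned pixel is a boundary pixel iff a
different final region touches it with correlation above threshold.
"""

import numpy as np
import pytest

from roaflow import (
    PipelineConfig,
    detect_roas,
    filter_min_area,
    find_seeds,
    grow_regions,
    range_projection,
)

from conftest import make_dff

OFFS = {
    4: ((-1, 0), (0, -1), (0, 1), (1, 0)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


def oracle_grow(data, valid, seeds, thr, connectivity=8):
    T, H, W = data.shape
    offs = OFFS[connectivity]
    std = data.std(axis=0)
    ok = valid & (std > 0)
    labels = np.zeros((H, W), dtype=int)
    kept = []
    for sy, sx in seeds:
        if ok[sy, sx]:
            kept.append((sy, sx))
    for rid, (sy, sx) in enumerate(kept, start=1):
        if labels[sy, sx] == 0:
            labels[sy, sx] = rid

    cache = {}

    def corr(y, x, rid):
        key = (y, x, rid)
        if key not in cache:
            sy, sx = kept[rid - 1]
            cache[key] = float(np.corrcoef(data[:, y, x], data[:, sy, sx])[0, 1])
        return cache[key]

    while True:
        best = None
        for rid in range(1, len(kept) + 1):
            ys, xs = np.nonzero(labels == rid)
            for y, x in zip(ys, xs):
                for dy, dx in offs:
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < H and 0 <= nx < W):
                        continue
                    if labels[ny, nx] != 0 or not ok[ny, nx]:
                        continue
                    r = corr(ny, nx, rid)
                    if r >= thr:
                        cand = (-r, rid, ny, nx)
                        if best is None or cand < best:
                            best = cand
        if best is None:
            break
        _, rid, y, x = best
        labels[y, x] = rid

    boundary = np.zeros((H, W), dtype=bool)
    for y in range(H):
        for x in range(W):
            a = labels[y, x]
            if a == 0:
                continue
            for dy, dx in offs:
                ny, nx = y + dy, x + dx
                if 0 <= ny < H and 0 <= nx < W and labels[ny, nx] not in (0, a):
                    if corr(y, x, labels[ny, nx]) >= thr:
                        boundary[y, x] = True
    return labels, boundary, kept


def _random_stack(rng, n_patches, shape=(100, 16, 16)):
    """Noise stack with up to 3 implanted correlated patches; returns seeds."""
    T, H, W = shape
    data = rng.normal(0, 0.05, size=shape)
    seeds = []
    anchors = [(3, 3), (11, 10), (4, 11)]
    for p in range(n_patches):
        cy, cx = anchors[p]
        h, w = rng.integers(2, 5), rng.integers(2, 5)
        sig = rng.normal(0, 1, T)
        kernel = np.convolve(sig, np.ones(5) / 5, mode="same") * 0.2
        data[:, cy : cy + h, cx : cx + w] += kernel[:, None, None]
        seeds.append((int(cy), int(cx)))
    if not seeds:
        seeds = [(int(rng.integers(0, H)), int(rng.integers(0, W)))]
    return data, seeds


class TestRangeProjection:
    def test_matches_bruteforce_on_random_stack(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(20, 8, 8))
        dff = make_dff(data)
        expected = np.array(
            [[data[:, y, x].max() - data[:, y, x].min() for x in range(8)]
             for y in range(8)]
        )
        np.testing.assert_allclose(range_projection(dff), expected)

    def test_constant_pixel_zero_and_invalid_zero(self):
        data = np.zeros((5, 3, 3))
        data[:, 1, 1] = [-0.05, 0.0, 0.25, 0.1, 0.0]
        valid = np.ones((3, 3), bool)
        valid[2, 2] = False
        data[:, 2, 2] = [0, 5, 0, 0, 0]
        rp = range_projection(make_dff(data, valid=valid))
        assert rp[0, 0] == 0.0
        assert rp[1, 1] == pytest.approx(0.30)
        assert rp[2, 2] == 0.0


class TestFindSeeds:
    def _bump(self, cy, cx, shape=(24, 24), amp=1.0):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        return amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / 8.0))

    def test_single_bump_single_seed(self):
        seeds = find_seeds(self._bump(10, 10), neighborhood=3, k=3.0)
        assert seeds == [(10, 10)]

    def test_two_separated_bumps(self):
        m = self._bump(5, 5) + self._bump(18, 18)
        assert len(find_seeds(m, neighborhood=3, k=3.0)) == 2

    def test_flat_map_no_seeds(self):
        assert find_seeds(np.zeros((16, 16)), 3, 3.0) == []

    def test_plateau_yields_single_seed(self):
        m = np.zeros((20, 20))
        m[8:10, 8:10] = 1.0  # exact plateau, as block transforms produce
        assert find_seeds(m, 3, 3.0) == [(8, 8)]


class TestGrowRegions:
    def test_identical_traces_cover_all_valid_pixels(self):
        rng = np.random.default_rng(2)
        trace = rng.normal(size=30)
        data = np.tile(trace[:, None, None], (1, 6, 6))
        roa = grow_regions(make_dff(data), [(2, 2)], 0.2, 8)
        assert (roa.labels == 1).all()
        assert not roa.boundary_mask.any()

    @pytest.mark.parametrize("n_patches", [1, 2, 3])
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_oracle(self, n_patches, connectivity):
        rng = np.random.default_rng(10 * n_patches + connectivity)
        data, seeds = _random_stack(rng, n_patches)
        dff = make_dff(data)
        roa = grow_regions(dff, seeds, 0.2, connectivity)
        labels, boundary, kept = oracle_grow(
            data, np.ones(data.shape[1:], bool), seeds, 0.2, connectivity
        )
        np.testing.assert_array_equal(roa.labels, labels)
        np.testing.assert_array_equal(roa.boundary_mask, boundary)

    def test_boundary_pixel_keeps_higher_correlation_region(self):
        # interface pixel's trace is the average of the two seeds' traces
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        data = np.tile(rng.normal(0, 0.01, 200)[:, None, None], (1, 3, 5))
        data[:, :, 0] = a[:, None]
        data[:, :, 1] = a[:, None]
        data[:, :, 3] = b[:, None]
        data[:, :, 4] = b[:, None]
        mix = 0.6 * a + 0.4 * b  # correlates more with a
        data[:, :, 2] = mix[:, None]
        dff = make_dff(data)
        roa = grow_regions(dff, [(1, 0), (1, 4)], 0.2, 4)
        assert (roa.labels[:, 2] == 1).all()  # assigned to the higher-r region
        assert roa.boundary_mask[:, 2].all()

    def test_zero_variance_pixel_never_admitted(self):
        rng = np.random.default_rng(4)
        data = np.tile(rng.normal(size=20)[:, None, None], (1, 3, 3))
        data[:, 1, 1] = 0.0
        roa = grow_regions(make_dff(data), [(0, 0)], 0.2, 8)
        assert roa.labels[1, 1] == 0

    def test_invalid_seed_skipped(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(20, 4, 4))
        valid = np.ones((4, 4), bool)
        valid[2, 2] = False
        roa = grow_regions(make_dff(data, valid=valid), [(2, 2)], 0.2, 8)
        assert roa.n_roas == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        data, seeds = _random_stack(rng, 2)
        dff = make_dff(data)
        lo = grow_regions(dff, seeds, 0.2, 8)
        hi = grow_regions(dff, seeds, 0.6, 8)
        assert (hi.pixel_counts() <= lo.pixel_counts()).all()


class TestFilterMinArea:
    def _map_with_regions(self, sizes, pixel_size):
        """Stacked horizontal strips, one region per requested pixel count."""
        H = len(sizes) * 2
        W = max(sizes) + 1
        rng = np.random.default_rng(0)
        data = rng.normal(0, 0.01, size=(50, H, W))
        seeds = []
        for i, n in enumerate(sizes):
            tr = rng.normal(size=50)
            data[:, 2 * i, :n] += tr[:, None] * 2
            seeds.append((2 * i, 0))
        dff = make_dff(data, pixel_size=pixel_size)
        return grow_regions(dff, seeds, 0.5, 8)

    def test_small_region_removed_large_kept(self):
        roa = self._map_with_regions([4, 20], pixel_size=1.0)
        assert list(roa.pixel_counts()) == [4, 20]
        kept = filter_min_area(roa, 5.0)
        assert kept.n_roas == 1
        assert kept.areas[0] == pytest.approx(20.0)
        assert kept.labels.max() == 1  # renumbered densely

    def test_area_uses_pixel_size(self):
        roa = self._map_with_regions([30], pixel_size=0.5)
        assert roa.areas[0] == pytest.approx(30 * 0.25)
        kept = filter_min_area(roa, 5.0)
        assert kept.n_roas == 1  # 7.5 um^2 survives

    def test_areas_equal_pixel_count_times_pixel_area(self):
        roa = self._map_with_regions([4, 8, 20], pixel_size=0.7)
        np.testing.assert_allclose(roa.areas, roa.pixel_counts() * 0.49)


class TestDetectRoas:
    def test_event_free_noise_movie_empty(self):
        rng = np.random.default_rng(8)
        dff = make_dff(rng.normal(0, 0.02, size=(80, 24, 24)))
        roa = detect_roas(dff, PipelineConfig())
        assert roa.n_roas == 0

    def test_partition_and_seed_membership(self, small_astro):
        import roaflow

        cfg, movie, truth = small_astro
        roa, ev, summ = roaflow.run_pipeline(movie)
        assert roa.n_roas > 0
        # labels partition foreground; boundary within foreground
        assert roa.boundary_mask[roa.labels == 0].sum() == 0
        for k, (sy, sx) in enumerate(roa.seeds, start=1):
            assert roa.labels[sy, sx] == k
        # areas consistent with pixel counts
        np.testing.assert_allclose(
            roa.areas, roa.pixel_counts() * movie.pixel_size**2
        )
        assert (roa.areas >= PipelineConfig().min_roa_area).all()
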