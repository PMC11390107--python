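"""The five accessibility metrics and the rank-based combined score."""

import math

import numpy as np
import pytest
from skimage.color import deltaE_ciede2000, rgb2lab

from cvdscreen.color import apply_deutan
from cvdscreen.image import RasterImage, quantize, simulate_quantized
from cvdscreen.metrics import (
    ColorPairRecord,
    MetricVector,
    compute_metric_vector,
    enumerate_pairs,
    high_ratio_count,
    high_ratio_pixel_proportion,
    largest_ratio,
    max_ratio,
    mean_pixelwise_distance,
    mean_spatial_distance,
    rank_based_scores,
)
from oracles import oracle_average_ranks, oracle_metrics

RED = (255, 0, 0)
GREEN = (0, 160, 0)
GRAY = (128, 128, 128)


def _quantized(colors):
    """Quantize a nested list of 8-bit color rows into a palette image."""
    arr = np.asarray(colors, dtype=np.uint8)
    if arr.ndim == 2:
        arr = arr[None]
    return quantize(RasterImage.from_uint8(arr))


def _pair_record(ratio, dist_orig=10.0):
    return ColorPairRecord(0, 1, (0, 0, 0), (0, 0, 0), dist_orig,
                           dist_orig / ratio, ratio)


class TestMeanPixelwiseDistance:
    def test_zero_at_severity_zero(self):
        q = _quantized([[RED, GREEN]])
        sim = simulate_quantized(q, 0.0)
        assert mean_pixelwise_distance(q, sim) == 0.0

    def test_grayscale_near_zero(self):
        q = _quantized([[GRAY, (40, 40, 40)]])
        sim = simulate_quantized(q, 0.8)
        assert mean_pixelwise_distance(q, sim) < 0.005

    def test_two_pixel_value_matches_hand_computation(self):
        q = _quantized([[RED, GREEN]])
        sim = simulate_quantized(q, 0.8)
        expected = 0.0
        for c in (RED, GREEN):
            rgb = np.array(c) / 255.0
            d = deltaE_ciede2000(rgb2lab(rgb), rgb2lab(apply_deutan(rgb, 0.8)))
            expected += float(d) / 2.0
        assert mean_pixelwise_distance(q, sim) == pytest.approx(expected / 100.0, rel=1e-9)

    def test_dimension_mismatch_rejected(self):
        q1 = _quantized([[RED, GREEN]])
        q2 = _quantized([[RED, GREEN, GRAY]])
        with pytest.raises(ValueError):
            mean_pixelwise_distance(q1, simulate_quantized(q2, 0.8))


class TestEnumeratePairs:
    def test_gray_excluded(self):
        q = _quantized([[RED, GREEN, GRAY]])
        pairs = enumerate_pairs(q, simulate_quantized(q, 0.8))
        assert len(pairs) == 1
        assert pairs[0].index_a < pairs[0].index_b

    def test_four_chromatic_colors_give_six_pairs(self):
        q = _quantized([[RED, GREEN, (0, 0, 255), (255, 200, 0)]])
        pairs = enumerate_pairs(q, simulate_quantized(q, 0.8))
        assert len(pairs) == 6

    def test_fewer_than_two_chromatic_colors(self):
        q = _quantized([[RED, GRAY, (255, 255, 255)]])
        assert enumerate_pairs(q, simulate_quantized(q, 0.8)) == [] or \
            len(enumerate_pairs(q, simulate_quantized(q, 0.8))) == 0

    def test_ratio_matches_hand_computation(self):
        q = _quantized([[RED, GREEN]])
        pairs = enumerate_pairs(q, simulate_quantized(q, 0.8))
        a, b = np.array(RED) / 255.0, np.array(GREEN) / 255.0
        d_o = float(deltaE_ciede2000(rgb2lab(a), rgb2lab(b)))
        d_s = float(deltaE_ciede2000(rgb2lab(apply_deutan(a, 0.8)),
                                     rgb2lab(apply_deutan(b, 0.8))))
        assert pairs[0].dist_orig == pytest.approx(d_o, rel=1e-9)
        assert pairs[0].ratio == pytest.approx(d_o / d_s, rel=1e-9)


class TestRatioMetrics:
    def test_max_ratio_empty(self):
        assert max_ratio([]) == 0.0

    def test_max_ratio_single(self):
        assert max_ratio([_pair_record(7.2)]) == 7.2

    def test_max_ratio_selects_by_largest_original_distance(self):
        pairs = [_pair_record(2.0, dist_orig=50.0), _pair_record(9.0, dist_orig=30.0)]
        assert max_ratio(pairs) == 2.0
        assert largest_ratio(pairs) == 9.0

    def test_high_ratio_count_strict_inequality(self):
        pairs = [_pair_record(r) for r in (4.9, 5.0, 5.1)]
        assert high_ratio_count(pairs, 5.0) == 1
        assert high_ratio_count([], 5.0) == 0


class TestPixelProportion:
    def test_all_pixels_in_union(self):
        q = _quantized([[RED] * 3 + [GREEN] * 3])
        pairs = [ColorPairRecord(0, 1, (0,) * 3, (0,) * 3, 50.0, 5.0, 10.0)]
        # palette order is lexicographic; map indices onto actual palette
        pal8 = {tuple(np.rint(c * 255).astype(int)): i for i, c in enumerate(q.palette)}
        pairs = [ColorPairRecord(pal8[GREEN], pal8[RED], (0,) * 3, (0,) * 3, 50.0, 5.0, 10.0)]
        assert high_ratio_pixel_proportion(q, pairs) == 1.0

    def test_no_high_ratio_pairs(self):
        q = _quantized([[RED, GREEN]])
        assert high_ratio_pixel_proportion(q, [_pair_record(2.0)]) == 0.0

    def test_partial_coverage(self):
        row = [RED] * 2 + [GREEN] * 2 + [GRAY] * 6
        q = _quantized([row])
        pal8 = {tuple(np.rint(c * 255).astype(int)): i for i, c in enumerate(q.palette)}
        pairs = [ColorPairRecord(min(pal8[RED], pal8[GREEN]), max(pal8[RED], pal8[GREEN]),
                                 (0,) * 3, (0,) * 3, 50.0, 5.0, 10.0)]
        assert high_ratio_pixel_proportion(q, pairs) == pytest.approx(0.4)

    def test_monotone_in_threshold(self):
        q = _quantized([[RED, GREEN, (0, 0, 255), (255, 200, 0)]])
        pairs = enumerate_pairs(q, simulate_quantized(q, 0.8))
        props = [high_ratio_pixel_proportion(q, pairs, t) for t in (10.0, 5.0, 2.0, 0.5)]
        assert all(a <= b for a, b in zip(props, props[1:]))


class TestMeanSpatialDistance:
    def _pairs_for(self, q, a8, b8, ratio=10.0):
        pal8 = {tuple(np.rint(c * 255).astype(int)): i for i, c in enumerate(q.palette)}
        i, j = sorted((pal8[a8], pal8[b8]))
        return [ColorPairRecord(i, j, (0,) * 3, (0,) * 3, 50.0, 5.0, ratio)]

    def test_single_cross_pair(self):
        q = _quantized([[RED, GREEN]])
        assert mean_spatial_distance(q, self._pairs_for(q, RED, GREEN)) == 1.0

    def test_three_pixel_enumeration(self):
        q = _quantized([[RED, GREEN, GREEN]])
        assert mean_spatial_distance(q, self._pairs_for(q, RED, GREEN)) == pytest.approx(1.5)

    def test_undefined_when_no_high_ratio_pairs(self):
        q = _quantized([[RED, GREEN]])
        assert math.isnan(mean_spatial_distance(q, self._pairs_for(q, RED, GREEN, ratio=2.0)))

    def test_subsample_close_to_exact_on_two_blocks(self):
        arr = np.zeros((20, 20, 3), dtype=np.uint8)
        arr[:, :10] = RED
        arr[:, 10:] = GREEN
        q = quantize(RasterImage.from_uint8(arr))
        pairs = self._pairs_for(q, RED, GREEN)
        exact = mean_spatial_distance(q, pairs, cap=None)
        sampled = mean_spatial_distance(q, pairs, cap=10_000, seed=5)
        assert abs(sampled - exact) / exact < 0.01

    def test_seeded_subsample_deterministic(self):
        arr = np.zeros((30, 30, 3), dtype=np.uint8)
        arr[:, :15] = RED
        arr[:, 15:] = GREEN
        q = quantize(RasterImage.from_uint8(arr))
        pairs = self._pairs_for(q, RED, GREEN)
        a = mean_spatial_distance(q, pairs, cap=1000, seed=9)
        b = mean_spatial_distance(q, pairs, cap=1000, seed=9)
        assert a == b


class TestComputeMetricVector:
    def test_grayscale_fixture(self, grayscale_fixture):
        mv = grayscale_fixture.metrics
        assert mv.grayscale
        assert mv.mean_pixelwise_dist < 0.005
        assert mv.max_ratio == 0.0
        assert mv.high_ratio_count == 0
        assert mv.high_ratio_pixel_prop == 0.0
        assert math.isnan(mv.mean_spatial_dist)

    def test_confusable_fixture(self, confusable_fixture):
        mv = confusable_fixture.metrics
        assert mv.high_ratio_count >= 1
        assert mv.high_ratio_pixel_prop == 1.0

    def test_friendly_fixture(self, friendly_fixture):
        assert friendly_fixture.metrics.high_ratio_count == 0

    def test_block_permutation_changes_only_spatial_metric(self):
        a = np.zeros((300, 90, 3), dtype=np.uint8)
        a[:, :30] = (234, 63, 31)
        a[:, 30:60] = (99, 123, 1)
        a[:, 60:] = (234, 63, 31)
        b = np.zeros((300, 90, 3), dtype=np.uint8)  # blocks moved apart
        b[:, :30] = (234, 63, 31)
        b[:, 30:60] = (234, 63, 31)
        b[:, 60:] = (99, 123, 1)
        mva = compute_metric_vector(RasterImage.from_uint8(a))
        mvb = compute_metric_vector(RasterImage.from_uint8(b))
        assert mva.mean_pixelwise_dist == pytest.approx(mvb.mean_pixelwise_dist, rel=1e-12)
        assert mva.max_ratio == pytest.approx(mvb.max_ratio, rel=1e-12)
        assert mva.high_ratio_count == mvb.high_ratio_count
        assert mva.high_ratio_pixel_prop == pytest.approx(mvb.high_ratio_pixel_prop)
        assert mva.mean_spatial_dist != pytest.approx(mvb.mean_spatial_dist, rel=1e-3)


class TestOracleEquivalence:
    """Implementation vs. exhaustive brute force on tiny palette images."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_images(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(2, 7))
        pal = r.integers(0, 256, (k, 3), dtype=np.uint8)
        arr = pal[r.integers(0, k, (8, 8))]
        img = RasterImage.from_uint8(arr)
        q = quantize(img)
        sim = simulate_quantized(q, 0.8)
        expected = oracle_metrics(q.palette, sim.palette, q.index_map)
        pairs = enumerate_pairs(q, sim)
        got = {
            "mean_pixelwise_dist": mean_pixelwise_distance(q, sim),
            "max_ratio": max_ratio(pairs),
            "high_ratio_count": high_ratio_count(pairs),
            "high_ratio_pixel_prop": high_ratio_pixel_proportion(q, pairs),
            "mean_spatial_dist": mean_spatial_distance(q, pairs, cap=None),
        }
        for name, exp in expected.items():
            if isinstance(exp, float) and math.isnan(exp):
                assert math.isnan(got[name]), name
            else:
                assert got[name] == pytest.approx(exp, rel=1e-9, abs=1e-12), name


def _mv(**kw):
    base = dict(mean_pixelwise_dist=0.1, max_ratio=1.0, high_ratio_count=0,
                high_ratio_pixel_prop=0.0, mean_spatial_dist=math.nan, grayscale=False)
    base.update(kw)
    return MetricVector(**base)


class TestRankBasedScores:
    def test_identical_vectors_share_combined_score(self):
        corpus = [_mv() for _ in range(5)]
        scores = rank_based_scores(corpus)
        assert len({s.combined for s in scores}) == 1

    def test_ordered_corpus_matches_hand_ranks(self):
        corpus = [
            _mv(mean_pixelwise_dist=0.3, max_ratio=9.0, high_ratio_count=3,
                high_ratio_pixel_prop=0.9, mean_spatial_dist=5.0),
            _mv(mean_pixelwise_dist=0.2, max_ratio=6.0, high_ratio_count=2,
                high_ratio_pixel_prop=0.5, mean_spatial_dist=50.0),
            _mv(mean_pixelwise_dist=0.1, max_ratio=1.0, high_ratio_count=0,
                high_ratio_pixel_prop=0.0, mean_spatial_dist=math.nan),
        ]
        scores = rank_based_scores(corpus)
        assert [s.combined for s in scores] == [1.0, 2.0, 3.0]

    def test_permutation_invariance(self, rng):
        corpus = [
            _mv(mean_pixelwise_dist=float(rng.random()), max_ratio=float(rng.random() * 10),
                high_ratio_count=int(rng.integers(0, 4)),
                high_ratio_pixel_prop=float(rng.random()),
                mean_spatial_dist=float(rng.random() * 100) if rng.random() > 0.3 else math.nan)
            for _ in range(20)
        ]
        base = {v.source_id or i: s.combined
                for i, (v, s) in enumerate(zip(corpus, rank_based_scores(corpus)))}
        perm = list(np.random.default_rng(3).permutation(20))
        shuffled = [corpus[i] for i in perm]
        got = rank_based_scores(shuffled)
        for j, i in enumerate(perm):
            assert got[j].combined == pytest.approx(base[i])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_average_ranks(self, seed):
        r = np.random.default_rng(seed)
        corpus = []
        for _ in range(50):
            corpus.append(_mv(
                mean_pixelwise_dist=float(r.choice([0.1, 0.2, 0.3])),  # force ties
                max_ratio=float(r.choice([0.0, 5.0, 8.0])),
                high_ratio_count=int(r.integers(0, 3)),
                high_ratio_pixel_prop=float(r.choice([0.0, 0.5, 1.0])),
                mean_spatial_dist=float(r.choice([10.0, 40.0])) if r.random() > 0.4 else math.nan,
            ))
        scores = rank_based_scores(corpus)
        expected = {
            "mean_pixelwise_dist": oracle_average_ranks([v.mean_pixelwise_dist for v in corpus]),
            "max_ratio": oracle_average_ranks([v.max_ratio for v in corpus]),
            "high_ratio_count": oracle_average_ranks([float(v.high_ratio_count) for v in corpus]),
            "high_ratio_pixel_prop": oracle_average_ranks([v.high_ratio_pixel_prop for v in corpus]),
            "mean_spatial_dist": oracle_average_ranks(
                [v.mean_spatial_dist for v in corpus], higher_is_worse=False),
        }
        for i, s in enumerate(scores):
            for name, exp in expected.items():
                assert s.per_metric_ranks[name] == pytest.approx(exp[i]), name
            comb = np.mean([expected[name][i] for name in expected])
            assert s.combined == pytest.approx(comb)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            rank_based_scores([])
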