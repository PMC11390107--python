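"""Per-image color-accessibility metrics and the corpus-level rank score.

Five quantities summarize how much chromatic contrast an image loses under
deuteranopia simulation:

1. ``mean_pixelwise_dist`` — mean CIEDE2000 difference between each pixel's
   original and simulated color, divided by 100 so values live on a 0-1-ish
   scale.
2. ``max_ratio`` — for the chromatic color pair with the largest original
   CIEDE2000 distance, the ratio of original to simulated distance.
3. ``high_ratio_count`` — number of chromatic color pairs whose
   original/simulated distance ratio exceeds a threshold (default 5):
   pairs with high contrast for normal trichromats but low contrast for
   deuteranopes.
4. ``high_ratio_pixel_prop`` — proportion of pixels whose color belongs to
   at least one high-ratio pair.
5. ``mean_spatial_dist`` — mean two-dimensional Euclidean distance (in
   pixels of the resized image) between pixels of the two colors of each
   high-ratio pair, averaged over those pairs; colors that are confusable
   *and* adjacent are worse than confusable colors far apart.  Undefined
   (NaN) when there are no high-ratio pairs.

Black, white, and gray palette entries are excluded from pair enumeration.
A corpus is prioritized by ranking each metric (rank 1 = most problematic)
and averaging the five ranks into a combined score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .color import delta_e_2000, is_achromatic, srgb_to_lab
from .image import (
    DEFAULT_MAX_COLORS,
    DEFAULT_TARGET_HEIGHT,
    QuantizedImage,
    RasterImage,
    detect_grayscale,
    quantize,
    resize_to_height,
    simulate_quantized,
)

__all__ = [
    "ColorPairRecord",
    "MetricVector",
    "RankScore",
    "METRIC_COLUMNS",
    "DEFAULT_RATIO_THRESHOLD",
    "DEFAULT_SPREAD_TOL",
    "DEFAULT_SEVERITY",
    "mean_pixelwise_distance",
    "enumerate_pairs",
    "max_ratio",
    "largest_ratio",
    "high_ratio_count",
    "high_ratio_pixel_proportion",
    "mean_spatial_distance",
    "compute_metric_vector",
    "rank_based_scores",
]

DEFAULT_SEVERITY = 0.8
DEFAULT_RATIO_THRESHOLD = 5.0
DEFAULT_SPREAD_TOL = 10.0
DEFAULT_RATIO_EPS = 1e-6
DEFAULT_RATIO_CAP = 1e6
DEFAULT_SPATIAL_CAP = 100_000

#: Fixed serialization order for metric tables.
METRIC_COLUMNS = (
    "mean_pixelwise_dist",
    "max_ratio",
    "high_ratio_count",
    "high_ratio_pixel_prop",
    "mean_spatial_dist",
    "grayscale",
)


@dataclass(frozen=True)
class ColorPairRecord:
    """An unordered pair of chromatic palette colors with original and
    simulated CIEDE2000 distances and their ratio.  ``index_a < index_b``
    refer to positions in the originating palette."""

    index_a: int
    index_b: int
    color_a: tuple[float, float, float]
    color_b: tuple[float, float, float]
    dist_orig: float
    dist_sim: float
    ratio: float


@dataclass
class MetricVector:
    """The five per-image accessibility metrics plus the grayscale flag.

    ``mean_spatial_dist`` is NaN when the image has no high-ratio pair;
    ranking treats that as least problematic.
    """

    mean_pixelwise_dist: float
    max_ratio: float
    high_ratio_count: int
    high_ratio_pixel_prop: float
    mean_spatial_dist: float
    grayscale: bool
    source_id: str = ""

    def to_dict(self) -> dict:
        d = {c: getattr(self, c) for c in METRIC_COLUMNS}
        d["source_id"] = self.source_id
        return d

    def feature_array(self) -> np.ndarray:
        """The five numeric metrics in canonical order (spatial may be NaN)."""
        return np.array(
            [self.mean_pixelwise_dist, self.max_ratio, float(self.high_ratio_count),
             self.high_ratio_pixel_prop, self.mean_spatial_dist], dtype=np.float64
        )


@dataclass
class RankScore:
    """Per-metric ranks (1 = most problematic) and their mean."""

    per_metric_ranks: dict[str, float]
    combined: float


def mean_pixelwise_distance(orig: QuantizedImage, sim: QuantizedImage) -> float:
    """Mean per-pixel CIEDE2000 between original and simulated image, / 100.

    Because the simulation is palette-wise, the mean is the count-weighted
    mean of palette-entry distances.
    """
    if orig.index_map.shape != sim.index_map.shape:
        raise ValueError("original and simulated dimensions differ")
    if len(orig.palette) != len(sim.palette):
        raise ValueError("palettes do not correspond")
    d = delta_e_2000(srgb_to_lab(orig.palette), srgb_to_lab(sim.palette))
    d = np.abs(np.atleast_1d(d))
    return float((d * orig.counts).sum() / orig.counts.sum() / 100.0)


def enumerate_pairs(
    orig: QuantizedImage,
    sim: QuantizedImage,
    spread_tol: float = DEFAULT_SPREAD_TOL,
    eps: float = DEFAULT_RATIO_EPS,
    ratio_cap: float = DEFAULT_RATIO_CAP,
) -> list[ColorPairRecord]:
    """All unordered pairs of chromatic palette colors with original and
    simulated distances.

    ``sim`` must be the palette-wise simulation of ``orig`` (positional
    correspondence).  Achromatic entries are excluded; the ratio divides by
    ``max(dist_sim, eps)`` and is capped at ``ratio_cap``.
    """
    if len(orig.palette) != len(sim.palette):
        raise ValueError("palettes do not correspond")
    chrom = np.flatnonzero(~np.atleast_1d(is_achromatic(orig.palette, spread_tol)))
    if len(chrom) < 2:
        return []
    lab_o = srgb_to_lab(orig.palette[chrom])
    lab_s = srgb_to_lab(sim.palette[chrom])
    ii, jj = np.triu_indices(len(chrom), k=1)
    d_o = np.abs(np.atleast_1d(delta_e_2000(lab_o[ii], lab_o[jj])))
    d_s = np.abs(np.atleast_1d(delta_e_2000(lab_s[ii], lab_s[jj])))
    ratios = np.minimum(d_o / np.maximum(d_s, eps), ratio_cap)
    records = []
    for k in range(len(ii)):
        a, b = int(chrom[ii[k]]), int(chrom[jj[k]])
        records.append(
            ColorPairRecord(
                index_a=a,
                index_b=b,
                color_a=tuple(orig.palette[a]),
                color_b=tuple(orig.palette[b]),
                dist_orig=float(d_o[k]),
                dist_sim=float(d_s[k]),
                ratio=float(ratios[k]),
            )
        )
    return records


def max_ratio(pairs: Sequence[ColorPairRecord]) -> float:
    """Ratio of the pair with the largest *original* distance; 0 if empty.

    Note this selects by original contrast, not by largest ratio; see
    :func:`largest_ratio` for the alternative reading.
    """
    if not pairs:
        return 0.0
    best = max(pairs, key=lambda p: p.dist_orig)
    return best.ratio


def largest_ratio(pairs: Sequence[ColorPairRecord]) -> float:
    """The maximum ratio over all pairs; 0 if empty."""
    if not pairs:
        return 0.0
    return max(p.ratio for p in pairs)


def high_ratio_count(pairs: Sequence[ColorPairRecord],
                     threshold: float = DEFAULT_RATIO_THRESHOLD) -> int:
    """Number of pairs with ratio strictly greater than the threshold."""
    return sum(1 for p in pairs if p.ratio > threshold)


def high_ratio_pixel_proportion(
    q: QuantizedImage,
    pairs: Sequence[ColorPairRecord],
    threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> float:
    """Fraction of pixels whose palette color appears in a high-ratio pair."""
    high = {i for p in pairs if p.ratio > threshold for i in (p.index_a, p.index_b)}
    if not high:
        return 0.0
    n = sum(int(q.counts[i]) for i in high)
    return n / int(q.counts.sum())


def _cross_distance_mean(
    pos_a: np.ndarray, pos_b: np.ndarray, cap: int | None, rng: np.random.Generator
) -> float:
    """Mean Euclidean distance over the cross product of two position sets,
    uniformly subsampled to ``cap`` pairs when the product exceeds it."""
    na, nb = len(pos_a), len(pos_b)
    total = na * nb
    if cap is None or total <= cap:
        diff = pos_a[:, None, :] - pos_b[None, :, :]
        return float(np.hypot(diff[..., 0], diff[..., 1]).mean())
    ia = rng.integers(0, na, size=cap)
    ib = rng.integers(0, nb, size=cap)
    d = pos_a[ia] - pos_b[ib]
    return float(np.hypot(d[:, 0], d[:, 1]).mean())


def mean_spatial_distance(
    q: QuantizedImage,
    pairs: Sequence[ColorPairRecord],
    threshold: float = DEFAULT_RATIO_THRESHOLD,
    cap: int | None = DEFAULT_SPATIAL_CAP,
    seed: int = 0,
    pool_cross_pairs: bool = False,
) -> float:
    """Mean 2-D distance between pixels of the two colors of each
    high-ratio pair, in pixel units of the (resized) image.

    Default behavior averages the per-pair means with equal weight;
    ``pool_cross_pairs=True`` instead pools every cross pixel pair across
    color pairs (weighting each color pair by its number of pixel pairs).
    Returns NaN when there is no high-ratio pair.  When a pair has more
    than ``cap`` cross pixel pairs, a seeded uniform subsample of ``cap``
    pairs is used.
    """
    high = [p for p in pairs if p.ratio > threshold]
    if not high:
        return math.nan
    rng = np.random.default_rng(seed)
    means, weights = [], []
    for p in high:
        pos_a = np.argwhere(q.index_map == p.index_a).astype(np.float64)
        pos_b = np.argwhere(q.index_map == p.index_b).astype(np.float64)
        means.append(_cross_distance_mean(pos_a, pos_b, cap, rng))
        weights.append(len(pos_a) * len(pos_b))
    if pool_cross_pairs:
        return float(np.average(means, weights=weights))
    return float(np.mean(means))


def compute_metric_vector(
    img: RasterImage,
    severity: float = DEFAULT_SEVERITY,
    *,
    target_height: int = DEFAULT_TARGET_HEIGHT,
    max_colors: int = DEFAULT_MAX_COLORS,
    spread_tol: float = DEFAULT_SPREAD_TOL,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    eps: float = DEFAULT_RATIO_EPS,
    ratio_cap: float = DEFAULT_RATIO_CAP,
    spatial_cap: int | None = DEFAULT_SPATIAL_CAP,
    seed: int = 0,
    linear_rgb: bool = False,
    pool_cross_pairs: bool = False,
) -> MetricVector:
    """Run the full per-image pipeline: resize to a standard height,
    quantize to at most 256 colors, simulate deuteranopia palette-wise,
    and compute the five metrics.  Deterministic for a fixed seed."""
    resized = resize_to_height(img, target_height)
    q = quantize(resized, max_colors)
    sim = simulate_quantized(q, severity, linear_rgb=linear_rgb)
    gray = detect_grayscale(q, spread_tol)
    pairs = enumerate_pairs(q, sim, spread_tol, eps, ratio_cap)
    return MetricVector(
        mean_pixelwise_dist=mean_pixelwise_distance(q, sim),
        max_ratio=max_ratio(pairs),
        high_ratio_count=high_ratio_count(pairs, ratio_threshold),
        high_ratio_pixel_prop=high_ratio_pixel_proportion(q, pairs, ratio_threshold),
        mean_spatial_dist=mean_spatial_distance(
            q, pairs, ratio_threshold, spatial_cap, seed, pool_cross_pairs
        ),
        grayscale=gray,
        source_id=img.source_id,
    )


def rank_based_scores(corpus: Sequence[MetricVector]) -> list[RankScore]:
    """Rank each metric across a corpus and average the five ranks.

    Rank 1 is the most problematic image for that metric: the *largest*
    value for the four loss-of-contrast metrics, the *smallest* value for
    the spatial-distance metric (confusable colors close together are
    worse).  Undefined spatial distances rank as least problematic.  Ties
    receive the average of the tied ranks.
    """
    if len(corpus) == 0:
        raise ValueError("corpus must be non-empty")
    cols = {
        "mean_pixelwise_dist": np.array([v.mean_pixelwise_dist for v in corpus]),
        "max_ratio": np.array([v.max_ratio for v in corpus]),
        "high_ratio_count": np.array([float(v.high_ratio_count) for v in corpus]),
        "high_ratio_pixel_prop": np.array([v.high_ratio_pixel_prop for v in corpus]),
    }
    ranks = {name: rankdata(-vals, method="average") for name, vals in cols.items()}
    spatial = np.array([v.mean_spatial_dist for v in corpus])
    spatial = np.where(np.isnan(spatial), np.inf, spatial)
    ranks["mean_spatial_dist"] = rankdata(spatial, method="average")
    out = []
    for i in range(len(corpus)):
        per = {name: float(r[i]) for name, r in ranks.items()}
        out.append(RankScore(per_metric_ranks=per, combined=float(np.mean(list(per.values())))))
    return out
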