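"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: explicit Python loops, skimage's CIEDE2000 (not the
package's own), no subsampling, no vectorization.  These never import the
metric implementations they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from skimage.color import deltaE_ciede2000, rgb2lab


def oracle_delta_e(rgb_a, rgb_b) -> float:
    return float(deltaE_ciede2000(rgb2lab(np.asarray(rgb_a, dtype=float)),
                                  rgb2lab(np.asarray(rgb_b, dtype=float))))


def oracle_is_achromatic(rgb, spread_tol: float) -> bool:
    v = [c * 255.0 for c in rgb]
    return (max(v) - min(v)) <= spread_tol


def oracle_metrics(palette, sim_palette, index_map, spread_tol=10.0,
                   threshold=5.0, eps=1e-6, ratio_cap=1e6) -> dict:
    """All five metrics by exhaustive enumeration on a quantized image.

    ``palette``/``sim_palette`` are (k, 3) unit-range float arrays with
    positional correspondence; ``index_map`` is (h, w) palette indices.
    Spatial distance is exact (all cross pixel pairs, no cap).
    """
    palette = np.asarray(palette, dtype=float)
    sim_palette = np.asarray(sim_palette, dtype=float)
    index_map = np.asarray(index_map)
    h, w = index_map.shape
    n_pixels = h * w
    counts = {k: 0 for k in range(len(palette))}
    for i in range(h):
        for j in range(w):
            counts[int(index_map[i, j])] += 1

    # mean pixel-wise original-vs-simulated distance / 100
    total = 0.0
    for i in range(h):
        for j in range(w):
            k = int(index_map[i, j])
            total += oracle_delta_e(palette[k], sim_palette[k])
    mean_pixelwise = total / n_pixels / 100.0

    chromatic = [k for k in range(len(palette))
                 if not oracle_is_achromatic(palette[k], spread_tol)]
    pairs = []
    for a, b in combinations(chromatic, 2):
        d_o = oracle_delta_e(palette[a], palette[b])
        d_s = oracle_delta_e(sim_palette[a], sim_palette[b])
        ratio = min(d_o / max(d_s, eps), ratio_cap)
        pairs.append((a, b, d_o, d_s, ratio))

    if pairs:
        best = max(pairs, key=lambda p: p[2])
        max_ratio = best[4]
    else:
        max_ratio = 0.0
    high = [p for p in pairs if p[4] > threshold]
    high_count = len(high)

    high_colors = set()
    for a, b, *_ in high:
        high_colors.add(a)
        high_colors.add(b)
    prop = sum(counts[k] for k in high_colors) / n_pixels if high_colors else 0.0

    if not high:
        spatial = math.nan
    else:
        per_pair = []
        for a, b, *_ in high:
            pos_a = [(i, j) for i in range(h) for j in range(w)
                     if index_map[i, j] == a]
            pos_b = [(i, j) for i in range(h) for j in range(w)
                     if index_map[i, j] == b]
            dists = [math.hypot(ia - ib, ja - jb)
                     for ia, ja in pos_a for ib, jb in pos_b]
            per_pair.append(sum(dists) / len(dists))
        spatial = sum(per_pair) / len(per_pair)

    return {
        "mean_pixelwise_dist": mean_pixelwise,
        "max_ratio": max_ratio,
        "high_ratio_count": high_count,
        "high_ratio_pixel_prop": prop,
        "mean_spatial_dist": spatial,
    }


def oracle_auroc(scores, labels) -> float:
    """Concordant-pair (Mann-Whitney) AUROC: ties count half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return math.nan
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_average_ranks(values, higher_is_worse=True) -> list[float]:
    """Average ranks with rank 1 = most problematic; NaN ranks last."""
    n = len(values)

    def key(v):
        if isinstance(v, float) and math.isnan(v):
            return math.inf  # least problematic under either orientation
        return -v if higher_is_worse else v

    keyed = [key(v) for v in values]
    ranks = []
    for i in range(n):
        smaller = sum(1 for j in range(n) if keyed[j] < keyed[i])
        equal = sum(1 for j in range(n) if keyed[j] == keyed[i])
        ranks.append(smaller + (equal + 1) / 2.0)
    return ranks
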