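"""Deterministic synthetic images with known chromatic structure.

Real figure corpora (and their human review labels) cannot ship with the
package, so every other module is exercised against generated fixtures
whose chromatic properties are *certified*: after an image is generated,
the promised facts (e.g. "contains at least one high-ratio color pair and
every pixel uses one of its colors", or "all pairwise ratios are below the
threshold") are recomputed with the metrics module and generation fails
loudly if they do not hold.  The presence of particular color
combinations does not by itself make an image problematic, so the
promises are checked, not assumed.

Confusable palettes draw on red/brown vs. olive/green combinations —
high contrast for normal trichromats that largely collapses under
deuteranopia simulation.  Friendly palettes use blue/orange and
blue/yellow combinations that survive simulation.

Fixtures are generated at the pipeline's native 300-pixel height so the
resize step is the identity and certificates are exact; PNG round-trips
are lossless for these palettes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import LabeledExample, ReviewLabel
from .image import RasterImage, save_png
from .metrics import MetricVector, compute_metric_vector

__all__ = [
    "FixtureSpec",
    "CertifiedFixture",
    "FixtureCertificationError",
    "CONFUSABLE_PALETTES",
    "FRIENDLY_PALETTES",
    "make_fixture",
    "make_labeled_corpus",
    "save_corpus",
    "corpus_to_examples",
]

DEFAULT_HEIGHT = 300
DEFAULT_BLOCK_WIDTH = 60

#: Certified-by-construction color pairs (8-bit sRGB) whose CIEDE2000
#: original/simulated ratio at severity 0.8 comfortably exceeds 5.
CONFUSABLE_PALETTES: tuple[tuple[tuple[int, int, int], tuple[int, int, int]], ...] = (
    ((234, 63, 31), (99, 123, 1)),     # red vs. olive green
    ((173, 73, 36), (97, 102, 17)),    # brick vs. dark olive
    ((206, 137, 29), (100, 192, 0)),   # ochre vs. green
    ((240, 158, 27), (81, 231, 3)),    # orange vs. bright green
    ((182, 134, 46), (107, 161, 29)),  # tan vs. moss green
)

#: Color pairs whose ratio stays well below 5 (contrast survives simulation).
FRIENDLY_PALETTES: tuple[tuple[tuple[int, int, int], tuple[int, int, int]], ...] = (
    ((40, 80, 200), (240, 150, 40)),   # blue vs. orange
    ((50, 90, 220), (240, 220, 60)),   # blue vs. yellow
    ((40, 80, 200), (220, 50, 40)),    # blue vs. red
    ((140, 60, 180), (40, 170, 170)),  # purple vs. teal
)

_GRAY_LEVELS = ((40, 40, 40), (128, 128, 128), (220, 220, 220))


class FixtureCertificationError(RuntimeError):
    """A generated fixture failed its promised chromatic certificate."""


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic image.

    ``kind`` is one of grayscale, confusable_blocks, friendly_blocks,
    labeled_blocks, gradient.  ``palette`` lists 8-bit sRGB colors;
    block kinds use the first two as the left/right fields.  ``gap``
    inserts a mid-gray spacer between the fields (0 = full bleed);
    ``block_width`` sets each field's width in columns.  Generation is a
    pure function of the spec.
    """

    kind: str
    height: int = DEFAULT_HEIGHT
    block_width: int = DEFAULT_BLOCK_WIDTH
    gap: int = 0
    palette: tuple[tuple[int, int, int], ...] = ()
    seed: int = 0
    name: str = ""


@dataclass
class CertifiedFixture:
    image: RasterImage
    ground_truth: ReviewLabel
    certificate: dict
    spec: FixtureSpec

    @property
    def metrics(self) -> MetricVector:
        return self.certificate["metric_vector"]


def _blocks_array(spec: FixtureSpec) -> np.ndarray:
    a, b = spec.palette[0], spec.palette[1]
    h, bw, gap = spec.height, spec.block_width, spec.gap
    img = np.empty((h, 2 * bw + gap, 3), dtype=np.uint8)
    img[:, :bw] = a
    if gap:
        img[:, bw:bw + gap] = (128, 128, 128)
    img[:, bw + gap:] = b
    return img


def _grayscale_array(spec: FixtureSpec) -> np.ndarray:
    levels = spec.palette or _GRAY_LEVELS
    h = spec.height
    w = spec.block_width * len(levels)
    img = np.empty((h, w, 3), dtype=np.uint8)
    for i, lev in enumerate(levels):
        img[:, i * spec.block_width:(i + 1) * spec.block_width] = lev
    return img


def _gradient_array(spec: FixtureSpec) -> np.ndarray:
    a = np.array(spec.palette[0], dtype=np.float64)
    b = np.array(spec.palette[1], dtype=np.float64)
    w = max(2, 2 * spec.block_width + spec.gap)
    t = np.linspace(0.0, 1.0, w)[:, None]
    row = np.rint(a * (1 - t) + b * t).astype(np.uint8)
    return np.broadcast_to(row[None, :, :], (spec.height, w, 3)).copy()


def _labeled_array(spec: FixtureSpec) -> np.ndarray:
    # Confusable blocks with dark label strips, emulating within-image
    # text labels that can mitigate problematic colors.
    img = _blocks_array(spec)
    h, w = img.shape[:2]
    sh = max(4, h // 20)
    img[h // 8: h // 8 + sh, w // 10: w // 2 - w // 10] = (20, 20, 20)
    img[h // 8: h // 8 + sh, w // 2 + w // 10: w - w // 10] = (20, 20, 20)
    return img


def make_fixture(spec: FixtureSpec, severity: float = 0.8) -> CertifiedFixture:
    """Generate an image from a spec and certify its chromatic promises.

    Raises :class:`FixtureCertificationError` naming the failed fact when
    the promised property does not hold (e.g. a "friendly" palette that is
    actually confusable).
    """
    builders = {
        "grayscale": _grayscale_array,
        "confusable_blocks": _blocks_array,
        "friendly_blocks": _blocks_array,
        "labeled_blocks": _labeled_array,
        "gradient": _gradient_array,
    }
    if spec.kind not in builders:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    if spec.kind != "grayscale" and len(spec.palette) < 2:
        raise ValueError(f"kind {spec.kind!r} needs at least two palette colors")
    arr = builders[spec.kind](spec)
    img = RasterImage.from_uint8(arr, source_id=spec.name or f"{spec.kind}:{spec.seed}")
    mv = compute_metric_vector(img, severity, seed=spec.seed)

    cert: dict = {"metric_vector": mv, "kind": spec.kind}
    if spec.kind == "grayscale":
        if not mv.grayscale:
            raise FixtureCertificationError("grayscale fixture contains chromatic colors")
        truth = ReviewLabel.GRAYSCALE
        cert["fact"] = "all palette colors achromatic"
    elif spec.kind in ("confusable_blocks", "labeled_blocks"):
        if mv.high_ratio_count < 1:
            raise FixtureCertificationError(
                f"confusable fixture has no high-ratio pair (max_ratio={mv.max_ratio:.2f})"
            )
        if spec.kind == "confusable_blocks" and spec.gap == 0 and mv.high_ratio_pixel_prop < 1.0:
            raise FixtureCertificationError(
                "full-bleed confusable fixture must have every pixel in a high-ratio pair"
            )
        truth = ReviewLabel.DEFINITELY_PROBLEMATIC
        cert["fact"] = ">=1 pair with ratio > 5"
    elif spec.kind == "friendly_blocks":
        if mv.high_ratio_count != 0:
            raise FixtureCertificationError(
                f"friendly fixture has {mv.high_ratio_count} high-ratio pair(s)"
            )
        if mv.grayscale:
            raise FixtureCertificationError("friendly fixture must be chromatic")
        truth = ReviewLabel.DEFINITELY_OKAY
        cert["fact"] = "all pairwise ratios < 5"
    else:  # gradient: no promise beyond construction; label follows metrics
        truth = (ReviewLabel.DEFINITELY_PROBLEMATIC if mv.high_ratio_count >= 1
                 else ReviewLabel.DEFINITELY_OKAY)
        cert["fact"] = "gradient between palette endpoints"
    return CertifiedFixture(img, truth, cert, spec)


def _jitter(color: tuple[int, int, int], rng: np.random.Generator,
            amount: int = 8) -> tuple[int, int, int]:
    c = np.array(color, dtype=np.int64) + rng.integers(-amount, amount + 1, 3)
    return tuple(int(v) for v in np.clip(c, 0, 255))


def make_labeled_corpus(
    n: int,
    problem_fraction: float = 0.1,
    seed: int = 0,
    *,
    height: int = DEFAULT_HEIGHT,
    block_width: int = DEFAULT_BLOCK_WIDTH,
    grayscale_fraction: float = 0.2,
    severity: float = 0.8,
) -> list[CertifiedFixture]:
    """Generate ``n`` certified fixtures with exact label counts.

    ``round(n * problem_fraction)`` fixtures are problematic (certified
    confusable palettes, adjacent blocks); the rest are okay (certified
    friendly palettes, with a fraction of grayscale images, all labeled
    definitely okay — a colorless image poses no deutan-contrast problem).
    Geometry and palettes are jittered deterministically per seed; each
    fixture's certificate is verified, falling back to the unjittered base
    palette if a jittered palette fails certification.
    """
    if n < 20:
        raise ValueError("corpus size must be at least 20")
    if not 0.0 < problem_fraction < 1.0:
        raise ValueError("problem_fraction must be strictly between 0 and 1")
    n_prob = round(n * problem_fraction)
    if n_prob < 1 or n_prob >= n:
        raise ValueError(f"infeasible label counts: {n_prob} of {n} problematic")
    master = np.random.default_rng(seed)
    fixtures: list[CertifiedFixture] = []
    for i in range(n):
        rng = np.random.default_rng(master.integers(0, 2**31))
        bw = int(block_width + rng.integers(-10, 11))
        problematic = i < n_prob
        if problematic:
            bases, kind = CONFUSABLE_PALETTES, "confusable_blocks"
        elif rng.random() < grayscale_fraction:
            bases, kind = None, "grayscale"
        else:
            bases, kind = FRIENDLY_PALETTES, "friendly_blocks"
        if kind == "grayscale":
            levels = tuple(
                (int(v), int(v), int(v)) for v in sorted(rng.integers(20, 236, 3))
            )
            spec = FixtureSpec("grayscale", height, bw, palette=levels,
                               seed=seed + i, name=f"corpus-{seed}-{i:04d}-gray")
            fx = make_fixture(spec, severity)
            fx = CertifiedFixture(fx.image, ReviewLabel.DEFINITELY_OKAY,
                                  fx.certificate, fx.spec)
            fixtures.append(fx)
            continue
        base = bases[int(rng.integers(0, len(bases)))]
        fx = None
        for _attempt in range(10):
            pal = (_jitter(base[0], rng), _jitter(base[1], rng))
            spec = FixtureSpec(kind, height, bw, palette=pal, seed=seed + i,
                               name=f"corpus-{seed}-{i:04d}-{kind}")
            try:
                fx = make_fixture(spec, severity)
                break
            except FixtureCertificationError:
                continue
        if fx is None:  # certified base palette always passes
            spec = FixtureSpec(kind, height, bw, palette=base, seed=seed + i,
                               name=f"corpus-{seed}-{i:04d}-{kind}")
            fx = make_fixture(spec, severity)
        fixtures.append(fx)
    labels = [f.ground_truth for f in fixtures]
    assert labels.count(ReviewLabel.DEFINITELY_PROBLEMATIC) == n_prob
    return fixtures


def corpus_to_examples(fixtures: Sequence[CertifiedFixture]) -> list[LabeledExample]:
    """View a certified corpus as labeled classifier examples."""
    return [LabeledExample(f.metrics, f.ground_truth, f.image.source_id)
            for f in fixtures]


def save_corpus(fixtures: Sequence[CertifiedFixture], out_dir: str | Path) -> Path:
    """Write fixtures as PNGs plus a ``manifest.csv`` (path, label, and a
    certificate summary); returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, fx in enumerate(fixtures):
        name = f"fixture_{i:04d}.png"
        save_png(fx.image, out_dir / name)
        mv = fx.metrics
        rows.append({
            "path": name,
            "label": fx.ground_truth.value,
            "kind": fx.spec.kind,
            "certificate": fx.certificate.get("fact", ""),
            "high_ratio_count": mv.high_ratio_count,
            "high_ratio_pixel_prop": mv.high_ratio_pixel_prop,
            "mean_spatial_dist": mv.mean_spatial_dist,
            "grayscale": mv.grayscale,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
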