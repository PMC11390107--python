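"""Decode, normalize, resize, quantize, and grayscale-screen raster images.

The preprocessing pipeline standardizes figures before accessibility
metrics are computed: scale to a uniform 300-pixel height (aspect
preserved, bilinear), then reduce to a palette of at most 256 colors with
a deterministic median-cut quantizer.  Determinism matters here: tests and
batch re-runs must produce identical palettes, so the quantizer uses fixed
tie-breaking rules rather than an external imaging tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .color import apply_deutan, is_achromatic

__all__ = [
    "RasterImage",
    "QuantizedImage",
    "ImageDecodeError",
    "load_image",
    "resize_to_height",
    "quantize",
    "simulate_quantized",
    "detect_grayscale",
    "save_png",
]

DEFAULT_TARGET_HEIGHT = 300
DEFAULT_MAX_COLORS = 256


class ImageDecodeError(ValueError):
    """Raised when a file cannot be decoded as a supported raster image."""


@dataclass
class RasterImage:
    """Decoded pixel grid in gamma-encoded sRGB, unit range.

    ``pixels`` has shape (height, width, 3), float32 in [0, 1];
    ``source_id`` is an opaque provenance string (usually the file path).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("pixels must have shape (height, width, 3)")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def to_uint8(self) -> np.ndarray:
        return np.rint(self.pixels * 255.0).astype(np.uint8)

    @classmethod
    def from_uint8(cls, arr: np.ndarray, source_id: str = "") -> "RasterImage":
        return cls(np.asarray(arr, dtype=np.float32) / 255.0, source_id)


@dataclass
class QuantizedImage:
    """Palette-indexed image: at most 256 palette colors (unit-range sRGB
    rows), a per-pixel index map, and per-entry pixel counts."""

    palette: np.ndarray        # (k, 3) float64 in [0, 1]
    index_map: np.ndarray      # (height, width) integer indices into palette
    counts: np.ndarray         # (k,) pixel tallies
    source_id: str = ""

    def __post_init__(self) -> None:
        self.palette = np.asarray(self.palette, dtype=np.float64)
        self.index_map = np.asarray(self.index_map)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.palette.ndim != 2 or self.palette.shape[1] != 3:
            raise ValueError("palette must have shape (k, 3)")
        if len(self.counts) != len(self.palette):
            raise ValueError("counts must align with palette")
        if int(self.counts.sum()) != self.index_map.size:
            raise ValueError("counts must sum to the pixel count")

    @property
    def height(self) -> int:
        return self.index_map.shape[0]

    @property
    def width(self) -> int:
        return self.index_map.shape[1]

    @property
    def n_colors(self) -> int:
        return len(self.palette)

    def reconstruct(self) -> RasterImage:
        """Rebuild a RasterImage by looking up each pixel's palette color."""
        return RasterImage(self.palette[self.index_map].astype(np.float32), self.source_id)


def load_image(path: str | Path) -> RasterImage:
    """Decode a PNG or JPEG file into sRGB; alpha is composited over white.

    Raises :class:`ImageDecodeError` naming the path for unreadable,
    truncated, or unsupported files.
    """
    path = Path(path)
    if not path.exists():
        raise ImageDecodeError(f"no such file: {path}")
    try:
        with Image.open(path) as im:
            if im.format not in ("PNG", "JPEG"):
                raise ImageDecodeError(f"unsupported format {im.format!r}: {path}")
            if im.mode in ("RGBA", "LA", "PA") or (im.mode == "P" and "transparency" in im.info):
                rgba = im.convert("RGBA")
                bg = Image.new("RGBA", rgba.size, (255, 255, 255, 255))
                rgb = Image.alpha_composite(bg, rgba).convert("RGB")
            else:
                rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except ImageDecodeError:
        raise
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ImageDecodeError(f"cannot decode image {path}: {exc}") from exc
    return RasterImage.from_uint8(arr, source_id=str(path))


def save_png(img: RasterImage, path: str | Path) -> Path:
    """Write an image as PNG (lossless for 8-bit palettes)."""
    path = Path(path)
    Image.fromarray(img.to_uint8(), mode="RGB").save(path, format="PNG")
    return path


def resize_to_height(img: RasterImage, target_h: int = DEFAULT_TARGET_HEIGHT) -> RasterImage:
    """Scale to the target height, preserving aspect ratio (bilinear).

    Width becomes ``round(width * target_h / height)`` with a floor of one
    pixel; upscaling is permitted so that all images share a uniform height.
    """
    if img.pixels.size == 0:
        raise ValueError("cannot resize an empty image")
    if target_h < 1:
        raise ValueError("target height must be positive")
    if img.height == target_h:
        return img
    new_w = max(1, round(img.width * target_h / img.height))
    pil = Image.fromarray(img.to_uint8(), mode="RGB")
    out = pil.resize((new_w, target_h), resample=Image.BILINEAR)
    return RasterImage.from_uint8(np.asarray(out, dtype=np.uint8), img.source_id)


def _median_cut(colors: np.ndarray, counts: np.ndarray, max_colors: int) -> list[np.ndarray]:
    """Split unique colors (int16 rows, pixel counts) into at most
    ``max_colors`` boxes.  Deterministic: always split the box with the
    largest single-channel range, ties broken by lower channel index
    (R before G before B) and then by box creation order; the split point
    is the weighted median along that channel."""
    boxes: list[np.ndarray] = [np.arange(len(colors))]
    while len(boxes) < max_colors:
        best, best_range, best_chan = -1, 0, 0
        for bi, box in enumerate(boxes):
            if len(box) < 2:
                continue
            sub = colors[box]
            ranges = sub.max(axis=0) - sub.min(axis=0)
            chan = int(np.argmax(ranges))  # argmax takes the first max: R>G>B
            r = int(ranges[chan])
            if r > best_range:
                best, best_range, best_chan = bi, r, chan
        if best < 0:
            break
        box = boxes[best]
        order = box[np.argsort(colors[box, best_chan], kind="stable")]
        cum = np.cumsum(counts[order])
        half = cum[-1] / 2.0
        split = int(np.searchsorted(cum, half)) + 1
        split = min(max(split, 1), len(order) - 1)
        boxes[best] = order[:split]
        boxes.append(order[split:])
    return boxes


def quantize(img: RasterImage, max_colors: int = DEFAULT_MAX_COLORS) -> QuantizedImage:
    """Reduce an image to a palette of at most ``max_colors`` colors.

    If the image already uses at most ``max_colors`` distinct colors the
    palette is exactly those colors (lexicographic R, G, B order).
    Otherwise a deterministic median-cut runs on the unique colors weighted
    by pixel counts; each cell's palette entry is the count-weighted mean
    color, rounded to 8 bits (which stays inside the cell's color bounding
    box).  No dithering.
    """
    if max_colors < 2:
        raise ValueError("max_colors must be at least 2")
    if img.pixels.size == 0:
        raise ValueError("cannot quantize an empty image")
    h, w = img.height, img.width
    flat = img.to_uint8().reshape(-1, 3)
    uniq, inverse, ucounts = np.unique(
        flat, axis=0, return_inverse=True, return_counts=True
    )
    inverse = inverse.ravel()
    if len(uniq) <= max_colors:
        palette = uniq.astype(np.float64) / 255.0
        return QuantizedImage(palette, inverse.reshape(h, w).astype(np.int32),
                              ucounts, img.source_id)

    boxes = _median_cut(uniq.astype(np.int16), ucounts, max_colors)
    uniq_to_box = np.empty(len(uniq), dtype=np.int32)
    reps = np.empty((len(boxes), 3), dtype=np.uint8)
    for bi, box in enumerate(boxes):
        uniq_to_box[box] = bi
        wts = ucounts[box].astype(np.float64)
        mean = (uniq[box].astype(np.float64) * wts[:, None]).sum(axis=0) / wts.sum()
        reps[bi] = np.rint(mean).astype(np.uint8)

    # Rounded representatives of distinct boxes can collide; merge them so
    # palette entries stay pairwise distinct.
    pal_uniq, pal_inverse = np.unique(reps, axis=0, return_inverse=True)
    pal_inverse = pal_inverse.ravel()
    index_map = pal_inverse[uniq_to_box[inverse]].reshape(h, w).astype(np.int32)
    counts = np.bincount(index_map.ravel(), minlength=len(pal_uniq))
    return QuantizedImage(pal_uniq.astype(np.float64) / 255.0, index_map,
                          counts, img.source_id)


def simulate_quantized(q: QuantizedImage, severity: float = 0.8,
                       linear_rgb: bool = False) -> QuantizedImage:
    """Apply deuteranopia simulation palette-wise: same index map and
    counts, transformed palette (entries may coincide after simulation)."""
    sim_palette = apply_deutan(q.palette, severity, linear_rgb=linear_rgb)
    return QuantizedImage(sim_palette, q.index_map, q.counts,
                          f"{q.source_id}|deutan{severity:g}")


def detect_grayscale(q: QuantizedImage, spread_tol: float = 10.0) -> bool:
    """True iff every palette color is achromatic (black/white/gray).

    Defined on the quantized palette rather than raw pixels so that JPEG
    chroma noise does not defeat the check.
    """
    return bool(np.all(is_achromatic(q.palette, spread_tol)))
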