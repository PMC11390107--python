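"""Screening reports: run the metric pipeline over images or directories
and serialize per-image rows plus run metadata as CSV or JSON with a
stable column order and a schema version."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .color import simulate_deutan
from .image import ImageDecodeError, load_image, save_png
from .metrics import (
    DEFAULT_RATIO_THRESHOLD,
    DEFAULT_SEVERITY,
    compute_metric_vector,
    rank_based_scores,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")

#: Stable column order; optional columns appear only when computed.
BASE_COLUMNS = (
    "source_id",
    "grayscale",
    "mean_pixelwise_dist",
    "max_ratio",
    "high_ratio_count",
    "high_ratio_pixel_prop",
    "mean_spatial_dist",
)
OPTIONAL_COLUMNS = ("rank_combined", "prediction")


@dataclass
class ScreeningReport:
    """Rows for successfully processed images, failures with reasons, and
    run metadata (severity, thresholds, seeds, package version)."""

    rows: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        cols = list(BASE_COLUMNS)
        for c in OPTIONAL_COLUMNS:
            if any(c in r for r in self.rows):
                cols.append(c)
        return cols

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns)


def write_report(report: ScreeningReport, path: str | Path,
                 fmt: str | None = None) -> Path:
    """Write a report as CSV or JSON (inferred from the suffix when
    ``fmt`` is None).  JSON omits the failures section when empty; CSV
    carries metadata (including the schema version) as ``#`` comment
    lines before the table."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# schema_version={SCHEMA_VERSION}\n")
            for k, v in sorted(report.metadata.items()):
                fh.write(f"# {k}={v}\n")
            report.to_frame().to_csv(fh, index=False)
        return path
    if fmt == "json":
        payload: dict = {
            "schema_version": SCHEMA_VERSION,
            "metadata": report.metadata,
            "rows": [_jsonsafe(r) for r in report.rows],
        }
        if report.failures:
            payload["failures"] = report.failures
        path.write_text(json.dumps(payload, indent=2))
        return path
    raise ValueError(f"unknown report format {fmt!r} (use csv or json)")


def read_report(path: str | Path) -> ScreeningReport:
    """Reload a report written by :func:`write_report` (lossless for JSON;
    CSV values round-trip to full float precision)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported report schema version")
        rows = [
            {k: (math.nan if v is None else v) for k, v in r.items()}
            for r in payload["rows"]
        ]
        return ScreeningReport(rows, payload.get("failures", []),
                               payload.get("metadata", {}))
    metadata: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
            metadata[key] = value
    if metadata.pop("schema_version", None) != SCHEMA_VERSION:
        raise ValueError("unsupported report schema version")
    df = pd.read_csv(path, comment="#")
    return ScreeningReport(df.to_dict(orient="records"), [], metadata)


def _jsonsafe(row: dict) -> dict:
    return {k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in row.items()}


def collect_image_paths(target: str | Path) -> list[Path]:
    """A single readable image path, or every PNG/JPEG under a directory
    (sorted for reproducible reports)."""
    target = Path(target)
    if target.is_dir():
        return sorted(p for p in target.iterdir()
                      if p.suffix.lower() in IMAGE_SUFFIXES)
    return [target]


def screen(
    target: str | Path | Sequence[str | Path],
    severity: float = DEFAULT_SEVERITY,
    model=None,
    *,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    seed: int = 0,
    preview_dir: str | Path | None = None,
    **metric_kwargs,
) -> ScreeningReport:
    """Compute accessibility metrics for one image or a directory of them.

    With at least two processed images, corpus-relative rank scores are
    added (rank is meaningless for a single image).  When ``model`` is
    supplied (a fitted feature model or a trained CNN), a probabilistic
    prediction column is added.  Unreadable files are logged and listed in
    the failures section; processing continues.  ``preview_dir`` writes a
    deuteranopia-simulated PNG per image.
    """
    if isinstance(target, (str, Path)):
        paths = collect_image_paths(target)
    else:
        paths = [Path(p) for p in target]
    if not paths:
        raise ValueError("no input images found")
    logger.info("screening %d image(s): severity=%s ratio_threshold=%s seed=%s",
                len(paths), severity, ratio_threshold, seed)
    rows, failures, vectors, images = [], [], [], []
    for p in paths:
        try:
            img = load_image(p)
            mv = compute_metric_vector(
                img, severity, ratio_threshold=ratio_threshold, seed=seed,
                **metric_kwargs,
            )
        except (ImageDecodeError, ValueError, OSError) as exc:
            logger.warning("failed: %s (%s)", p, exc)
            failures.append({"path": str(p), "reason": str(exc)})
            continue
        logger.info("processed %s grayscale=%s high_ratio_count=%d",
                    p, mv.grayscale, mv.high_ratio_count)
        vectors.append(mv)
        images.append(img)
        rows.append({
            "source_id": str(p),
            "grayscale": mv.grayscale,
            "mean_pixelwise_dist": mv.mean_pixelwise_dist,
            "max_ratio": mv.max_ratio,
            "high_ratio_count": mv.high_ratio_count,
            "high_ratio_pixel_prop": mv.high_ratio_pixel_prop,
            "mean_spatial_dist": mv.mean_spatial_dist,
        })
        if preview_dir is not None:
            out = Path(preview_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_png(simulate_deutan(img, severity),
                     out / f"{p.stem}.deutan{severity:g}.png")
    metadata = {
        "severity": severity,
        "ratio_threshold": ratio_threshold,
        "seed": seed,
        "version": __version__,
    }
    if len(rows) >= 2:
        for row, rs in zip(rows, rank_based_scores(vectors)):
            row["rank_combined"] = rs.combined
    else:
        metadata["note"] = "rank scores omitted: corpus-relative, needs >= 2 images"
    if model is not None:
        from .classify import FittedModel

        if isinstance(model, FittedModel):
            scores = model.predict_scores(vectors)
        else:  # trained CNN
            from .cnn import predict as cnn_predict

            scores = cnn_predict(model, images)
        for row, s in zip(rows, scores):
            row["prediction"] = float(s)
    return ScreeningReport(rows, failures, metadata)
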