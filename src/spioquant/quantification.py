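"""Convert foreground pixel coverage into particle-count estimates.

The estimator is coverage-based: a particle of diameter d covers an expected
``(pi·d²/4) / pixel_size²`` pixels (its *footprint*), so the number of
particles in a region is the foreground ("red") pixel count divided by the
footprint, rounded half-up. At the reference settings — d = 11.5 nm on a
3.88 nm/pixel raster (0.97 nm native, reduced 4x) — the physical footprint
is ~6.90 px/particle; a footprint override is supported for workflows that
use an empirically calibrated per-particle area instead.

Coverage division undercounts when particles overlap appreciably; no
declumping correction is applied.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from ._rounding import round_half_up, round_half_up_decimals
from .errors import ValidationError
from .roi import RegionOfInterest
from .thresholding import SegmentedImage


@dataclass(frozen=True)
class ParticleModel:
    """Per-particle geometry: diameter, pixel size, and pixel footprint.

    ``footprint_px`` defaults to the physical footprint (pi·d²/4)/px² and
    may be overridden with a calibrated or conventional value.
    """

    diameter_nm: float
    pixel_size_nm: float
    footprint_px: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.diameter_nm > 0:
            raise ValidationError(f"diameter_nm must be positive, got {self.diameter_nm}")
        if not self.pixel_size_nm > 0:
            raise ValidationError(
                f"pixel_size_nm must be positive, got {self.pixel_size_nm}"
            )
        if self.footprint_px is None:
            object.__setattr__(self, "footprint_px", physical_footprint_px(self))
        elif not self.footprint_px > 0:
            raise ValidationError(
                f"footprint_px must be positive, got {self.footprint_px}"
            )


@dataclass(frozen=True)
class QuantRecord:
    """One per-ROI report row: pixel counts, coverage, particle estimate."""

    roi_name: str
    total_px: int
    red_px: int
    red_pct: float
    est_particles: int

    def __post_init__(self) -> None:
        if not 0 <= self.red_px <= self.total_px:
            raise ValidationError(
                f"record '{self.roi_name}': red_px {self.red_px} outside "
                f"[0, total_px={self.total_px}]"
            )
        if self.est_particles < 0:
            raise ValidationError("est_particles must be non-negative")


@dataclass(frozen=True)
class QuantSummary:
    """Per-ROI records plus an averages row.

    Averages follow the report convention: pixel-count means rounded
    half-up; the percentage is the pooled ratio 100·Σred/Σtotal rounded
    half-up to an integer percent; the particle-count mean is truncated
    toward zero.
    """

    records: tuple[QuantRecord, ...]
    avg_total_px: int
    avg_red_px: int
    avg_red_pct: int
    avg_est_particles: int


def physical_footprint_px(model: ParticleModel) -> float:
    """Expected pixels covered by one particle: (pi·d²/4) / pixel_size²."""
    return (math.pi * model.diameter_nm**2 / 4.0) / model.pixel_size_nm**2


def estimate_particles(red_px: int, footprint_px: float) -> int:
    """Particle count = round-half-up(red_px / footprint_px)."""
    if red_px < 0:
        raise ValidationError(f"red_px must be non-negative, got {red_px}")
    if not footprint_px > 0:
        raise ValidationError(f"footprint_px must be positive, got {footprint_px}")
    return round_half_up(red_px / footprint_px)


def quantify_roi(
    seg: SegmentedImage, roi: RegionOfInterest, model: ParticleModel
) -> QuantRecord:
    """Count foreground pixels inside one ROI and estimate its particles."""
    if roi.mask.shape != seg.shape:
        raise ValidationError(
            f"ROI '{roi.name}' shape {roi.mask.shape} does not match "
            f"segmentation {seg.shape}"
        )
    total_px = roi.area_px
    red_px = int(seg.foreground_mask[roi.mask].sum())
    red_pct = round_half_up_decimals(100.0 * red_px / total_px, 2)
    return QuantRecord(
        roi_name=roi.name,
        total_px=total_px,
        red_px=red_px,
        red_pct=red_pct,
        est_particles=estimate_particles(red_px, model.footprint_px),
    )


def summarize(records: Sequence[QuantRecord]) -> QuantSummary:
    """Aggregate records into the averages row (see class docstring)."""
    if len(records) == 0:
        raise ValidationError("cannot summarize an empty record list")
    n = len(records)
    sum_total = sum(r.total_px for r in records)
    sum_red = sum(r.red_px for r in records)
    mean_est = sum(r.est_particles for r in records) / n
    return QuantSummary(
        records=tuple(records),
        avg_total_px=round_half_up(sum_total / n),
        avg_red_px=round_half_up(sum_red / n),
        avg_red_pct=round_half_up(100.0 * sum_red / sum_total),
        avg_est_particles=int(mean_est),  # truncation toward zero
    )


def write_report(summary: QuantSummary, path: Union[str, Path]) -> None:
    """Write the per-ROI report as UTF-8 CSV with LF endings.

    Columns: roi,total_px,red_px,red_pct,est_particles; a final AVERAGE row
    carries the aggregate values (percentage as an integer).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["roi", "total_px", "red_px", "red_pct", "est_particles"])
        for r in summary.records:
            writer.writerow(
                [r.roi_name, r.total_px, r.red_px, f"{r.red_pct:.2f}", r.est_particles]
            )
        writer.writerow(
            [
                "AVERAGE",
                summary.avg_total_px,
                summary.avg_red_px,
                summary.avg_red_pct,
                summary.avg_est_particles,
            ]
        )


def read_report(path: Union[str, Path]) -> list[dict]:
    """Read back a report CSV as a list of row dicts (strings -> numbers)."""
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                {
                    "roi": row["roi"],
                    "total_px": int(row["total_px"]),
                    "red_px": int(row["red_px"]),
                    "red_pct": float(row["red_pct"]),
                    "est_particles": int(row["est_particles"]),
                }
            )
    return rows


def quantify_image(
    img,
    rois: Sequence[RegionOfInterest],
    model: ParticleModel,
    method: str = "otsu",
    smooth_window: int = 5,
    threshold_scope: str = "image",
) -> tuple[QuantSummary, "SegmentedImage"]:
    """Full per-image pipeline: threshold, binarize, quantify every ROI.

    ``threshold_scope`` selects where the histogram is taken: "image" uses
    the whole micrograph (one global threshold), "roi" recomputes the
    threshold from each ROI's own histogram before counting — useful when a
    vesicle interior differs in brightness from the extracellular
    background.

    Returns the summary and the (last) segmentation, whose ``threshold_used``
    records method provenance.
    """
    from .image_model import histogram
    from .thresholding import binarize, first_minimum_threshold, otsu_threshold

    if method not in ("otsu", "first-min", "first_minimum"):
        raise ValidationError(f"unknown threshold method {method!r}")
    if threshold_scope not in ("image", "roi"):
        raise ValidationError(f"unknown threshold scope {threshold_scope!r}")

    def pick(hist):
        if method == "otsu":
            return otsu_threshold(hist)
        return first_minimum_threshold(hist, smooth_window=smooth_window)

    if len(rois) == 0:
        raise ValidationError("ROI list is empty")

    records = []
    seg = None
    if threshold_scope == "image":
        seg = binarize(img, pick(histogram(img)))
        for roi in rois:
            records.append(quantify_roi(seg, roi, model))
    else:
        for roi in rois:
            seg = binarize(img, pick(histogram(img, roi)))
            records.append(quantify_roi(seg, roi, model))
    return summarize(records), seg
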