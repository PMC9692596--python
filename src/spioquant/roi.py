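"""Regions of interest: lysosome/microvesicle geometry and rasterization.

ROIs are user-supplied — in the underlying workflow lysosomes are selected
manually on each micrograph — as rectangles or polygons in a small JSON
schema::

    [{"name": "lyso1", "type": "rect", "coords": [r0, c0, r1, c1]},
     {"name": "lyso2", "type": "polygon", "coords": [[r, c], ...]}]

Coordinates are 0-based (row, col), rectangles half-open. A pixel belongs to
a polygon when its center (r + 0.5, c + 0.5) is inside under the even-odd
rule, so an axis-aligned square polygon rasterizes identically to the
equivalent half-open rectangle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class RegionOfInterest:
    """A named vesicle/lysosome mask aligned to an image."""

    name: str
    mask: np.ndarray
    shape_type: str  # "rect" | "polygon" | "mask"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValidationError(f"ROI '{self.name}': mask must be 2-D")
        if not m.any():
            raise ValidationError(f"ROI '{self.name}' selects zero pixels")
        object.__setattr__(self, "mask", m)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def rect_roi(
    name: str,
    coords: Sequence[int],
    image_shape: tuple[int, int],
) -> RegionOfInterest:
    """Build a rectangular ROI from half-open bounds (r0, c0, r1, c1)."""
    r0, c0, r1, c1 = (int(v) for v in coords)
    h, w = image_shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValidationError(
            f"ROI '{name}': rect ({r0},{c0},{r1},{c1}) out of bounds for "
            f"image {h}x{w}"
        )
    mask = np.zeros(image_shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return RegionOfInterest(name=name, mask=mask, shape_type="rect")


def _polygon_mask(
    vertices: np.ndarray, image_shape: tuple[int, int]
) -> np.ndarray:
    """Even-odd fill testing pixel centers against the polygon."""
    h, w = image_shape
    vr = vertices[:, 0]
    vc = vertices[:, 1]
    r_lo = max(int(math.floor(vr.min())), 0)
    r_hi = min(int(math.ceil(vr.max())), h)
    c_lo = max(int(math.floor(vc.min())), 0)
    c_hi = min(int(math.ceil(vc.max())), w)
    mask = np.zeros(image_shape, dtype=bool)
    if r_hi <= r_lo or c_hi <= c_lo:
        return mask
    yy = np.arange(r_lo, r_hi) + 0.5
    xx = np.arange(c_lo, c_hi) + 0.5
    y = yy[:, None]
    x = xx[None, :]
    inside = np.zeros((yy.size, xx.size), dtype=bool)
    n = len(vertices)
    for i in range(n):
        y1, x1 = vertices[i]
        y2, x2 = vertices[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edge never crosses a horizontal ray
        crosses = (y1 > y) != (y2 > y)
        x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < x_at)
    mask[r_lo:r_hi, c_lo:c_hi] = inside
    return mask


def polygon_roi(
    name: str,
    vertices: Sequence[Sequence[float]],
    image_shape: tuple[int, int],
) -> RegionOfInterest:
    """Build a polygonal ROI from (row, col) vertices, even-odd filled."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValidationError(
            f"ROI '{name}': polygon needs >= 3 (row, col) vertices"
        )
    h, w = image_shape
    if v[:, 0].min() < 0 or v[:, 0].max() > h or v[:, 1].min() < 0 or v[:, 1].max() > w:
        raise ValidationError(
            f"ROI '{name}': polygon vertices out of bounds for image {h}x{w}"
        )
    mask = _polygon_mask(v, image_shape)
    if not mask.any():
        raise ValidationError(f"ROI '{name}' selects zero pixels")
    return RegionOfInterest(name=name, mask=mask, shape_type="polygon")


def load_rois(
    path: Union[str, Path], image_shape: tuple[int, int]
) -> list[RegionOfInterest]:
    """Load and rasterize ROIs from a JSON file against an image shape."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read ROI file: no such file {path}")
    with open(path, encoding="utf-8") as fh:
        entries = json.load(fh)
    return rois_from_entries(entries, image_shape)


def rois_from_entries(
    entries: Sequence[dict], image_shape: tuple[int, int]
) -> list[RegionOfInterest]:
    """Rasterize a parsed list of ROI dicts (the JSON schema above)."""
    if not isinstance(entries, list) or len(entries) == 0:
        raise ValidationError("ROI list is empty")
    rois = []
    for i, entry in enumerate(entries):
        name = entry.get("name", f"roi{i + 1}")
        kind = entry.get("type")
        coords = entry.get("coords")
        if kind == "rect":
            rois.append(rect_roi(name, coords, image_shape))
        elif kind == "polygon":
            rois.append(polygon_roi(name, coords, image_shape))
        else:
            raise ValidationError(
                f"ROI '{name}': unknown type {kind!r} (expected rect|polygon)"
            )
    return rois


def roi_diameter_nm(roi: RegionOfInterest, pixel_size_nm: float) -> float:
    """Equivalent-circle diameter of the ROI, 2·sqrt(area/pi)·pixel_size."""
    if not pixel_size_nm > 0:
        raise ValidationError("pixel_size_nm must be positive")
    return 2.0 * math.sqrt(roi.area_px / math.pi) * pixel_size_nm
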