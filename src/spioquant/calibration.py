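"""Footprint calibration from isolated single particles.

Extracellular background regions of a micrograph typically contain isolated
single nanoparticles; their segmented areas give a direct, empirical
per-particle pixel footprint. Components are size-gated to the pixel-area
equivalents of the expected crystallite diameter range (10-13 nm by
default), discarding noise specks and clumps, and the median surviving area
and equivalent diameter become the calibrated footprint and particle size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from .errors import CalibrationError
from .quantification import ParticleModel
from .roi import RegionOfInterest
from .thresholding import SegmentedImage


@dataclass(frozen=True)
class ComponentStats:
    """One 8-connected foreground component."""

    component_id: int
    area_px: int
    equivalent_diameter_nm: float
    centroid: tuple[float, float]  # (row, col)


def connected_components(
    seg: SegmentedImage, roi: Optional[RegionOfInterest] = None
) -> list[ComponentStats]:
    """8-connected components of the foreground class, raster-ordered.

    Components are ordered by their first pixel in raster (top-most,
    left-most) order. An empty foreground yields an empty list.
    """
    fg = seg.foreground_mask
    if roi is not None:
        fg = fg & roi.mask
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        return []
    props = measure.regionprops(labels)
    # first-pixel raster index per component, for a deterministic order
    flat = labels.ravel()
    first_index = np.full(labels.max() + 1, flat.size, dtype=np.int64)
    occupied = np.flatnonzero(flat)
    np.minimum.at(first_index, flat[occupied], occupied)
    order = np.argsort(first_index[1:], kind="stable")

    out = []
    for new_id, idx in enumerate(order, start=1):
        p = props[idx]
        area = int(p.area)
        eq_d = 2.0 * math.sqrt(area / math.pi) * seg.pixel_size_nm
        out.append(
            ComponentStats(
                component_id=new_id,
                area_px=area,
                equivalent_diameter_nm=eq_d,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
            )
        )
    return out


def diameter_to_area_px(diameter_nm: float, pixel_size_nm: float) -> float:
    """Disk area in pixels for a given physical diameter."""
    return (math.pi * diameter_nm**2 / 4.0) / pixel_size_nm**2


def calibrate_footprint(
    components: Sequence[ComponentStats],
    pixel_size_nm: float,
    min_area: Optional[int] = None,
    max_area: Optional[int] = None,
    min_diameter_nm: float = 10.0,
    max_diameter_nm: float = 13.0,
) -> ParticleModel:
    """Median-based footprint/diameter estimate from size-gated singles.

    Components with area outside [min_area, max_area] (defaulting to the
    pixel-area equivalents of the 10-13 nm diameter range) are discarded as
    noise or clumps; at least 3 must survive. Returns a ParticleModel whose
    ``footprint_px`` is the median surviving area and whose ``diameter_nm``
    is the median equivalent diameter.
    """
    if min_area is None:
        min_area = int(math.floor(diameter_to_area_px(min_diameter_nm, pixel_size_nm)))
    if max_area is None:
        max_area = int(math.ceil(diameter_to_area_px(max_diameter_nm, pixel_size_nm)))
    surviving = [c for c in components if min_area <= c.area_px <= max_area]
    if len(surviving) < 3:
        raise CalibrationError(
            f"only {len(surviving)} components in area range [{min_area}, "
            f"{max_area}]; need >= 3 — supply a manual footprint instead"
        )
    footprint = float(np.median([c.area_px for c in surviving]))
    diameter = float(np.median([c.equivalent_diameter_nm for c in surviving]))
    return ParticleModel(
        diameter_nm=diameter, pixel_size_nm=pixel_size_nm, footprint_px=footprint
    )
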