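"""Synthetic TEM-like scenes with known ground truth.

Scenes emulate the morphology relevant to uptake quantification: a light
noisy background (resin/cytoplasm), round membrane-bound vesicles 160-250 nm
across rendered slightly darker with a darker rim, electron-dense particle
disks 10-13 nm across clustered inside the vesicles, and isolated single
particles in the background (the singles a calibration step would use). The
native scale is 0.97 nm/pixel; an optional block reduction can be applied
afterwards with :func:`spioquant.image_model.block_downsample`.

Disk edges are anti-aliased by sub-pixel coverage sampling so a disk's
rasterized area converges to pi·d²/4 as resolution grows. Particle placement
is rejection-sampled so that pairwise overlap stays below a configurable
fraction of a particle's area (default 5%), matching the approximately
non-overlapping coverage the counting model assumes. One seed produces one
bit-exact image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from ._rounding import round_half_up_array
from .errors import GenerationError, ValidationError
from .image_model import GrayImage

_SUBSAMPLES = 4  # sub-pixel grid per axis for disk coverage


@dataclass(frozen=True)
class VesicleSpec:
    """One vesicle: center (row, col) in px, diameter in nm, particle count."""

    center: tuple[float, float]
    diameter_nm: float
    particle_count: int


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Intensity defaults give the strong particle/background contrast typical
    of stained TEM sections: background ~200, vesicle interior ~180,
    particles ~60 on the 8-bit scale. Particles must be darker than the
    background (electron-dense).
    """

    image_size_px: tuple[int, int] = (288, 288)
    pixel_size_nm: float = 0.97
    background_mean: float = 200.0
    background_sd: float = 4.0
    vesicle_mean: float = 180.0
    rim_mean: float = 140.0
    rim_width_nm: float = 4.0
    particle_mean: float = 60.0
    particle_diameter_nm: float = 11.5
    vesicle_specs: tuple[VesicleSpec, ...] = ()
    free_particle_count: int = 0
    noise_sd: float = 5.0
    max_overlap_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.particle_mean < self.background_mean:
            raise ValidationError(
                "particle_mean must be below background_mean (particles are dark)"
            )
        if self.particle_diameter_nm <= 0 or self.pixel_size_nm <= 0:
            raise ValidationError("diameters and pixel size must be positive")
        h, w = self.image_size_px
        for v in self.vesicle_specs:
            r = v.diameter_nm / 2.0 / self.pixel_size_nm
            rim = self.rim_width_nm / self.pixel_size_nm
            if (
                v.center[0] - r - rim < 0
                or v.center[1] - r - rim < 0
                or v.center[0] + r + rim > h
                or v.center[1] + r + rim > w
            ):
                raise ValidationError(
                    f"vesicle at {v.center} (d={v.diameter_nm} nm) does not "
                    f"fit inside the {h}x{w} image"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that a real micrograph hides."""

    vesicle_counts: tuple[int, ...]
    vesicle_masks: tuple[np.ndarray, ...]  # interior (ROI-like) masks
    particle_centers: tuple[tuple[float, float], ...]  # all, vesicles first
    free_particle_centers: tuple[tuple[float, float], ...]
    footprint_px: float  # analytic per-particle area (pi d^2/4)/px^2
    particle_coverage: np.ndarray  # float coverage in [0, 1] per pixel

    @property
    def total_particles(self) -> int:
        return len(self.particle_centers)


def _disk_coverage_patch(
    center: tuple[float, float], radius_px: float, shape: tuple[int, int]
) -> tuple[slice, slice, np.ndarray]:
    """Sub-pixel coverage of one disk over its bounding box."""
    cr, cc = center
    r0 = max(int(math.floor(cr - radius_px)) - 1, 0)
    r1 = min(int(math.ceil(cr + radius_px)) + 1, shape[0])
    c0 = max(int(math.floor(cc - radius_px)) - 1, 0)
    c1 = min(int(math.ceil(cc + radius_px)) + 1, shape[1])
    sub = (np.arange(_SUBSAMPLES) + 0.5) / _SUBSAMPLES
    rows = (np.arange(r0, r1)[:, None] + sub[None, :]).ravel()
    cols = (np.arange(c0, c1)[:, None] + sub[None, :]).ravel()
    d2 = (rows[:, None] - cr) ** 2 + (cols[None, :] - cc) ** 2
    inside = d2 <= radius_px**2
    cov = inside.reshape(
        r1 - r0, _SUBSAMPLES, c1 - c0, _SUBSAMPLES
    ).mean(axis=(1, 3))
    return slice(r0, r1), slice(c0, c1), cov


def _paint_disk(
    canvas: np.ndarray,
    coverage_acc: Optional[np.ndarray],
    center: tuple[float, float],
    radius_px: float,
    value: float,
) -> None:
    """Alpha-blend a disk of the given intensity onto the canvas."""
    rs, cs, cov = _disk_coverage_patch(center, radius_px, canvas.shape)
    canvas[rs, cs] = canvas[rs, cs] * (1.0 - cov) + value * cov
    if coverage_acc is not None:
        coverage_acc[rs, cs] = np.maximum(coverage_acc[rs, cs], cov)


def min_center_distance_px(radius_px: float, max_overlap_frac: float) -> float:
    """Center distance at which two equal disks overlap by the given fraction.

    Solves the circular-lens area 2r²·acos(t/2r) − (t/2)·sqrt(4r²−t²) =
    frac·pi·r² for the distance t; frac <= 0 returns 2r (tangency).
    """
    if max_overlap_frac <= 0:
        return 2.0 * radius_px
    target = max_overlap_frac * math.pi * radius_px**2

    def lens_minus_target(t: float) -> float:
        lens = 2 * radius_px**2 * math.acos(
            t / (2 * radius_px)
        ) - (t / 2.0) * math.sqrt(4 * radius_px**2 - t**2)
        return lens - target

    return float(brentq(lens_minus_target, 0.0, 2.0 * radius_px))


def _place_in_disk(
    rng: np.random.Generator,
    center: tuple[float, float],
    container_radius_px: float,
    count: int,
    min_dist_px: float,
    max_attempts_per_particle: int = 400,
) -> list[tuple[float, float]]:
    """Rejection-sample disk centers inside a circular container."""
    placed: list[tuple[float, float]] = []
    attempts_left = max_attempts_per_particle * max(count, 1)
    while len(placed) < count:
        if attempts_left <= 0:
            raise GenerationError(
                f"cannot place {count} particles at min spacing "
                f"{min_dist_px:.2f} px inside a radius-{container_radius_px:.1f} px "
                "region — relax the overlap limit or reduce the count"
            )
        attempts_left -= 1
        rho = container_radius_px * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        cand = (center[0] + rho * math.sin(theta), center[1] + rho * math.cos(theta))
        if all(
            (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_dist_px**2
            for p in placed
        ):
            placed.append(cand)
    return placed


def generate_scene(
    spec: SceneSpec,
) -> tuple[GrayImage, GroundTruth, list[dict]]:
    """Render a scene; returns (image, ground truth, ROI JSON entries).

    The returned ROI entries are half-open bounding rectangles around each
    vesicle (named ``lyso1``, ``lyso2``, ...), directly serializable to the
    ROI JSON schema.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    p_rad = spec.particle_diameter_nm / 2.0 / spec.pixel_size_nm
    rim_px = spec.rim_width_nm / spec.pixel_size_nm
    min_dist = min_center_distance_px(p_rad, spec.max_overlap_frac)

    canvas = rng.normal(spec.background_mean, spec.background_sd, size=(h, w))
    coverage = np.zeros((h, w), dtype=float)

    vesicle_masks = []
    vesicle_counts = []
    all_centers: list[tuple[float, float]] = []
    roi_entries = []

    for i, v in enumerate(spec.vesicle_specs):
        v_rad = v.diameter_nm / 2.0 / spec.pixel_size_nm
        # rim first, interior over it, so the rim remains as an annulus
        _paint_disk(canvas, None, v.center, v_rad + rim_px, spec.rim_mean)
        _paint_disk(canvas, None, v.center, v_rad, spec.vesicle_mean)

        rs, cs, cov = _disk_coverage_patch(v.center, v_rad, (h, w))
        mask = np.zeros((h, w), dtype=bool)
        mask[rs, cs] = cov > 0.5
        vesicle_masks.append(mask)

        usable = v_rad - p_rad - 1.0
        if usable <= 0 and v.particle_count > 0:
            raise GenerationError(
                f"vesicle {i + 1} too small to hold particles of "
                f"{spec.particle_diameter_nm} nm"
            )
        centers = _place_in_disk(rng, v.center, usable, v.particle_count, min_dist)
        vesicle_counts.append(len(centers))
        all_centers.extend(centers)

        margin = int(math.ceil(v_rad + rim_px)) + 2
        roi_entries.append(
            {
                "name": f"lyso{i + 1}",
                "type": "rect",
                "coords": [
                    max(int(v.center[0]) - margin, 0),
                    max(int(v.center[1]) - margin, 0),
                    min(int(v.center[0]) + margin, h),
                    min(int(v.center[1]) + margin, w),
                ],
            }
        )

    free_centers = _place_free_singles(rng, spec, p_rad)
    all_centers.extend(free_centers)

    for c in all_centers:
        _paint_disk(canvas, coverage, c, p_rad, spec.particle_mean)

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=(h, w))
    pixels = np.clip(round_half_up_array(canvas), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        vesicle_counts=tuple(vesicle_counts),
        vesicle_masks=tuple(vesicle_masks),
        particle_centers=tuple(all_centers),
        free_particle_centers=tuple(free_centers),
        footprint_px=(math.pi * spec.particle_diameter_nm**2 / 4.0)
        / spec.pixel_size_nm**2,
        particle_coverage=coverage,
    )
    return GrayImage(pixels=pixels, pixel_size_nm=spec.pixel_size_nm), truth, roi_entries


def _place_free_singles(
    rng: np.random.Generator, spec: SceneSpec, p_rad: float
) -> list[tuple[float, float]]:
    """Isolated background singles, kept clear of vesicles and each other."""
    if spec.free_particle_count == 0:
        return []
    h, w = spec.image_size_px
    rim_px = spec.rim_width_nm / spec.pixel_size_nm
    margin = 3.0 * p_rad + 1.0
    sep = 6.0 * p_rad  # generous spacing: singles must stay resolvable
    vesicles = [
        (v.center, v.diameter_nm / 2.0 / spec.pixel_size_nm + rim_px + sep)
        for v in spec.vesicle_specs
    ]
    placed: list[tuple[float, float]] = []
    attempts_left = 2000 * spec.free_particle_count
    while len(placed) < spec.free_particle_count:
        if attempts_left <= 0:
            raise GenerationError(
                f"cannot place {spec.free_particle_count} isolated background "
                "particles — image too crowded"
            )
        attempts_left -= 1
        cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if any(
            (cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 < r**2
            for c, r in vesicles
        ):
            continue
        if all(
            (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= sep**2
            for p in placed
        ):
            placed.append(cand)
    return placed


def default_scene(
    particle_count: int = 50,
    noise_sd: float = 5.0,
    seed: int = 0,
    vesicle_diameter_nm: float = 200.0,
    free_particle_count: int = 0,
    image_size_px: tuple[int, int] = (288, 288),
    **overrides,
) -> SceneSpec:
    """A one-vesicle scene centered in the image — the standard test scene."""
    h, w = image_size_px
    return SceneSpec(
        image_size_px=image_size_px,
        vesicle_specs=(
            VesicleSpec(
                center=(h / 2.0, w / 2.0),
                diameter_nm=vesicle_diameter_nm,
                particle_count=particle_count,
            ),
        ),
        free_particle_count=free_particle_count,
        noise_sd=noise_sd,
        seed=seed,
        **overrides,
    )
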