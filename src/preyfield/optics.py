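"""Pinhole-camera geometry: orientation compensation, pixel-to-physical
conversion, resolvable range, and the pyramidal imaged volume.

The imaged water volume of a single frame is approximated by a pyramid
with its apex at the camera and a rectangular base at the resolvable
range ``r``: ``V = w * h * r / 3``, where ``w`` and ``h`` are the
physical width and height of the frame at range ``r``.

All internal lengths are millimetres and volumes cubic metres; unit
conversions happen at operation boundaries, never implicitly.

Orientation compensation
------------------------
Elongated prey are imaged at random body angles.  For a rod at angle
``theta`` to the image plane, the projected length is ``|cos theta|``
times the true length (with a floor at the body's axial width, seen
head- or tail-on).  For ``theta`` uniform on (-180, 180] degrees the
median projected fraction is ``sqrt(2)/2 ~ 0.7071``, the projection at
45 degrees.  Dividing a *median* imaged length by this factor therefore
recovers a median full length; the compensation applies to medians, not
to individual animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: median of |cos theta| for theta uniform on (-180, 180] degrees
MEDIAN_PROJECTION = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class CameraModel:
    """Frame geometry of the video logger.

    Defaults describe the deployed logger: 1280 x 960 px frames with a
    31 x 24 degree field of view at 30 fps (frame rate is informational
    and enters no calculation).
    """

    width_px: int = 1280
    height_px: int = 960
    hfov_deg: float = 31.0
    vfov_deg: float = 24.0
    frame_rate_fps: float = 30.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "hfov_deg", "vfov_deg", "frame_rate_fps"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"camera {name} must be positive")

    @property
    def focal_px(self) -> float:
        """Pixels per unit tangent along the vertical axis: height/(2 tan(vfov/2)).

        An object of physical size ``s`` at range ``z`` (same units)
        images to ``s * focal_px / z`` pixels.
        """
        return self.height_px / (2.0 * math.tan(math.radians(self.vfov_deg) / 2.0))


@dataclass(frozen=True)
class PreyLengthModel:
    """Reference physical length distribution of the prey.

    Defaults are Antarctic krill lengths from predator diet samples:
    31-60 mm, mean 43 mm (sd 4.3 mm), median 42 mm.  The *median* is the
    reference length used in pixel-to-mm conversion, pairing with the
    median orientation projection.
    """

    mean_mm: float = 43.0
    sd_mm: float = 4.3
    median_mm: float = 42.0
    min_mm: float = 31.0
    max_mm: float = 60.0

    def __post_init__(self) -> None:
        if not (self.min_mm <= self.median_mm <= self.max_mm):
            raise ValidationError("prey lengths must satisfy min <= median <= max")
        if not self.sd_mm > 0:
            raise ValidationError("prey sd must be positive")


@dataclass(frozen=True)
class VolumeEstimate:
    """Resolved geometry chain for one boundary value."""

    conversion_px_per_mm: float
    imaged_width_mm: float
    imaged_height_mm: float
    resolvable_range_mm: float
    volume_m3: float


def orientation_factor(
    method: str = "closed_form",
    axial_width_fraction: float = 0.0,
    n: int = 1_000_000,
    seed: int = 0,
    angle_sampler=None,
) -> float:
    """Median projected-length fraction for uniformly oriented elongated prey.

    Parameters
    ----------
    method
        ``"closed_form"`` returns sqrt(2)/2 directly; ``"monte_carlo"``
        estimates the median of ``max(|cos theta|, axial_width_fraction)``
        over ``n`` sampled angles.
    axial_width_fraction
        Body width as a fraction of body length, the projected-length
        floor for head-/tail-on animals.  Must be below sqrt(2)/2: a
        wider floor would dominate the median and the rod model breaks.
    angle_sampler
        Optional callable ``(rng, n) -> angles_rad`` replacing the
        uniform angle distribution (testing hook).
    """
    if not 0.0 <= axial_width_fraction < MEDIAN_PROJECTION:
        raise ValidationError(
            f"axial_width_fraction must be in [0, {MEDIAN_PROJECTION:.4f}); "
            f"got {axial_width_fraction} (floor would dominate the median)"
        )
    if method == "closed_form":
        if angle_sampler is not None:
            raise ValueError("angle_sampler applies only to the monte_carlo method")
        return MEDIAN_PROJECTION
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    if angle_sampler is None:
        theta = rng.uniform(-math.pi, math.pi, n)
    else:
        theta = np.asarray(angle_sampler(rng, n), dtype=float)
    projected = np.maximum(np.abs(np.cos(theta)), axial_width_fraction)
    return float(np.median(projected))


def px_per_mm(
    L_boundary_px: float, orientation_factor: float, reference_length_mm: float
) -> float:
    """Pixel-to-millimetre conversion at the resolvable-range limit.

    The boundary size is first divided by the orientation factor to
    recover the full-length pixel size of a median-orientation animal,
    then divided by the reference (median) physical length.
    """
    for name, v in (
        ("L_boundary_px", L_boundary_px),
        ("orientation_factor", orientation_factor),
        ("reference_length_mm", reference_length_mm),
    ):
        if not v > 0:
            raise ValidationError(f"{name} must be positive, got {v}")
    return (L_boundary_px / orientation_factor) / reference_length_mm


def volume_from_boundary(
    L_boundary_px: float,
    camera: CameraModel | None = None,
    prey: PreyLengthModel | None = None,
    orientation_factor: float = MEDIAN_PROJECTION,
) -> VolumeEstimate:
    """Full geometry chain from a pixel boundary to the imaged volume.

    The resolvable range is derived from the *vertical* field of view:
    ``r = h / (2 tan(vfov/2))`` with ``h`` the physical frame height at
    that range, so ``h = height_px / conversion``.  The imaged volume is
    the pyramid ``V = w * h * r / 3``.
    """
    camera = camera or CameraModel()
    prey = prey or PreyLengthModel()
    c = px_per_mm(L_boundary_px, orientation_factor, prey.median_mm)
    width_mm = camera.width_px / c
    height_mm = camera.height_px / c
    range_mm = height_mm / (2.0 * math.tan(math.radians(camera.vfov_deg) / 2.0))
    volume_m3 = width_mm * height_mm * range_mm / 3.0 * 1e-9
    return VolumeEstimate(
        conversion_px_per_mm=c,
        imaged_width_mm=width_mm,
        imaged_height_mm=height_mm,
        resolvable_range_mm=range_mm,
        volume_m3=volume_m3,
    )


def pyramid_volume_m3(width_mm: float, height_mm: float, range_mm: float) -> float:
    """Volume (m^3) of a pyramid with apex at the camera and base w x h at the given range."""
    if min(width_mm, height_mm, range_mm) <= 0:
        raise ValidationError("pyramid dimensions must be positive")
    return width_mm * height_mm * range_mm / 3.0 * 1e-9
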