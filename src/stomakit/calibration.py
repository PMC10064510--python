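"""Optical calibration for handheld-microscope magnification profiles.

A :class:`MagnificationProfile` binds image pixels to physical units for one
lens: pixel density (px/mm), field of view (mm) and resolving power (um).
The built-in registry holds the three profiles of the ProScope HR5 handheld
microscope lenses (100x, 200x, 400x); custom profiles can be registered by
name, e.g. for a different capture device.

All length conversions report micrometres, areas square micrometres and
stomatal densities stomata per square millimetre, the conventional units of
the stomatal literature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised for invalid optical constants or unusable profile configuration."""


@dataclass(frozen=True)
class MagnificationProfile:
    """Optical constants for one microscope lens.

    Parameters
    ----------
    name : str
        Profile label, e.g. ``"400x"``.
    px_per_mm : float
        Pixel density: number of image pixels spanning one millimetre of leaf.
    fov_width_mm, fov_height_mm : float
        Physical field of view captured in one image, in millimetres.
    resolving_power_um : float
        Smallest resolvable feature of the lens, in micrometres.
    """

    name: str
    px_per_mm: float
    fov_width_mm: float
    fov_height_mm: float
    resolving_power_um: float

    def __post_init__(self) -> None:
        for field in ("px_per_mm", "fov_width_mm", "fov_height_mm", "resolving_power_um"):
            value = getattr(self, field)
            if not (value > 0 and math.isfinite(value)):
                raise CalibrationError(f"{field} must be positive and finite, got {value!r}")

    @property
    def um_per_px(self) -> float:
        """Micrometres spanned by one pixel."""
        return 1000.0 / self.px_per_mm


#: Built-in registry: the three handheld-microscope lenses.
PROFILES: dict[str, MagnificationProfile] = {
    "100x": MagnificationProfile("100x", 198.0, 2.87, 2.17, 4.0),
    "200x": MagnificationProfile("200x", 415.0, 1.36, 1.03, 2.0),
    "400x": MagnificationProfile("400x", 652.0, 0.75, 0.57, 1.0),
}


def get_profile(name: str) -> MagnificationProfile:
    """Look up a profile by name in the registry."""
    try:
        return PROFILES[name]
    except KeyError:
        raise CalibrationError(
            f"unknown magnification profile {name!r}; known: {sorted(PROFILES)}"
        ) from None


def register_profile(profile: MagnificationProfile) -> None:
    """Add (or replace) a custom profile in the registry."""
    PROFILES[profile.name] = profile


def px_to_um(length_px: float, profile: MagnificationProfile) -> float:
    """Convert a pixel length to micrometres.

    ``652 px`` at the 400x profile (1 mm = 652 pixels) is exactly 1000 um.
    """
    if length_px < 0:
        raise ValueError(f"length_px must be >= 0, got {length_px}")
    return length_px * 1000.0 / profile.px_per_mm


def um_to_px(length_um: float, profile: MagnificationProfile) -> float:
    """Convert a micrometre length to pixels (inverse of :func:`px_to_um`)."""
    if length_um < 0:
        raise ValueError(f"length_um must be >= 0, got {length_um}")
    return length_um * profile.px_per_mm / 1000.0


def area_px_to_um2(area_px: float, profile: MagnificationProfile) -> float:
    """Convert a pixel area to square micrometres."""
    if area_px < 0:
        raise ValueError(f"area_px must be >= 0, got {area_px}")
    return area_px * (1000.0 / profile.px_per_mm) ** 2


def fov_area_mm2(profile: MagnificationProfile) -> float:
    """Physical area of the profile's full field of view, in mm^2."""
    return profile.fov_width_mm * profile.fov_height_mm


def density_per_mm2(
    count: float,
    profile: MagnificationProfile,
    imaged_area_mm2: float | None = None,
) -> float:
    """Stomatal density (stomata per mm^2 of leaf) for a per-image count.

    By default the denominator is the profile's full optical field of view,
    since each capture images exactly that area. Pass ``imaged_area_mm2`` to
    override for cropped or tiled images.
    """
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    area = fov_area_mm2(profile) if imaged_area_mm2 is None else imaged_area_mm2
    if not area > 0:
        raise CalibrationError(f"imaged area must be positive, got {area}")
    return count / area


def check_image_dimensions(
    width_px: int, height_px: int, profile: MagnificationProfile, tolerance: float = 0.05
) -> bool:
    """Warn (but proceed) if image pixel dimensions disagree with the profile.

    Capture software may letterbox or rescale; the profile remains
    authoritative. Returns True when dimensions agree within ``tolerance``.
    """
    expect_w = profile.fov_width_mm * profile.px_per_mm
    expect_h = profile.fov_height_mm * profile.px_per_mm
    ok = (
        abs(width_px - expect_w) <= tolerance * expect_w
        and abs(height_px - expect_h) <= tolerance * expect_h
    )
    if not ok:
        logger.warning(
            "image is %dx%d px but profile %s implies %.0fx%.0f px; "
            "using profile calibration anyway",
            width_px, height_px, profile.name, expect_w, expect_h,
        )
    return ok
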