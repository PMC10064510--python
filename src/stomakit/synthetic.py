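"""Synthetic leaf-epidermis scenes with exact per-stoma ground truth.

Generates grayscale brightfield-like micrographs of a leaf surface populated
with stomatal complexes, together with the exact bounding box, outline
polygon, aperture polygon and physical-unit traits of every stoma. Two
patterning archetypes are modelled:

* ``rows`` — graminoid patterning: stomata in parallel longitudinal files
  with dumbbell-shaped complexes (wheat- and rice-like).
* ``scattered`` — dicot patterning: elliptical complexes placed by a
  hard-core (minimum-distance) point process at random orientations
  (tomato-like).

Imaging artifacts emulated: optical blur tied to the lens resolving power,
additive sensor noise, a multiplicative illumination gradient, and bright
circular air-bubble artifacts of the kind that plague imprint-based
sampling. The generator exists so the detection, measurement and evaluation
chain can be exercised and validated without real images or trained models;
archetype dimensions are configurable defaults, not measured species values.

Every scene is a pure function of its :class:`SceneSpec` (including the
seed): re-rendering yields bit-identical images and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .calibration import MagnificationProfile, get_profile

# fraction of complex length spanned by the aperture (pore) along the major axis
APERTURE_LENGTH_FRACTION = 0.6
# openness below this renders and records the stoma as closed (no aperture)
CLOSED_OPENNESS = 0.02

__all__ = [
    "SpeciesArchetype",
    "SceneSpec",
    "StomaTruth",
    "GroundTruth",
    "ARCHETYPES",
    "PackingError",
    "place_stomata",
    "render_scene",
    "stoma_template",
]


class PackingError(RuntimeError):
    """Target density is infeasible under the archetype's minimum spacing."""


@dataclass(frozen=True)
class SpeciesArchetype:
    """Statistical recipe for one species-like stomatal pattern.

    Dimension means/sds are in micrometres. ``aperture_openness`` is the
    ratio of aperture width to complex width, in [0, 1]. ``orientation_jitter_deg``
    is the sd of the angle around the file direction for rowed patterns;
    ``None`` means uniformly random orientation (scattered patterns).
    """

    name: str
    arrangement: str  # "rows" | "scattered"
    complex_length_um: tuple[float, float]  # (mean, sd)
    complex_width_um: tuple[float, float]
    aperture_openness: tuple[float, float]
    min_spacing_um: float
    shape: str = "ellipse"  # "ellipse" | "dumbbell"
    orientation_jitter_deg: float | None = None
    row_pitch_um: float | None = None

    def __post_init__(self) -> None:
        if self.arrangement not in ("rows", "scattered"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.shape not in ("ellipse", "dumbbell"):
            raise ValueError(f"unknown shape {self.shape!r}")
        for mean, _sd in (self.complex_length_um, self.complex_width_um):
            if mean <= 0:
                raise ValueError("complex dimensions must be positive")
        if not 0.0 <= self.aperture_openness[0] <= 1.0:
            raise ValueError("aperture openness mean must lie in [0, 1]")
        if self.min_spacing_um < 0:
            raise ValueError("min_spacing_um must be >= 0")
        if self.arrangement == "rows" and not self.row_pitch_um:
            raise ValueError("rows arrangement requires row_pitch_um")


#: Built-in archetypes. Dimensions follow the qualitative ordering of real
#: leaves (wheat stomata much larger than rice or tomato) but are generator
#: defaults, not measured values.
ARCHETYPES: dict[str, SpeciesArchetype] = {
    "graminoid-large": SpeciesArchetype(
        name="graminoid-large", arrangement="rows", shape="dumbbell",
        complex_length_um=(60.0, 6.0), complex_width_um=(28.0, 3.0),
        aperture_openness=(0.35, 0.12), min_spacing_um=45.0,
        orientation_jitter_deg=6.0, row_pitch_um=110.0,
    ),
    "graminoid-small": SpeciesArchetype(
        name="graminoid-small", arrangement="rows", shape="dumbbell",
        complex_length_um=(24.0, 3.0), complex_width_um=(11.0, 1.5),
        aperture_openness=(0.30, 0.10), min_spacing_um=20.0,
        orientation_jitter_deg=6.0, row_pitch_um=55.0,
    ),
    "dicot": SpeciesArchetype(
        name="dicot", arrangement="scattered", shape="ellipse",
        complex_length_um=(26.0, 3.0), complex_width_um=(18.0, 2.5),
        aperture_openness=(0.30, 0.10), min_spacing_um=24.0,
        orientation_jitter_deg=None,
    ),
}


@dataclass(frozen=True)
class SceneSpec:
    """Deterministic recipe for one synthetic scene."""

    profile: MagnificationProfile
    image_size_px: tuple[int, int]  # (width, height)
    target_density_mm2: float
    archetype: SpeciesArchetype
    blur_from_optics: bool = True
    noise_sd: float = 6.0  # additive Gaussian sd on the 8-bit intensity scale
    illumination_gradient: float = 0.15  # peak-to-peak multiplicative amplitude
    bubble_count: int = 0
    bubble_radius_um: tuple[float, float] = (30.0, 120.0)
    border_policy: str = "cull"  # "cull" | "keep-clipped"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_density_mm2 < 0:
            raise ValueError("target_density_mm2 must be >= 0")
        if self.border_policy not in ("cull", "keep-clipped"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")
        w, h = self.image_size_px
        if w < 8 or h < 8:
            raise ValueError("image_size_px too small")

    @property
    def imaged_area_mm2(self) -> float:
        w, h = self.image_size_px
        return (w / self.profile.px_per_mm) * (h / self.profile.px_per_mm)


def default_scene_size(profile: MagnificationProfile) -> tuple[int, int]:
    """Pixel size implied by the profile's full field of view."""
    return (
        int(round(profile.fov_width_mm * profile.px_per_mm)),
        int(round(profile.fov_height_mm * profile.px_per_mm)),
    )


@dataclass
class Placement:
    """Centre/orientation/size draw for one stoma, in pixel units."""

    cx: float
    cy: float
    angle_rad: float
    length_px: float
    width_px: float
    openness: float


@dataclass
class StomaTruth:
    """Exact ground truth for one rendered stoma."""

    stoma_id: int
    bbox: tuple[float, float, float, float]  # x, y, w, h (px, half-open)
    complex_polygon: np.ndarray  # (N, 2) float, (x, y) px
    aperture_polygon: np.ndarray | None  # None when closed
    traits: dict[str, float | None]  # *_um / *_um2 trait values


@dataclass
class GroundTruth:
    """Per-scene ground truth: all stomata plus realized count/density."""

    stomata: list[StomaTruth]
    realized_count: int
    realized_density_mm2: float
    profile_name: str
    image_size_px: tuple[int, int]


# ---------------------------------------------------------------------------
# silhouette geometry
# ---------------------------------------------------------------------------

def _silhouette(shape: str, length: float, width: float, n: int = 96) -> np.ndarray:
    """Closed outline polygon in local coords, exactly length x width in extent.

    The dumbbell profile narrows the mid-section (the guard-cell waist between
    the two terminal lobes); both shapes are normalized so the polygon's
    axis-aligned extents equal (length, width) exactly.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = 0.5 * np.cos(t)
    if shape == "ellipse":
        y = 0.5 * np.sin(t)
    else:  # dumbbell: waist at mid-length, lobes toward the poles
        y = 0.5 * np.sin(t) * (0.45 + 0.55 * np.abs(np.cos(t)))
    x = x / (x.max() - x.min()) * length
    y = y / (y.max() - y.min()) * width
    return np.column_stack([x, y])


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _transform(poly: np.ndarray, angle: float, cx: float, cy: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    rot = poly @ np.array([[c, s], [-s, c]])
    return rot + np.array([cx, cy])


def _stoma_polygons(
    p: Placement, shape: str
) -> tuple[np.ndarray, np.ndarray | None, dict[str, float]]:
    """Complex and aperture polygons (image frame) plus pixel-unit traits."""
    complex_local = _silhouette(shape, p.length_px, p.width_px)
    complex_poly = _transform(complex_local, p.angle_rad, p.cx, p.cy)
    traits_px = {
        "complex_area_px2": _shoelace_area(complex_local),
        "complex_length_px": p.length_px,
        "complex_width_px": p.width_px,
    }
    aperture_poly = None
    if p.openness > CLOSED_OPENNESS:
        ap_len = APERTURE_LENGTH_FRACTION * p.length_px
        ap_wid = p.openness * p.width_px
        # the aperture must stay strictly inside the complex; the dumbbell
        # waist is the narrowest section, so cap the aperture width there
        if shape == "dumbbell":
            ap_wid = min(ap_wid, 0.40 * p.width_px)
        ap_local = _silhouette("ellipse", ap_len, ap_wid, n=64)
        aperture_poly = _transform(ap_local, p.angle_rad, p.cx, p.cy)
        traits_px.update(
            aperture_length_px=ap_len,
            aperture_width_px=ap_wid,
            aperture_area_px2=_shoelace_area(ap_local),
        )
    return complex_poly, aperture_poly, traits_px


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _draw_size(rng: np.random.Generator, arch: SpeciesArchetype,
               profile: MagnificationProfile) -> tuple[float, float, float]:
    upp = profile.um_per_px
    length = max(4.0, rng.normal(*arch.complex_length_um)) / upp
    width = max(2.0, rng.normal(*arch.complex_width_um)) / upp
    width = min(width, 0.95 * length)  # length is the major axis by definition
    openness = float(np.clip(rng.normal(*arch.aperture_openness), 0.0, 1.0))
    return length, width, openness


def place_stomata(spec: SceneSpec, rng: np.random.Generator | None = None) -> list[Placement]:
    """Draw stomatal centres, orientations and sizes for a scene.

    Rows mode lays centres on parallel horizontal files spaced at the
    archetype's row pitch, with along-row spacing chosen to hit the target
    density and Gaussian positional jitter. Scattered mode places a Poisson
    number of centres by sequential rejection under hard-core inhibition
    (no two centres closer than ``min_spacing_um``). Centres are confined to
    a margin inset by each stoma's own half-diagonal so complexes do not
    cross the border under the default "cull" policy.

    Raises
    ------
    PackingError
        If the rejection sampler cannot reach the target count; the message
        names the achievable density.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    arch = spec.archetype
    prof = spec.profile
    w_px, h_px = spec.image_size_px
    area_mm2 = spec.imaged_area_mm2
    expected = spec.target_density_mm2 * area_mm2
    if expected <= 0:
        return []
    min_spacing_px = arch.min_spacing_um * prof.px_per_mm / 1000.0

    placements: list[Placement] = []

    def margin_for(length: float, width: float) -> float:
        return 0.5 * math.hypot(length, width) + 1.0

    def far_enough(cx: float, cy: float) -> bool:
        return all(
            math.hypot(cx - q.cx, cy - q.cy) >= min_spacing_px for q in placements
        )

    if arch.arrangement == "rows":
        n_total = int(round(expected))
        pitch_px = arch.row_pitch_um * prof.px_per_mm / 1000.0
        n_rows = max(1, int(round(h_px / pitch_px)))
        y0 = (h_px - (n_rows - 1) * pitch_px) / 2.0
        per_row = [n_total // n_rows] * n_rows
        for i in range(n_total % n_rows):
            per_row[i % n_rows] += 1
        for r in range(n_rows):
            n_r = per_row[r]
            if n_r == 0:
                continue
            step = w_px / n_r
            for j in range(n_r):
                length, width, openness = _draw_size(rng, arch, prof)
                m = margin_for(length, width)
                cx = (j + 0.5) * step + rng.normal(0.0, 0.12 * step)
                cy = y0 + r * pitch_px + rng.normal(0.0, 0.10 * pitch_px)
                angle = math.radians(rng.normal(0.0, arch.orientation_jitter_deg or 0.0))
                if spec.border_policy == "cull" and not (
                    m <= cx <= w_px - m and m <= cy <= h_px - m
                ):
                    continue
                if not far_enough(cx, cy):
                    continue
                placements.append(Placement(cx, cy, angle, length, width, openness))
    else:
        n_total = int(rng.poisson(expected))
        max_attempts = 200
        for _ in range(n_total):
            length, width, openness = _draw_size(rng, arch, prof)
            m = margin_for(length, width)
            if 2 * m >= min(w_px, h_px):
                raise PackingError("image too small to contain one stomatal complex")
            placed = False
            for _attempt in range(max_attempts):
                cx = rng.uniform(m, w_px - m)
                cy = rng.uniform(m, h_px - m)
                if far_enough(cx, cy):
                    angle = (
                        rng.uniform(0.0, np.pi)
                        if arch.orientation_jitter_deg is None
                        else math.radians(rng.normal(0.0, arch.orientation_jitter_deg))
                    )
                    placements.append(Placement(cx, cy, angle, length, width, openness))
                    placed = True
                    break
            if not placed:
                s_mm = arch.min_spacing_um / 1000.0
                hard_core_max = 2.0 / (math.sqrt(3.0) * s_mm * s_mm)
                raise PackingError(
                    f"cannot place {n_total} stomata at min spacing "
                    f"{arch.min_spacing_um} um; achieved "
                    f"{len(placements) / area_mm2:.1f} per mm^2 "
                    f"(hard-core packing bound ~{hard_core_max:.0f} per mm^2)"
                )
    return placements


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

# rendered intensities on a [0, 1] scale (before artifacts)
_BG = 0.78
_COMPLEX_FILL = 0.60
_OUTLINE = 0.34
_APERTURE_FILL = 0.12


def _rasterize(poly: np.ndarray, shape_hw: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape_hw)
    mask = np.zeros(shape_hw, dtype=bool)
    mask[rr, cc] = True
    return mask


def _truth_from_placement(
    stoma_id: int, p: Placement, spec: SceneSpec
) -> StomaTruth:
    prof = spec.profile
    upp = prof.um_per_px
    complex_poly, aperture_poly, tpx = _stoma_polygons(p, spec.archetype.shape)
    x0, y0 = complex_poly.min(axis=0)
    x1, y1 = complex_poly.max(axis=0)
    traits: dict[str, float | None] = {
        "complex_area_um2": tpx["complex_area_px2"] * upp**2,
        "complex_length_um": tpx["complex_length_px"] * upp,
        "complex_width_um": tpx["complex_width_px"] * upp,
        "aperture_length_um": None,
        "aperture_width_um": None,
        "aperture_area_um2": None,
        "openness": None,
    }
    if aperture_poly is not None:
        traits["aperture_length_um"] = tpx["aperture_length_px"] * upp
        traits["aperture_width_um"] = tpx["aperture_width_px"] * upp
        traits["aperture_area_um2"] = tpx["aperture_area_px2"] * upp**2
        traits["openness"] = tpx["aperture_width_px"] / tpx["complex_width_px"]
    return StomaTruth(
        stoma_id=stoma_id,
        bbox=(float(x0), float(y0), float(x1 - x0), float(y1 - y0)),
        complex_polygon=complex_poly,
        aperture_polygon=aperture_poly,
        traits=traits,
    )


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an 8-bit grayscale image with exact ground truth.

    Pipeline: epidermal background texture -> stomatal complexes (darker
    fill, dark outline, near-black aperture ellipse) -> bright air-bubble
    artifacts -> optical Gaussian blur (sd = half the resolving power in px)
    -> multiplicative illumination gradient -> additive sensor noise ->
    quantization to uint8. Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    w_px, h_px = spec.image_size_px
    prof = spec.profile

    placements = place_stomata(spec, rng)

    # background with smooth epidermal texture
    img = np.full((h_px, w_px), _BG, dtype=np.float64)
    texture = rng.standard_normal((h_px, w_px))
    texture = ndimage.gaussian_filter(texture, sigma=6.0)
    if texture.std() > 0:
        img += 0.03 * texture / texture.std()

    truths: list[StomaTruth] = []
    outline_px = max(1, int(round(1.5 * prof.px_per_mm / 1000.0)))
    for i, p in enumerate(placements):
        truth = _truth_from_placement(i, p, spec)
        cmask = _rasterize(truth.complex_polygon, (h_px, w_px))
        if not cmask.any():
            continue  # fully off-image (keep-clipped pathological case)
        interior = ndimage.binary_erosion(cmask, iterations=outline_px)
        img[cmask] = _OUTLINE
        img[interior] = _COMPLEX_FILL
        if truth.aperture_polygon is not None:
            amask = _rasterize(truth.aperture_polygon, (h_px, w_px))
            img[amask] = _APERTURE_FILL
        truths.append(truth)

    # bright air-bubble artifacts with soft edges (imprint-style defects)
    for _ in range(spec.bubble_count):
        r_um = rng.uniform(*spec.bubble_radius_um)
        r_px = r_um * prof.px_per_mm / 1000.0
        bx, by = rng.uniform(0, w_px), rng.uniform(0, h_px)
        yy, xx = np.mgrid[0:h_px, 0:w_px]
        d = np.hypot(xx - bx, yy - by)
        edge = 0.15 * r_px + 1.0
        bubble = np.clip((r_px - d) / edge, 0.0, 1.0)
        img = img + 0.18 * bubble

    if spec.blur_from_optics:
        sigma_px = prof.resolving_power_um * prof.px_per_mm / 1000.0 / 2.0
        img = ndimage.gaussian_filter(img, sigma=sigma_px)

    if spec.illumination_gradient > 0:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        yy, xx = np.mgrid[0:h_px, 0:w_px]
        ramp = (xx * math.cos(theta) + yy * math.sin(theta))
        ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1.0)
        img = img * (1.0 - spec.illumination_gradient / 2.0 + spec.illumination_gradient * ramp)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd / 255.0, size=img.shape)

    image8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    gt = GroundTruth(
        stomata=truths,
        realized_count=len(truths),
        realized_density_mm2=len(truths) / spec.imaged_area_mm2,
        profile_name=prof.name,
        image_size_px=spec.image_size_px,
    )
    return image8, gt


def stoma_template(
    length_um: float,
    profile: MagnificationProfile,
    angle_rad: float = 0.0,
    shape: str = "dumbbell",
    aspect: float = 0.45,
    openness: float = 0.3,
    blur: bool = True,
) -> np.ndarray:
    """Render one noise-free stoma on a tight canvas, as a matched template.

    Used by the classical detector to build its normalized cross-correlation
    template bank. Returns a float image in [0, 1].
    """
    length_px = length_um * profile.px_per_mm / 1000.0
    width_px = aspect * length_px
    if length_px < 4:
        raise ValueError("template below 4 px; use a higher-magnification profile")
    pad = 0.35 * length_px
    half = 0.5 * math.hypot(length_px, width_px) + pad
    size = int(2 * math.ceil(half))
    p = Placement(size / 2.0, size / 2.0, angle_rad, length_px, width_px, openness)
    cpoly, apoly, _ = _stoma_polygons(p, shape)
    img = np.full((size, size), _BG, dtype=np.float64)
    cmask = _rasterize(cpoly, (size, size))
    outline_px = max(1, int(round(1.5 * profile.px_per_mm / 1000.0)))
    interior = ndimage.binary_erosion(cmask, iterations=outline_px)
    img[cmask] = _OUTLINE
    img[interior] = _COMPLEX_FILL
    if apoly is not None:
        img[_rasterize(apoly, (size, size))] = _APERTURE_FILL
    if blur:
        sigma_px = profile.resolving_power_um * profile.px_per_mm / 1000.0 / 2.0
        img = ndimage.gaussian_filter(img, sigma=sigma_px)
    return img


def make_scene_spec(
    profile: str | MagnificationProfile = "400x",
    archetype: str | SpeciesArchetype = "dicot",
    image_size_px: tuple[int, int] | None = None,
    **kwargs,
) -> SceneSpec:
    """Convenience constructor resolving registry names to objects."""
    prof = get_profile(profile) if isinstance(profile, str) else profile
    arch = ARCHETYPES[archetype] if isinstance(archetype, str) else archetype
    if image_size_px is None:
        image_size_px = default_scene_size(prof)
    kwargs.setdefault("target_density_mm2", 120.0)
    return SceneSpec(profile=prof, image_size_px=image_size_px,
                     archetype=arch, **kwargs)
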