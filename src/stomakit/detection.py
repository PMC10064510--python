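"""Stomatal bounding-box detection.

Two backends produce per-image :class:`DetectionBox` lists:

* :func:`detect_classical` — a deterministic classical detector that scores
  the image by normalized cross-correlation against a small bank of
  synthetic stoma templates (one per orientation, rendered at the expected
  physical scale for the active magnification profile) after band-pass
  filtering, then thresholds and applies non-maximum suppression. It runs on
  one CPU with no trained weights.
* :func:`read_detection_file` — adapter for externally produced detections
  in the normalized-bounding-box text dialect (one line per box:
  ``class cx cy w h [conf]``, coordinates in [0, 1] relative to the image).

Box convention throughout: 0-based pixel coordinates, origin top-left,
half-open ``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max

from .calibration import MagnificationProfile, um_to_px
from . import synthetic

__all__ = [
    "DetectionBox",
    "DetectorConfig",
    "DetectionFileError",
    "detect_classical",
    "non_max_suppression",
    "crop_for_measurement",
    "read_detection_file",
    "write_detection_file",
]


class DetectionFileError(ValueError):
    """Malformed normalized-box detection file."""


@dataclass(frozen=True)
class DetectionBox:
    """One detected or annotated stoma as an axis-aligned pixel box."""

    image_id: str
    bbox: tuple[float, float, float, float]  # x, y, w, h
    confidence: float = 1.0
    label: str = "stoma"

    def __post_init__(self) -> None:
        _, _, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError(f"box must have positive extent, got w={w}, h={h}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")

    @property
    def area(self) -> float:
        return self.bbox[2] * self.bbox[3]


@dataclass(frozen=True)
class DetectorConfig:
    """Settings for the classical template-matching detector.

    ``expected_length_um`` is the physical scale prior for the stomatal
    complex (major axis). Template shape/aspect default to a generic
    dumbbell complex; set ``template_shape="ellipse"`` for dicot-like
    material.
    """

    expected_length_um: float = 40.0
    orientations: tuple[float, ...] = (0.0,)  # radians
    match_threshold: float = 0.5
    nms_iou: float = 0.3
    template_shape: str = "dumbbell"
    template_aspect: float | None = None  # width/length; default per shape

    @property
    def aspect(self) -> float:
        if self.template_aspect is not None:
            return self.template_aspect
        return 0.7 if self.template_shape == "ellipse" else 0.45

    def __post_init__(self) -> None:
        if not 0.0 <= self.match_threshold <= 1.0:
            raise ValueError("match_threshold must lie in [0, 1]")
        if not 0.0 <= self.nms_iou < 1.0:
            raise ValueError("nms_iou must lie in [0, 1)")
        if self.expected_length_um <= 0:
            raise ValueError("expected_length_um must be positive")


def _box_iou(a: tuple[float, float, float, float],
             b: tuple[float, float, float, float]) -> float:
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix = max(0.0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def non_max_suppression(boxes: list[DetectionBox], nms_iou: float) -> list[DetectionBox]:
    """Greedy NMS: keep the most confident box, drop overlapping rivals.

    Ties in confidence are broken by larger area, then by input order, so
    the result is deterministic and stable under permutation when
    confidences are distinct.
    """
    order = sorted(
        range(len(boxes)),
        key=lambda i: (-boxes[i].confidence, -boxes[i].area, i),
    )
    kept: list[int] = []
    for i in order:
        if all(_box_iou(boxes[i].bbox, boxes[j].bbox) <= nms_iou for j in kept):
            kept.append(i)
    return [boxes[i] for i in sorted(kept)]


def detect_classical(
    image: np.ndarray,
    profile: MagnificationProfile,
    config: DetectorConfig | None = None,
    image_id: str = "image",
) -> list[DetectionBox]:
    """Detect stomata by multi-orientation template correlation.

    The image is band-pass filtered at the expected stomatal scale
    (difference of Gaussians) to suppress illumination gradients and
    fine-grained noise, then correlated with synthetic stoma templates
    rendered at ``expected_length_um`` for each configured orientation.
    Local correlation maxima above ``match_threshold`` become boxes of the
    template's tight extent; greedy NMS removes duplicates. Output is
    sorted by descending confidence.

    Raises
    ------
    ValueError
        If the expected complex measures under 4 px at this profile — the
        organ is below resolvability and a higher magnification is needed.
    """
    if config is None:
        config = DetectorConfig()
    length_px = um_to_px(config.expected_length_um, profile)
    if length_px < 4:
        raise ValueError(
            f"expected stomatal length {config.expected_length_um} um is only "
            f"{length_px:.1f} px at profile {profile.name}; "
            "use a higher-magnification profile"
        )
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.0:
        img = img / 255.0

    # band-pass at the stomatal scale: keeps blob-sized structure
    lo = ndimage.gaussian_filter(img, sigma=length_px / 8.0)
    hi = ndimage.gaussian_filter(img, sigma=length_px / 2.0)
    band = lo - hi

    # darkness prior: after flat-field normalization by the wide surround
    # (which also removes the illumination gradient), the stoma core — at
    # the scale of its minor axis — must be darker than its surround by a
    # minimal relative contrast
    width_px = config.aspect * length_px
    core = ndimage.gaussian_filter(img, sigma=max(1.0, width_px / 2.0))
    surround = np.maximum(ndimage.gaussian_filter(img, sigma=2.0 * length_px), 1e-6)
    darkness = np.clip((1.0 - core / surround) / 0.15, 0.0, 1.0)

    scores: list[np.ndarray] = []
    extents: list[tuple[int, int]] = []
    for angle in config.orientations:
        tmpl = synthetic.stoma_template(
            config.expected_length_um, profile, angle_rad=angle,
            shape=config.template_shape, aspect=config.aspect,
        )
        t_lo = ndimage.gaussian_filter(tmpl, sigma=length_px / 8.0)
        t_hi = ndimage.gaussian_filter(tmpl, sigma=length_px / 2.0)
        t_band = t_lo - t_hi
        if t_band.shape[0] > band.shape[0] or t_band.shape[1] > band.shape[1]:
            continue  # template larger than image at this orientation
        ncc = match_template(band, t_band, pad_input=True, mode="reflect")
        # NCC is contrast-invariant, so faint background texture can score
        # as high as a real stoma; damp the score by (a) the local band-pass
        # energy relative to the template's own contrast and (b) a darkness
        # prior — a stoma is darker than its surround, texture is not
        local_rms = np.sqrt(
            ndimage.uniform_filter(band**2, size=min(t_band.shape))
        )
        contrast = np.clip(local_rms / (0.5 * t_band.std() + 1e-12), 0.0, 1.0)
        contrast = contrast * darkness
        scores.append(ncc * contrast)
        # box extent: axis-aligned bounds of the expected complex (ellipse
        # with semi-axes L/2, W/2) at this orientation — matches the
        # ground-truth tight-AABB convention
        c, s = abs(np.cos(angle)), abs(np.sin(angle))
        ew = 2.0 * np.hypot(length_px / 2.0 * c, width_px / 2.0 * s)
        eh = 2.0 * np.hypot(length_px / 2.0 * s, width_px / 2.0 * c)
        extents.append((ew, eh))
    if not scores:
        return []
    stack = np.stack(scores)
    best_score = stack.max(axis=0)
    best_orient = stack.argmax(axis=0)

    peaks = peak_local_max(
        best_score,
        min_distance=max(2, int(length_px / 4)),
        threshold_abs=config.match_threshold,
        exclude_border=False,
    )
    boxes: list[DetectionBox] = []
    h_img, w_img = img.shape
    for py, px_ in peaks:
        conf = float(np.clip(best_score[py, px_], 0.0, 1.0))
        ew, eh = extents[int(best_orient[py, px_])]
        x = float(np.clip(px_ - ew / 2.0, 0, w_img - 1))
        y = float(np.clip(py - eh / 2.0, 0, h_img - 1))
        w = min(float(ew), w_img - x)
        h = min(float(eh), h_img - y)
        boxes.append(DetectionBox(image_id=image_id, bbox=(x, y, w, h), confidence=conf))
    boxes = non_max_suppression(boxes, config.nms_iou)
    return sorted(boxes, key=lambda b: -b.confidence)


def crop_for_measurement(
    image: np.ndarray, box: DetectionBox, pad_fraction: float = 0.25
) -> tuple[np.ndarray, tuple[int, int]]:
    """Extract a padded crop around a detection for single-stoma measurement.

    Returns ``(crop, (x_offset, y_offset))``; adding the offset to crop
    coordinates recovers full-image coordinates. The crop is clipped to the
    image bounds.
    """
    h_img, w_img = image.shape[:2]
    x, y, w, h = box.bbox
    px, py = pad_fraction * w, pad_fraction * h
    x0 = max(0, int(np.floor(x - px)))
    y0 = max(0, int(np.floor(y - py)))
    x1 = min(w_img, int(np.ceil(x + w + px)))
    y1 = min(h_img, int(np.ceil(y + h + py)))
    return image[y0:y1, x0:x1], (x0, y0)


# ---------------------------------------------------------------------------
# normalized-box text dialect
# ---------------------------------------------------------------------------

def read_detection_file(
    path: str | Path, image_size_px: tuple[int, int], image_id: str | None = None
) -> list[DetectionBox]:
    """Read a normalized-bounding-box text file into pixel boxes.

    Each non-empty line is ``class cx cy w h [conf]`` with centre
    coordinates and extents normalized to [0, 1] by image width/height.
    Pixel conversion: ``x = (cx - w/2) * W`` etc. A missing confidence
    defaults to 1.0. An empty file is a valid empty detection set.

    Raises
    ------
    DetectionFileError
        Naming the offending line on malformed input or out-of-range values.
    """
    path = Path(path)
    if image_id is None:
        image_id = path.stem
    w_img, h_img = image_size_px
    boxes: list[DetectionBox] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise DetectionFileError(
                f"{path.name}:{lineno}: expected 5 or 6 fields, got {len(parts)}"
            )
        try:
            cx, cy, w, h = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
        except ValueError as exc:
            raise DetectionFileError(f"{path.name}:{lineno}: {exc}") from None
        if not (0 <= cx <= 1 and 0 <= cy <= 1 and 0 < w <= 1 and 0 < h <= 1
                and 0 <= conf <= 1):
            raise DetectionFileError(
                f"{path.name}:{lineno}: values out of normalized range: {line!r}"
            )
        boxes.append(DetectionBox(
            image_id=image_id,
            bbox=((cx - w / 2) * w_img, (cy - h / 2) * h_img, w * w_img, h * h_img),
            confidence=conf,
        ))
    return boxes


def write_detection_file(
    path: str | Path, boxes: list[DetectionBox], image_size_px: tuple[int, int]
) -> None:
    """Write boxes in the normalized-box text dialect (inverse of the reader)."""
    w_img, h_img = image_size_px
    lines = []
    for b in boxes:
        x, y, w, h = b.bbox
        lines.append(
            f"0 {(x + w / 2) / w_img:.6f} {(y + h / 2) / h_img:.6f} "
            f"{w / w_img:.6f} {h / h_img:.6f} {b.confidence:.6f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
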