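"""COCO-style instance-annotation files for stomatal complexes and apertures.

The on-disk format is the standard COCO JSON layout with two categories,
``stomatal_complex`` and ``aperture``. Boxes use the ``[x, y, w, h]`` pixel
convention; polygons are flat ``[x0, y0, x1, y1, ...]`` coordinate lists.
Apertures carry no explicit link to their complex; on reading, an aperture
is attached to the complex polygon containing its centroid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon

COMPLEX_CATEGORY = "stomatal_complex"
APERTURE_CATEGORY = "aperture"


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation file."""


def _poly_to_flat(poly: np.ndarray) -> list[float]:
    return [round(float(v), 3) for v in np.asarray(poly, dtype=float).ravel()]


def _flat_to_poly(flat: list[float], where: str) -> np.ndarray:
    arr = np.asarray(flat, dtype=float)
    if arr.size < 6 or arr.size % 2:
        raise AnnotationError(f"{where}: polygon needs >= 3 (x, y) vertices")
    return arr.reshape(-1, 2)


def write_coco(
    path: str | Path,
    images: list[dict],
    instances: list[dict],
) -> None:
    """Write a COCO-style annotation file.

    ``images`` entries need ``id``, ``file_name``, ``width``, ``height``.
    ``instances`` entries need ``image_id``, ``category`` (one of the two
    category names) and ``polygon`` as an (N, 2) array.
    """
    categories = [
        {"id": 1, "name": COMPLEX_CATEGORY},
        {"id": 2, "name": APERTURE_CATEGORY},
    ]
    cat_ids = {c["name"]: c["id"] for c in categories}
    annotations = []
    for i, inst in enumerate(instances, start=1):
        poly = np.asarray(inst["polygon"], dtype=float)
        x0, y0 = poly.min(axis=0)
        x1, y1 = poly.max(axis=0)
        annotations.append({
            "id": i,
            "image_id": inst["image_id"],
            "category_id": cat_ids[inst["category"]],
            "bbox": [round(float(v), 3) for v in (x0, y0, x1 - x0, y1 - y0)],
            "area": round(float(Polygon(poly).area), 3),
            "segmentation": [_poly_to_flat(poly)],
            "iscrowd": 0,
        })
    doc = {"images": images, "categories": categories, "annotations": annotations}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path: str | Path) -> tuple[list[dict], dict[int, list[dict]]]:
    """Read a COCO-style file into images plus per-image instance lists.

    Returns ``(images, instances_by_image)`` where each instance dict has
    ``category`` (name) and ``polygon`` ((N, 2) array).
    """
    doc = json.loads(Path(path).read_text())
    try:
        cat_names = {c["id"]: c["name"] for c in doc["categories"]}
    except (KeyError, TypeError):
        raise AnnotationError(f"{path}: missing or invalid category map") from None
    names = set(cat_names.values())
    if not {COMPLEX_CATEGORY, APERTURE_CATEGORY} <= names:
        raise AnnotationError(
            f"{path}: categories must include {COMPLEX_CATEGORY!r} and "
            f"{APERTURE_CATEGORY!r}, got {sorted(names)}"
        )
    by_image: dict[int, list[dict]] = {}
    for ann in doc.get("annotations", []):
        seg = ann.get("segmentation") or []
        if not seg:
            raise AnnotationError(f"{path}: annotation {ann.get('id')} has no polygon")
        poly = _flat_to_poly(seg[0], f"{path}: annotation {ann.get('id')}")
        by_image.setdefault(ann["image_id"], []).append({
            "id": ann.get("id"),
            "category": cat_names[ann["category_id"]],
            "polygon": poly,
        })
    return doc.get("images", []), by_image


def attach_apertures(
    instances: list[dict],
) -> tuple[list[tuple[np.ndarray, np.ndarray | None]], list]:
    """Pair aperture polygons with the complex containing their centroid.

    Returns ``(pairs, orphans)`` where each pair is
    ``(complex_polygon, aperture_polygon_or_None)`` and orphans lists the
    ids of apertures whose centroid lies in no complex.
    """
    complexes = [i for i in instances if i["category"] == COMPLEX_CATEGORY]
    apertures = [i for i in instances if i["category"] == APERTURE_CATEGORY]
    shapes = [Polygon(c["polygon"]) for c in complexes]
    paired: list[np.ndarray | None] = [None] * len(complexes)
    orphans = []
    for ap in apertures:
        centroid = Point(Polygon(ap["polygon"]).centroid)
        for k, shp in enumerate(shapes):
            if shp.contains(centroid):
                paired[k] = ap["polygon"]
                break
        else:
            orphans.append(ap.get("id"))
    return [(c["polygon"], paired[k]) for k, c in enumerate(complexes)], orphans
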