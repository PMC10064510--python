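"""Batch orchestration: images in, trait and summary tables out.

`run_pipeline` drives the full chain per image — detect (or read external
detections) -> crop -> segment (or read external instance annotations) ->
measure -> summarize — and writes the per-stoma trait CSV, the per-image
summary CSV and a machine-readable run manifest. A failure on one image is
recorded as a status row and does not abort the batch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .annotations import write_coco
from .calibration import (MagnificationProfile, check_image_dimensions,
                          get_profile, register_profile)
from .detection import (DetectionBox, DetectorConfig, crop_for_measurement,
                        detect_classical, read_detection_file,
                        write_detection_file)
from .measure import (TRAIT_CSV_COLUMNS, ImageSummary, SegmentationConfig,
                      StomaMask, TraitRecord, measure,
                      read_instance_annotations, segment_stoma,
                      summarize_image)
from .synthetic import GroundTruth, make_scene_spec, render_scene

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")

SUMMARY_CSV_COLUMNS = [
    "image_id", "profile", "status", "stomata_count", "density_mm2",
    "mean_complex_area_um2", "median_complex_area_um2",
    "mean_aperture_length_um", "fraction_open",
]


@dataclass
class RunConfig:
    """Configuration of one batch run (all CLI flags map onto these keys)."""

    profile: str = "400x"
    detector_backend: str = "classical"  # "classical" | "external-files"
    segmentation_backend: str = "classical"  # "classical" | "external-files"
    images_dir: str = "."
    detections_dir: str | None = None
    annotations_dir: str | None = None
    output_dir: str = "out"
    expected_length_um: float = 40.0
    template_shape: str = "dumbbell"
    n_orientations: int = 1
    match_threshold: float = 0.5
    nms_iou: float = 0.3
    iou_eval: float = 0.5
    pad_fraction: float = 0.25
    seed: int = 0
    custom_profile: dict | None = None

    def resolve_profile(self) -> MagnificationProfile:
        if self.custom_profile:
            prof = MagnificationProfile(**self.custom_profile)
            register_profile(prof)
            return prof
        return get_profile(self.profile)

    def detector_config(self) -> DetectorConfig:
        angles = tuple(
            k * np.pi / self.n_orientations for k in range(self.n_orientations)
        )
        return DetectorConfig(
            expected_length_um=self.expected_length_um,
            orientations=angles,
            match_threshold=self.match_threshold,
            nms_iou=self.nms_iou,
            template_shape=self.template_shape,
        )


def load_image(path: str | Path) -> np.ndarray:
    """Load an image as 8-bit grayscale."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def save_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def _touches_border(box: DetectionBox, width: int, height: int) -> bool:
    x, y, w, h = box.bbox
    return x <= 0 or y <= 0 or x + w >= width or y + h >= height


def process_image(
    image: np.ndarray,
    image_id: str,
    profile: MagnificationProfile,
    boxes: list[DetectionBox],
    seg_config: SegmentationConfig | None = None,
    pad_fraction: float = 0.25,
    masks: list[StomaMask] | None = None,
) -> tuple[list[TraitRecord], ImageSummary]:
    """Measure every detected stoma on one image and summarize.

    If ``masks`` is given (external segmentation backend) they are measured
    directly; otherwise each box is cropped and segmented classically.
    Border-touching detections are counted but flagged ``border`` so they do
    not enter size statistics.
    """
    h_img, w_img = image.shape[:2]
    records: list[TraitRecord] = []
    if masks is not None:
        for mask in masks:
            records.append(measure(mask, profile, image_id))
    else:
        for i, box in enumerate(boxes):
            crop, offset = crop_for_measurement(image, box, pad_fraction)
            mask = segment_stoma(crop, profile, seg_config, offset=offset, stoma_id=i)
            rec = measure(mask, profile, image_id)
            if rec.status == "ok" and _touches_border(box, w_img, h_img):
                rec.status = "border"
            records.append(rec)
    count = len(boxes) if masks is None else len(masks)
    summary = summarize_image(records, count, profile, image_id)
    return records, summary


def traits_to_frame(records: list[TraitRecord],
                    boxes_by_image: dict[str, list[DetectionBox]] | None = None
                    ) -> pd.DataFrame:
    rows = []
    for rec in records:
        box = (None, None, None, None)
        if boxes_by_image is not None:
            blist = boxes_by_image.get(rec.image_id, [])
            if isinstance(rec.stoma_id, int) and rec.stoma_id < len(blist):
                box = blist[rec.stoma_id].bbox
        rows.append({
            "stoma_id": rec.stoma_id, "image_id": rec.image_id,
            "x": box[0], "y": box[1], "w": box[2], "h": box[3],
            "complex_area_um2": rec.complex_area_um2,
            "complex_length_um": rec.complex_length_um,
            "complex_width_um": rec.complex_width_um,
            "aperture_length_um": rec.aperture_length_um,
            "aperture_width_um": rec.aperture_width_um,
            "aperture_area_um2": rec.aperture_area_um2,
            "openness": rec.openness, "status": rec.status,
        })
    return pd.DataFrame(rows, columns=TRAIT_CSV_COLUMNS)


def summaries_to_frame(summaries: list[ImageSummary],
                       statuses: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for s in summaries:
        status = (statuses or {}).get(s.image_id, "ok")
        rows.append({
            "image_id": s.image_id, "profile": s.profile_name, "status": status,
            "stomata_count": s.stomata_count, "density_mm2": s.density_mm2,
            "mean_complex_area_um2": s.mean_complex_area_um2,
            "median_complex_area_um2": s.median_complex_area_um2,
            "mean_aperture_length_um": s.mean_aperture_length_um,
            "fraction_open": s.fraction_open,
        })
    return pd.DataFrame(rows, columns=SUMMARY_CSV_COLUMNS)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full phenotyping chain over a directory of images.

    Returns the output directory, which holds ``traits.csv`` (per stoma),
    ``summaries.csv`` (per image), per-image detection files and
    ``manifest.json`` recording the configuration, software version and
    per-image status.
    """
    profile = config.resolve_profile()
    images_dir = Path(config.images_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_paths = sorted(
        p for p in images_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )

    all_records: list[TraitRecord] = []
    summaries: list[ImageSummary] = []
    statuses: dict[str, str] = {}
    boxes_by_image: dict[str, list[DetectionBox]] = {}
    for path in image_paths:
        image_id = path.stem
        try:
            image = load_image(path)
        except Exception as exc:  # unreadable image: record and continue
            logger.warning("skipping unreadable image %s: %s", path.name, exc)
            statuses[image_id] = f"error: {exc}"
            summaries.append(ImageSummary(image_id, profile.name, 0, 0.0,
                                          None, None, None, None))
            continue
        check_image_dimensions(image.shape[1], image.shape[0], profile)
        logger.info("processing %s", path.name)

        masks = None
        if config.detector_backend == "external-files":
            det_path = Path(config.detections_dir or images_dir) / f"{image_id}.txt"
            boxes = read_detection_file(
                det_path, (image.shape[1], image.shape[0]), image_id
            ) if det_path.exists() else []
        else:
            boxes = detect_classical(image, profile, config.detector_config(),
                                     image_id=image_id)
        boxes_by_image[image_id] = boxes
        if config.segmentation_backend == "external-files":
            ann_path = Path(config.annotations_dir or images_dir) / f"{image_id}.json"
            masks = []
            if ann_path.exists():
                for mask_list in read_instance_annotations(ann_path).values():
                    masks.extend(mask_list)
        records, summary = process_image(
            image, image_id, profile, boxes,
            pad_fraction=config.pad_fraction, masks=masks,
        )
        write_detection_file(out_dir / f"{image_id}.txt", boxes,
                             (image.shape[1], image.shape[0]))
        all_records.extend(records)
        summaries.append(summary)
        statuses[image_id] = "ok"

    traits_to_frame(all_records, boxes_by_image).to_csv(
        out_dir / "traits.csv", index=False
    )
    summaries_to_frame(summaries, statuses).to_csv(
        out_dir / "summaries.csv", index=False
    )
    manifest = {
        "stomakit_version": __version__,
        "config": dataclasses.asdict(config),
        "n_images": len(image_paths),
        "per_image_status": statuses,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def ground_truth_to_records(
    gt: GroundTruth, image_id: str
) -> list[TraitRecord]:
    """Ground truth as trait records (for GT trait CSVs and comparisons)."""
    records = []
    for s in gt.stomata:
        t = s.traits
        records.append(TraitRecord(
            stoma_id=s.stoma_id, image_id=image_id,
            complex_area_um2=t["complex_area_um2"],
            complex_length_um=t["complex_length_um"],
            complex_width_um=t["complex_width_um"],
            aperture_length_um=t["aperture_length_um"],
            aperture_width_um=t["aperture_width_um"],
            aperture_area_um2=t["aperture_area_um2"],
            openness=t["openness"], status="ok",
        ))
    return records


def ground_truth_boxes(gt: GroundTruth, image_id: str) -> list[DetectionBox]:
    return [
        DetectionBox(image_id=image_id, bbox=s.bbox, confidence=1.0)
        for s in gt.stomata
    ]


def write_ground_truth(
    out_dir: Path, image_id: str, image: np.ndarray, gt: GroundTruth
) -> None:
    """Write a scene's image (PNG), COCO annotations (JSON) and boxes (txt)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    save_image(out_dir / f"{image_id}.png", image)
    instances = []
    for s in gt.stomata:
        instances.append({"image_id": 1, "category": "stomatal_complex",
                          "polygon": s.complex_polygon})
        if s.aperture_polygon is not None:
            instances.append({"image_id": 1, "category": "aperture",
                              "polygon": s.aperture_polygon})
    w, h = gt.image_size_px
    write_coco(
        out_dir / f"{image_id}.json",
        images=[{"id": 1, "file_name": f"{image_id}.png", "width": w, "height": h}],
        instances=instances,
    )
    write_detection_file(out_dir / f"{image_id}.txt",
                         ground_truth_boxes(gt, image_id), gt.image_size_px)


def simulate_batch(
    out_dir: str | Path,
    n_images: int,
    profile: str = "400x",
    archetype: str = "dicot",
    target_density_mm2: float = 120.0,
    noise_sd: float = 6.0,
    illumination_gradient: float = 0.15,
    bubble_count: int = 0,
    seed: int = 0,
    image_size_px: tuple[int, int] | None = None,
) -> Path:
    """Generate a deterministic fixture set: images + annotations + GT traits."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_records: list[TraitRecord] = []
    for i in range(n_images):
        spec = make_scene_spec(
            profile=profile, archetype=archetype, image_size_px=image_size_px,
            target_density_mm2=target_density_mm2, noise_sd=noise_sd,
            illumination_gradient=illumination_gradient,
            bubble_count=bubble_count, seed=seed + i,
        )
        image, gt = render_scene(spec)
        image_id = f"scene_{i:03d}"
        write_ground_truth(out_dir, image_id, image, gt)
        all_records.extend(ground_truth_to_records(gt, image_id))
    traits_to_frame(all_records).to_csv(out_dir / "gt_traits.csv", index=False)
    return out_dir
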