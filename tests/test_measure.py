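from dataclasses import replace

import numpy as np
import pytest
from shapely.geometry import Polygon

import stomakit as sk
from stomakit.annotations import AnnotationError, write_coco
from stomakit.detection import crop_for_measurement
from stomakit.measure import (SegmentationConfig, StomaMask, measure,
                              mask_from_polygons, polygon_ellipse,
                              read_instance_annotations, segment_stoma,
                              summarize_image)
from stomakit.pipeline import ground_truth_boxes, process_image
from stomakit.synthetic import render_scene

from conftest import single_stoma_scene


def ellipse_polygon(cx, cy, a, b, angle=0.0, n=128):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    c, s = np.cos(angle), np.sin(angle)
    return np.column_stack([cx + x * c - y * s, cy + x * s + y * c])


def render_single(openness, seed0=0, tries=15, noise_sd=0.0):
    """First seed that produces exactly one rendered stoma."""
    spec = single_stoma_scene(openness_mean=openness, noise_sd=noise_sd)
    for seed in range(seed0, seed0 + tries):
        image, gt = render_scene(replace(spec, seed=seed))
        if gt.realized_count == 1:
            return spec, image, gt
    raise RuntimeError("no single-stoma render found")


class TestPolygonEllipse:
    def test_recovers_ellipse_axes_exactly(self):
        poly = ellipse_polygon(10, 20, 8, 3, angle=0.7)
        (cx, cy), (maj, mi), ang = polygon_ellipse(poly)
        assert (cx, cy) == pytest.approx((10, 20), abs=1e-6)
        assert maj == pytest.approx(8, rel=1e-3)
        assert mi == pytest.approx(3, rel=1e-3)
        assert ang % np.pi == pytest.approx(0.7, abs=1e-3)

    def test_invariant_to_vertex_order_and_start(self):
        poly = ellipse_polygon(5, 5, 6, 2, angle=0.3)
        ref = polygon_ellipse(poly)
        rolled = np.roll(poly, 17, axis=0)
        reversed_ = poly[::-1]
        for variant in (rolled, reversed_):
            (c, axes, ang) = polygon_ellipse(variant)
            assert c == pytest.approx(ref[0], abs=1e-9)
            assert axes == pytest.approx(ref[1], rel=1e-9)


class TestSegmentStoma:
    def test_elliptical_complex_area_recovered(self, p400):
        spec, image, gt = render_single(openness=0.3)
        boxes = ground_truth_boxes(gt, "img")
        crop, offset = crop_for_measurement(image, boxes[0], 0.25)
        mask = segment_stoma(crop, p400, offset=offset)
        assert mask.status == "ok"
        est = Polygon(mask.complex_polygon).area
        true = Polygon(gt.stomata[0].complex_polygon).area
        assert est == pytest.approx(true, rel=0.05)

    def test_open_stoma_gets_aperture_inside_complex(self, p400):
        spec, image, gt = render_single(openness=0.45)
        crop, offset = crop_for_measurement(image, ground_truth_boxes(gt, "i")[0], 0.25)
        mask = segment_stoma(crop, p400, offset=offset)
        assert mask.aperture_polygon is not None
        cshape = Polygon(mask.complex_polygon)
        ashape = Polygon(mask.aperture_polygon)
        assert ashape.intersection(cshape).area >= 0.95 * ashape.area

    def test_closed_stoma_has_no_aperture(self, p400):
        spec, image, gt = render_single(openness=0.0)
        crop, offset = crop_for_measurement(image, ground_truth_boxes(gt, "i")[0], 0.25)
        mask = segment_stoma(crop, p400, offset=offset)
        assert mask.status == "ok"
        assert mask.aperture_polygon is None

    def test_blank_crop_fails_gracefully(self, p400):
        blank = np.full((40, 40), 180, dtype=np.uint8)
        mask = segment_stoma(blank, p400)
        assert mask.status == "failed"
        assert mask.complex_polygon is None

    def test_empty_crop_fails_gracefully(self, p400):
        mask = segment_stoma(np.zeros((0, 0)), p400)
        assert mask.status == "failed"


class TestMeasure:
    def test_unit_square_area_at_400x(self, p400):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        rec = measure(mask_from_polygons(0, sq), p400)
        assert rec.complex_area_um2 == pytest.approx((1000 / 652) ** 2, rel=1e-9)
        assert rec.complex_area_um2 == pytest.approx(2.3524, abs=1e-3)

    def test_ground_truth_mask_reproduces_traits(self, p400):
        # measuring the generator's own polygons must recover its traits
        spec, image, gt = render_single(openness=0.4)
        s = gt.stomata[0]
        rec = measure(mask_from_polygons(0, s.complex_polygon, s.aperture_polygon), p400)
        assert rec.complex_area_um2 == pytest.approx(s.traits["complex_area_um2"], rel=0.05)
        assert rec.complex_length_um == pytest.approx(s.traits["complex_length_um"], rel=0.05)
        assert rec.complex_width_um == pytest.approx(s.traits["complex_width_um"], rel=0.05)
        assert rec.aperture_width_um == pytest.approx(s.traits["aperture_width_um"], rel=0.05)
        assert rec.openness == pytest.approx(s.traits["openness"], rel=0.05)

    def test_closed_mask_gives_null_aperture_fields(self, p400):
        poly = ellipse_polygon(20, 20, 10, 6)
        rec = measure(mask_from_polygons(0, poly), p400)
        assert rec.aperture_length_um is None
        assert rec.openness is None
        assert rec.complex_length_um >= rec.complex_width_um > 0

    def test_failed_mask_gives_failed_record(self, p400):
        rec = measure(StomaMask(0, None, status="failed"), p400)
        assert rec.status == "failed"
        assert rec.complex_area_um2 is None

    def test_scale_consistency_across_profiles(self):
        # the same physical stoma imaged at 200x and 400x must yield
        # physical traits agreeing within 10%
        results = {}
        for prof_name in ("200x", "400x"):
            prof = sk.get_profile(prof_name)
            spec = single_stoma_scene(openness_mean=0.3, profile=prof_name)
            for seed in range(15):
                image, gt = render_scene(replace(spec, seed=seed))
                if gt.realized_count != 1:
                    continue
                crop, offset = crop_for_measurement(
                    image, ground_truth_boxes(gt, "i")[0], 0.25
                )
                mask = segment_stoma(crop, prof, offset=offset)
                rec = measure(mask, prof)
                if rec.status == "ok":
                    # normalize by the true size so different draws compare
                    results[prof_name] = rec.complex_area_um2 / gt.stomata[0].traits["complex_area_um2"]
                    break
        assert set(results) == {"200x", "400x"}
        assert results["200x"] == pytest.approx(results["400x"], rel=0.10)


class TestAnnotationsRoundTrip:
    def test_write_then_read_recovers_polygons(self, tmp_path, dicot_scene):
        spec, image, gt = dicot_scene
        instances = []
        for s in gt.stomata:
            instances.append({"image_id": 1, "category": "stomatal_complex",
                              "polygon": s.complex_polygon})
            if s.aperture_polygon is not None:
                instances.append({"image_id": 1, "category": "aperture",
                                  "polygon": s.aperture_polygon})
        path = tmp_path / "ann.json"
        write_coco(path, [{"id": 1, "file_name": "x.png",
                           "width": spec.image_size_px[0],
                           "height": spec.image_size_px[1]}], instances)
        masks = read_instance_annotations(path)[1]
        assert len(masks) == gt.realized_count
        n_open_gt = sum(s.aperture_polygon is not None for s in gt.stomata)
        assert sum(m.aperture_polygon is not None for m in masks) == n_open_gt
        got = sorted(Polygon(m.complex_polygon).area for m in masks)
        want = sorted(Polygon(s.complex_polygon).area for s in gt.stomata)
        assert got == pytest.approx(want, rel=1e-3)

    def test_aperture_attached_by_containment(self, tmp_path):
        c1 = ellipse_polygon(20, 20, 10, 6)
        c2 = ellipse_polygon(60, 20, 10, 6)
        ap = ellipse_polygon(20, 20, 5, 1.5)
        path = tmp_path / "ann.json"
        write_coco(path, [{"id": 1, "file_name": "x", "width": 100, "height": 40}], [
            {"image_id": 1, "category": "stomatal_complex", "polygon": c1},
            {"image_id": 1, "category": "stomatal_complex", "polygon": c2},
            {"image_id": 1, "category": "aperture", "polygon": ap},
        ])
        masks = read_instance_annotations(path)[1]
        assert len(masks) == 2
        has_ap = [m.aperture_polygon is not None for m in masks]
        assert has_ap.count(True) == 1

    def test_orphan_aperture_rejected_with_id(self, tmp_path):
        path = tmp_path / "ann.json"
        write_coco(path, [{"id": 1, "file_name": "x", "width": 100, "height": 40}], [
            {"image_id": 1, "category": "stomatal_complex",
             "polygon": ellipse_polygon(20, 20, 10, 6)},
            {"image_id": 1, "category": "aperture",
             "polygon": ellipse_polygon(80, 20, 5, 1.5)},
        ])
        with pytest.raises(AnnotationError, match=r"\[2\]"):
            read_instance_annotations(path)

    def test_degenerate_polygon_rejected(self, tmp_path):
        import json
        doc = {
            "images": [], "categories": [
                {"id": 1, "name": "stomatal_complex"}, {"id": 2, "name": "aperture"}],
            "annotations": [{"id": 1, "image_id": 1, "category_id": 1,
                             "segmentation": [[0, 0, 1, 1]], "bbox": [0, 0, 1, 1]}],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(AnnotationError, match="3"):
            read_instance_annotations(path)

    def test_missing_category_map_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"images": [], "annotations": []}')
        with pytest.raises(AnnotationError, match="category"):
            read_instance_annotations(path)


class TestSummaries:
    def test_empty_image_summary(self, p400):
        s = summarize_image([], 0, p400, "img")
        assert s.stomata_count == 0
        assert s.density_mm2 == 0.0
        assert s.mean_complex_area_um2 is None
        assert s.fraction_open is None

    def test_density_from_measured_count(self, p400):
        recs = [measure(mask_from_polygons(i, ellipse_polygon(20, 20, 10, 6)), p400)
                for i in range(47)]
        s = summarize_image(recs, 47, p400)
        assert s.density_mm2 == pytest.approx(47 / 0.4275)
        assert s.fraction_open == 0.0

    def test_count_includes_failed_but_stats_exclude_them(self, p400):
        ok = measure(mask_from_polygons(0, ellipse_polygon(20, 20, 10, 6)), p400)
        bad = measure(StomaMask(1, None, status="failed"), p400)
        s = summarize_image([ok, bad], 2, p400)
        assert s.stomata_count == 2
        assert s.mean_complex_area_um2 == pytest.approx(ok.complex_area_um2)


def test_pipeline_traits_track_truth_on_clean_scene(clean_dicot_scene, p400):
    """Noise-free end-to-end: measured areas regress on truth ~1:1."""
    from stomakit.comparison import PairedMeasurements, fit_regression
    from stomakit.validation import detector_config_for

    _, image, gt = clean_dicot_scene
    boxes = sk.detect_classical(image, p400, detector_config_for("dicot"))
    records, _ = process_image(image, "img", p400, boxes)
    match = sk.match_detections([s.bbox for s in gt.stomata], boxes, 0.5)
    xs, ys = [], []
    for gi, pi, _ in match.pairs:
        rec = records[pi]
        if rec.status == "ok" and rec.complex_area_um2 is not None:
            xs.append(gt.stomata[gi].traits["complex_area_um2"])
            ys.append(rec.complex_area_um2)
    assert len(xs) >= 0.8 * gt.realized_count
    res = fit_regression(PairedMeasurements(
        tuple(map(str, range(len(xs)))), tuple(xs), tuple(ys)))
    assert 0.9 <= res.slope <= 1.1
    assert res.r2 >= 0.95
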