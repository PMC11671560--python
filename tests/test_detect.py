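"""Detectors and the nine-feature classification layer."""

import numpy as np
import pytest

from cle_afq import (
    Detection,
    FieldImage,
    SceneSpec,
    analyze_frame,
    classify_features,
    detect_cells,
    detect_diffuse,
    detect_fibers,
    detect_round,
    detect_spots,
    render_scene,
)
from cle_afq.benchmarks import match_detections, spot_recovery
from cle_afq.detect import DetectorParams
from cle_afq.frames import IMAGE_SHAPE, PIXEL_SIZE_UM
from cle_afq.simulate import NoiseParams


def _dets(cls, n):
    return [Detection(cls, 10.0, 10.0) for _ in range(n)]


class TestClassificationBoundaries:
    """The count thresholds are exact: <50/>=50 spots, <5/>=5 cells."""

    @pytest.mark.parametrize(
        "n,sparse,dense",
        [(0, False, False), (1, True, False), (49, True, False), (50, False, True),
         (120, False, True)],
    )
    def test_punctuate_thresholds(self, n, sparse, dense):
        fv = classify_features(_dets("spot", n))
        assert (fv.sparse_punctuate, fv.dense_punctuate) == (sparse, dense)

    @pytest.mark.parametrize("cls,flag", [("small_cell", "small_cells"),
                                          ("large_cell", "large_cells")])
    @pytest.mark.parametrize(
        "n,sparse,dense",
        [(0, False, False), (1, True, False), (4, True, False), (5, False, True)],
    )
    def test_cell_thresholds(self, cls, flag, n, sparse, dense):
        fv = classify_features(_dets(cls, n))
        assert getattr(fv, f"sparse_{flag}") is sparse
        assert getattr(fv, f"dense_{flag}") is dense

    def test_single_occurrence_flags(self):
        fv = classify_features(_dets("fiber", 1) + _dets("round", 1))
        assert fv.fibers and fv.round_structures

    def test_empty_frame_all_false(self):
        fv = classify_features([], (False, 0.0))
        assert not any(fv.flags().values())

    def test_sparse_and_dense_never_both(self):
        for n in range(0, 130):
            fv = classify_features(_dets("spot", n))
            assert not (fv.sparse_punctuate and fv.dense_punctuate)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            classify_features([Detection("vessel_like", 0, 0)])


def _textured_square_frame(d_um, amplitude=250.0, background=500.0, seed=0):
    """Noiseless frame with one textured square of exact equivalent diameter."""
    rng = np.random.default_rng(seed)
    px = np.full(IMAGE_SHAPE, background)
    side = int(round(np.sqrt(np.pi) * (d_um / 2.0) / PIXEL_SIZE_UM))
    r0, c0 = 400, 800
    texture = 1.0 + 0.3 * np.sign(rng.standard_normal((side, side)))
    px[r0 : r0 + side, c0 : c0 + side] += amplitude * texture
    img = FieldImage(pixels=px.astype(np.uint16))
    actual_d_um = 2.0 * np.sqrt(side * side / np.pi) * PIXEL_SIZE_UM
    return img, actual_d_um


class TestCellDetector:
    def test_six_small_cells_recovered(self):
        spec = SceneSpec(n_small_cells=6, small_cell_diameter_um=(15, 15), seed=31)
        img, gt = render_scene(spec, "BP", seed=31)
        dets = detect_cells(img)
        small = [d for d in dets if d.cls == "small_cell"]
        assert abs(len(small) - 6) <= 1
        assert len(small) >= 5

    def test_single_large_cell(self):
        spec = SceneSpec(n_large_cells=1, large_cell_diameter_um=(30, 30), seed=32)
        img, gt = render_scene(spec, "BP", seed=32)
        dets = detect_cells(img)
        assert [d.cls for d in dets] == ["large_cell"]

    @pytest.mark.parametrize(
        "d_um,expected",
        [(24.9, "small_cell"), (25.0, "large_cell"), (25.1, "large_cell"),
         (3.0, None), (3.1, "small_cell")],
    )
    def test_size_routing_boundaries_exact(self, d_um, expected):
        from cle_afq.detect import cell_size_class

        assert cell_size_class(d_um) == expected

    @pytest.mark.parametrize("d_um,expected", [(22.0, "small_cell"), (28.0, "large_cell")])
    def test_segmented_component_classified_by_measured_size(self, d_um, expected):
        img, actual = _textured_square_frame(d_um)
        dets = detect_cells(img)
        assert len(dets) == 1
        assert dets[0].cls == expected
        # the measured equivalent diameter tracks the planted one closely
        assert dets[0].equivalent_diameter_um == pytest.approx(actual, rel=0.08)


class TestFiberDetector:
    def test_length_within_20_percent(self):
        spec = SceneSpec(n_fibers=1, fiber_length_um=(100, 100),
                         fiber_width_um=(2, 2), seed=41)
        img, gt = render_scene(spec, "BP", seed=41)
        dets = detect_fibers(img)
        assert len(dets) == 1
        true_len = gt.of_class("fiber")[0].length_um
        assert dets[0].skeleton_length_um == pytest.approx(true_len, rel=0.20)

    def test_blank_frame_has_no_fibers(self, blank_frame):
        assert detect_fibers(blank_frame) == []

    def test_spots_only_frame_has_no_fibers(self):
        spec = SceneSpec(n_spots=30, seed=45)
        img, _ = render_scene(spec, "BP", seed=45)
        assert detect_fibers(img) == []


class TestRoundDetector:
    def test_weak_disk_detected_with_diameter(self):
        spec = SceneSpec(n_round=1, round_diameter_um=(40, 40), seed=35)
        img, gt = render_scene(spec, "BP", seed=35)
        dets = detect_round(img)
        assert len(dets) == 1
        assert dets[0].equivalent_diameter_um == pytest.approx(40.0, rel=0.10)

    def test_disk_below_10_um_not_reported(self):
        # hand-drawn 5 µm weak homogeneous disk
        px = np.full(IMAGE_SHAPE, 500.0)
        rr, cc = np.ogrid[:IMAGE_SHAPE[0], :IMAGE_SHAPE[1]]
        dist = np.hypot(rr - 500, cc - 900)
        px[dist <= 2.5 / PIXEL_SIZE_UM] += 90.0
        img = FieldImage(pixels=px.astype(np.uint16))
        assert detect_round(img) == []

    def test_blank_frame_none(self, blank_frame):
        assert detect_round(blank_frame) == []


class TestDiffuseDetector:
    def test_strong_diffuse_covers_fov(self):
        spec = SceneSpec(diffuse_level=95.0, seed=51)  # ~3x the noise s.d.
        img, _ = render_scene(spec, "BP", seed=51)
        flag, coverage = detect_diffuse(img)
        assert flag
        assert coverage >= 0.9

    def test_baseline_frame_clean(self, blank_frame):
        flag, coverage = detect_diffuse(blank_frame)
        assert not flag
        assert coverage <= 0.05

    def test_discrete_objects_masked_out(self):
        spec = SceneSpec(n_spots=30, seed=53)
        img, _ = render_scene(spec, "BP", seed=53)
        flag, _ = detect_diffuse(img)
        assert not flag


class TestSpotDetector:
    def test_recall_precision_on_planted_spots(self, spots_frame):
        img, gt = spots_frame
        dets = detect_spots(img)
        tp, nd, ng = match_detections(dets, gt, "spot", tol_um=1.0)
        assert tp / ng >= 0.9
        assert tp / nd >= 0.9

    def test_false_detections_rare_on_blanks(self):
        fps = []
        for seed in range(100, 120):
            img, _ = render_scene(SceneSpec(seed=seed), "BP", seed=seed)
            fps.append(len(detect_spots(img)))
        assert np.mean(fps) <= 1.0

    def test_noiseless_centroid_within_one_pixel(self):
        spec = SceneSpec(n_spots=1, spot_diameter_um=(2.0, 2.0),
                         noise=NoiseParams(0.0, 0.0), seed=21)
        img, gt = render_scene(spec, "BP", seed=21)
        dets = detect_spots(img)
        assert len(dets) == 1
        o = gt.of_class("spot")[0]
        err_px = np.hypot(dets[0].x_um - o.x_um, dets[0].y_um - o.y_um) / PIXEL_SIZE_UM
        assert err_px <= 1.0

    def test_monotone_in_planted_count_noiseless(self):
        detected = []
        for n in (0, 5, 10, 20, 40):
            spec = SceneSpec(n_spots=n, noise=NoiseParams(0.0, 0.0), seed=33)
            img, _ = render_scene(spec, "BP", seed=33)
            detected.append(len(detect_spots(img)))
        assert detected == sorted(detected)


class TestAnalyzeFrame:
    def test_mixed_frame_recovery(self, mixed_frame):
        img, gt = mixed_frame
        dets, fv = analyze_frame(img)
        expected = gt.counts()
        assert abs(fv.n_spots - expected["spot"]) <= 3
        assert abs(fv.n_small_cells - expected["small_cell"]) <= 1
        assert fv.n_large_cells == expected["large_cell"]
        assert fv.n_fibers >= 1
        assert fv.n_round >= 2
        assert fv.diffuse == gt.diffuse

    def test_each_detection_has_one_class(self, mixed_frame):
        dets, fv = analyze_frame(mixed_frame[0])
        total = fv.n_spots + fv.n_small_cells + fv.n_large_cells + fv.n_fibers + fv.n_round
        assert total == len(dets)

    def test_detector_params_yaml_round_trip(self, tmp_path):
        p = DetectorParams(spot_log_threshold=2.0, round_cv_ceiling=0.2)
        p.to_yaml(tmp_path / "det.yaml")
        assert DetectorParams.from_yaml(tmp_path / "det.yaml") == p


def test_spot_recovery_benchmark_interface():
    res = spot_recovery(n_frames=2, seed=7)
    assert res["recall"] >= 0.9
    assert res["precision"] >= 0.9
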