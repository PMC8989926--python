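import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uslesion import (BBox, PipelineConfig, box_jaccard, enclosing_box,
                      intersection_box, mask_to_bbox)
from uslesion.io import (DetectionRecord, read_detections, read_image,
                         write_detections, write_detections_csv)

from conftest import random_box
from oracles import pixel_set_jaccard


class TestBBox:
    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            BBox(0, 0, 0, 5)
        with pytest.raises(ValueError):
            BBox(0, 0, 5, -1)
        with pytest.raises(ValueError):
            BBox(0, 0, 5, 5, confidence=1.5)

    def test_half_open_geometry(self):
        b = BBox(3, 2, 5, 4)
        assert b.area == 20
        assert b.center == (5.5, 4.0)
        assert (b.x2, b.y2) == (8, 6)


class TestMaskToBBox:
    def test_tight_box_around_foreground(self):
        mask = np.zeros((10, 12), dtype=bool)
        mask[2:6, 3:8] = True  # rows 2..5, cols 3..7
        assert mask_to_bbox(mask) == BBox(3, 2, 5, 4)

    def test_full_mask_gives_whole_frame(self):
        assert mask_to_bbox(np.ones((6, 9), dtype=bool)) == BBox(0, 0, 9, 6)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="no lesion"):
            mask_to_bbox(np.zeros((5, 5), dtype=bool))

    def test_rasterized_box_round_trips(self, rng):
        for _ in range(50):
            box = random_box(rng)
            mask = np.zeros((64, 64), dtype=bool)
            mask[int(box.y):int(box.y2), int(box.x):int(box.x2)] = True
            assert mask_to_bbox(mask) == box


class TestBoxJaccard:
    def test_identity_and_disjoint(self):
        a = BBox(0, 0, 10, 10)
        assert box_jaccard(a, a) == 1.0
        assert box_jaccard(a, BBox(20, 20, 5, 5)) == 0.0

    def test_half_shift_worked_value(self):
        # intersection 50, union 150
        assert box_jaccard(BBox(0, 0, 10, 10), BBox(5, 0, 10, 10)) == pytest.approx(1 / 3)

    def test_matches_pixel_set_oracle(self, rng):
        """Continuous-area Jaccard equals the rasterized pixel-set value for
        1000 random integer box pairs in a 64x64 grid."""
        for _ in range(1000):
            a, b = random_box(rng), random_box(rng)
            assert box_jaccard(a, b) == pytest.approx(
                pixel_set_jaccard(a, b), abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_symmetry_range_and_identity(self, data):
        def box(tag):
            x = data.draw(st.floats(0, 40), label=f"x{tag}")
            y = data.draw(st.floats(0, 40), label=f"y{tag}")
            w = data.draw(st.floats(0.5, 30), label=f"w{tag}")
            h = data.draw(st.floats(0.5, 30), label=f"h{tag}")
            return BBox(x, y, w, h)

        a, b = box("a"), box("b")
        j = box_jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == box_jaccard(b, a)
        assert (j == 1.0) == ((a.x, a.y, a.w, a.h) == (b.x, b.y, b.w, b.h))


class TestBoxOps:
    def test_intersection_and_enclosure(self):
        a, b = BBox(0, 0, 10, 10), BBox(5, 5, 10, 10)
        inter = intersection_box(a, b)
        assert (inter.x, inter.y, inter.w, inter.h) == (5, 5, 5, 5)
        enc = enclosing_box(a, b)
        assert (enc.x, enc.y, enc.w, enc.h) == (0, 0, 15, 15)
        assert intersection_box(a, BBox(30, 30, 2, 2)) is None


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"clip_fraction": 0.0},
        {"background_jaccard": 0.6},       # violates ordering with cluster 0.5
        {"total_steps": 0},
        {"canny_low": 0.5, "canny_high": 0.2},
    ])
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            PipelineConfig(**kwargs)

    def test_dict_round_trip(self):
        cfg = PipelineConfig(total_steps=6)
        assert PipelineConfig.from_dict(cfg.to_dict()) == cfg


class TestDetectionIO:
    def test_round_trip(self, tmp_path):
        recs = [DetectionRecord.from_box("img1", BBox(1, 2, 3, 4, confidence=0.9)),
                DetectionRecord.from_box("img2", BBox(0.5, 1.5, 2.5, 3.5))]
        path = tmp_path / "det.json"
        write_detections(recs, path)
        back = read_detections(path)
        assert back == recs
        assert back[0].to_box() == BBox(1, 2, 3, 4, confidence=0.9)

    def test_empty_list_round_trips(self, tmp_path):
        path = tmp_path / "empty.json"
        write_detections([], path)
        assert read_detections(path) == []

    def test_nonpositive_width_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('[{"image_id": "a", "x": 0, "y": 0, "w": 0, "h": 5}]')
        with pytest.raises(ValueError, match="positive"):
            read_detections(path)

    def test_missing_file_and_malformed(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_detections(tmp_path / "nope.json")
        bad = tmp_path / "notalist.json"
        bad.write_text('{"image_id": "a"}')
        with pytest.raises(ValueError):
            read_detections(bad)

    def test_csv_export(self, tmp_path):
        recs = [DetectionRecord.from_box("img1", BBox(1, 2, 3, 4, confidence=0.5))]
        path = tmp_path / "det.csv"
        write_detections_csv(recs, path)
        text = path.read_text()
        assert text.splitlines()[0] == "image_id,x,y,w,h,confidence"

    def test_read_image_missing(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "nope.png")
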