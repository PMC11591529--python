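import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrseg.doppler_io import (
    load_mask,
    preprocess,
    rasterize_labelme,
    save_mask,
    save_split,
    stratified_split,
)
from oracles import rasterize_scan


def shapes_doc(shapes):
    return {"shapes": shapes}


class TestRasterize:
    def test_empty_document_gives_all_background(self):
        mask = rasterize_labelme(shapes_doc([]), 30, 30)
        assert mask.shape == (30, 30)
        assert (mask == 0).all()

    def test_la_square_pixel_count(self):
        # square spanning pixel centers (10..19) x (10..19)
        poly = [[10, 10], [20, 10], [20, 20], [10, 20]]
        mask = rasterize_labelme(shapes_doc([{"label": "LA", "points": poly}]), 30, 30)
        assert (mask == 2).sum() == 100
        assert (mask == 1).sum() == 0

    def test_mr_overrides_la_on_overlap(self):
        la = [[0, 0], [10, 0], [10, 10], [0, 10]]
        mr = [[0, 0], [5, 0], [5, 5], [0, 5]]
        mask = rasterize_labelme(
            shapes_doc(
                [{"label": "LA", "points": la}, {"label": "MR", "points": mr}]
            ),
            10,
            10,
        )
        assert (mask == 1).sum() == 25
        assert (mask == 2).sum() == 75

    def test_unknown_label_is_an_error_naming_the_label(self):
        doc = shapes_doc([{"label": "RV", "points": [[0, 0], [1, 0], [1, 1]]}])
        with pytest.raises(ValueError, match="RV"):
            rasterize_labelme(doc, 5, 5)

    def test_degenerate_polygon_is_an_error(self):
        doc = shapes_doc([{"label": "MR", "points": [[0, 0], [3, 3]]}])
        with pytest.raises(ValueError, match="3 vertices"):
            rasterize_labelme(doc, 5, 5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_point_in_polygon_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h, w = int(rng.integers(8, 33)), int(rng.integers(8, 33))
        shapes = []
        for label in rng.choice(["MR", "LA"], size=rng.integers(1, 4)):
            n = int(rng.integers(3, 8))
            pts = np.stack(
                [rng.uniform(0, w - 1e-6, n), rng.uniform(0, h - 1e-6, n)], axis=1
            )
            shapes.append({"label": str(label), "points": pts.tolist()})
        got = rasterize_labelme(shapes_doc(shapes), h, w)
        expected = rasterize_scan(shapes, h, w)
        assert (got == expected).all()


class TestPreprocess:
    def test_identity_crop_is_identity(self, rng):
        img = rng.integers(0, 256, size=(600, 800, 3), dtype=np.uint8)
        out = preprocess(img, (0, 0, 600, 800))
        assert (out == img).all()

    def test_downscale_to_target_size(self, rng):
        img = rng.integers(0, 256, size=(1200, 1600, 3), dtype=np.uint8)
        out = preprocess(img, (0, 0, 1200, 1600))
        assert out.shape == (600, 800, 3)

    def test_mask_resampling_introduces_no_new_labels(self, rng):
        img = rng.integers(0, 256, size=(300, 400, 3), dtype=np.uint8)
        mask = rng.choice([0, 2], size=(300, 400)).astype(np.int64)
        _, mout = preprocess(img, (10, 10, 280, 380), mask)
        assert set(np.unique(mout)) <= {0, 2}
        assert mout.shape == (600, 800)

    def test_roi_outside_bounds_is_an_error(self, rng):
        img = rng.integers(0, 256, size=(100, 100, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="roi"):
            preprocess(img, (50, 50, 100, 100))

    def test_idempotent_under_identity_roi(self, rng):
        img = rng.integers(0, 256, size=(600, 800, 3), dtype=np.uint8)
        once = preprocess(img, (0, 0, 600, 800))
        twice = preprocess(once, (0, 0, 600, 800))
        assert (once == twice).all()


class TestStratifiedSplit:
    def test_study_cohort_counts(self):
        # 8:2 split of the 100/137/130 grade cohort
        split = stratified_split(
            {"mild": 100, "moderate": 137, "severe": 130}, 0.8, seed=0
        )
        assert split.per_class_counts == {
            "mild": (80, 20),
            "moderate": (109, 28),
            "severe": (104, 26),
        }
        assert len(split.train_items) == 293
        assert len(split.test_items) == 74

    @pytest.mark.parametrize(
        "counts,frac,expected",
        [
            ({"a": 10}, 0.5, {"a": (5, 5)}),
            ({"a": 7, "b": 3}, 0.8, {"a": (5, 2), "b": (2, 1)}),
        ],
    )
    def test_floor_rule(self, counts, frac, expected):
        split = stratified_split(counts, frac, seed=3)
        assert split.per_class_counts == expected

    def test_deterministic_and_partitions_exactly(self):
        counts = {"mild": 13, "moderate": 9, "severe": 21}
        a = stratified_split(counts, 0.8, seed=42)
        b = stratified_split(counts, 0.8, seed=42)
        assert a.train_items == b.train_items and a.test_items == b.test_items
        union = set(a.train_items) | set(a.test_items)
        assert not (set(a.train_items) & set(a.test_items))
        assert len(union) == sum(counts.values())

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError, match="no cases"):
            stratified_split({"a": 5, "b": 0}, 0.8, seed=0)

    def test_manifest_round_trip(self, tmp_path):
        split = stratified_split({"a": 5, "b": 4}, 0.8, seed=7)
        save_split(tmp_path / "split.json", split)
        doc = json.loads((tmp_path / "split.json").read_text())
        assert doc["seed"] == 7
        assert sorted(doc["train"] + doc["test"]) == sorted(
            split.train_items + split.test_items
        )


class TestMaskRoundTrip:
    def test_paletted_png_is_lossless(self, tmp_path, rng):
        mask = rng.choice([0, 1, 2], size=(40, 50)).astype(np.int64)
        save_mask(tmp_path / "m.png", mask)
        assert (load_mask(tmp_path / "m.png") == mask).all()
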