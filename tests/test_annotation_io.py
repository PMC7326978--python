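from __future__ import annotations

import json

import numpy as np
import pytest

from berrypheno.annotation_io import (
    AnnotatedRegion,
    DetectionInstance,
    diff_corrections,
    polygon_from_mask,
    read_detections,
    read_ground_truth,
    read_via,
    write_detections,
    write_via,
)
from berrypheno.geometry import PolygonOutline
from berrypheno.validation import load_schema, validate

from conftest import disk_mask


def _via_project(flat=True):
    entry = {
        "filename": "branch01.png",
        "size": -1,
        "file_attributes": {},
        "regions": [
            {
                "shape_attributes": {
                    "name": "polygon",
                    "all_points_x": [10, 30, 30, 10],
                    "all_points_y": [10, 10, 30, 30],
                },
                "region_attributes": {"maturity": "Mature"},
            },
            {
                "shape_attributes": {
                    "name": "polygon",
                    "all_points_x": [40, 60, 50],
                    "all_points_y": [40, 40, 60],
                },
                "region_attributes": {"maturity": "immature"},
            },
        ],
    }
    project = {"branch01.png-1": entry}
    if flat:
        return json.dumps(project)
    return json.dumps({"_via_img_metadata": project, "_via_settings": {}})


@pytest.mark.parametrize("flat", [True, False], ids=["flat", "img_metadata"])
def test_read_via_both_dialects(flat):
    regions = read_via(_via_project(flat=flat))
    assert len(regions) == 2
    assert {r.label for r in regions} == {"mature", "immature"}  # case-normalized
    assert all(r.image_id == "branch01.png" for r in regions)


def test_read_via_skips_non_polygon_with_warning():
    data = json.loads(_via_project())
    data["branch01.png-1"]["regions"].append(
        {
            "shape_attributes": {"name": "rect", "x": 1, "y": 1, "width": 5, "height": 5},
            "region_attributes": {"maturity": "mature"},
        }
    )
    with pytest.warns(UserWarning, match="non-polygon"):
        regions = read_via(json.dumps(data))
    assert len(regions) == 2


def test_read_via_skips_unknown_label_with_warning():
    data = json.loads(_via_project())
    data["branch01.png-1"]["regions"][0]["region_attributes"]["maturity"] = "ripe-ish"
    with pytest.warns(UserWarning, match="unknown label"):
        regions = read_via(json.dumps(data))
    assert len(regions) == 1


def test_read_via_rejects_malformed_json():
    with pytest.raises(json.JSONDecodeError):
        read_via("{not json")
    with pytest.raises(ValueError):
        read_via(json.dumps({"some": "dict"}))


def test_via_round_trip_is_identity():
    regions = read_via(_via_project())
    again = read_via(write_via(regions))
    assert sorted(again, key=lambda r: r.label) == sorted(regions, key=lambda r: r.label)
    # a second write/read cycle is stable too
    assert read_via(write_via(again)) == again


def test_write_via_empty_project_is_valid():
    assert read_via(write_via([])) == []


def test_detection_json_round_trip_and_schema():
    instances = [
        DetectionInstance(
            image_id="a.png",
            label="mature",
            score=0.9,
            polygon=PolygonOutline([(1.0, 1.0), (9.0, 1.0), (9.0, 9.0), (1.0, 9.0)]),
        ),
        DetectionInstance(
            image_id="a.png",
            label="immature",
            polygon=PolygonOutline([(12.0, 2.0), (20.0, 4.0), (15.0, 12.0)]),
        ),
    ]
    text = write_detections(instances)
    validate(json.loads(text), load_schema("detections"))
    again = read_detections(text)
    assert len(again) == 2
    for orig, back in zip(instances, again):
        assert back.image_id == orig.image_id
        assert back.label == orig.label
        assert back.score == orig.score
        assert np.allclose(back.polygon.vertices, orig.polygon.vertices)
    assert write_detections(again) == text


def test_polygon_from_mask_covers_the_blob():
    mask = disk_mask((60, 60), 30, 30, 10)
    poly = polygon_from_mask(mask)
    # the traced contour area should be close to the raster area
    assert poly.area == pytest.approx(mask.area, rel=0.05)


def test_detection_instance_validation():
    with pytest.raises(ValueError):
        DetectionInstance(image_id="a", label="rotten", mask=disk_mask((10, 10), 5, 5, 2))
    with pytest.raises(ValueError):
        DetectionInstance(image_id="a", label="mature")  # no geometry
    with pytest.raises(ValueError):
        DetectionInstance(
            image_id="a", label="mature", score=1.5, mask=disk_mask((10, 10), 5, 5, 2)
        )


def test_read_ground_truth_checks_columns(tmp_path):
    good = tmp_path / "gt.csv"
    good.write_text("sample_id,cultivar,view,image,N_t,N_c\ns1,Star,0,a.png,12,3\n")
    df = read_ground_truth(good)
    assert df.loc[0, "N_t"] == 12
    bad = tmp_path / "bad.csv"
    bad.write_text("sample,count\ns1,12\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_ground_truth(bad)


class TestDiffCorrections:
    @staticmethod
    def _regions():
        sq1 = PolygonOutline([(0, 0), (10, 0), (10, 10), (0, 10)])
        sq2 = PolygonOutline([(20, 20), (30, 20), (30, 30), (20, 30)])
        return [
            AnnotatedRegion("img", sq1, "mature"),
            AnnotatedRegion("img", sq2, "immature"),
        ]

    def test_identity_all_unchanged(self):
        regs = self._regions()
        report = diff_corrections(regs, regs)
        assert report.unchanged == 2
        assert report.added == report.removed == report.relabeled == report.reshaped == 0

    def test_added_region(self):
        regs = self._regions()
        extra = AnnotatedRegion(
            "img", PolygonOutline([(50, 50), (60, 50), (60, 60), (50, 60)]), "mature"
        )
        report = diff_corrections(regs, regs + [extra])
        assert report.added == 1 and report.unchanged == 2

    def test_relabeled_region(self):
        regs = self._regions()
        flipped = [AnnotatedRegion(r.image_id, r.outline, "mature") for r in regs]
        report = diff_corrections(regs, flipped)
        assert report.relabeled == 1 and report.unchanged == 1

    def test_reshaped_region(self):
        regs = self._regions()
        shrunk = PolygonOutline([(0, 0), (8, 0), (8, 10), (0, 10)])  # IOU 0.8
        corrected = [AnnotatedRegion("img", shrunk, "mature"), regs[1]]
        report = diff_corrections(regs, corrected, reshape_iou=0.95)
        assert report.reshaped == 1 and report.unchanged == 1

    def test_swap_antisymmetry(self):
        regs = self._regions()
        extra = AnnotatedRegion(
            "img", PolygonOutline([(50, 50), (60, 50), (60, 60), (50, 60)]), "mature"
        )
        fwd = diff_corrections(regs, regs + [extra])
        rev = diff_corrections(regs + [extra], regs)
        assert fwd.added == rev.removed == 1
        assert fwd.removed == rev.added == 0

    def test_accounts_for_every_region(self):
        regs = self._regions()
        corrected = regs[:1]
        report = diff_corrections(regs, corrected)
        assert report.total_events == 2  # one unchanged pair + one removed

    def test_rejects_bad_threshold(self):
        with pytest.raises(ValueError):
            diff_corrections([], [], iou_match_threshold=0.0)
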