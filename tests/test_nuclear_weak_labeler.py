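import numpy as np
import pytest

from conftest import raster8
from mxifseg.nuclear_weak_labeler import (
    BACKGROUND,
    BOUNDARY,
    INTERIOR,
    EditOverlay,
    NuclearSegResult,
    apply_edit_overlay,
    distance_seeds,
    instances_to_three_class,
    otsu_threshold,
    rgb_to_three_class,
    seeded_watershed,
    segment_nuclei_classic,
    three_class_to_instances,
    three_class_to_rgb,
)
from mxifseg.raster_core import convert_16_to_8
from oracles import otsu_brute_force, watershed_priority_flood


class TestOtsu:
    def test_bimodal_split(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        thr, degenerate = otsu_threshold(raster8(img))
        assert not degenerate
        assert thr == otsu_brute_force(img)
        assert 0 <= thr < 255  # separates the populations: 0s below, 255s above

    def test_constant_image_degenerate(self):
        with pytest.warns(UserWarning):
            thr, degenerate = otsu_threshold(raster8(np.full((5, 5), 77)))
        assert degenerate and thr == 77

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_oracle(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (20, 20)).astype(np.uint8)
        thr, _ = otsu_threshold(raster8(img))
        assert thr == otsu_brute_force(img)


class TestDistanceSeeds:
    def test_single_disk_center(self):
        rr, cc = np.mgrid[0:21, 0:21]
        disk = (rr - 10) ** 2 + (cc - 10) ** 2 <= 36
        markers = distance_seeds(disk)
        coords = np.argwhere(markers > 0)
        assert len(coords) == 1
        assert tuple(coords[0]) == (10, 10)

    def test_two_disjoint_disks(self):
        rr, cc = np.mgrid[0:20, 0:40]
        m = ((rr - 10) ** 2 + (cc - 8) ** 2 <= 16) | ((rr - 10) ** 2 + (cc - 30) ** 2 <= 16)
        markers = distance_seeds(m)
        assert len(np.unique(markers[markers > 0])) == 2

    def test_empty_mask(self):
        assert (distance_seeds(np.zeros((5, 5), dtype=bool)) == 0).all()

    def test_markers_inside_foreground(self, rng):
        mask = rng.random((30, 30)) > 0.4
        markers = distance_seeds(mask)
        assert ((markers > 0) & ~mask).sum() == 0


class TestSeededWatershed:
    def test_one_marker_flat_fills_mask(self):
        markers = np.zeros((5, 5), dtype=int)
        markers[2, 2] = 1
        mask = np.ones((5, 5), dtype=bool)
        mask[0, 0] = False
        out = seeded_watershed(np.zeros((5, 5)), markers, mask)
        assert (out[mask] == 1).all() and out[0, 0] == 0

    def test_flat_ridge_tie_break(self):
        # two markers on a flat 1x5 row: the equidistant column floods from
        # the lexicographically earlier side
        elev = np.zeros((1, 5))
        markers = np.zeros((1, 5), dtype=int)
        markers[0, 0], markers[0, 4] = 1, 2
        out = seeded_watershed(elev, markers)
        assert out.tolist() == [[1, 1, 1, 2, 2]]

    def test_no_markers_all_background(self):
        out = seeded_watershed(np.zeros((4, 4)), np.zeros((4, 4), dtype=int))
        assert (out == 0).all()

    def test_marker_outside_mask_rejected(self):
        markers = np.zeros((3, 3), dtype=int)
        markers[0, 0] = 1
        with pytest.raises(ValueError):
            seeded_watershed(np.zeros((3, 3)), markers, np.zeros((3, 3), dtype=bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_priority_flood_oracle(self, seed):
        rng = np.random.default_rng(seed)
        elev = rng.integers(0, 50, (32, 32)).astype(float)
        markers = np.zeros((32, 32), dtype=int)
        for lab in range(1, 4):
            r, c = rng.integers(0, 32, 2)
            markers[r, c] = lab
        assert np.array_equal(
            seeded_watershed(elev, markers), watershed_priority_flood(elev, markers)
        )

    def test_labels_subset_and_coverage(self, rng):
        elev = rng.integers(0, 30, (20, 20)).astype(float)
        mask = rng.random((20, 20)) > 0.3
        markers = np.zeros((20, 20), dtype=int)
        placed = []
        for lab in (1, 2, 5):
            pts = np.argwhere(mask)
            r, c = pts[rng.integers(0, len(pts))]
            markers[r, c] = lab
            placed.append(lab)
        out = seeded_watershed(elev, markers, mask)
        labs = set(np.unique(out[out > 0]).tolist())
        assert labs <= set(placed)
        # every masked pixel reachable from a marker is labeled
        from scipy import ndimage as ndi

        comp, _ = ndi.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        reachable = np.isin(comp, np.unique(comp[markers > 0]))
        assert (out[mask & reachable] > 0).all()
        # each region is connected and contains its marker
        from scipy import ndimage as ndi

        for lab in labs:
            comp, n = ndi.label(out == lab, structure=np.array(
                [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
            assert n == 1
            assert (markers == lab)[out == lab].any()


class TestThreeClassEncoding:
    def test_empty_map(self):
        assert (instances_to_three_class(np.zeros((4, 4), dtype=int)) == BACKGROUND).all()

    def test_single_3x3_square(self):
        inst = np.zeros((5, 5), dtype=int)
        inst[1:4, 1:4] = 1
        tc = instances_to_three_class(inst)
        assert (tc == BOUNDARY).sum() == 8
        assert (tc == INTERIOR).sum() == 1
        assert tc[2, 2] == INTERIOR

    def test_touching_squares_boundary_both_sides(self):
        inst = np.zeros((6, 8), dtype=int)
        inst[1:5, 1:4] = 1
        inst[1:5, 4:7] = 2
        tc = instances_to_three_class(inst)
        assert (tc[1:5, 3] == BOUNDARY).all()  # right edge of object 1
        assert (tc[1:5, 4] == BOUNDARY).all()  # left edge of object 2

    def test_round_trip_identity_on_separated_objects(self):
        inst = np.zeros((12, 12), dtype=int)
        inst[1:4, 1:4] = 1
        inst[6:11, 6:11] = 2
        back, report = three_class_to_instances(instances_to_three_class(inst))
        assert np.array_equal(back > 0, inst > 0)
        # same partition up to label names
        for oid in (1, 2):
            vals = np.unique(back[inst == oid])
            assert len(vals) == 1
        assert report["dropped_boundary_pixels"] == 0

    def test_all_background_decodes_empty(self):
        inst, report = three_class_to_instances(np.zeros((4, 4), dtype=np.uint8))
        assert (inst == 0).all() and report["n_objects"] == 0

    def test_lone_boundary_ring_dropped(self):
        tc = np.zeros((5, 5), dtype=np.uint8)
        tc[1:4, 1:4] = BOUNDARY
        tc[2, 2] = BOUNDARY  # no interior at all
        inst, report = three_class_to_instances(tc)
        assert (inst == 0).all()
        assert report["dropped_boundary_pixels"] == 9

    def test_rgb_round_trip(self):
        tc = np.array([[BACKGROUND, INTERIOR], [BOUNDARY, BACKGROUND]], dtype=np.uint8)
        assert np.array_equal(rgb_to_three_class(three_class_to_rgb(tc)), tc)


def _result_from_instances(inst):
    return NuclearSegResult(instances=inst, three_class=instances_to_three_class(inst))


class TestEditOverlay:
    def test_empty_overlay_identity(self):
        inst = np.zeros((6, 6), dtype=int)
        inst[1:5, 1:5] = 1
        res = _result_from_instances(inst)
        out, stats = apply_edit_overlay(res, EditOverlay())
        assert out is res
        assert stats["removed_objects"] == 0

    def test_split_line_bisects_object(self):
        inst = np.zeros((9, 9), dtype=int)
        inst[1:8, 1:8] = 1
        res = _result_from_instances(inst)
        overlay = EditOverlay(split_lines=[[(0, 4), (8, 4)]])
        out, _ = apply_edit_overlay(res, overlay)
        assert out.n_objects == 2

    def test_removal_contour_deletes_one_of_two(self):
        inst = np.zeros((10, 16), dtype=int)
        inst[2:7, 2:7] = 1
        inst[2:7, 9:14] = 2
        res = _result_from_instances(inst)
        contour = [(1, 8), (1, 15), (8, 15), (8, 8)]
        out, stats = apply_edit_overlay(res, EditOverlay(removal_contours=[contour]))
        assert out.n_objects == 1
        assert stats["removed_objects"] == 1
        assert (out.instances[2:7, 2:7] > 0).all()

    def test_edit_does_not_touch_pixels_far_from_edits(self):
        inst = np.zeros((20, 20), dtype=int)
        inst[2:6, 2:6] = 1
        inst[12:18, 12:18] = 2
        res = _result_from_instances(inst)
        overlay = EditOverlay(split_lines=[[(11, 15), (19, 15)]])
        out, _ = apply_edit_overlay(res, overlay)
        # object 1 untouched up to relabeling
        assert np.array_equal(out.instances[2:6, 2:6] > 0, inst[2:6, 2:6] > 0)
        labs = np.unique(out.instances[2:6, 2:6])
        assert len(labs) == 1

    def test_out_of_bounds_rejected(self):
        res = _result_from_instances(np.ones((4, 4), dtype=int))
        with pytest.raises(ValueError):
            apply_edit_overlay(res, EditOverlay(split_lines=[[(0, 0), (9, 9)]]))

    def test_json_round_trip(self, tmp_path):
        overlay = EditOverlay(
            split_lines=[[(1, 2), (3, 4)]], removal_contours=[[(0, 0), (0, 3), (3, 3)]]
        )
        overlay.save(tmp_path / "edits.json")
        back = EditOverlay.load(tmp_path / "edits.json")
        assert back.split_lines == overlay.split_lines
        assert back.removal_contours == overlay.removal_contours


class TestSegmentNucleiClassic:
    def test_blank_image_empty_result(self):
        with pytest.warns(UserWarning):
            res = segment_nuclei_classic(raster8(np.zeros((32, 32))))
        assert res.n_objects == 0

    def test_well_separated_blobs_counted(self, packed_roi):
        d8 = convert_16_to_8(packed_roi.dapi)
        res = segment_nuclei_classic(d8)
        n_gt = len(np.unique(packed_roi.gt_nuclei[packed_roi.gt_nuclei > 0]))
        assert res.n_objects == n_gt

    def test_two_overlapping_blobs_split(self):
        # two blobs with distinct distance maxima merged into one foreground
        img = np.zeros((30, 40), dtype=np.uint8)
        rr, cc = np.mgrid[0:30, 0:40]
        img[((rr - 15) ** 2 + (cc - 12) ** 2 <= 64)] = 200
        img[((rr - 15) ** 2 + (cc - 26) ** 2 <= 64)] = 200
        res = segment_nuclei_classic(raster8(img))
        assert res.n_objects == 2
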