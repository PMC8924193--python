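import numpy as np
import pytest

from mxifseg.eval_metrics import (
    ObjectMetricReport,
    boundary_points,
    dice,
    evaluate_rois,
    hausdorff,
    match_objects,
    object_dice,
    object_hausdorff,
    pairwise_agreement,
)
from oracles import (
    boundary_brute_force,
    dice_brute_force,
    hausdorff_brute_force,
    object_dice_brute_force,
    object_hausdorff_brute_force,
    random_instance_map,
)


class TestDice:
    def test_identical(self):
        m = np.eye(4, dtype=bool)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        # two 2x2 squares overlapping in 2 px: 2*2/(4+4) = 0.5
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0:2, 0:2] = True
        b[1:3, 0:2] = True
        assert dice(a, b) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3), dtype=bool)
        assert dice(z, z) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        assert dice(a, b) == pytest.approx(dice_brute_force(a, b))


class TestHausdorff:
    def test_identical_sets(self):
        pts = np.array([[0, 0], [1, 2]])
        assert hausdorff(pts, pts) == 0.0

    def test_three_four_five(self):
        assert hausdorff(np.array([[0, 0]]), np.array([[3, 4]])) == 5.0

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            hausdorff(np.empty((0, 2)), np.array([[0, 0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 20, (6, 2))
        b = rng.integers(0, 20, (4, 2))
        assert hausdorff(a, b) == pytest.approx(hausdorff_brute_force(a, b))

    @pytest.mark.parametrize("seed", range(3))
    def test_boundary_extraction_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((10, 10)) > 0.6
        got = {tuple(p) for p in boundary_points(mask)}
        exp = {tuple(int(v) for v in p) for p in boundary_brute_force(mask)}
        assert got == exp


class TestMatchObjects:
    def test_identity_matching(self):
        m = random_instance_map(np.random.default_rng(0))
        s2g, g2s, flagged = match_objects(m, m)
        assert not flagged
        assert all(bid == aid and ov for aid, (bid, ov) in s2g.items())

    def test_majority_overlap_wins(self):
        seg = np.zeros((6, 10), dtype=int)
        seg[1:5, 1:9] = 1  # spans both reference objects
        ref = np.zeros((6, 10), dtype=int)
        ref[1:5, 1:6] = 1  # ~60%
        ref[1:5, 6:9] = 2  # ~40%
        s2g, _, _ = match_objects(seg, ref)
        assert s2g[1] == (1, True)

    def test_zero_overlap_falls_back_to_nearest_boundary(self):
        seg = np.zeros((10, 10), dtype=int)
        seg[0:2, 0:2] = 1
        ref = np.zeros((10, 10), dtype=int)
        ref[3:5, 3:5] = 1  # near
        ref[8:10, 8:10] = 2  # far
        s2g, _, _ = match_objects(seg, ref)
        assert s2g[1] == (1, False)

    def test_empty_side_flagged(self):
        empty = np.zeros((4, 4), dtype=int)
        m = np.ones((4, 4), dtype=int)
        _, _, flagged = match_objects(empty, m)
        assert flagged


class TestObjectDice:
    def test_self_is_one(self):
        for seed in range(5):
            m = random_instance_map(np.random.default_rng(seed))
            assert object_dice(m, m) == pytest.approx(1.0)

    def test_empty_vs_empty(self):
        z = np.zeros((4, 4), dtype=int)
        assert object_dice(z, z) == 1.0

    def test_empty_vs_nonempty(self):
        z = np.zeros((4, 4), dtype=int)
        m = np.ones((4, 4), dtype=int)
        assert object_dice(z, m) == 0.0

    def test_split_object_matches_oracle(self):
        seg = np.zeros((6, 8), dtype=int)
        seg[1:5, 1:7] = 1
        ref = np.zeros((6, 8), dtype=int)
        ref[1:5, 1:4] = 1
        ref[1:5, 4:7] = 2
        assert object_dice(seg, ref) == pytest.approx(object_dice_brute_force(seg, ref))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            s = random_instance_map(rng)
            g = random_instance_map(rng)
            assert object_dice(s, g) == pytest.approx(object_dice(g, s))

    def test_merging_touching_cells_lowers_od(self):
        # the motivating example: high plain Dice but lower object Dice
        ref = np.zeros((8, 12), dtype=int)
        ref[1:7, 1:6] = 1
        ref[1:7, 6:11] = 2
        merged = np.zeros((8, 12), dtype=int)
        merged[1:7, 1:11] = 1
        correct = ref.copy()
        assert object_dice(merged, ref) < object_dice(correct, ref)
        assert dice(merged > 0, ref > 0) == 1.0  # pixel-level Dice is blind to the merge

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_instance_map(rng, n_objects=rng.integers(1, 4))
        g = random_instance_map(rng, n_objects=rng.integers(1, 4))
        assert object_dice(s, g) == pytest.approx(object_dice_brute_force(s, g))

    @pytest.mark.parametrize("seed", range(20))
    def test_in_unit_interval(self, seed):
        rng = np.random.default_rng(100 + seed)
        s = random_instance_map(rng)
        g = random_instance_map(rng)
        assert 0.0 <= object_dice(s, g) <= 1.0


class TestObjectHausdorff:
    def test_self_is_zero(self):
        for seed in range(5):
            m = random_instance_map(np.random.default_rng(seed))
            if (m > 0).any():
                assert object_hausdorff(m, m) == 0.0

    def test_single_pair_equals_plain_hausdorff(self):
        s = np.zeros((10, 10), dtype=int)
        s[1:4, 1:4] = 1
        g = np.zeros((10, 10), dtype=int)
        g[5:9, 5:9] = 1
        expected = hausdorff(boundary_points(s == 1), boundary_points(g == 1))
        assert object_hausdorff(s, g) == pytest.approx(expected)

    def test_empty_side_raises(self):
        z = np.zeros((4, 4), dtype=int)
        m = np.ones((4, 4), dtype=int)
        with pytest.raises(ValueError):
            object_hausdorff(z, m)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_instance_map(rng, n_objects=rng.integers(1, 4))
        g = random_instance_map(rng, n_objects=rng.integers(1, 4))
        if not (s > 0).any() or not (g > 0).any():
            return
        assert object_hausdorff(s, g) == pytest.approx(object_hausdorff_brute_force(s, g))


class TestReportsAndAgreement:
    def test_report_aggregates(self):
        m1 = random_instance_map(np.random.default_rng(0))
        m2 = random_instance_map(np.random.default_rng(1))
        report = evaluate_rois([("a", m1, m1), ("b", m2, m2)])
        assert report.od_mean == pytest.approx(1.0)
        assert report.oh_mean == pytest.approx(0.0)
        assert report.od_sd == pytest.approx(0.0)

    def test_report_csv_round_trip(self, tmp_path):
        import pandas as pd

        m = random_instance_map(np.random.default_rng(0))
        report = evaluate_rois([("roi0", m, m)])
        report.to_csv(tmp_path / "r.csv")
        back = pd.read_csv(tmp_path / "r.csv")
        assert list(back.columns) == ["roi", "object_dice", "object_hausdorff"]
        assert back.iloc[0]["object_dice"] == pytest.approx(1.0)

    def test_empty_roi_flagged_not_fatal(self):
        z = np.zeros((4, 4), dtype=int)
        m = np.ones((4, 4), dtype=int)
        report = evaluate_rois([("bad", z, m)])
        assert report.flagged_rois == ["bad"]
        assert np.isnan(report.per_roi[0][2])

    def test_three_identical_observers(self):
        m = random_instance_map(np.random.default_rng(0))
        rep = pairwise_agreement([[m], [m], [m]])
        assert rep.n_pairs == 3
        assert rep.od_mean == pytest.approx(1.0)
        assert rep.oh_mean == pytest.approx(0.0)

    def test_two_observers_equal_single_pair(self):
        a = random_instance_map(np.random.default_rng(0))
        b = random_instance_map(np.random.default_rng(1))
        rep = pairwise_agreement([[a], [b]])
        assert rep.n_pairs == 1
        assert rep.od_mean == pytest.approx(object_dice(a, b))

    def test_three_observers_mean_is_hand_computed(self):
        maps = [random_instance_map(np.random.default_rng(s)) for s in (0, 1, 2)]
        rep = pairwise_agreement([[m] for m in maps])
        expected_od = np.mean(
            [object_dice(maps[i], maps[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        )
        assert rep.od_mean == pytest.approx(expected_od)

    def test_single_observer_fatal(self):
        with pytest.raises(ValueError):
            pairwise_agreement([[np.ones((2, 2), dtype=int)]])
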