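import numpy as np
import pytest

import myofuse as mf
from myofuse.errors import UndefinedIndexError, ValidationError

from conftest import make_image


def region_from_box(label, shape, top, left, h, w):
    mask = np.zeros(shape, bool)
    mask[top : top + h, left : left + w] = True
    return mf.FiberRegion.from_mask(label, mask)


def det(i, x, y):
    return mf.NucleusDetection(x=x, y=y, intensity=1.0, id=i)


class TestAssignNuclei:
    def test_rounded_centroid_containment(self):
        fiber = region_from_box(1, (32, 32), top=10, left=10, h=1, w=1)
        out = mf.assign_nuclei([det(0, 10.4, 10.4)], [fiber])
        assert out[0].nucleus_ids == [0]

    def test_nucleus_outside_all_masks_unassigned(self):
        fiber = region_from_box(1, (32, 32), top=10, left=10, h=4, w=4)
        out = mf.assign_nuclei([det(0, 25.0, 25.0)], [fiber])
        assert out[0].nucleus_ids == []

    def test_out_of_grid_centroid_rejected(self):
        fiber = region_from_box(1, (32, 32), top=10, left=10, h=4, w=4)
        with pytest.raises(ValidationError):
            mf.assign_nuclei([det(0, 40.0, 10.0)], [fiber])

    def test_matches_brute_force_containment(self, rng):
        """100 random nuclei against 5 random disjoint masks: assignments must
        equal an exhaustive per-pixel containment check."""
        shape = (96, 96)
        fibers = [region_from_box(i + 1, shape, top=4 + 18 * i, left=8, h=10, w=60)
                  for i in range(5)]
        dets = [det(i, rng.uniform(0, 95), rng.uniform(0, 95)) for i in range(100)]
        out = mf.assign_nuclei(dets, fibers)
        for fiber, annotated in zip(fibers, out):
            pixel_set = {tuple(p) for p in np.argwhere(fiber.mask)}
            expected = [
                d.id for d in dets
                if (int(np.rint(d.y)), int(np.rint(d.x))) in pixel_set
            ]
            assert sorted(annotated.nucleus_ids) == sorted(expected)

    def test_input_regions_not_mutated(self):
        fiber = region_from_box(1, (32, 32), top=10, left=10, h=4, w=4)
        mf.assign_nuclei([det(0, 11.0, 11.0)], [fiber])
        assert fiber.nucleus_ids == []


class TestFusionIndex:
    def _fibers(self, shape, assignments):
        out = []
        for i, ids in enumerate(assignments):
            f = region_from_box(i + 1, shape, top=4 + 12 * i, left=4, h=6, w=40)
            f.nucleus_ids = list(ids)
            out.append(f)
        return out

    def test_three_nucleus_fiber_counts(self):
        dets = [det(i, 5.0, 5.0) for i in range(10)]
        fibers = self._fibers((64, 64), [[0, 1, 2]])
        res = mf.fusion_index(dets, fibers)
        assert res.fusion_index_pct == pytest.approx(30.0)
        assert res.n_fused_fibers == 1

    def test_two_nucleus_fiber_is_ambiguous_not_fused(self):
        dets = [det(i, 5.0, 5.0) for i in range(10)]
        fibers = self._fibers((64, 64), [[0, 1]])
        res = mf.fusion_index(dets, fibers)
        assert res.fusion_index_pct == 0.0
        assert res.fused_nuclei == 0

    def test_no_nuclei_raises_not_zero(self):
        with pytest.raises(UndefinedIndexError):
            mf.fusion_index([], [])

    def test_permutation_invariance(self, rng):
        dets = [det(i, 5.0, 5.0) for i in range(12)]
        fibers = self._fibers((64, 64), [[0, 1, 2, 3], [4, 5, 6]])
        base = mf.fusion_index(dets, fibers)
        shuffled = mf.fusion_index(
            [dets[i] for i in rng.permutation(12)], fibers[::-1]
        )
        assert shuffled.fusion_index_pct == base.fusion_index_pct
        assert sorted(shuffled.fiber_areas_px) == sorted(base.fiber_areas_px)

    def test_extra_unfused_nucleus_dilutes_index(self):
        dets = [det(i, 5.0, 5.0) for i in range(6)]
        fibers = self._fibers((64, 64), [[0, 1, 2]])
        with_extra = mf.fusion_index(dets + [det(6, 50.0, 50.0)], fibers)
        without = mf.fusion_index(dets, fibers)
        assert with_extra.fusion_index_pct < without.fusion_index_pct


class TestObjectContrast:
    def _img(self, arr):
        return make_image(np.asarray(arr, dtype=np.uint16), "cytoplasm")

    def test_uniform_object_over_uniform_background(self):
        arr = np.full((32, 32), 50, dtype=np.uint16)
        arr[8:16, 8:16] = 200
        obj = np.zeros((32, 32), bool)
        obj[8:16, 8:16] = True
        bgd = ~obj
        m = mf.object_contrast(self._img(arr), obj, bgd)
        assert m.contrast_j == pytest.approx(3.0)
        assert (m.s_j, m.bgd) == (200.0, 50.0)

    def test_equal_means_give_zero_contrast(self):
        arr = np.full((32, 32), 80, dtype=np.uint16)
        obj = np.zeros((32, 32), bool)
        obj[:4] = True
        m = mf.object_contrast(self._img(arr), obj, ~obj)
        assert m.contrast_j == 0.0

    def test_mean_arithmetic_on_explicit_pixel_sets(self):
        arr = np.zeros((32, 32), dtype=np.uint16)
        arr[0, 0], arr[0, 1] = 100, 200
        arr[5, 5], arr[5, 6] = 40, 60
        m = mf.object_contrast(
            self._img(arr), np.array([[0, 0], [0, 1]]), np.array([[5, 5], [5, 6]])
        )
        assert (m.s_j, m.bgd, m.contrast_j) == (150.0, 50.0, 2.0)

    def test_scale_invariant_but_not_shift_invariant(self, rng):
        arr = rng.integers(10, 200, size=(32, 32)).astype(np.uint16)
        obj = np.zeros((32, 32), bool)
        obj[10:20, 10:20] = True
        base = mf.object_contrast(self._img(arr), obj, ~obj)
        scaled = mf.object_contrast(self._img(arr * 3), obj, ~obj)
        shifted = mf.object_contrast(self._img(arr + 100), obj, ~obj)
        assert scaled.contrast_j == pytest.approx(base.contrast_j)
        assert shifted.contrast_j != pytest.approx(base.contrast_j)

    def test_zero_background_raises_division_error(self):
        arr = np.zeros((32, 32), dtype=np.uint16)
        arr[0, 0] = 10
        obj = np.zeros((32, 32), bool)
        obj[0, 0] = True
        with pytest.raises(ZeroDivisionError):
            mf.object_contrast(self._img(arr), obj, ~obj)

    def test_overlapping_sets_rejected(self):
        arr = np.full((32, 32), 10, dtype=np.uint16)
        obj = np.zeros((32, 32), bool)
        obj[0:5] = True
        with pytest.raises(ValidationError):
            mf.object_contrast(self._img(arr), obj, obj)


class TestSceneMetrics:
    def test_recovers_simulated_truth_within_tolerance(self, day7_scene):
        scene, gt = day7_scene
        res = mf.scene_metrics(scene)
        assert abs(res.fusion_index_pct - gt.true_fusion_index_pct) <= 5.0
        assert res.total_nuclei == pytest.approx(gt.true_nuclei_count, abs=3)

    def test_no_fusion_scenario_yields_zero_index(self):
        scene, gt = mf.simulate_scene(mf.SimulationParams(f_max=0.0, seed=3), day=8)
        assert gt.true_fusion_index_pct == 0.0
        res = mf.scene_metrics(scene)
        assert res.fusion_index_pct <= 1.0

    def test_deterministic_for_fixed_input(self, day7_scene):
        scene, _ = day7_scene
        assert mf.scene_metrics(scene) == mf.scene_metrics(scene)
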