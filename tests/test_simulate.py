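import numpy as np
import pytest

import myofuse as mf
from myofuse.core import fusion_index_from_memberships
from myofuse.errors import ValidationError
from myofuse.simulate import fused_fraction_at, nuclei_count_at, render_scene, scene_rng


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"f_max": 1.5},
            {"drug_effect": -0.1},
            {"fusion_rate": -1.0},
            {"autofluorescence_level": 0.0},
            {"binucleate_rate": 2.0},
            {"biological_cv": -0.5},
        ],
    )
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            mf.SimulationParams(**kwargs)


class TestFusionDynamics:
    def test_no_fusion_before_differentiation_start(self, default_params):
        nd = mf.ExposureSchedule.preset("ND")
        assert fused_fraction_at(default_params, nd, 0) == 0.0
        assert fused_fraction_at(default_params, nd, 3) == 0.0
        assert fused_fraction_at(default_params, nd, 4) > 0.0

    def test_fully_inhibitory_continuous_drug_freezes_fusion(self):
        params = mf.SimulationParams(drug_effect=0.0)
        cont = mf.ExposureSchedule.preset("continuous")
        for day in range(3, 11):
            assert fused_fraction_at(params, cont, day) == 0.0

    def test_late_exposure_matches_nd_through_day_7(self):
        params = mf.SimulationParams(drug_effect=0.0)
        nd = mf.ExposureSchedule.preset("ND")
        late = mf.ExposureSchedule.preset("late")
        for day in range(0, 8):
            assert fused_fraction_at(params, late, day) == pytest.approx(
                fused_fraction_at(params, nd, day)
            )
        assert fused_fraction_at(params, late, 10) < fused_fraction_at(params, nd, 10)

    @pytest.mark.parametrize("drug_effect", [0.0, 0.3, 1.0])
    def test_fused_fraction_is_non_decreasing_and_bounded(self, drug_effect):
        params = mf.SimulationParams(drug_effect=drug_effect)
        sched = mf.ExposureSchedule.preset("continuous")
        series = [fused_fraction_at(params, sched, d) for d in range(0, 15)]
        assert all(b >= a for a, b in zip(series, series[1:]))
        assert series[-1] <= params.f_max

    def test_nuclei_growth_plateaus(self, default_params):
        counts = [nuclei_count_at(default_params, d) for d in range(0, 12)]
        assert counts[0] == default_params.n_nuclei_day0
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == default_params.plateau_nuclei


class TestSceneSynthesis:
    def test_same_params_and_seed_give_identical_pixels(self, default_params):
        s1, g1 = mf.simulate_scene(default_params, day=6)
        s2, g2 = mf.simulate_scene(default_params, day=6)
        np.testing.assert_array_equal(s1.cytoplasm.pixels, s2.cytoplasm.pixels)
        np.testing.assert_array_equal(s1.nucleus.pixels, s2.nucleus.pixels)
        assert g1.true_fusion_index_pct == g2.true_fusion_index_pct

    def test_no_fusion_scenario_has_no_fused_nuclei(self):
        _, gt = mf.simulate_scene(mf.SimulationParams(f_max=0.0, seed=5), day=9)
        assert gt.true_fusion_index_pct == 0.0
        assert gt.fused_fiber_labels == []

    def test_forced_single_fiber_population(self, default_params):
        """12 nuclei with a 3-nucleus fiber and 9 solitary cells: the >= 3
        rule forces a fusion index of exactly 25%."""
        rng = np.random.default_rng(0)
        params = mf.SimulationParams(binucleate_rate=0.0)
        _, gt = render_scene(params, n_nuclei=12, fused_fraction=0.25, rng=rng)
        assert gt.true_nuclei_count == 12
        assert gt.true_fusion_index_pct == pytest.approx(25.0)
        assert len(gt.fused_fiber_labels) == 1

    def test_ground_truth_index_recomputable_from_memberships(self, day7_scene):
        _, gt = day7_scene
        recomputed = fusion_index_from_memberships([n.fiber_id for n in gt.nuclei])
        assert recomputed == gt.true_fusion_index_pct

    def test_fused_fraction_realized_within_rounding(self, default_params):
        for seed in range(5):
            params = mf.SimulationParams(seed=seed, biological_cv=0.0)
            _, gt = mf.simulate_scene(params, day=8)
            nd = mf.ExposureSchedule.preset("ND")
            target = fused_fraction_at(params, nd, 8) * gt.true_nuclei_count
            fused = sum(1 for n in gt.nuclei if n.fiber_id in set(gt.fused_fiber_labels))
            assert abs(fused - target) <= 2.5

    def test_fiber_masks_disjoint_and_nuclei_inside(self, day7_scene):
        _, gt = day7_scene
        for n in gt.nuclei:
            if n.fiber_id is not None:
                assert gt.fiber_masks[int(round(n.y)), int(round(n.x))] == n.fiber_id

    def test_margin_background_converges_to_autofluorescence(self, default_params):
        scene, _ = mf.simulate_scene(default_params, day=5)
        m = default_params.border_margin_px
        strip = scene.cytoplasm.pixels[:m, :].astype(float)
        level = default_params.autofluorescence_level
        # Poisson + read-noise variance, 3 standard errors of the strip mean
        se = np.sqrt(level + default_params.read_noise_sigma**2) / np.sqrt(strip.size)
        assert abs(strip.mean() - level) <= 3 * se + 0.5  # +0.5 for clipping bias

    def test_label_combo_contrast_ordering(self):
        """The cGFP+nmCherry combination images with higher cytoplasm
        contrast than cmCherry+nGFP, as measured by the contrast metric."""
        contrasts = {}
        for combo in ("cGFP+nmCherry", "cmCherry+nGFP"):
            params = mf.SimulationParams(label_combo=combo, seed=11)
            scene, gt = mf.simulate_scene(params, day=7)
            obj = gt.fiber_masks > 0
            bgd = np.zeros_like(obj)
            bgd[: params.border_margin_px, :] = True
            m = mf.object_contrast(scene.cytoplasm, obj, bgd)
            contrasts[combo] = m.contrast_j
        assert contrasts["cGFP+nmCherry"] > contrasts["cmCherry+nGFP"]


class TestTimecourseAndPlate:
    def test_unsorted_days_rejected(self, default_params):
        nd = mf.ExposureSchedule.preset("ND")
        with pytest.raises(ValidationError):
            mf.simulate_timecourse(default_params, nd, [5, 3])

    def test_plate_counts_and_manifest(self, tmp_path):
        params = mf.SimulationParams(width=160, height=160, n_nuclei_day0=5, plateau_nuclei=10)
        conds = [
            ("A", params, mf.ExposureSchedule.preset("ND")),
            ("B", params, mf.ExposureSchedule.preset("continuous")),
        ]
        records, manifest = mf.simulate_plate(
            conds, n_wells=2, n_fields=2, days=[3, 5], seed=9, out_dir=tmp_path
        )
        assert len(records) == 2 * 2 * 2 * 2
        assert len(manifest["scenes"]) == 16
        assert (tmp_path / "manifest.json").exists()
        scene, gt = mf.read_scene_bundle(tmp_path / manifest["scenes"][0]["path"])
        assert gt is not None

    def test_duplicate_condition_names_rejected(self, default_params):
        nd = mf.ExposureSchedule.preset("ND")
        with pytest.raises(ValidationError):
            mf.simulate_plate([("X", default_params, nd), ("X", default_params, nd)],
                              n_wells=1, n_fields=1, days=[3], seed=0)

    def test_scene_streams_are_stable_under_plate_growth(self):
        """Adding wells or fields never perturbs existing scenes."""
        r1 = scene_rng(7, "ND", 0, 5, 0).integers(0, 1 << 30, 4)
        r2 = scene_rng(7, "ND", 0, 5, 0).integers(0, 1 << 30, 4)
        other = scene_rng(7, "ND", 1, 5, 0).integers(0, 1 << 30, 4)
        np.testing.assert_array_equal(r1, r2)
        assert not np.array_equal(r1, other)
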