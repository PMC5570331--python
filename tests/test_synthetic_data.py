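import numpy as np
import pytest
from skimage.measure import label as cc_label

from scenegaze.gaze_preprocess import detect_events
from scenegaze.io_core import DEFAULT_GEOMETRY
from scenegaze.roi_partition import build_roiset
from scenegaze.scene_saliency import SaliencyMap
from scenegaze.synthetic_data import (
    DatasetDesign,
    GazeSimSpec,
    PlacementError,
    SceneSpec,
    SimulationError,
    generate_scene,
    simulate_dataset,
    simulate_trial,
)


class TestGenerateScene:
    def test_seeded_determinism(self):
        spec = SceneSpec(size_px=(160, 120), n_heads=2, n_bodies=2,
                         n_distractors=3, seed=1)
        img1, m1 = generate_scene(spec)
        img2, m2 = generate_scene(spec)
        np.testing.assert_array_equal(img1, img2)
        np.testing.assert_array_equal(m1["head"], m2["head"])
        np.testing.assert_array_equal(m1["body"], m2["body"])

    def test_no_social_content(self):
        spec = SceneSpec(size_px=(160, 120), n_heads=0, n_bodies=0,
                         n_distractors=4, seed=2)
        img, masks = generate_scene(spec)
        assert not masks["head"].any()
        assert not masks["body"].any()
        assert np.ptp(img) > 0.3  # distractors still give contrast

    def test_head_component_count(self):
        spec = SceneSpec(size_px=(300, 220), n_heads=5, n_bodies=0,
                         n_distractors=0, seed=3)
        _, masks = generate_scene(spec)
        assert cc_label(masks["head"], connectivity=2).max() == 5

    def test_regions_disjoint(self):
        spec = SceneSpec(size_px=(200, 160), n_heads=3, n_bodies=3,
                         n_distractors=4, seed=4)
        _, masks = generate_scene(spec)
        assert not (masks["head"] & masks["body"]).any()

    def test_impossible_placement_raises(self):
        spec = SceneSpec(size_px=(40, 40), n_heads=50, n_bodies=0,
                         n_distractors=0, head_radius_frac=(0.2, 0.3),
                         max_retries=50, seed=5)
        with pytest.raises(PlacementError):
            generate_scene(spec)

    def test_image_in_unit_range(self):
        img, _ = generate_scene(SceneSpec(size_px=(160, 120), seed=6))
        assert img.min() >= 0.0 and img.max() <= 1.0


class TestGazeSimSpec:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GazeSimSpec(preference_weights={"head": 0.5, "body": 0.2,
                                            "low_sal": 0.2, "high_sal": 0.2})

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            GazeSimSpec(preference_weights={"head": -0.1, "body": 0.4,
                                            "low_sal": 0.3, "high_sal": 0.4})


class TestSimulateTrial:
    def test_pure_head_preference(self, small_scene, free_meta, geom):
        sim = GazeSimSpec(
            preference_weights={"head": 1.0, "body": 0.0, "low_sal": 0.0,
                                "high_sal": 0.0},
            noise_sd_px=0.0, drift_sd_px=0.0, blink_rate_hz=0.0)
        rng = np.random.default_rng(0)
        _, gt = simulate_trial(small_scene["roiset"], free_meta(), sim,
                               geom, rng)
        head = small_scene["roiset"].mask("head")
        scene_fix = [f for f in gt.fixations if f.category is not None]
        assert scene_fix
        for f in scene_fix:
            assert f.category == "head"
            assert head[int(round(f.y_px)), int(round(f.x_px))]

    def test_noiseless_event_count_recovered(self, small_scene, free_meta,
                                             clean_sim, geom):
        rng = np.random.default_rng(1)
        rec, gt = simulate_trial(small_scene["roiset"], free_meta(), clean_sim,
                                 geom, rng, drift_px=(0.0, 0.0))
        ev = detect_events(rec, geom)
        scene_fix_gt = len(gt.fixations)
        # the detector merges the cross fixation with nothing; counts match
        assert len(ev.fixations) == scene_fix_gt
        assert len(ev.saccades) == len(gt.saccades)

    def test_drift_construction(self, small_scene, free_meta, clean_sim, geom):
        rng = np.random.default_rng(2)
        meta = free_meta()
        rec, gt = simulate_trial(small_scene["roiset"], meta, clean_sim,
                                 geom, rng, drift_px=(10.0, -5.0))
        assert gt.drift_px == (10.0, -5.0)
        pre = rec.time_ms < meta.stimulus_onset_ms
        assert rec.x_px[pre].mean() - meta.cross_position_px[0] == pytest.approx(10.0, abs=1e-6)
        assert rec.y_px[pre].mean() - meta.cross_position_px[1] == pytest.approx(-5.0, abs=1e-6)

    def test_empty_roi_with_weight_raises(self, free_meta, geom):
        # scene with no head pixels but full head preference
        sal = SaliencyMap(values=np.linspace(0, 1, 120 * 160).reshape(120, 160))
        rs = build_roiset(None, sal, q=80)
        sim = GazeSimSpec(preference_weights={"head": 1.0, "body": 0.0,
                                              "low_sal": 0.0, "high_sal": 0.0},
                          noise_sd_px=0.0, drift_sd_px=0.0, blink_rate_hz=0.0)
        with pytest.raises(SimulationError):
            simulate_trial(rs, free_meta(cross=(80.0, 60.0)), sim, geom,
                           np.random.default_rng(0))

    def test_ground_truth_peaks_exceed_threshold(self, small_scene, free_meta,
                                                 clean_sim, geom):
        rng = np.random.default_rng(3)
        _, gt = simulate_trial(small_scene["roiset"], free_meta(), clean_sim,
                               geom, rng)
        for s in gt.saccades:
            assert s.peak_velocity_deg_s > 30.0

    def test_blinks_flagged_not_dropped(self, small_scene, free_meta, geom):
        sim = GazeSimSpec(noise_sd_px=0.0, drift_sd_px=0.0, blink_rate_hz=1.0)
        rng = np.random.default_rng(4)
        rec, _ = simulate_trial(small_scene["roiset"], free_meta(), sim,
                                geom, rng)
        assert (~rec.valid).any()
        assert len(rec) == int(free_meta().stimulus_onset_ms
                               + free_meta().presentation_ms)


class TestSimulateDataset:
    def _design(self, n_social=2, n_nonsocial=2, tasks=("free", "count")):
        return DatasetDesign(
            tasks=tasks, n_social=n_social, n_nonsocial=n_nonsocial,
            scene=SceneSpec(size_px=(160, 120), n_heads=2, n_bodies=2,
                            n_distractors=4),
            presentation_ms=1200.0, pre_stimulus_ms=600.0,
        )

    def test_trial_count(self, geom):
        ds = simulate_dataset(2, self._design(2, 2, ("free", "count",
                                                     "define", "estimate")),
                              GazeSimSpec(), geom, master_seed=5)
        assert len(ds.metas) == 2 * 4 * 4
        assert len(ds.recordings) == 32

    def test_master_seed_reproducibility(self, geom):
        d = self._design()
        ds1 = simulate_dataset(2, d, GazeSimSpec(), geom, master_seed=9)
        ds2 = simulate_dataset(2, d, GazeSimSpec(), geom, master_seed=9)
        for tid in ds1.recordings:
            np.testing.assert_array_equal(ds1.recordings[tid].x_px,
                                          ds2.recordings[tid].x_px)
            np.testing.assert_array_equal(ds1.recordings[tid].valid,
                                          ds2.recordings[tid].valid)
        assert ds1.metas == ds2.metas

    def test_nonsocial_trials_have_no_social_targets(self, geom):
        ds = simulate_dataset(1, self._design(), GazeSimSpec(), geom,
                              master_seed=11)
        for meta in ds.metas:
            if meta.category == "nonsocial":
                gt = ds.ground_truth[meta.trial_id]
                for f in gt.fixations:
                    assert f.category not in ("head", "body")
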