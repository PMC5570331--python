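import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scenegaze.gaze_preprocess import (
    BaselineRecord,
    FixationEvent,
    ParticipantDataError,
    TrialEvents,
    TrialRecord,
    apply_exclusions,
    compute_baseline,
    detect_events,
    drift_correct,
    recursive_outlier_removal,
    resolve_baselines,
)
from scenegaze.io_core import GazeRecording, TrialMeta
from scenegaze.synthetic_data import GazeSimSpec, simulate_trial


def make_rec(x, y, valid=None, trial_id="t"):
    n = len(x)
    return GazeRecording(
        trial_id=trial_id,
        time_ms=np.arange(n, dtype=float),
        x_px=np.asarray(x, dtype=float),
        y_px=np.asarray(y, dtype=float),
        valid=np.ones(n, bool) if valid is None else np.asarray(valid, bool),
    )


class TestDetectEvents:
    def test_constant_position_single_fixation(self, geom):
        n = 10_000
        rec = make_rec(np.full(n, 500.0), np.full(n, 400.0))
        ev = detect_events(rec, geom)
        assert len(ev.saccades) == 0
        assert len(ev.fixations) == 1
        assert ev.fixations[0].duration_ms == pytest.approx(n)

    def test_subthreshold_drift_no_saccade(self, geom):
        # uniform motion at 20 deg/s stays below the 30 deg/s threshold
        n = 2000
        px_per_deg = 1.0 / np.degrees(
            2 * np.arctan2(geom.pitch_mm("horizontal") / 2, geom.distance_mm)
        )
        speed_px_per_ms = 20.0 * px_per_deg / 1000.0
        x = 200.0 + speed_px_per_ms * np.arange(n)
        ev = detect_events(make_rec(x, np.full(n, 400.0)), geom)
        assert len(ev.saccades) == 0
        assert len(ev.fixations) == 1

    def test_simulator_ground_truth_recovery(self, geom, small_scene,
                                             free_meta, clean_sim):
        meta = free_meta(presentation_ms=4000.0)
        found = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rec, gt = simulate_trial(small_scene["roiset"], meta, clean_sim,
                                     geom, rng, drift_px=(0.0, 0.0))
            ev = detect_events(rec, geom)
            assert len(ev.saccades) == len(gt.saccades)
            for g, d in zip(gt.saccades, ev.saccades):
                # detection cannot precede movement by more than the velocity
                # half-window (2) plus the acceleration half-window (1), nor
                # lag the pointwise threshold crossing by > 2 samples
                assert g.onset_ms - 3.0 <= d.onset_ms <= g.detectable_onset_ms + 2.0
            found += len(gt.saccades)
        assert found > 10

    def test_all_invalid_flagged(self, geom):
        rec = make_rec(np.zeros(100), np.zeros(100), valid=np.zeros(100, bool))
        ev = detect_events(rec, geom)
        assert ev.all_invalid
        assert ev.fixations == [] and ev.saccades == []

    def test_partition_invariant(self, geom, small_scene, free_meta):
        # fixation + saccade + blink time == trial duration (sample resolution)
        sim = GazeSimSpec(noise_sd_px=0.2, blink_rate_hz=0.2)
        meta = free_meta(presentation_ms=3000.0)
        rng = np.random.default_rng(9)
        rec, _ = simulate_trial(small_scene["roiset"], meta, sim, geom, rng)
        ev = detect_events(rec, geom)
        covered = sum(f.duration_ms for f in ev.fixations)
        covered += sum(s.duration_ms for s in ev.saccades)
        covered += ev.blink_ms
        assert covered == pytest.approx(ev.total_ms, abs=1e-9)

    def test_saccade_peaks_exceed_threshold(self, geom, small_scene,
                                            free_meta, clean_sim):
        rng = np.random.default_rng(4)
        rec, _ = simulate_trial(small_scene["roiset"], free_meta(), clean_sim,
                                geom, rng, drift_px=(0.0, 0.0))
        ev = detect_events(rec, geom)
        for s in ev.saccades:
            assert s.peak_velocity_deg_s >= 30.0


def outlier_removal_oracle(values, k=3.0):
    """Independent step-by-step trace of the stated removal procedure."""
    vals = {i: v for i, v in enumerate(values)}
    if len(vals) < 3:
        return set(vals)
    while True:
        if len(vals) < 3:
            break
        items = sorted(vals.items(), key=lambda kv: kv[1])
        i_min, v_min = items[0]
        i_max, v_max = items[-1]
        rest = [v for i, v in vals.items() if i not in (i_min, i_max)]
        mean = sum(rest) / len(rest)
        if len(rest) > 1:
            sd = (sum((v - mean) ** 2 for v in rest) / (len(rest) - 1)) ** 0.5
        else:
            sd = float("nan")
        removed = False
        for i, v in ((i_min, v_min), (i_max, v_max)):
            if not (mean - k * sd <= v <= mean + k * sd):
                del vals[i]
                removed = True
        if not removed:
            break
    return set(vals)


class TestRecursiveOutlierRemoval:
    def test_hand_trace_single_outlier(self):
        keep, removed = recursive_outlier_removal([1, 1, 1, 1, 100])
        assert list(removed) == [4]
        assert keep.tolist() == [True] * 4 + [False]

    def test_all_equal_nothing_removed(self):
        keep, removed = recursive_outlier_removal([5.0] * 6)
        assert keep.all() and len(removed) == 0

    def test_short_sequences_unchanged(self):
        keep, removed = recursive_outlier_removal([1.0, 100.0])
        assert keep.all() and len(removed) == 0

    def test_matches_scripted_oracle(self):
        cases = [
            [0, 10, 10, 10, 10, 10, 20],
            [1, 2, 3, 4, 5, 100],
            [-50, 0, 0, 0, 1, 2, 50],
        ]
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            cases.append(list(rng.normal(0, 1, n) + rng.choice([0, 20], n,
                                                               p=[0.9, 0.1])))
        for values in cases:
            keep, _ = recursive_outlier_removal(values)
            kept_idx = set(np.flatnonzero(keep))
            assert kept_idx == outlier_removal_oracle(values), values

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                              allow_nan=False), min_size=3, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_idempotent_property(self, values):
        keep, _ = recursive_outlier_removal(values)
        kept_values = [v for v, k in zip(values, keep) if k]
        keep2, removed2 = recursive_outlier_removal(kept_values)
        assert keep2.all() and len(removed2) == 0


class TestBaselines:
    def test_compute_baseline_window(self):
        n = 1000
        x = np.full(n, 100.0)
        x[700:] = 140.0  # the last 300 ms before onset at t=1000
        rec = make_rec(x, np.full(n, 50.0))
        bl = compute_baseline(rec, stimulus_onset_ms=1000.0, window_ms=300.0)
        assert bl.bx_px == pytest.approx(140.0)
        assert bl.status == "valid"

    def test_missing_baseline(self):
        rec = make_rec(np.zeros(100), np.zeros(100),
                       valid=np.zeros(100, bool))
        bl = compute_baseline(rec, stimulus_onset_ms=100.0)
        assert bl.status == "missing"

    def test_all_valid_untouched(self):
        records = [BaselineRecord(f"t{i}", 10.0 + i * 0.01, 20.0)
                   for i in range(10)]
        out = resolve_baselines(records)
        assert all(r.status == "valid" for r in out)

    def test_outlier_replaced_with_mean_of_others(self):
        records = [BaselineRecord(f"t{i}", 10.0, 20.0) for i in range(9)]
        records.append(BaselineRecord("t9", 500.0, 20.0))
        out = resolve_baselines(records)
        assert out[9].status == "replaced"
        assert out[9].bx_px == pytest.approx(10.0)
        assert out[9].by_px == pytest.approx(20.0)
        assert all(r.status == "valid" for r in out[:9])

    def test_missing_replaced_regardless(self):
        records = [BaselineRecord(f"t{i}", 10.0, 20.0) for i in range(5)]
        records.append(BaselineRecord("t5", np.nan, np.nan, status="missing"))
        out = resolve_baselines(records)
        assert out[5].status == "replaced"
        assert out[5].bx_px == pytest.approx(10.0)

    def test_zero_valid_raises(self):
        records = [BaselineRecord("t0", np.nan, np.nan, status="missing")]
        with pytest.raises(ParticipantDataError):
            resolve_baselines(records)


class TestDriftCorrect:
    def fixes(self):
        return [FixationEvent(0, 100, 50.0, 60.0),
                FixationEvent(150, 400, 80.0, 30.0)]

    def test_identity_when_baseline_equals_cross(self):
        out = drift_correct(self.fixes(), BaselineRecord("t", 10.0, 20.0),
                            (10.0, 20.0))
        assert out[0].x_px == 50.0 and out[0].y_px == 60.0
        assert all(f.corrected for f in out)

    def test_offset_shift(self):
        out = drift_correct(self.fixes(), BaselineRecord("t", 20.0, 15.0),
                            (10.0, 20.0))
        # baseline offset (+10, -5) -> fixations shifted (-10, +5)
        assert out[0].x_px == pytest.approx(40.0)
        assert out[0].y_px == pytest.approx(65.0)

    def test_durations_and_distances_preserved(self):
        src = self.fixes()
        out = drift_correct(src, BaselineRecord("t", 37.0, -12.0), (1.0, 2.0))
        for a, b in zip(src, out):
            assert b.duration_ms == a.duration_ms
        d_src = np.hypot(src[1].x_px - src[0].x_px, src[1].y_px - src[0].y_px)
        d_out = np.hypot(out[1].x_px - out[0].x_px, out[1].y_px - out[0].y_px)
        assert d_out == pytest.approx(d_src, abs=1e-12)

    def test_recovers_simulator_landing_points(self, geom, small_scene,
                                               free_meta, clean_sim):
        rng = np.random.default_rng(12)
        meta = free_meta()
        rec, gt = simulate_trial(small_scene["roiset"], meta, clean_sim,
                                 geom, rng, drift_px=(12.0, -7.0))
        ev = detect_events(rec, geom)
        bl = compute_baseline(rec, meta.stimulus_onset_ms)
        corrected = drift_correct(ev.fixations, bl, meta.cross_position_px)
        gt_fix = [f for f in gt.fixations if f.category is not None]
        det = [f for f in corrected if f.onset_ms >= meta.stimulus_onset_ms]
        assert len(det) == len(gt_fix)
        for g, d in zip(gt_fix, det):
            assert abs(d.x_px - g.x_px) < 1.0
            assert abs(d.y_px - g.y_px) < 1.0

    def test_prestimulus_drift_visible_in_baseline(self, geom, small_scene,
                                                   free_meta, clean_sim):
        rng = np.random.default_rng(13)
        meta = free_meta()
        rec, _ = simulate_trial(small_scene["roiset"], meta, clean_sim,
                                geom, rng, drift_px=(10.0, -5.0))
        pre = rec.time_ms < meta.stimulus_onset_ms
        assert rec.x_px[pre].mean() - meta.cross_position_px[0] == pytest.approx(10.0, abs=0.2)
        assert rec.y_px[pre].mean() - meta.cross_position_px[1] == pytest.approx(-5.0, abs=0.2)


def _trial(subject, trial_id, task, blink_ms, responded, baseline_status,
           presentation=10_000.0):
    meta = TrialMeta(subject, trial_id, "stim", task, "social", 0.0,
                     (0.0, 0.0), presentation,
                     click_time_ms=5000.0 if responded and task != "free" else None)
    events = TrialEvents(
        trial_id, [FixationEvent(0.0, presentation - blink_ms, 1.0, 1.0)],
        [], blink_ms, presentation)
    return TrialRecord(meta=meta, events=events,
                       baseline=BaselineRecord(trial_id, 0.0, 0.0,
                                               status=baseline_status),
                       responded=responded)


class TestExclusions:
    def test_blink_rule_arithmetic(self):
        t_drop = _trial("s", "t0", "free", 2500.0, True, "valid")
        t_keep = _trial("s", "t1", "free", 1900.0, True, "valid")
        kept, report = apply_exclusions([t_drop, t_keep])
        assert [t.meta.trial_id for t in kept] == ["t1"]
        assert report.iloc[0]["rule"] == "blinks"
        assert report.iloc[0]["value"] == pytest.approx(0.75)

    def test_baseline_participant_rule(self):
        # 9 replaced baselines out of 40 -> 22.5% > 20% -> participant dropped
        trials = [
            _trial("s", f"t{i}", "free", 0.0, True,
                   "replaced" if i < 9 else "valid")
            for i in range(40)
        ]
        kept, report = apply_exclusions(trials)
        assert kept == []
        assert report.iloc[0]["rule"] == "bad_baselines"
        assert report.iloc[0]["value"] == pytest.approx(0.225)

    def test_missing_response_rule(self):
        trials = [_trial("s", f"t{i}", "count", 0.0, i >= 3, "valid")
                  for i in range(10)]
        kept, report = apply_exclusions(trials)  # 30% missing > 25%
        assert kept == []
        assert report.iloc[0]["rule"] == "missing_responses"

    def test_free_viewing_needs_no_response(self):
        trials = [_trial("s", f"t{i}", "free", 0.0, True, "valid")
                  for i in range(10)]
        kept, report = apply_exclusions(trials)
        assert len(kept) == 10 and report.empty
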