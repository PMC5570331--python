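"""Raw gaze streams -> drift-corrected fixation/saccade events + exclusions.

Saccades are runs of samples whose angular velocity exceeds 30 deg/s or
whose angular acceleration exceeds 8000 deg/s^2; the intervals between
saccades are fixations.  Baselines are the mean gaze over the 300 ms
before stimulus onset, cleaned by a recursive outlier-removal procedure
and used to drift-correct fixation positions against the fixation cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from scenegaze.io_core import (
    GazeRecording,
    ScreenGeometry,
    TrialMeta,
)

__all__ = [
    "FixationEvent",
    "SaccadeEvent",
    "BaselineRecord",
    "TrialEvents",
    "detect_events",
    "recursive_outlier_removal",
    "compute_baseline",
    "resolve_baselines",
    "drift_correct",
    "apply_exclusions",
    "ParticipantDataError",
]


class ParticipantDataError(ValueError):
    """Raised when a participant has no usable baseline data at all."""


@dataclass(frozen=True)
class FixationEvent:
    onset_ms: float
    offset_ms: float
    x_px: float
    y_px: float
    corrected: bool = False

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    peak_velocity_deg_s: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class TrialEvents:
    """Segmentation result of one trial."""

    trial_id: str
    fixations: list[FixationEvent]
    saccades: list[SaccadeEvent]
    blink_ms: float
    total_ms: float
    all_invalid: bool = False

    @property
    def blink_free_frac(self) -> float:
        return 1.0 - self.blink_ms / self.total_ms if self.total_ms > 0 else 0.0


@dataclass
class BaselineRecord:
    trial_id: str
    bx_px: float
    by_px: float
    status: str = "valid"  # valid | outlier_removed | missing | replaced


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


def _positions_deg(
    x_px: np.ndarray, y_px: np.ndarray, geom: ScreenGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Gaze positions as visual angles relative to the screen centre."""
    cx = (geom.width_px - 1) / 2.0
    cy = (geom.height_px - 1) / 2.0
    px = geom.pitch_mm("horizontal")
    py = geom.pitch_mm("vertical")
    ax = np.degrees(np.arctan2((x_px - cx) * px, geom.distance_mm))
    ay = np.degrees(np.arctan2((y_px - cy) * py, geom.distance_mm))
    return ax, ay


def _central_diff(values: np.ndarray, times_s: np.ndarray, half: int) -> np.ndarray:
    """Central difference over +-half samples, shrinking at the edges."""
    n = len(values)
    out = np.full(n, np.nan)
    for h in range(half, 0, -1):
        idx = np.arange(h, n - h)
        est = (values[idx + h] - values[idx - h]) / (times_s[idx + h] - times_s[idx - h])
        fill = np.isnan(out[idx])
        out[idx] = np.where(fill, est, out[idx])
    # edge samples: one-sided estimate
    if n >= 2:
        out[0] = (values[1] - values[0]) / (times_s[1] - times_s[0])
        out[-1] = (values[-1] - values[-2]) / (times_s[-1] - times_s[-2])
    return out


def _pad_invalid(valid: np.ndarray, time_ms: np.ndarray, pad_ms: float) -> np.ndarray:
    """Extend invalid spans by +-pad_ms (guard against blink artifacts)."""
    if pad_ms <= 0 or valid.all():
        return valid
    invalid = ~valid
    out = invalid.copy()
    idx = np.flatnonzero(invalid)
    for i in idx:
        lo = np.searchsorted(time_ms, time_ms[i] - pad_ms, side="left")
        hi = np.searchsorted(time_ms, time_ms[i] + pad_ms, side="right")
        out[lo:hi] = True
    return ~out


def detect_events(
    rec: GazeRecording,
    geom: ScreenGeometry,
    vel_thresh_deg_s: float = 30.0,
    acc_thresh_deg_s2: float = 8000.0,
    velocity_window: int = 5,
    blink_pad_ms: float = 25.0,
) -> TrialEvents:
    """Segment a recording into saccades and fixations.

    A sample is in-saccade when its speed exceeds ``vel_thresh_deg_s`` OR its
    acceleration magnitude exceeds ``acc_thresh_deg_s2``.  Maximal runs of
    in-saccade samples form saccades; the complementary valid intervals are
    fixations.  Invalid (blink) spans, padded by ``blink_pad_ms``, belong to
    neither.  Event times are sample-aligned; each sample owns one sample
    period, so fixation + saccade + blink time partitions the trial.
    """
    n = len(rec)
    dt_ms = 1000.0 / rec.sample_rate_hz
    total_ms = n * dt_ms
    valid = _pad_invalid(rec.valid.copy(), rec.time_ms, blink_pad_ms)

    if valid.sum() < 3:
        return TrialEvents(rec.trial_id, [], [], total_ms, total_ms, all_invalid=True)

    t_s = rec.time_ms / 1000.0
    ax, ay = _positions_deg(rec.x_px, rec.y_px, geom)
    half = max(1, velocity_window // 2)
    vx = _central_diff(ax, t_s, half)
    vy = _central_diff(ay, t_s, half)
    speed = np.hypot(vx, vy)
    # acceleration from the tightest central difference: wider windows smear
    # event boundaries beyond the 2-sample tolerance the thresholds warrant
    accel = np.abs(_central_diff(speed, t_s, 1))

    in_saccade = (speed > vel_thresh_deg_s) | (accel > acc_thresh_deg_s2)

    fixations: list[FixationEvent] = []
    saccades: list[SaccadeEvent] = []

    # walk maximal valid runs, segmenting each by the in-saccade flag
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        run = slice(i, j)
        flags = in_saccade[run]
        k = i
        while k < j:
            m = k
            while m < j and in_saccade[m] == in_saccade[k]:
                m += 1
            onset = rec.time_ms[k]
            offset = rec.time_ms[m - 1] + dt_ms
            if in_saccade[k]:
                saccades.append(
                    SaccadeEvent(onset, offset, float(np.nanmax(speed[k:m])))
                )
            else:
                fixations.append(
                    FixationEvent(
                        onset,
                        offset,
                        float(rec.x_px[k:m].mean()),
                        float(rec.y_px[k:m].mean()),
                    )
                )
            k = m
        i = j

    blink_ms = float((~valid).sum()) * dt_ms
    return TrialEvents(rec.trial_id, fixations, saccades, blink_ms, total_ms)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def recursive_outlier_removal(
    values: Sequence[float], k: float = 3.0, sd_ddof: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Recursive max/min outlier screen; returns a boolean keep-mask and the
    indices removed, in removal order.

    Each iteration temporarily removes the current maximum and minimum,
    computes mean and SD of the remainder, permanently discards temporary
    values outside mean +- k*SD and returns the rest; iteration stops when
    nothing is removed.  Sequences with fewer than 3 values are returned
    unchanged (the SD of <=1 value is undefined).
    """
    arr = np.asarray(values, dtype=float)
    keep = np.ones(len(arr), dtype=bool)
    removed: list[int] = []
    if len(arr) < 3:
        return keep, np.array(removed, dtype=int)

    while True:
        idx = np.flatnonzero(keep)
        if len(idx) < 3:
            break
        sub = arr[idx]
        i_max = idx[int(np.argmax(sub))]
        i_min = idx[int(np.argmin(sub))]
        rest = idx[(idx != i_max) & (idx != i_min)]
        mean = arr[rest].mean()
        sd = arr[rest].std(ddof=sd_ddof) if len(rest) > sd_ddof else 0.0
        lo, hi = mean - k * sd, mean + k * sd
        dropped_any = False
        for i in {i_max, i_min}:
            if not (lo <= arr[i] <= hi):
                keep[i] = False
                removed.append(int(i))
                dropped_any = True
        if not dropped_any:
            break
    return keep, np.array(removed, dtype=int)


def compute_baseline(
    rec: GazeRecording, stimulus_onset_ms: float, window_ms: float = 300.0
) -> BaselineRecord:
    """Mean gaze over the ``window_ms`` directly before stimulus onset."""
    sel = (
        (rec.time_ms >= stimulus_onset_ms - window_ms)
        & (rec.time_ms < stimulus_onset_ms)
        & rec.valid
    )
    if not sel.any():
        return BaselineRecord(rec.trial_id, math.nan, math.nan, status="missing")
    return BaselineRecord(
        rec.trial_id,
        float(rec.x_px[sel].mean()),
        float(rec.y_px[sel].mean()),
        status="valid",
    )


def resolve_baselines(
    records: Sequence[BaselineRecord], k: float = 3.0, sd_ddof: int = 1
) -> list[BaselineRecord]:
    """Finalize one participant's baselines.

    x and y coordinates are screened separately by
    :func:`recursive_outlier_removal`; trials with a removed coordinate or
    missing baseline data get both coordinates replaced by the mean of the
    valid baselines and ``status='replaced'`` (these are excluded from
    first-fixation analyses downstream).
    """
    present = [r for r in records if r.status != "missing"]
    if present:
        xs = np.array([r.bx_px for r in present])
        ys = np.array([r.by_px for r in present])
        keep_x, _ = recursive_outlier_removal(xs, k, sd_ddof)
        keep_y, _ = recursive_outlier_removal(ys, k, sd_ddof)
        good = keep_x & keep_y
    else:
        good = np.array([], dtype=bool)

    if not good.any():
        raise ParticipantDataError("participant has zero valid baselines")
    mean_x = float(np.mean([r.bx_px for r, g in zip(present, good) if g]))
    mean_y = float(np.mean([r.by_px for r, g in zip(present, good) if g]))

    by_id = {r.trial_id: g for r, g in zip(present, good)}
    out = []
    for r in records:
        if r.status != "missing" and by_id[r.trial_id]:
            out.append(replace(r, status="valid"))
        else:
            out.append(
                BaselineRecord(r.trial_id, mean_x, mean_y, status="replaced")
            )
    return out


def drift_correct(
    fixations: Iterable[FixationEvent],
    baseline: BaselineRecord,
    cross_px: tuple[float, float],
) -> list[FixationEvent]:
    """Shift fixation positions by -(baseline - cross); durations unchanged."""
    dx = baseline.bx_px - cross_px[0]
    dy = baseline.by_px - cross_px[1]
    return [
        replace(f, x_px=f.x_px - dx, y_px=f.y_px - dy, corrected=True)
        for f in fixations
    ]


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """Everything the exclusion stage needs to know about one trial."""

    meta: TrialMeta
    events: TrialEvents
    baseline: BaselineRecord
    responded: bool


def apply_exclusions(
    trials: Sequence[TrialRecord],
    min_blink_free_frac: float = 0.8,
    max_missing_response_frac: float = 0.25,
    max_bad_baseline_frac: float = 0.20,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Apply trial- and participant-level exclusion rules.

    Trials with a blink-free fraction of the presentation below
    ``min_blink_free_frac`` are dropped.  Participants with a missing
    response in more than ``max_missing_response_frac`` of their task trials
    (free viewing requires no response), or with more than
    ``max_bad_baseline_frac`` replaced/missing baselines, are dropped
    entirely.  Returns the kept trials and a report of every drop.
    """
    report_rows = []
    by_subject: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_subject.setdefault(t.meta.subject_id, []).append(t)

    kept: list[TrialRecord] = []
    for subject, sub_trials in by_subject.items():
        task_trials = [t for t in sub_trials if t.meta.task != "free"]
        if task_trials:
            miss_frac = sum(not t.responded for t in task_trials) / len(task_trials)
        else:
            miss_frac = 0.0
        bad_bl = sum(t.baseline.status != "valid" for t in sub_trials) / len(sub_trials)

        if miss_frac > max_missing_response_frac:
            report_rows.append(
                {"level": "participant", "id": subject, "rule": "missing_responses",
                 "value": miss_frac, "threshold": max_missing_response_frac}
            )
            continue
        if bad_bl > max_bad_baseline_frac:
            report_rows.append(
                {"level": "participant", "id": subject, "rule": "bad_baselines",
                 "value": bad_bl, "threshold": max_bad_baseline_frac}
            )
            continue

        for t in sub_trials:
            # blink fraction judged over the stimulus presentation window
            onset = t.meta.stimulus_onset_ms
            frac = _blink_free_frac_presentation(t, onset)
            if frac < min_blink_free_frac:
                report_rows.append(
                    {"level": "trial", "id": t.meta.trial_id, "rule": "blinks",
                     "value": frac, "threshold": min_blink_free_frac}
                )
                continue
            kept.append(t)

    report = pd.DataFrame(
        report_rows, columns=["level", "id", "rule", "value", "threshold"]
    )
    return kept, report


def _blink_free_frac_presentation(t: TrialRecord, onset_ms: float) -> float:
    """Blink-free fraction within [onset, onset + presentation]."""
    pres = t.meta.presentation_ms
    end = onset_ms + pres
    blink = 0.0
    covered = 0.0
    ev: list[tuple[float, float, bool]] = []
    for f in t.events.fixations:
        ev.append((f.onset_ms, f.offset_ms, False))
    for s in t.events.saccades:
        ev.append((s.onset_ms, s.offset_ms, False))
    ev.sort()
    for a, b, _ in ev:
        covered += max(0.0, min(b, end) - max(a, onset_ms))
    window = min(pres, t.events.total_ms)
    blink = max(0.0, window - covered)
    return 1.0 - blink / pres if pres > 0 else 0.0
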