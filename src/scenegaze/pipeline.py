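"""End-to-end orchestration: dataset -> events -> density -> tidy metrics.

This is glue over the analysis modules; it exists so the CLI, the tests
and parameter-recovery studies all run the identical processing path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scenegaze import attention_metrics, fixation_density, gaze_preprocess
from scenegaze.gaze_preprocess import (
    BaselineRecord,
    TrialRecord,
    compute_baseline,
    detect_events,
    drift_correct,
    resolve_baselines,
)
from scenegaze.io_core import ScreenGeometry, DEFAULT_GEOMETRY
from scenegaze.synthetic_data import Dataset

__all__ = ["process_dataset", "ProcessedTrial", "metrics_table", "first_fixation_table"]


@dataclass
class ProcessedTrial:
    meta: object
    events: object
    baseline: BaselineRecord
    fixations_corrected: list  # post-discard, drift-corrected, scene fixations
    pre_fixations: list
    post_fixations: list


def process_dataset(
    dataset: Dataset,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
    config: dict | None = None,
) -> tuple[list[ProcessedTrial], pd.DataFrame]:
    """Run detection, baseline resolution, exclusions and drift correction.

    Returns the kept trials (with window-split corrected fixations) and the
    exclusion report.
    """
    from scenegaze.io_core import DEFAULT_CONFIG

    cfg = config or DEFAULT_CONFIG
    ev_cfg, bl_cfg, ex_cfg = cfg["events"], cfg["baseline"], cfg["exclusions"]

    records: list[TrialRecord] = []
    by_subject: dict[str, list[tuple]] = {}
    for meta in dataset.metas:
        rec = dataset.recordings[meta.trial_id]
        events = detect_events(
            rec,
            geom,
            vel_thresh_deg_s=ev_cfg["velocity_thresh_deg_s"],
            acc_thresh_deg_s2=ev_cfg["accel_thresh_deg_s2"],
            velocity_window=ev_cfg["velocity_window"],
            blink_pad_ms=ev_cfg["blink_pad_ms"],
        )
        baseline = compute_baseline(rec, meta.stimulus_onset_ms, bl_cfg["window_ms"])
        by_subject.setdefault(meta.subject_id, []).append((meta, events, baseline))

    skipped_subjects = []
    for subject, items in by_subject.items():
        try:
            resolved = resolve_baselines(
                [b for _, _, b in items],
                k=bl_cfg["outlier_sd"],
                sd_ddof=bl_cfg["sd_ddof"],
            )
        except gaze_preprocess.ParticipantDataError:
            skipped_subjects.append(
                {"level": "participant", "id": subject,
                 "rule": "no_valid_baselines", "value": 0.0, "threshold": 0.0}
            )
            continue
        for (meta, events, _), baseline in zip(items, resolved):
            records.append(
                TrialRecord(
                    meta=meta,
                    events=events,
                    baseline=baseline,
                    responded=meta.click_time_ms is not None or meta.task == "free",
                )
            )

    kept, report = gaze_preprocess.apply_exclusions(
        records,
        min_blink_free_frac=ex_cfg["min_blink_free_frac"],
        max_missing_response_frac=ex_cfg["max_missing_response_frac"],
        max_bad_baseline_frac=ex_cfg["max_bad_baseline_frac"],
    )
    if skipped_subjects:
        report = pd.concat(
            [report, pd.DataFrame(skipped_subjects)], ignore_index=True
        )

    processed: list[ProcessedTrial] = []
    for t in kept:
        corrected = drift_correct(
            t.events.fixations, t.baseline, t.meta.cross_position_px
        )
        scene_fix = [
            f for f in corrected if f.onset_ms >= t.meta.stimulus_onset_ms
        ]
        retained = fixation_density.discard_first_fixation(
            scene_fix, t.meta.stimulus_onset_ms
        )
        pre, post = fixation_density.split_by_response(
            retained, t.meta.click_time_ms
        )
        processed.append(
            ProcessedTrial(
                meta=t.meta,
                events=t.events,
                baseline=t.baseline,
                fixations_corrected=retained,
                pre_fixations=pre,
                post_fixations=post,
            )
        )
    return processed, report


def metrics_table(
    trials: list[ProcessedTrial],
    dataset: Dataset,
    sigma_px: float = 36.0,
    windows: tuple[str, ...] = ("pre_response", "post_response"),
) -> pd.DataFrame:
    """Tidy metric rows: subject x stimulus x task x ROI x window.

    Metrics: raw and area-normalized fixation-density proportions plus the
    fixation-count variant, per the processed trials' corrected fixations.
    """
    rows = []
    for t in trials:
        scene = dataset.scenes[t.meta.stimulus_id]
        size = (scene.roiset.labels.shape[1], scene.roiset.labels.shape[0])
        for window in windows:
            fixes = t.pre_fixations if window == "pre_response" else t.post_fixations
            if not fixes:
                continue
            dmap = fixation_density.build_density_map(
                fixes, size, sigma_px=sigma_px, discard_first=False, window=window
            )
            for roi in ("head", "body", "low_sal", "high_sal"):
                raw, norm = attention_metrics.roi_density_score(
                    dmap, scene.roiset, roi
                )
                craw, cnorm = attention_metrics.fixation_count_score(
                    fixes, scene.roiset, roi
                )
                rows.append(
                    {
                        "subject": t.meta.subject_id,
                        "stimulus": t.meta.stimulus_id,
                        "task": t.meta.task,
                        "category": t.meta.category,
                        "roi": roi,
                        "window": window,
                        "density_raw": raw,
                        "density_norm": norm,
                        "count_raw": craw,
                        "count_norm": cnorm,
                    }
                )
    return pd.DataFrame(rows)


def first_fixation_table(
    trials: list[ProcessedTrial], dataset: Dataset, n_fix: int = 3
) -> pd.DataFrame:
    """Per-subject first-fixation frequencies over social scenes.

    Excludes replaced-baseline trials (gaze start position unknown) and
    non-social stimuli; scores are normalized by the mean ROI area across
    the social scenes of the dataset.
    """
    social_roisets = {
        sid: s.roiset for sid, s in dataset.scenes.items() if s.category == "social"
    }
    rows = []
    by_subject: dict[str, list] = {}
    for t in trials:
        if t.baseline.status != "valid":
            continue
        if t.meta.stimulus_id not in social_roisets:
            continue
        by_subject.setdefault(t.meta.subject_id, []).append(
            (t.meta.stimulus_id, t.fixations_corrected)
        )
    for subject, pairs in by_subject.items():
        table = attention_metrics.first_fixation_frequencies(
            pairs, social_roisets, n_fix=n_fix
        )
        table.insert(0, "subject", subject)
        rows.append(table)
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)
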