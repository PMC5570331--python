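"""Outcome measures: ROI density scores, first-fixation frequencies, RTs.

All ROI scores come in a raw (proportion-of-total) and an area-normalized
flavor; the normalized score equals 1 under spatially uniform viewing.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from scenegaze.fixation_density import DensityMap
from scenegaze.gaze_preprocess import FixationEvent
from scenegaze.io_core import TrialMeta
from scenegaze.roi_partition import CATEGORY_LABELS, RoiSet

__all__ = [
    "roi_density_score",
    "roi_density_scores",
    "fixation_count_score",
    "classify_fixation",
    "first_fixation_frequencies",
    "reaction_time",
]


def roi_density_score(
    dmap: DensityMap, roiset: RoiSet, roi: str
) -> tuple[float, float]:
    """(raw proportion, area-normalized score) of one ROI's density share.

    raw = sum of density inside the ROI / sum over the image;
    normalized = raw / (ROI area / image area).  Returns ``(nan, nan)`` for
    an all-zero map or an empty ROI (missing, not zero).
    """
    values = np.asarray(dmap.values, dtype=float)
    total = float(values.sum())
    mask = roiset.mask(roi)
    area = int(mask.sum())
    if total == 0.0 or area == 0:
        return math.nan, math.nan
    raw = float(values[mask].sum()) / total
    normalized = raw / (area / roiset.image_area)
    return raw, normalized


def roi_density_scores(dmap: DensityMap, roiset: RoiSet) -> pd.DataFrame:
    """Raw + normalized density scores for every category, tidy."""
    rows = []
    for roi in CATEGORY_LABELS:
        raw, norm = roi_density_score(dmap, roiset, roi)
        rows.append({"roi": roi, "raw": raw, "normalized": norm})
    return pd.DataFrame(rows)


def classify_fixation(f: FixationEvent, roiset: RoiSet) -> str | None:
    """Category containing the fixation's rounded pixel, or None off-image."""
    h, w = roiset.labels.shape
    xi, yi = int(round(f.x_px)), int(round(f.y_px))
    if not (0 <= xi < w and 0 <= yi < h):
        return None
    value = int(roiset.labels[yi, xi])
    for name, lab in CATEGORY_LABELS.items():
        if lab == value:
            return name
    return None


def fixation_count_score(
    fixations: Sequence[FixationEvent], roiset: RoiSet, roi: str
) -> tuple[float, float]:
    """Like :func:`roi_density_score` but each fixation counts 1 (no
    duration weighting, no smoothing).  Off-image fixations are ignored."""
    cats = [classify_fixation(f, roiset) for f in fixations]
    cats = [c for c in cats if c is not None]
    if not cats:
        return math.nan, math.nan
    area = int(roiset.mask(roi).sum())
    if area == 0:
        return math.nan, math.nan
    raw = sum(c == roi for c in cats) / len(cats)
    return raw, raw / (area / roiset.image_area)


def first_fixation_frequencies(
    trials: Sequence[tuple[str, Sequence[FixationEvent]]],
    roisets: Mapping[str, RoiSet],
    n_fix: int = 3,
) -> pd.DataFrame:
    """Per-ROI relative frequencies of the first ``n_fix`` fixations.

    ``trials`` holds ``(stimulus_id, fixations)`` pairs where the fixation
    lists are drift-corrected, have the trial-initial overlapping fixation
    already discarded, and exclude replaced-baseline trials.  For each
    fixation index the relative frequency of a category is its count over
    the count of all classified fixations at that index; the normalized
    score divides by (mean category area across the supplied scenes /
    image area).  Indices with zero classifiable fixations give missing
    values.
    """
    scene_ids = sorted({sid for sid, _ in trials})
    if not scene_ids:
        raise ValueError("no trials supplied")
    image_area = next(iter(roisets.values())).image_area
    mean_area = {
        cat: float(np.mean([roisets[sid].mask(cat).sum() for sid in scene_ids]))
        for cat in CATEGORY_LABELS
    }

    rows = []
    for index in range(1, n_fix + 1):
        cats = []
        for sid, fixations in trials:
            if len(fixations) >= index:
                c = classify_fixation(fixations[index - 1], roisets[sid])
                if c is not None:
                    cats.append(c)
        total = len(cats)
        for cat in CATEGORY_LABELS:
            if total == 0 or mean_area[cat] == 0:
                freq = norm = math.nan
            else:
                freq = sum(c == cat for c in cats) / total
                norm = freq / (mean_area[cat] / image_area)
            rows.append(
                {
                    "fixation_index": index,
                    "roi": cat,
                    "relative_frequency": freq,
                    "normalized": norm,
                    "n_classified": total,
                }
            )
    return pd.DataFrame(rows)


def reaction_time(meta: TrialMeta) -> float:
    """Click time minus stimulus onset; no click -> the full presentation."""
    if meta.click_time_ms is None:
        return float(meta.presentation_ms)
    return float(meta.click_time_ms - meta.stimulus_onset_ms)
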