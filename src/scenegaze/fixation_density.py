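"""Duration-weighted, Gaussian-smoothed, max-normalized fixation maps.

Each retained fixation adds its duration (ms) at its rounded pixel
position; the grid is convolved with an isotropic Gaussian (SD 36 px at
the reference 1200x900 stimulus size, kernel truncated at 4 SD, mass
falling off-image lost) and divided by its maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from scenegaze.gaze_preprocess import FixationEvent

__all__ = [
    "DensityMap",
    "split_by_response",
    "discard_first_fixation",
    "build_density_map",
]


@dataclass
class DensityMap:
    values: np.ndarray  # (h, w), in [0, 1]
    window: str = "whole"  # pre_response | post_response | whole
    n_fixations_used: int = 0
    n_dropped_off_image: int = 0


def split_by_response(
    fixations: Sequence[FixationEvent], click_ms: float | None
) -> tuple[list[FixationEvent], list[FixationEvent]]:
    """Split fixations into pre-/post-response windows at the mouse click.

    A fixation spanning the click is cut into two events at the click time,
    with durations apportioned; total duration is conserved.  With no click
    everything is pre-response (free viewing: the whole presentation).
    """
    if click_ms is None:
        return list(fixations), []
    pre: list[FixationEvent] = []
    post: list[FixationEvent] = []
    for f in fixations:
        if f.offset_ms <= click_ms:
            pre.append(f)
        elif f.onset_ms >= click_ms:
            post.append(f)
        else:
            pre.append(replace(f, offset_ms=click_ms))
            post.append(replace(f, onset_ms=click_ms))
    return pre, post


def discard_first_fixation(
    fixations: Sequence[FixationEvent], stimulus_onset_ms: float
) -> list[FixationEvent]:
    """Drop the first fixation whose onset follows stimulus onset.

    Applied once per trial before any pre/post split: that fixation usually
    continues the pre-stimulus fixation period and carries no scene-driven
    information.
    """
    out = list(fixations)
    for i, f in enumerate(out):
        if f.onset_ms >= stimulus_onset_ms:
            del out[i]
            break
    return out


def build_density_map(
    fixations: Sequence[FixationEvent],
    size_px: tuple[int, int],
    sigma_px: float = 36.0,
    discard_first: bool = True,
    truncate_sd: float = 4.0,
    window: str = "whole",
) -> DensityMap:
    """Duration-weighted density map over a (width, height) grid.

    ``discard_first`` drops the first fixation of the given sequence (use
    :func:`discard_first_fixation` instead when the trial is split into
    windows first).  Fixations whose rounded position lies within
    ``truncate_sd * sigma_px`` outside the grid still contribute their
    on-image Gaussian tail; fixations further out are dropped and counted.
    """
    w, h = size_px
    if w <= 0 or h <= 0:
        raise ValueError("size_px must be positive")
    fixes = list(fixations)
    if discard_first and fixes:
        fixes = fixes[1:]

    pad = int(math.ceil(truncate_sd * sigma_px))
    grid = np.zeros((h + 2 * pad, w + 2 * pad))
    used = 0
    dropped = 0
    for f in fixes:
        xi = int(round(f.x_px)) + pad
        yi = int(round(f.y_px)) + pad
        if 0 <= xi < w + 2 * pad and 0 <= yi < h + 2 * pad:
            grid[yi, xi] += f.duration_ms
            used += 1
        else:
            dropped += 1

    if used:
        grid = ndimage.gaussian_filter(
            grid, sigma=sigma_px, mode="constant", truncate=truncate_sd
        )
    values = grid[pad : pad + h, pad : pad + w].copy()
    peak = float(values.max())
    if peak > 0:
        values /= peak
    return DensityMap(
        values=values,
        window=window,
        n_fixations_used=used,
        n_dropped_off_image=dropped,
    )


def build_density_map_raw(
    fixations: Sequence[FixationEvent],
    size_px: tuple[int, int],
    sigma_px: float = 36.0,
    discard_first: bool = True,
    truncate_sd: float = 4.0,
) -> np.ndarray:
    """Unnormalized (pre-max-division) density grid; used by linearity tests."""
    w, h = size_px
    fixes = list(fixations)
    if discard_first and fixes:
        fixes = fixes[1:]
    pad = int(math.ceil(truncate_sd * sigma_px))
    grid = np.zeros((h + 2 * pad, w + 2 * pad))
    for f in fixes:
        xi = int(round(f.x_px)) + pad
        yi = int(round(f.y_px)) + pad
        if 0 <= xi < w + 2 * pad and 0 <= yi < h + 2 * pad:
            grid[yi, xi] += f.duration_ms
    if grid.any():
        grid = ndimage.gaussian_filter(
            grid, sigma=sigma_px, mode="constant", truncate=truncate_sd
        )
    return grid[pad : pad + h, pad : pad + w].copy()
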