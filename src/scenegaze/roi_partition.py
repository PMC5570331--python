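"""Four-way ROI partition of a scene: head, body, low- and high-saliency.

Head/body pixels come verbatim from hand-drawn (or synthetic) masks; the
remaining pixels are split at a percentile of their own saliency
distribution (ties at the cutoff go to the low-saliency side).  The same
rule optionally dissociates each social category by its internal saliency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage.measure import label as cc_label

from scenegaze.scene_saliency import SaliencyMap

__all__ = [
    "RoiSet",
    "CATEGORY_LABELS",
    "SUB_LABELS",
    "build_roiset",
    "split_social_by_saliency",
    "count_rois",
    "relative_roi_saliency",
    "percentile_cutoff",
]

HEAD, BODY, LOW_SAL, HIGH_SAL = 1, 2, 3, 4
CATEGORY_LABELS: dict[str, int] = {
    "head": HEAD,
    "body": BODY,
    "low_sal": LOW_SAL,
    "high_sal": HIGH_SAL,
}
SUB_LABELS = ("head_low", "head_high", "body_low", "body_high", "bg_low", "bg_high")


@dataclass
class RoiSet:
    """Mutually exclusive, jointly exhaustive pixel categories of a scene."""

    labels: np.ndarray  # int grid of CATEGORY_LABELS values
    sub_labels: np.ndarray | None = None  # optional within-social saliency split

    def mask(self, category: str) -> np.ndarray:
        return self.labels == CATEGORY_LABELS[category]

    def sub_mask(self, sub: str) -> np.ndarray:
        if self.sub_labels is None:
            raise ValueError("sub-labels not built; call split_social_by_saliency")
        return self.sub_labels == SUB_LABELS.index(sub) + 1

    @property
    def areas(self) -> dict[str, int]:
        return {c: int(self.mask(c).sum()) for c in CATEGORY_LABELS}

    @property
    def image_area(self) -> int:
        return int(self.labels.size)


def percentile_cutoff(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the value at rank ceil(q/100 * N) (1-based)."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(v)
    if n == 0:
        raise ValueError("cannot take a percentile of an empty set")
    rank = max(1, math.ceil(q / 100.0 * n))
    return float(v[min(rank, n) - 1])


def build_roiset(
    mask: Mapping[str, np.ndarray] | None,
    saliency: SaliencyMap,
    q: float = 80.0,
) -> RoiSet:
    """Build the 4-way partition for one scene.

    ``mask`` maps 'head'/'body' to boolean grids (head wins where they
    overlap) or is None for non-social scenes.  The percentile is computed
    over the saliency values of the non-social pixels only; values <= the
    cutoff become low-saliency, the rest high-saliency.
    """
    sal = np.asarray(saliency.values, dtype=float)
    labels = np.zeros(sal.shape, dtype=np.int8)
    if mask is not None:
        for name in mask:
            if name not in ("head", "body"):
                raise ValueError(f"unexpected mask category {name!r}")
        body = np.asarray(mask.get("body", np.zeros(sal.shape, bool)), dtype=bool)
        head = np.asarray(mask.get("head", np.zeros(sal.shape, bool)), dtype=bool)
        if body.shape != sal.shape or head.shape != sal.shape:
            raise ValueError("mask dimensions do not match the saliency map")
        labels[body] = BODY
        labels[head] = HEAD  # head wins overlaps
    remaining = labels == 0
    cutoff = percentile_cutoff(sal[remaining], q)
    low = remaining & (sal <= cutoff)
    labels[low] = LOW_SAL
    labels[remaining & ~low] = HIGH_SAL
    return RoiSet(labels=labels)


def split_social_by_saliency(
    roiset: RoiSet, saliency: SaliencyMap, q: float = 80.0
) -> RoiSet:
    """Dissociate head/body by internal saliency; background keeps its split.

    Returns a new RoiSet carrying ``sub_labels`` over
    {head_low, head_high, body_low, body_high, bg_low, bg_high}.
    """
    sal = np.asarray(saliency.values, dtype=float)
    sub = np.zeros(sal.shape, dtype=np.int8)
    for category, (lo_name, hi_name) in (
        ("head", ("head_low", "head_high")),
        ("body", ("body_low", "body_high")),
    ):
        m = roiset.mask(category)
        if not m.any():
            continue
        cutoff = percentile_cutoff(sal[m], q)
        low = m & (sal <= cutoff)
        sub[low] = SUB_LABELS.index(lo_name) + 1
        sub[m & ~low] = SUB_LABELS.index(hi_name) + 1
    sub[roiset.mask("low_sal")] = SUB_LABELS.index("bg_low") + 1
    sub[roiset.mask("high_sal")] = SUB_LABELS.index("bg_high") + 1
    return RoiSet(labels=roiset.labels, sub_labels=sub)


def count_rois(roiset: RoiSet, connectivity: int = 8) -> dict[str, int]:
    """Connected-component count per category (4- or 8-connectivity)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    counts = {}
    for name in CATEGORY_LABELS:
        m = roiset.mask(name)
        counts[name] = int(cc_label(m, connectivity=conn).max()) if m.any() else 0
    return counts


def relative_roi_saliency(
    roiset: RoiSet, saliency: SaliencyMap
) -> dict[str, float]:
    """Mean saliency inside each category divided by the whole-scene mean.

    Empty categories are reported as ``nan`` (missing), not zero.
    """
    sal = np.asarray(saliency.values, dtype=float)
    scene_mean = float(sal.mean())
    out = {}
    for name in CATEGORY_LABELS:
        m = roiset.mask(name)
        if not m.any() or scene_mean == 0.0:
            out[name] = math.nan
        else:
            out[name] = float(sal[m].mean() / scene_mean)
    return out
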