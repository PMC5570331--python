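"""Synthetic scenes and gaze recordings with known ground truth.

Scenes contain planted "head" and "body" regions plus colored distractor
blobs that give the saliency stage real contrast to work with.  Gaze is
simulated at 1000 Hz: a pre-stimulus phase fixating the cross, then
alternating fixations (gamma-distributed durations, ROI targets drawn
from preference weights) and saccades with a raised-cosine velocity
profile guaranteed to exceed the detection threshold.  Everything is
deterministic under a master seed (child seeds per subject x trial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from scenegaze.io_core import (
    GazeRecording,
    ScreenGeometry,
    TrialMeta,
    DEFAULT_GEOMETRY,
    degrees_per_pixel,
)
from scenegaze.roi_partition import CATEGORY_LABELS, RoiSet, build_roiset
from scenegaze.scene_saliency import SaliencyParams, compute_saliency

__all__ = [
    "SceneSpec",
    "GazeSimSpec",
    "DatasetDesign",
    "GroundTruthEvent",
    "GroundTruth",
    "SceneData",
    "Dataset",
    "generate_scene",
    "simulate_trial",
    "simulate_dataset",
    "PlacementError",
    "SimulationError",
]


class PlacementError(RuntimeError):
    """Planted regions could not be placed without overlap."""


class SimulationError(RuntimeError):
    """Gaze simulation hit an impossible configuration (e.g. empty target ROI)."""


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    size_px: tuple[int, int] = (1200, 900)  # (width, height)
    n_heads: int = 5
    n_bodies: int = 5
    n_distractors: int = 8
    head_radius_frac: tuple[float, float] = (0.02, 0.04)  # of image width
    body_size_frac: tuple[float, float] = (0.03, 0.06)
    distractor_radius_frac: tuple[float, float] = (0.03, 0.06)
    max_retries: int = 2000
    seed: int = 0


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return xx * xx + yy * yy <= radius * radius


def _place(
    occupied: np.ndarray,
    shape_mask: np.ndarray,
    rng: np.random.Generator,
    max_retries: int,
    margin: int = 2,
) -> tuple[int, int]:
    """Find a top-left anchor where *shape_mask* (dilated by margin) fits."""
    from scipy import ndimage

    h, w = occupied.shape
    sh, sw = shape_mask.shape
    if sh + 2 * margin >= h or sw + 2 * margin >= w:
        raise PlacementError("region larger than the scene")
    grown = ndimage.binary_dilation(shape_mask, iterations=margin)
    for _ in range(max_retries):
        y = int(rng.integers(margin, h - sh - margin))
        x = int(rng.integers(margin, w - sw - margin))
        window = occupied[y - margin : y - margin + grown.shape[0],
                          x - margin : x - margin + grown.shape[1]]
        if not (window & grown).any():
            return y, x
    raise PlacementError(
        f"could not place a region after {max_retries} retries"
    )


def generate_scene(
    spec: SceneSpec,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Deterministically render one scene.

    Returns ``(image, masks)`` with a float RGB image in [0, 1] and boolean
    masks for the planted head and body regions.  Heads are mid-gray disks,
    bodies darker rectangles; distractors are bright colored blobs that
    create genuine luminance/color contrast.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.size_px
    image = np.empty((h, w, 3))
    # smooth background gradient, low amplitude
    gy = np.linspace(0.35, 0.45, h)[:, None]
    gx = np.linspace(0.0, 0.05, w)[None, :]
    image[...] = (gy + gx)[..., None]

    occupied = np.zeros((h, w), dtype=bool)
    head_mask = np.zeros((h, w), dtype=bool)
    body_mask = np.zeros((h, w), dtype=bool)

    def frac_radius(lo_hi: tuple[float, float]) -> int:
        lo, hi = lo_hi
        return max(2, int(round(rng.uniform(lo, hi) * w)))

    for _ in range(spec.n_heads):
        r = frac_radius(spec.head_radius_frac)
        shape = _disk(r)
        y, x = _place(occupied, shape, rng, spec.max_retries)
        sl = (slice(y, y + shape.shape[0]), slice(x, x + shape.shape[1]))
        head_mask[sl] |= shape
        occupied[sl] |= shape
        image[sl][shape] = (0.75, 0.62, 0.52)  # skin-toned disk

    for _ in range(spec.n_bodies):
        bw = frac_radius(spec.body_size_frac)
        bh = int(bw * rng.uniform(1.8, 2.6))
        shape = np.ones((bh, bw), dtype=bool)
        y, x = _place(occupied, shape, rng, spec.max_retries)
        sl = (slice(y, y + bh), slice(x, x + bw))
        body_mask[sl] |= shape
        occupied[sl] |= shape
        image[sl][shape] = (0.30, 0.28, 0.40)  # clothed torso

    palette = [
        (0.95, 0.15, 0.10),
        (0.10, 0.35, 0.95),
        (0.95, 0.90, 0.10),
        (0.10, 0.85, 0.30),
        (0.95, 0.95, 0.95),
        (0.05, 0.05, 0.05),
    ]
    for i in range(spec.n_distractors):
        r = frac_radius(spec.distractor_radius_frac)
        shape = _disk(r)
        y, x = _place(occupied, shape, rng, spec.max_retries)
        sl = (slice(y, y + shape.shape[0]), slice(x, x + shape.shape[1]))
        occupied[sl] |= shape
        image[sl][shape] = palette[int(rng.integers(len(palette)))]

    # mild texture so intensity is never perfectly uniform anywhere
    image += rng.normal(0.0, 0.004, size=image.shape)
    return np.clip(image, 0.0, 1.0), {"head": head_mask, "body": body_mask}


# ---------------------------------------------------------------------------
# gaze simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GazeSimSpec:
    """Statistical structure of simulated gaze."""

    preference_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "head": 0.4, "body": 0.2, "low_sal": 0.2, "high_sal": 0.2
        }
    )
    fixation_shape: float = 4.0
    fixation_mean_ms: float = 250.0
    min_fixation_ms: float = 60.0
    saccade_vpeak_deg_s: tuple[float, float] = (200.0, 400.0)
    min_saccade_ms: float = 6.0
    min_saccade_amp_deg: float = 1.0
    # white per-sample jitter; at 1000 Hz the acceleration criterion turns
    # noisy above ~0.5 px SD, so the default stays comfortably below that
    noise_sd_px: float = 0.3
    drift_sd_px: float = 5.0
    detection_vel_thresh_deg_s: float = 30.0
    detection_acc_thresh_deg_s2: float = 8000.0
    blink_rate_hz: float = 0.05
    blink_dur_ms: tuple[float, float] = (100.0, 300.0)
    click_mean_ms: Mapping[str, float] = field(
        default_factory=lambda: {"define": 2500.0, "count": 4500.0, "estimate": 3500.0}
    )
    click_shape: float = 6.0
    respond_prob: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.preference_weights.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"preference weights must sum to 1, got {total}")
        if any(v < 0 for v in self.preference_weights.values()):
            raise ValueError("preference weights must be nonnegative")


@dataclass(frozen=True)
class GroundTruthEvent:
    kind: str  # "fixation" | "saccade"
    onset_ms: float
    offset_ms: float
    x_px: float = math.nan
    y_px: float = math.nan
    category: str | None = None
    peak_velocity_deg_s: float = math.nan
    # for saccades: span where the velocity profile exceeds the detection
    # threshold -- what a threshold detector can actually see (the
    # raised-cosine ramp starts below any finite velocity threshold)
    detectable_onset_ms: float = math.nan
    detectable_offset_ms: float = math.nan


@dataclass
class GroundTruth:
    events: list[GroundTruthEvent]
    drift_px: tuple[float, float]

    @property
    def fixations(self) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == "fixation"]

    @property
    def saccades(self) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == "saccade"]


def _raised_cosine_positions(n: int) -> np.ndarray:
    """Fraction of the displacement covered after samples 1..n of a saccade.

    Velocity profile v(t) ~ (1 - cos(2 pi t / D)) / 2; its integral gives
    g(t) = t/D - sin(2 pi t / D) / (2 pi), with g(D) = 1.
    """
    t = np.arange(1, n + 1) / n
    return t - np.sin(2 * np.pi * t) / (2 * np.pi)


def simulate_trial(
    roiset: RoiSet,
    meta: TrialMeta,
    sim: GazeSimSpec,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
    rng: np.random.Generator | None = None,
    drift_px: tuple[float, float] | None = None,
) -> tuple[GazeRecording, GroundTruth]:
    """Simulate one trial's 1000 Hz gaze stream over a partitioned scene.

    The stream covers ``[0, stimulus_onset + presentation)``: first a
    fixation on the cross (baseline phase), then alternating saccades and
    ROI-targeted fixations.  A constant per-trial drift offset is added to
    every sample; blinks flag samples invalid.  Ground-truth event
    boundaries, target ROIs and the drift are returned alongside.
    """
    rng = np.random.default_rng() if rng is None else rng
    onset = meta.stimulus_onset_ms
    total_ms = onset + meta.presentation_ms
    n = int(round(total_ms))  # 1 ms per sample
    dt_ms = 1.0

    # per-category pixel coordinates available as landing points
    pixels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cat in CATEGORY_LABELS:
        ys, xs = np.nonzero(roiset.mask(cat))
        pixels[cat] = (ys, xs)
        if sim.preference_weights.get(cat, 0.0) > 0 and len(ys) == 0:
            raise SimulationError(
                f"preference weight on empty ROI category {cat!r}"
            )

    deg_pp = 0.5 * (
        degrees_per_pixel("horizontal", geom) + degrees_per_pixel("vertical", geom)
    )
    cats = [c for c in CATEGORY_LABELS if sim.preference_weights.get(c, 0.0) > 0]
    probs = np.array([sim.preference_weights[c] for c in cats])
    probs = probs / probs.sum()

    x = np.empty(n)
    y = np.empty(n)
    events: list[GroundTruthEvent] = []

    cross = meta.cross_position_px
    x[: int(onset)] = cross[0]
    y[: int(onset)] = cross[1]
    events.append(GroundTruthEvent("fixation", 0.0, onset, cross[0], cross[1], None))

    def sample_target(cur: tuple[float, float]) -> tuple[float, float, str]:
        best = None
        best_dist = -1.0
        for _ in range(60):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            ys, xs = pixels[cat]
            j = int(rng.integers(len(ys)))
            tx, ty = float(xs[j]), float(ys[j])
            dist_deg = math.hypot(tx - cur[0], ty - cur[1]) * deg_pp
            if dist_deg >= sim.min_saccade_amp_deg:
                return tx, ty, cat
            if dist_deg > best_dist:
                best, best_dist = (tx, ty, cat), dist_deg
        if best is None or best_dist <= 0:
            raise SimulationError("cannot find a saccade target away from gaze")
        return best

    t = int(onset)
    cur = (float(cross[0]), float(cross[1]))
    while t < n:
        tx, ty, cat = sample_target(cur)
        amp_deg = math.hypot(tx - cur[0], ty - cur[1]) * deg_pp
        vpeak = float(rng.uniform(*sim.saccade_vpeak_deg_s))
        dur_ms = max(sim.min_saccade_ms, 2.0 * amp_deg / vpeak * 1000.0)
        n_sac = max(int(sim.min_saccade_ms), int(round(dur_ms)))
        n_sac = min(n_sac, n - t)
        if n_sac <= 0:
            break
        frac = _raised_cosine_positions(n_sac)
        x[t : t + n_sac] = cur[0] + (tx - cur[0]) * frac
        y[t : t + n_sac] = cur[1] + (ty - cur[1]) * frac
        actual_vpeak = 2.0 * amp_deg / (n_sac / 1000.0)
        # per-sample speed of the profile (deg/s) and its super-threshold span
        step = np.diff(np.concatenate(([0.0], frac)))
        speed = amp_deg * step * 1000.0
        acc = np.abs(np.diff(np.concatenate(([0.0], speed)))) * 1000.0
        above = np.flatnonzero(
            (speed > sim.detection_vel_thresh_deg_s)
            | (acc > sim.detection_acc_thresh_deg_s2)
        )
        det_on = float(t + above[0]) if len(above) else math.nan
        det_off = float(t + above[-1] + 1) if len(above) else math.nan
        events.append(
            GroundTruthEvent(
                "saccade", float(t), float(t + n_sac),
                peak_velocity_deg_s=actual_vpeak,
                detectable_onset_ms=det_on,
                detectable_offset_ms=det_off,
            )
        )
        t += n_sac
        if t >= n:
            break

        fix_ms = rng.gamma(
            sim.fixation_shape, sim.fixation_mean_ms / sim.fixation_shape
        )
        n_fix = max(int(sim.min_fixation_ms), int(round(fix_ms)))
        n_fix = min(n_fix, n - t)
        x[t : t + n_fix] = tx
        y[t : t + n_fix] = ty
        events.append(
            GroundTruthEvent("fixation", float(t), float(t + n_fix), tx, ty, cat)
        )
        t += n_fix
        cur = (tx, ty)

    if drift_px is None:
        drift = (
            float(rng.normal(0.0, sim.drift_sd_px)),
            float(rng.normal(0.0, sim.drift_sd_px)),
        )
    else:
        drift = (float(drift_px[0]), float(drift_px[1]))
    x += drift[0]
    y += drift[1]
    if sim.noise_sd_px > 0:
        x += rng.normal(0.0, sim.noise_sd_px, size=n)
        y += rng.normal(0.0, sim.noise_sd_px, size=n)

    valid = np.ones(n, dtype=bool)
    n_blinks = int(rng.poisson(sim.blink_rate_hz * total_ms / 1000.0))
    for _ in range(n_blinks):
        b0 = int(rng.integers(0, n))
        bdur = int(rng.uniform(*sim.blink_dur_ms))
        valid[b0 : b0 + bdur] = False

    rec = GazeRecording(
        trial_id=meta.trial_id,
        time_ms=np.arange(n, dtype=float) * dt_ms,
        x_px=x,
        y_px=y,
        valid=valid,
        sample_rate_hz=1000.0,
    )
    return rec, GroundTruth(events=events, drift_px=drift)


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetDesign:
    """Trial layout: every subject sees every stimulus under every task."""

    tasks: tuple[str, ...] = ("free", "define", "count", "estimate")
    n_social: int = 15
    n_nonsocial: int = 15
    scene: SceneSpec = SceneSpec()
    presentation_ms: float = 10_000.0
    pre_stimulus_ms: float = 2_000.0
    saliency: SaliencyParams = SaliencyParams()
    roi_percentile: float = 80.0


@dataclass
class SceneData:
    stimulus_id: str
    category: str
    image: np.ndarray
    masks: dict[str, np.ndarray] | None
    saliency: object
    roiset: RoiSet


@dataclass
class Dataset:
    scenes: dict[str, SceneData]
    metas: list[TrialMeta]
    recordings: dict[str, GazeRecording]
    ground_truth: dict[str, GroundTruth]


def _child_rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def build_scene_set(design: DatasetDesign, master_seed: int) -> dict[str, SceneData]:
    """Generate the stimulus pool: scenes, saliency maps and ROI partitions."""
    scenes: dict[str, SceneData] = {}
    idx = 0
    for category, count, social in (
        ("social", design.n_social, True),
        ("nonsocial", design.n_nonsocial, False),
    ):
        for _ in range(count):
            seed = int(_child_rng(master_seed, 0, idx).integers(2**31))
            spec = SceneSpec(
                size_px=design.scene.size_px,
                n_heads=design.scene.n_heads if social else 0,
                n_bodies=design.scene.n_bodies if social else 0,
                n_distractors=design.scene.n_distractors,
                head_radius_frac=design.scene.head_radius_frac,
                body_size_frac=design.scene.body_size_frac,
                distractor_radius_frac=design.scene.distractor_radius_frac,
                max_retries=design.scene.max_retries,
                seed=seed,
            )
            image, masks = generate_scene(spec)
            smap = compute_saliency(image, design.saliency)
            roiset = build_roiset(
                masks if social else None, smap, design.roi_percentile
            )
            stim_id = f"stim{idx:03d}"
            scenes[stim_id] = SceneData(
                stimulus_id=stim_id,
                category=category,
                image=image,
                masks=masks if social else None,
                saliency=smap,
                roiset=roiset,
            )
            idx += 1
    return scenes


def simulate_dataset(
    n_subjects: int,
    design: DatasetDesign,
    sim: GazeSimSpec,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
    master_seed: int = 0,
    scenes: dict[str, SceneData] | None = None,
) -> Dataset:
    """Simulate a full session: scenes + one trial per subject x task x stimulus.

    Child seeds derive deterministically from ``master_seed`` so the same
    seed reproduces the dataset bit-for-bit.  A pre-built ``scenes`` pool
    may be supplied to share stimuli across independent simulated cohorts.
    """
    if scenes is None:
        scenes = build_scene_set(design, master_seed)

    metas: list[TrialMeta] = []
    recordings: dict[str, GazeRecording] = {}
    ground_truth: dict[str, GroundTruth] = {}

    w, h = design.scene.size_px
    cross = ((w - 1) / 2.0, (h - 1) / 2.0)

    # simulation weights for non-social scenes: social mass re-split over
    # the background categories
    ns_weights = _nonsocial_weights(sim.preference_weights)

    for s_idx in range(n_subjects):
        subject_id = f"sub{s_idx:03d}"
        for t_idx, (task, stim_id) in enumerate(
            (task, stim_id) for task in design.tasks for stim_id in scenes
        ):
            scene = scenes[stim_id]
            rng = _child_rng(master_seed, 1, s_idx, t_idx)
            trial_sim = sim
            if scene.category == "nonsocial":
                trial_sim = _with_weights(sim, ns_weights)

            click: float | None = None
            if task != "free" and rng.uniform() < sim.respond_prob:
                mean = sim.click_mean_ms.get(task, 3000.0)
                rt = rng.gamma(sim.click_shape, mean / sim.click_shape)
                if rt < design.presentation_ms:
                    click = design.pre_stimulus_ms + rt

            meta = TrialMeta(
                subject_id=subject_id,
                trial_id=f"{subject_id}_t{t_idx:03d}",
                stimulus_id=stim_id,
                task=task,
                category=scene.category,
                stimulus_onset_ms=design.pre_stimulus_ms,
                presentation_ms=design.presentation_ms,
                click_time_ms=click,
                cross_position_px=cross,
            )
            rec, gt = simulate_trial(scene.roiset, meta, trial_sim, geom, rng)
            metas.append(meta)
            recordings[meta.trial_id] = rec
            ground_truth[meta.trial_id] = gt

    return Dataset(
        scenes=scenes, metas=metas, recordings=recordings, ground_truth=ground_truth
    )


def _nonsocial_weights(weights: Mapping[str, float]) -> dict[str, float]:
    social = weights.get("head", 0.0) + weights.get("body", 0.0)
    lo = weights.get("low_sal", 0.0)
    hi = weights.get("high_sal", 0.0)
    bg = lo + hi
    if bg == 0:
        return {"head": 0.0, "body": 0.0, "low_sal": 0.5, "high_sal": 0.5}
    return {
        "head": 0.0,
        "body": 0.0,
        "low_sal": lo + social * lo / bg,
        "high_sal": hi + social * hi / bg,
    }


def _with_weights(sim: GazeSimSpec, weights: Mapping[str, float]) -> GazeSimSpec:
    from dataclasses import replace

    return replace(sim, preference_weights=dict(weights))
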