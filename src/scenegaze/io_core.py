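"""Core I/O: gaze tables, images, ROI masks, screen geometry and config.

Coordinate convention: origin at the top-left corner of the raster,
x increases rightward, y downward, 0-based, pixel centers at integer
coordinates.  All times are in milliseconds, all on-screen lengths in
pixels unless a ``_mm`` / ``_deg`` suffix says otherwise.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

logger = logging.getLogger("scenegaze")

TASKS = ("free", "define", "count", "estimate")
CATEGORIES = ("social", "nonsocial")


class GeometryError(ValueError):
    """Raised for non-positive or otherwise invalid screen geometry."""


class SchemaError(ValueError):
    """Raised when a delimited input lacks a required column."""


class DataError(ValueError):
    """Raised for malformed data content (e.g. non-monotone timestamps)."""


# ---------------------------------------------------------------------------
# screen geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen description used for pixel <-> degree conversion."""

    width_mm: float
    height_mm: float
    width_px: int
    height_px: int
    distance_mm: float

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "width_px", "height_px", "distance_mm"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise GeometryError(f"{name} must be finite and > 0, got {value!r}")

    def pitch_mm(self, axis: str) -> float:
        """Physical size of one pixel along *axis* ('horizontal'|'vertical')."""
        if axis == "horizontal":
            return self.width_mm / self.width_px
        if axis == "vertical":
            return self.height_mm / self.height_px
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


#: Reference geometry of the 24" setup the defaults are tuned for.
DEFAULT_GEOMETRY = ScreenGeometry(
    width_mm=516.9, height_mm=323.1, width_px=1920, height_px=1200, distance_mm=500.0
)


def pixels_to_degrees(extent_px, axis: str, geom: ScreenGeometry):
    """Visual angle (degrees) subtended by an extent centred on the line of sight.

    Uses the full-angle formula ``2 * atan(extent_mm / 2 / distance)``.
    Accepts scalars or arrays; monotone increasing in ``extent_px``.
    """
    pitch = geom.pitch_mm(axis)
    extent_px = np.asarray(extent_px, dtype=float)
    out = np.degrees(2.0 * np.arctan2(extent_px * pitch / 2.0, geom.distance_mm))
    return float(out) if out.ndim == 0 else out


def degrees_to_pixels(extent_deg, axis: str, geom: ScreenGeometry):
    """Inverse of :func:`pixels_to_degrees` (same full-angle formula)."""
    pitch = geom.pitch_mm(axis)
    extent_deg = np.asarray(extent_deg, dtype=float)
    out = 2.0 * geom.distance_mm * np.tan(np.radians(extent_deg) / 2.0) / pitch
    return float(out) if out.ndim == 0 else out


def degrees_per_pixel(axis: str, geom: ScreenGeometry) -> float:
    """Local angular size of one pixel at the line of sight (small-extent limit)."""
    return math.degrees(2.0 * math.atan2(geom.pitch_mm(axis) / 2.0, geom.distance_mm))


# ---------------------------------------------------------------------------
# trial metadata and gaze recordings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialMeta:
    """Descriptive metadata of a single trial."""

    subject_id: str
    trial_id: str
    stimulus_id: str
    task: str
    category: str
    stimulus_onset_ms: float
    cross_position_px: tuple[float, float]
    presentation_ms: float = 10_000.0
    click_time_ms: float | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.click_time_ms is not None:
            lo = self.stimulus_onset_ms
            hi = self.stimulus_onset_ms + self.presentation_ms
            if not (lo <= self.click_time_ms <= hi):
                raise ValueError(
                    f"click_time_ms={self.click_time_ms} outside [{lo}, {hi}]"
                )


@dataclass
class GazeRecording:
    """Raw gaze sample stream of one trial (nominal 1000 Hz).

    Invalid (blink) samples are flagged via ``valid`` and never dropped.
    """

    trial_id: str
    time_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise DataError(f"trial {self.trial_id}: sample columns differ in length")
        if n > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise DataError(
                f"trial {self.trial_id}: timestamps not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.time_ms)


DEFAULT_GAZE_SCHEMA: Mapping[str, str] = {
    "trial": "trial_id",
    "time": "time_ms",
    "x": "x_px",
    "y": "y_px",
    "valid": "valid",
}


def parse_gaze_table(
    path: str | Path, schema: Mapping[str, str] = DEFAULT_GAZE_SCHEMA
) -> tuple[dict[str, GazeRecording], pd.DataFrame]:
    """Read a delimited gaze table into one :class:`GazeRecording` per trial.

    Returns ``(recordings, discarded)`` where *discarded* lists every input
    row that was not assigned to a trial, with a reason.  Row count is
    conserved: ``sum(len(rec)) + len(discarded) == n_input_rows``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    tcol, timecol = schema["trial"], schema["time"]
    xcol, ycol, vcol = schema["x"], schema["y"], schema["valid"]

    bad = df[[tcol, timecol, xcol, ycol]].isna().any(axis=1)
    discarded = df.loc[bad].copy()
    discarded["reason"] = "missing required field"
    df = df.loc[~bad]

    recordings: dict[str, GazeRecording] = {}
    for trial_id, grp in df.groupby(tcol, sort=False):
        times = grp[timecol].to_numpy(dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise DataError(
                f"{path}: non-monotone timestamps within trial {trial_id!r}"
            )
        recordings[str(trial_id)] = GazeRecording(
            trial_id=str(trial_id),
            time_ms=times,
            x_px=grp[xcol].to_numpy(dtype=float),
            y_px=grp[ycol].to_numpy(dtype=float),
            valid=grp[vcol].fillna(0).to_numpy(dtype=float) > 0,
        )
    return recordings, discarded


def write_gaze_table(
    recordings: Iterable[GazeRecording], path: str | Path
) -> None:
    """Serialize recordings to the canonical comma-separated dialect."""
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": rec.trial_id,
                    "time_ms": rec.time_ms,
                    "x_px": rec.x_px,
                    "y_px": rec.y_px,
                    "valid": rec.valid.astype(int),
                }
            )
        )
    # %.17g guarantees exact float round-trips through the text dialect
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_trial_meta(metas: Iterable[TrialMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "subject_id": m.subject_id,
                "trial_id": m.trial_id,
                "stimulus_id": m.stimulus_id,
                "task": m.task,
                "category": m.category,
                "stimulus_onset_ms": m.stimulus_onset_ms,
                "presentation_ms": m.presentation_ms,
                "click_time_ms": "" if m.click_time_ms is None else m.click_time_ms,
                "cross_x_px": m.cross_position_px[0],
                "cross_y_px": m.cross_position_px[1],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trial_meta(path: str | Path) -> list[TrialMeta]:
    df = pd.read_csv(path)
    metas = []
    for row in df.itertuples(index=False):
        click = getattr(row, "click_time_ms")
        metas.append(
            TrialMeta(
                subject_id=str(row.subject_id),
                trial_id=str(row.trial_id),
                stimulus_id=str(row.stimulus_id),
                task=str(row.task),
                category=str(row.category),
                stimulus_onset_ms=float(row.stimulus_onset_ms),
                presentation_ms=float(row.presentation_ms),
                click_time_ms=None if pd.isna(click) else float(click),
                cross_position_px=(float(row.cross_x_px), float(row.cross_y_px)),
            )
        )
    return metas


# ---------------------------------------------------------------------------
# images and ROI masks
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/JPEG into a float RGB array in [0, 1], shape (h, w, 3)."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"), dtype=float) / 255.0
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float RGB array in [0, 1] as 8-bit PNG/JPEG."""
    arr = np.clip(np.asarray(image) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def write_grayscale16(values: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grid as 16-bit grayscale PNG (maps, densities)."""
    arr = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 65535).round().astype(np.uint16)).save(path)


def write_mask(
    masks: Mapping[str, np.ndarray],
    path: str | Path,
    color_table: Mapping[str, Sequence[int]] | None = None,
) -> None:
    """Write category masks as an indexed-color PNG + JSON color-table sidecar.

    ``masks`` maps category name -> boolean grid; categories are painted in
    iteration order, later categories overwriting earlier ones.
    """
    path = Path(path)
    if color_table is None:
        palette_default = [(255, 0, 0), (255, 0, 255), (255, 255, 0), (0, 255, 0)]
        color_table = {
            name: palette_default[i % len(palette_default)]
            for i, name in enumerate(masks)
        }
    first = next(iter(masks.values()))
    index_grid = np.zeros(first.shape, dtype=np.uint8)
    palette = [0, 0, 0]  # index 0 = background, black
    for i, (name, mask) in enumerate(masks.items(), start=1):
        index_grid[np.asarray(mask, dtype=bool)] = i
        palette.extend(int(c) for c in color_table[name])
    img = Image.fromarray(index_grid, mode="P")
    img.putpalette(palette)
    img.save(path)
    sidecar = {name: [int(c) for c in color_table[name]] for name in masks}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


class MaskError(ValueError):
    """Raised when a mask color is absent from the sidecar color table."""


def read_mask(path: str | Path) -> dict[str, np.ndarray]:
    """Read an indexed-color mask PNG; returns {category: boolean grid}."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise MaskError(f"missing color-table sidecar {sidecar_path}")
    color_table = json.loads(sidecar_path.read_text())
    with Image.open(path) as img:
        rgb = np.asarray(img.convert("RGB"), dtype=int)
    masks: dict[str, np.ndarray] = {}
    covered = np.all(rgb == 0, axis=-1)
    for name, color in color_table.items():
        hit = np.all(rgb == np.asarray(color, dtype=int), axis=-1)
        masks[name] = hit
        covered |= hit
    if not covered.all():
        colors = {tuple(c) for c in rgb[~covered].reshape(-1, 3)}
        raise MaskError(f"{path}: colors {sorted(colors)} not in color table")
    return masks


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: All tunable thresholds of the pipeline, with the reference defaults.
DEFAULT_CONFIG: dict = {
    "geometry": {
        "width_mm": 516.9,
        "height_mm": 323.1,
        "width_px": 1920,
        "height_px": 1200,
        "distance_mm": 500.0,
    },
    "stimulus": {
        "width_px": 1200,
        "height_px": 900,
        "presentation_ms": 10_000.0,
        "cross_position_px": None,  # None -> image centre
    },
    "saliency": {
        "working_width": 32,
        "working_height": 24,
        "channels": ["intensity", "color", "orientation"],
        "pyramid_levels": [1, 2],
        "sigma_frac": 0.125,  # Gaussian falloff SD as fraction of grid width
        "tol": 1e-10,
        "max_iter": 10_000,
        "teleport": 1e-6,
        "algorithm": "graph",  # or "center_surround"
    },
    "events": {
        "velocity_thresh_deg_s": 30.0,
        "accel_thresh_deg_s2": 8000.0,
        "velocity_window": 5,
        "blink_pad_ms": 25.0,
    },
    "baseline": {
        "window_ms": 300.0,
        "outlier_sd": 3.0,
        "sd_ddof": 1,
    },
    "exclusions": {
        "min_blink_free_frac": 0.8,
        "max_missing_response_frac": 0.25,
        "max_bad_baseline_frac": 0.20,
    },
    "roi": {
        "percentile": 80.0,
        "connectivity": 8,
    },
    "density": {
        "sigma_px": 36.0,
        "truncate_sd": 4.0,
        "discard_first": True,
    },
    "stats": {
        "alpha": 0.05,
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in out:
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file merged over :data:`DEFAULT_CONFIG`.

    Unknown keys raise ``KeyError`` at load time so typos fail fast.
    """
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_merge(DEFAULT_CONFIG, user)


def geometry_from_config(config: Mapping) -> ScreenGeometry:
    g = config["geometry"]
    return ScreenGeometry(
        width_mm=g["width_mm"],
        height_mm=g["height_mm"],
        width_px=g["width_px"],
        height_px=g["height_px"],
        distance_mm=g["distance_mm"],
    )
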