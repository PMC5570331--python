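"""Graph-based saliency maps normalized to [0, 1].

Activation per feature channel is the stationary distribution of a Markov
chain over a coarse working grid: edge weights combine feature
dissimilarity with a Gaussian falloff in grid distance, followed by a
second "concentration" pass whose edges are re-weighted by the target
node's activation.  Channel maps are fused, upsampled to image size and
min-max normalized.  A centre-surround fallback is available behind the
same interface for robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import pyramid_gaussian, resize

__all__ = [
    "SaliencyMap",
    "SaliencyParams",
    "compute_feature_maps",
    "markov_equilibrium",
    "compute_saliency",
    "scene_saliency_summary",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Equilibrium solver failed to converge (reducible/degenerate chain)."""


class SizeError(ValueError):
    """Image smaller than the coarsest working resolution."""


@dataclass
class SaliencyMap:
    """Per-pixel conspicuity in [0, 1], same shape as the source image."""

    values: np.ndarray
    degenerate: bool = False
    channel_maps: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SaliencyParams:
    channels: tuple[str, ...] = ("intensity", "color", "orientation")
    pyramid_levels: tuple[int, ...] = (1, 2)
    working_width: int = 32
    working_height: int = 24
    sigma_frac: float = 0.125  # falloff SD as a fraction of working grid width
    tol: float = 1e-10
    max_iter: int = 10_000
    teleport: float = 1e-6
    algorithm: str = "graph"  # "graph" | "center_surround"


ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)


def _gabor_energy(intensity: np.ndarray, theta_deg: float) -> np.ndarray:
    """Oriented band-pass energy; channel angle = preferred stripe orientation.

    A grating whose stripes run horizontally (intensity varies with y)
    maximally drives the 0 degree channel.
    """
    from skimage.filters import gabor

    # skimage's theta is measured from the x axis toward y for the carrier
    # direction; stripes at angle a need a carrier at a + 90 degrees.
    theta = np.deg2rad(theta_deg + 90.0)
    real, imag = gabor(intensity, frequency=0.25, theta=theta)
    return np.hypot(real, imag)


def compute_feature_maps(
    image: np.ndarray,
    channels: tuple[str, ...] = ("intensity", "color", "orientation"),
    pyramid_levels: tuple[int, ...] = (1, 2),
    working_shape: tuple[int, int] = (24, 32),
) -> dict[str, np.ndarray]:
    """Multi-scale feature grids at the working resolution.

    Returns ``{"<channel>/<subchannel>@<level>": grid}`` with grids of shape
    ``working_shape`` (rows, cols).  Channels: ``intensity`` (mean RGB),
    ``color`` (red-green and blue-yellow opponency) and ``orientation``
    (band-pass energy at 0/45/90/135 degrees).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.size == 0:
        raise SizeError("empty image")
    if image.shape[0] < working_shape[0] or image.shape[1] < working_shape[1]:
        raise SizeError(
            f"image {image.shape[:2]} smaller than working resolution {working_shape}"
        )
    if not channels:
        raise ValueError("at least one channel must be requested")

    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    intensity = image.mean(axis=-1)
    base: dict[str, np.ndarray] = {}
    if "intensity" in channels:
        base["intensity/I"] = intensity
    if "color" in channels:
        base["color/rg"] = r - g
        base["color/by"] = b - (r + g) / 2.0
    if "orientation" in channels:
        for theta in ORIENTATIONS_DEG:
            base[f"orientation/{theta:g}"] = _gabor_energy(intensity, theta)
    unknown = set(channels) - {"intensity", "color", "orientation"}
    if unknown:
        raise ValueError(f"unknown channel(s) {sorted(unknown)}")

    maps: dict[str, np.ndarray] = {}
    max_level = max(pyramid_levels)
    for name, grid in base.items():
        pyramid = list(
            pyramid_gaussian(grid, max_layer=max_level, downscale=2, channel_axis=None)
        )
        for level in pyramid_levels:
            layer = pyramid[level]
            if layer.shape[0] < 2 or layer.shape[1] < 2:
                raise SizeError(f"pyramid level {level} collapses the image")
            maps[f"{name}@{level}"] = resize(
                layer, working_shape, order=1, anti_aliasing=False
            )
    return maps


def markov_equilibrium(
    weights: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    teleport: float = 1e-6,
) -> np.ndarray:
    """Stationary distribution of the row-normalized chain over *weights*.

    A uniform teleportation mass (``teleport``) is mixed in to guarantee
    irreducibility; the result sums to 1 and is a fixed point of the
    transition operator within ``tol``.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    n = w.shape[0]
    w = w + teleport
    rowsum = w.sum(axis=1, keepdims=True)
    if np.any(rowsum <= 0):
        raise ConvergenceError("zero row sum after regularization")
    p = w / rowsum

    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = pi @ p
        nxt /= nxt.sum()
        if np.abs(nxt - pi).sum() < tol:
            return nxt
        pi = nxt
    raise ConvergenceError(
        f"power iteration did not reach tol={tol} in {max_iter} iterations"
    )


def _grid_falloff(shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Pairwise Gaussian falloff exp(-d^2 / (2 sigma^2)) over grid locations."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-d2 / (2.0 * sigma**2))


def _dissimilarity(f: np.ndarray) -> np.ndarray:
    """Pairwise feature dissimilarity: |log ratio| where both positive,
    absolute difference otherwise."""
    flat = f.ravel()
    pos = flat > 0
    diff = np.abs(flat[:, None] - flat[None, :])
    if pos.all():
        with np.errstate(divide="ignore"):
            logf = np.log(flat)
        return np.abs(logf[:, None] - logf[None, :])
    if pos.any():
        out = diff
        logf = np.log(flat[pos])
        sub = np.abs(logf[:, None] - logf[None, :])
        idx = np.flatnonzero(pos)
        out[np.ix_(idx, idx)] = sub
        return out
    return diff


def compute_saliency(image: np.ndarray, params: SaliencyParams | None = None) -> SaliencyMap:
    """Full saliency map of an RGB image, min-max normalized to [0, 1].

    A perfectly uniform image yields an all-zero map with
    ``degenerate=True`` (and a warning) instead of 0/0.
    """
    params = params or SaliencyParams()
    image = np.asarray(image, dtype=float)
    out_shape = image.shape[:2]

    if float(image.max() - image.min()) == 0.0:
        warnings.warn("constant image: returning uniform zero saliency map")
        return SaliencyMap(values=np.zeros(out_shape), degenerate=True)

    if params.algorithm == "center_surround":
        fused = _center_surround_saliency(image, params)
        channel_maps: dict[str, np.ndarray] = {}
    else:
        working_shape = (params.working_height, params.working_width)
        feats = compute_feature_maps(
            image, params.channels, params.pyramid_levels, working_shape
        )
        sigma = params.sigma_frac * params.working_width
        falloff = _grid_falloff(working_shape, sigma)
        channel_maps = {}
        fused = np.zeros(working_shape)
        for name, grid in feats.items():
            if float(grid.max() - grid.min()) == 0.0:
                continue  # no contrast on this channel
            w1 = _dissimilarity(grid) * falloff
            activation = markov_equilibrium(
                w1, params.tol, params.max_iter, params.teleport
            )
            # concentration pass: mass flows toward strongly activated nodes
            w2 = falloff * activation[None, :]
            conc = markov_equilibrium(w2, params.tol, params.max_iter, params.teleport)
            cmap = conc.reshape(working_shape)
            channel_maps[name] = cmap
            fused = fused + cmap

    upsampled = resize(fused, out_shape, order=1, anti_aliasing=False)
    lo, hi = float(upsampled.min()), float(upsampled.max())
    if hi - lo == 0.0:
        warnings.warn("degenerate saliency (no channel contrast): zero map")
        return SaliencyMap(values=np.zeros(out_shape), degenerate=True,
                           channel_maps=channel_maps)
    values = (upsampled - lo) / (hi - lo)
    return SaliencyMap(values=values, degenerate=False, channel_maps=channel_maps)


def _center_surround_saliency(image: np.ndarray, params: SaliencyParams) -> np.ndarray:
    """Itti-Koch-style fallback: centre-surround differences via DoG filtering."""
    intensity = image.mean(axis=-1)
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    feats = [intensity, r - g, b - (r + g) / 2.0]
    acc = np.zeros_like(intensity)
    for f in feats:
        for c_sigma, s_sigma in ((2, 8), (4, 16)):
            center = ndimage.gaussian_filter(f, c_sigma)
            surround = ndimage.gaussian_filter(f, s_sigma)
            acc += np.abs(center - surround)
    working = (params.working_height, params.working_width)
    return resize(resize(acc, working, order=1), image.shape[:2], order=1)


def scene_saliency_summary(smap: SaliencyMap) -> tuple[float, float]:
    """(mean, SD) of the map over all pixels (population SD)."""
    v = np.asarray(smap.values, dtype=float)
    return float(v.mean()), float(v.std())
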