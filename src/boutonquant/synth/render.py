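"""Render per-terminal traces into a 16-bit movie stack.

Each terminal is an isotropic 2-D Gaussian spot whose peak amplitude tracks
its fluorescence trace, drawn over a diffuse background plus a fixed camera
offset, with the same read/shot noise model used for bare traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from boutonquant.errors import ConfigError, GenerationError
from boutonquant.synth.traces import NoiseParams


@dataclass(frozen=True)
class RenderGeometry:
    height: int = 96
    width: int = 96
    psf_sigma: float = 1.5
    min_separation: float = 4.0
    background: float = 20.0
    offset: float = 100.0
    edge_margin: int = 5

    def __post_init__(self) -> None:
        problems = []
        if self.height < 16 or self.width < 16:
            problems.append("image must be at least 16x16")
        if self.psf_sigma <= 0:
            problems.append("psf_sigma must be positive")
        if self.min_separation <= 0:
            problems.append("min_separation must be positive")
        if self.edge_margin < 0 or self.background < 0 or self.offset < 0:
            problems.append("edge_margin, background and offset must be non-negative")
        if problems:
            raise ConfigError(problems)


def _positions_array(terminals) -> np.ndarray:
    pos = []
    for t in terminals:
        p = t.position if hasattr(t, "position") else t
        if p is None:
            raise GenerationError("terminal has no position")
        pos.append(p)
    return np.asarray(pos, dtype=float).reshape(-1, 2)  # (x, y)


def render_movie(terminals, traces: np.ndarray, geometry: RenderGeometry,
                 noise: NoiseParams | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render ``traces`` (n_terminals, n_frames, a.u.) into a (T, H, W) uint16 stack.

    Raises :class:`GenerationError` for out-of-bounds positions or spot pairs
    closer than ``geometry.min_separation``.  Deterministic given ``rng``.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[None, :]
    pos = _positions_array(terminals)
    if pos.shape[0] != traces.shape[0]:
        raise GenerationError("terminal count does not match trace count")
    h, w = geometry.height, geometry.width
    if pos.shape[0]:
        x, y = pos[:, 0], pos[:, 1]
        m = geometry.edge_margin
        if np.any((x < m) | (x > w - 1 - m) | (y < m) | (y > h - 1 - m)):
            raise GenerationError("terminal positions must lie within image bounds/margin")
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 < geometry.min_separation ** 2):
            raise GenerationError(
                f"terminal spots closer than min_separation={geometry.min_separation}")

    n_frames = traces.shape[1]
    signal = np.full((n_frames, h, w), geometry.background, dtype=float)
    half = int(math.ceil(4 * geometry.psf_sigma))
    for (cx, cy), tr in zip(pos, traces):
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        kern = np.exp(-((xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2)
                      / (2 * geometry.psf_sigma ** 2))
        signal[:, y0:y1, x0:x1] += tr[:, None, None] * kern[None, :, :]

    movie = signal + geometry.offset
    if noise is not None and (noise.read_sd > 0 or noise.shot_scale > 0):
        if rng is None:
            rng = np.random.default_rng()
        shot_sd = np.sqrt(noise.shot_scale * np.clip(signal, 0.0, None))
        movie = (movie
                 + rng.standard_normal(movie.shape) * noise.read_sd
                 + rng.standard_normal(movie.shape) * shot_sd)
    return np.clip(np.round(movie), 0, 65535).astype(np.uint16)
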