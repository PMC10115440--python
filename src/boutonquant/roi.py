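"""Punctum detection, circular ROI placement and trace extraction.

The detector replaces the manual step of circling boutons by hand: local
maxima of a difference-of-Gaussians image above a (robust, data-derived)
threshold are accepted greedily in descending intensity with a minimum
pairwise separation.  Each terminal ROI is paired with a nearby, same-radius
background ROI found by a deterministic ring search; terminal traces are
background-corrected by frame-wise subtraction of the partner trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian

from boutonquant.errors import BoutonQuantError


@dataclass(frozen=True)
class Roi:
    roi_id: str
    center: tuple[float, float]  # (x, y) pixels
    radius: float
    kind: str = "terminal"       # terminal | background
    partner: Optional[str] = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.kind not in ("terminal", "background"):
            raise ValueError("kind must be 'terminal' or 'background'")


@dataclass
class Trace:
    values: np.ndarray
    frame_rate: float
    roi_id: str = ""
    corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.values)


def _in_bounds(cx: float, cy: float, radius: float, shape) -> bool:
    h, w = shape
    return (cx - radius >= 0 and cx + radius <= w - 1
            and cy - radius >= 0 and cy + radius <= h - 1)


def detect_puncta(image: np.ndarray, low_sigma: float = 1.0, high_sigma: float = 3.0,
                  threshold: Optional[float] = None, min_separation: float = 4.0,
                  radius: float = 3.0) -> list[Roi]:
    """Detect bouton-like puncta and return fixed-radius circular ROIs.

    Local maxima of a difference-of-Gaussians image above ``threshold``
    (default: median + 5 x 1.4826 x MAD of the DoG image) are accepted
    greedily in descending DoG intensity with pairwise separation at least
    ``min_separation``; ties break row-major.  A blank image yields an empty
    list; an empty array is an error.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise BoutonQuantError("detect_puncta requires a non-empty 2-D image")
    if low_sigma <= 0 or high_sigma <= low_sigma or min_separation <= 0 or radius <= 0:
        raise BoutonQuantError("detection parameters must be positive and ordered")

    dog = gaussian(image, low_sigma, preserve_range=True) - \
        gaussian(image, high_sigma, preserve_range=True)
    if threshold is None:
        med = np.median(dog)
        mad = np.median(np.abs(dog - med))
        threshold = med + 5.0 * 1.4826 * mad
    if threshold <= np.min(dog):  # degenerate flat image
        return []

    local_max = (dog == ndimage.maximum_filter(dog, size=3)) & (dog > threshold)
    ys, xs = np.nonzero(local_max)
    if len(xs) == 0:
        return []
    order = np.lexsort((xs, ys, -dog[ys, xs]))  # desc intensity, ties row-major
    accepted: list[tuple[float, float]] = []
    min_sep2 = min_separation ** 2
    for k in order:
        cx, cy = float(xs[k]), float(ys[k])
        if not _in_bounds(cx, cy, radius, image.shape):
            continue
        if any((cx - ax) ** 2 + (cy - ay) ** 2 < min_sep2 for ax, ay in accepted):
            continue
        accepted.append((cx, cy))
    return [Roi(roi_id=f"r{i:04d}", center=c, radius=radius) for i, c in enumerate(accepted)]


def _overlaps(c1, c2, r1, r2, margin: float = 0.5) -> bool:
    return math.hypot(c1[0] - c2[0], c1[1] - c2[1]) < r1 + r2 + margin


def place_background_rois(rois: list[Roi], image_shape, max_offset: float = 15.0,
                          n_angles: int = 8, step: float = 1.0):
    """Pair each terminal ROI with an adjacent non-synaptic background ROI.

    Candidates are enumerated on rings of increasing offset (starting just
    outside twice the ROI radius) at ``n_angles`` fixed angles; the first
    candidate circle inside the image that overlaps no terminal ROI and no
    previously placed background ROI wins.  Terminals with no valid position
    are returned in the ``excluded`` list.

    Returns ``(updated_terminal_rois, background_rois, excluded_ids)``.
    """
    terminals = [r for r in rois if r.kind == "terminal"]
    placed: list[Roi] = []
    updated: list[Roi] = []
    excluded: list[str] = []
    for roi in terminals:
        r = roi.radius
        found = None
        offset = 2 * r + 1.0
        while found is None and offset <= max_offset:
            for k in range(n_angles):
                ang = 2 * math.pi * k / n_angles
                cx = roi.center[0] + offset * math.cos(ang)
                cy = roi.center[1] + offset * math.sin(ang)
                if not _in_bounds(cx, cy, r, image_shape):
                    continue
                if any(_overlaps((cx, cy), t.center, r, t.radius) for t in terminals):
                    continue
                if any(_overlaps((cx, cy), b.center, r, b.radius) for b in placed):
                    continue
                found = (cx, cy)
                break
            offset += step
        if found is None:
            excluded.append(roi.roi_id)
            updated.append(roi)
            continue
        bg = Roi(roi_id=f"{roi.roi_id}_bg", center=found, radius=r, kind="background")
        placed.append(bg)
        updated.append(replace(roi, partner=bg.roi_id))
    return updated, placed, excluded


def roi_mask(roi: Roi, shape) -> np.ndarray:
    """Boolean pixel-membership mask (pixel centers inside the circle)."""
    h, w = shape
    ys, xs = np.ogrid[:h, :w]
    return (xs - roi.center[0]) ** 2 + (ys - roi.center[1]) ** 2 <= roi.radius ** 2


def extract_trace(stack: np.ndarray, roi: Roi, frame_rate: float) -> Trace:
    """Per-frame mean over the ROI's pixels."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise BoutonQuantError("stack must be (frames, height, width)")
    if not _in_bounds(roi.center[0], roi.center[1], roi.radius, stack.shape[1:]):
        raise BoutonQuantError(f"ROI {roi.roi_id} extends beyond image bounds")
    mask = roi_mask(roi, stack.shape[1:])
    return Trace(values=stack[:, mask].mean(axis=1), frame_rate=frame_rate,
                 roi_id=roi.roi_id)


def background_correct(terminal_trace: Trace, background_trace: Trace) -> Trace:
    """Frame-wise subtraction of the background partner trace."""
    if len(terminal_trace) != len(background_trace):
        raise BoutonQuantError("terminal and background traces differ in length")
    if terminal_trace.frame_rate != background_trace.frame_rate:
        raise BoutonQuantError("terminal and background frame rates differ")
    return Trace(values=terminal_trace.values - background_trace.values,
                 frame_rate=terminal_trace.frame_rate,
                 roi_id=terminal_trace.roi_id, corrected=True)


def average_trials(traces: list[Trace]) -> Trace:
    """Frame-wise mean over identically aligned trials."""
    if not traces:
        raise BoutonQuantError("average_trials requires at least one trace")
    n = len(traces[0])
    fr = traces[0].frame_rate
    for t in traces[1:]:
        if len(t) != n:
            raise BoutonQuantError("trial traces differ in length")
        if t.frame_rate != fr:
            raise BoutonQuantError("trial traces differ in frame rate")
    return Trace(values=np.mean([t.values for t in traces], axis=0),
                 frame_rate=fr, roi_id=traces[0].roi_id,
                 corrected=all(t.corrected for t in traces))


# -- tabular I/O --------------------------------------------------------------

def rois_to_frame(rois: list[Roi]) -> pd.DataFrame:
    return pd.DataFrame([{
        "roi_id": r.roi_id, "kind": r.kind, "x": r.center[0], "y": r.center[1],
        "radius": r.radius, "partner": r.partner if r.partner else "",
    } for r in rois])


def rois_from_frame(df: pd.DataFrame) -> list[Roi]:
    return [Roi(roi_id=str(row.roi_id), center=(float(row.x), float(row.y)),
                radius=float(row.radius), kind=str(row.kind),
                partner=(str(row.partner) or None) if isinstance(row.partner, str)
                else None)
            for row in df.itertuples()]


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Long-format trace table (roi_id, frame, value, corrected)."""
    parts = []
    for t in traces:
        parts.append(pd.DataFrame({
            "roi_id": t.roi_id, "frame": np.arange(len(t)),
            "value": t.values, "corrected": t.corrected,
        }))
    return pd.concat(parts, ignore_index=True)


def match_rois_to_terminals(rois: list[Roi], positions: np.ndarray,
                            max_dist: float = 2.0) -> dict[str, int]:
    """Greedy nearest match of detected terminal ROIs to ground-truth spot
    positions (x, y); used for recovery checks on rendered movies."""
    out: dict[str, int] = {}
    taken: set[int] = set()
    for r in rois:
        if r.kind != "terminal":
            continue
        d = np.hypot(positions[:, 0] - r.center[0], positions[:, 1] - r.center[1])
        d[list(taken)] = np.inf
        j = int(np.argmin(d))
        if d[j] <= max_dist:
            out[r.roi_id] = j
            taken.add(j)
    return out
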