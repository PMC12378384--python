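"""Central-sulcus tracing on a 2-D axial grayscale slice.

The sulcus appears as a dark (CSF-filled) groove between the brighter
precentral and postcentral gyri.  Starting from a manually or automatically
chosen seed at the fundus (the grey-matter pixel of the sulcus closest to
the midline — the sulcus never reaches the midline at this slice height),
the tracer walks centrifugally, at each step moving to the adjacent pixel
with the lowest intensity, until the image border, a length cap, or a
bright-tissue stop criterion.  An activation-peak coordinate is then
categorized relative to the traced path: on the line, at the fundus (within
one pixel of the seed), or anterior/posterior to the sulcus.

Coordinates are ``(x, y)`` with ``x`` the column and ``y`` the row of
``image[y, x]``; the anterior direction defaults to +y under the declared
slice orientation and is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)

#: 8-neighbourhood in clockwise order starting from (1, 0)
_NEIGHBOURS = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]


class PeakCategory(str, Enum):
    ON_LINE = "ON_LINE"
    FUNDUS = "FUNDUS"
    ANTERIOR = "ANTERIOR"
    POSTERIOR = "POSTERIOR"


@dataclass
class SulcusPath:
    """Ordered 8-connected pixel chain starting at the fundus seed."""

    seed: tuple[int, int]
    pixels: list[tuple[int, int]]
    hemisphere: str = "right"

    def __post_init__(self) -> None:
        if not self.pixels or tuple(self.pixels[0]) != tuple(self.seed):
            raise ValueError("path must start at the seed")
        if len(set(map(tuple, self.pixels))) != len(self.pixels):
            raise ValueError("path revisits a pixel")
        for (xa, ya), (xb, yb) in zip(self.pixels, self.pixels[1:]):
            if max(abs(xa - xb), abs(ya - yb)) != 1:
                raise ValueError("consecutive path pixels must be 8-neighbours")

    def __len__(self) -> int:
        return len(self.pixels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=float)


def _band_midpoint(img: np.ndarray) -> float:
    """Histogram-based stop level: midpoint between the darkest band (deep
    sulcal grey, 0.1th percentile) and the bulk-tissue level (median).

    An Otsu split is unreliable here because the sulcal band can be a tiny
    minority of the pixels; the extreme-percentile estimate stays robust to
    that imbalance.
    """
    dark, med = np.percentile(img, [0.1, 50])
    return float(0.5 * (dark + med))


def find_seed(
    image: np.ndarray,
    midline_x: int,
    hemisphere: str = "right",
    intensity_band: Optional[tuple[float, float]] = None,
    seed: Optional[tuple[int, int]] = None,
) -> tuple[int, int]:
    """Locate the fundus seed: the grey-matter-band pixel closest to the
    midline within the requested hemisphere.

    A user-supplied ``seed`` always overrides the search (seed selection was
    manual in the original procedure).
    """
    if seed is not None:
        return (int(seed[0]), int(seed[1]))
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if intensity_band is None:
        intensity_band = (img.min(), _band_midpoint(img))
    lo, hi = intensity_band
    ys, xs = np.nonzero((img >= lo) & (img <= hi))
    if hemisphere == "right":
        keep = xs > midline_x
    elif hemisphere == "left":
        keep = xs < midline_x
    else:
        raise ValueError("hemisphere must be 'left' or 'right'")
    xs, ys = xs[keep], ys[keep]
    if len(xs) == 0:
        raise ValueError("no pixel in the grey-matter intensity band")
    dist = np.abs(xs - midline_x)
    best = np.flatnonzero(dist == dist.min())
    darkest = best[np.argmin(img[ys[best], xs[best]])]
    return (int(xs[darkest]), int(ys[darkest]))


def trace_sulcus(
    image: np.ndarray,
    seed: tuple[int, int],
    max_len: int = 500,
    stop_intensity: Optional[float] = None,
    midline_x: Optional[int] = None,
    hemisphere: str = "right",
    centrifugal_slack: int = 0,
) -> SulcusPath:
    """Greedy lowest-intensity centrifugal walk from the seed.

    From the current pixel, among the 8-neighbours that are inside the
    image, not yet on the path, and centrifugal (distance from the midline
    column at least the current distance minus ``centrifugal_slack``), step
    to the pixel with the lowest intensity.  Stop at the image border, at
    ``max_len`` pixels, or when the best candidate is brighter than
    ``stop_intensity`` (default: midway between the dark sulcal band and
    the bulk tissue level, estimated from the image histogram).

    Strict centrifugality (slack 0) is the default: allowing re-approach of
    the midline lets the greedy walk step back onto a skipped neighbour of
    the line and trap itself against its own trail.  A slack of 1 px can be
    set for sulci that genuinely bend back toward the midline.

    Intensity ties break by preferring the continuation of the previous
    step direction, then by clockwise angular order.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    h, w = img.shape
    x0, y0 = int(seed[0]), int(seed[1])
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise ValueError("seed outside the image")
    if midline_x is None:
        midline_x = w // 2
    if stop_intensity is None:
        stop_intensity = _band_midpoint(img)
    if img[y0, x0] > stop_intensity:
        log.warning("seed intensity %.3g brighter than stop criterion %.3g",
                    img[y0, x0], stop_intensity)
        return SulcusPath(seed=(x0, y0), pixels=[(x0, y0)], hemisphere=hemisphere)

    pixels = [(x0, y0)]
    visited = {(x0, y0)}
    prev_step: Optional[tuple[int, int]] = None
    while len(pixels) < max_len:
        cx, cy = pixels[-1]
        cur_dist = abs(cx - midline_x)
        candidates = []
        for rank, (dx, dy) in enumerate(_NEIGHBOURS):
            nx, ny = cx + dx, cy + dy
            if not (0 <= nx < w and 0 <= ny < h):
                continue
            if (nx, ny) in visited:
                continue
            if abs(nx - midline_x) < cur_dist - centrifugal_slack:
                continue
            continuation = 0 if prev_step == (dx, dy) else 1
            candidates.append((img[ny, nx], continuation, rank, (nx, ny), (dx, dy)))
        if not candidates:
            break
        intensity, _, _, best, step = min(candidates)
        if intensity > stop_intensity:
            break
        pixels.append(best)
        visited.add(best)
        prev_step = step
    return SulcusPath(seed=(x0, y0), pixels=pixels, hemisphere=hemisphere)


def categorize_peak(
    path: SulcusPath,
    peak: tuple[float, float],
    fundus_radius: float = 1.0,
    on_line_radius: float = 1.0,
    anterior_axis: tuple[float, float] = (0.0, 1.0),
) -> PeakCategory:
    """Categorize an activation peak relative to the traced sulcus.

    Evaluation order is fixed: FUNDUS if the peak is within
    ``fundus_radius`` of the seed; else ON_LINE if its minimum distance to
    the path is below ``on_line_radius``; else ANTERIOR or POSTERIOR by the
    sign of the projection of (peak - nearest path point) onto
    ``anterior_axis``.
    """
    if len(path) < 2:
        raise ValueError("path must contain at least 2 pixels")
    p = np.asarray(peak, dtype=float)
    axis = np.asarray(anterior_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("anterior_axis must be non-zero")
    axis = axis / norm
    if np.linalg.norm(p - np.asarray(path.seed, dtype=float)) < fundus_radius:
        return PeakCategory.FUNDUS
    pts = path.as_array()
    d = np.linalg.norm(pts - p, axis=1)
    j = int(np.argmin(d))
    if d[j] < on_line_radius:
        return PeakCategory.ON_LINE
    projection = float(np.dot(p - pts[j], axis))
    return PeakCategory.ANTERIOR if projection > 0 else PeakCategory.POSTERIOR


def tally_categories(categories: Sequence[PeakCategory]) -> dict[str, int]:
    """Count peaks per category; counts sum to the number of peaks."""
    counts = {c.value: 0 for c in PeakCategory}
    for c in categories:
        counts[PeakCategory(c).value] += 1
    return counts
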