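"""Site delimitation on a landscape: peaks, the walk algorithm, ranking.

A peak is a landscape maximum; the hill around it marks the extent of the
binding site on each protein. The walk descends from the peak in the four
axial directions until the height drops below ``percent_peak`` times the
peak height, bounding a window-index rectangle that is converted to residue
ranges. Sharp spikes with no supporting hill (no possible walk step toward
some in-bounds neighbour) are rejected as spurious, and landscapes whose
tallest peak is below ``min_peak_height`` yield no predictions at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Interval
from .landscape import Landscape

#: rectangle in window-start indices, 1-based inclusive: (i0, i1, j0, j1)
Rect = tuple[int, int, int, int]


@dataclass(frozen=True)
class SiteParams:
    """Peak-selection and walk parameters.

    percent_peak: walk stop threshold as a fraction of the current peak
        height; larger values give more compact site predictions.
    min_peak_height: minimum landscape maximum (in co-occurrence counts)
        for the landscape to yield any prediction; 10 balances noisy peaks
        against discarding informative landscapes.
    max_peaks: number of ranked sites to report.
    """

    percent_peak: float = 0.30
    min_peak_height: int = 10
    max_peaks: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.percent_peak <= 1:
            raise ValueError("percent_peak must be in (0, 1]")
        if self.min_peak_height < 1:
            raise ValueError("min_peak_height must be >= 1")
        if self.max_peaks < 1:
            raise ValueError("max_peaks must be >= 1")


@dataclass(frozen=True)
class Peak:
    """A landscape cell, 1-based window-start indices."""

    i: int
    j: int
    height: int


@dataclass(frozen=True)
class SitePrediction:
    """One ranked binding-site prediction for a query pair."""

    rank: int
    peak: Peak
    rect: Rect
    range_a: Interval
    range_b: Interval


def find_global_peak(ls: Landscape, mask: np.ndarray | None = None) -> Peak | None:
    """Unmasked cell of maximum height; None if all masked or all zero.

    Ties broken by smallest row index i, then smallest column j, so the
    result is deterministic.
    """
    if ls.is_empty:
        return None
    H = ls.H
    if mask is not None:
        H = np.where(mask, -1, H)
    flat = int(np.argmax(H))  # row-major argmax == (smallest i, then j) tie rule
    i, j = divmod(flat, H.shape[1])
    height = int(H[i, j])
    if height <= 0:
        return None
    return Peak(i + 1, j + 1, height)


_DIRECTIONS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def is_spurious(ls: Landscape, p: Peak, params: SiteParams) -> bool:
    """True iff the walk cannot take one step toward some in-bounds neighbour.

    A direction falling outside the matrix counts as satisfied, so boundary
    peaks are not auto-rejected.
    """
    threshold = params.percent_peak * p.height
    n_a, n_b = ls.H.shape
    for di, dj in _DIRECTIONS:
        ni, nj = p.i + di, p.j + dj
        if not (1 <= ni <= n_a and 1 <= nj <= n_b):
            continue
        if ls.H[ni - 1, nj - 1] < threshold:
            return True
    return False


def walk(
    ls: Landscape,
    p: Peak,
    percent_peak: float,
    mask: np.ndarray | None = None,
) -> Rect:
    """Axial descent from peak ``p`` until height < percent_peak * height.

    Four independent runs (up, down, left, right) bound a rectangle that
    always contains the peak. Cells flagged in ``mask`` (claimed by earlier
    predictions) stop the walk, keeping ranked rectangles disjoint.
    """
    params = SiteParams(percent_peak=percent_peak, min_peak_height=1, max_peaks=1)
    if is_spurious(ls, p, params):
        raise ValueError(f"walk called on spurious peak at ({p.i},{p.j})")
    H = ls.H
    n_a, n_b = H.shape
    threshold = percent_peak * p.height

    def blocked(i: int, j: int) -> bool:
        if H[i - 1, j - 1] < threshold:
            return True
        return mask is not None and bool(mask[i - 1, j - 1])

    i0 = p.i
    while i0 > 1 and not blocked(i0 - 1, p.j):
        i0 -= 1
    i1 = p.i
    while i1 < n_a and not blocked(i1 + 1, p.j):
        i1 += 1
    j0 = p.j
    while j0 > 1 and not blocked(p.i, j0 - 1):
        j0 -= 1
    j1 = p.j
    while j1 < n_b and not blocked(p.i, j1 + 1):
        j1 += 1

    # the axial probes only inspect the peak's row and column, so the
    # bounding rectangle may still cover cells claimed earlier; shrink it
    # toward the peak until it is clean (the peak cell is never masked, and
    # the peak's own row/column inside the extents are mask-free because
    # the probes stopped before masked cells)
    if mask is not None:
        while True:
            rows, cols = np.nonzero(mask[i0 - 1:i1, j0 - 1:j1])
            if rows.size == 0:
                break
            r, c = i0 + int(rows[0]), j0 + int(cols[0])
            if r < p.i:
                i0 = r + 1
            elif r > p.i:
                i1 = r - 1
            elif c < p.j:
                j0 = c + 1
            else:
                j1 = c - 1
    return (i0, i1, j0, j1)


def rect_to_ranges(rect: Rect, w: int) -> tuple[Interval, Interval]:
    """Residue ranges (1-based inclusive) covered by a window rectangle."""
    i0, i1, j0, j1 = rect
    return (i0, i1 + w - 1), (j0, j1 + w - 1)


def predict_sites(ls: Landscape, params: SiteParams) -> list[SitePrediction]:
    """Ranked binding-site predictions for one landscape.

    Returns [] when the landscape is empty or its tallest peak is below
    ``min_peak_height``. Otherwise repeatedly takes the highest unmasked
    cell, skips (and masks) spurious peaks, walks the rest, and masks each
    predicted rectangle so later ranks claim disjoint cells. Stops after
    ``max_peaks`` predictions or when no peak >= min_peak_height remains.
    """
    if ls.is_empty:
        return []
    mask = np.zeros(ls.H.shape, dtype=bool)
    predictions: list[SitePrediction] = []
    while len(predictions) < params.max_peaks:
        peak = find_global_peak(ls, mask)
        if peak is None or peak.height < params.min_peak_height:
            break
        if is_spurious(ls, peak, params):
            mask[peak.i - 1, peak.j - 1] = True
            continue
        rect = walk(ls, peak, params.percent_peak, mask)
        range_a, range_b = rect_to_ranges(rect, ls.w)
        predictions.append(
            SitePrediction(
                rank=len(predictions) + 1,
                peak=peak,
                rect=rect,
                range_a=range_a,
                range_b=range_b,
            )
        )
        i0, i1, j0, j1 = rect
        mask[i0 - 1:i1, j0 - 1:j1] = True
    return predictions
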