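"""Microcarrier detection and isolation via the circular Hough transform.

Microcarriers image as near-circular bodies with a bright rim, so their
edges vote strongly in (center, radius) Hough space.  Edge pixels are
taken from the Sobel gradient magnitude above a configurable percentile
(gradient-based, hence invariant to constant intensity offsets), voting
is done by :func:`skimage.transform.hough_circle` with circumference-
normalized accumulators, and detections are pruned by greedy Euclidean
non-maximum suppression with deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.filters import sobel
from skimage.transform import hough_circle

from .config import AnalysisConfig
from .io import GrayImage


@dataclass(frozen=True)
class DetectedCircle:
    """One microcarrier hypothesis in pixel coordinates (0-based row/col)."""

    center_row: float
    center_col: float
    radius_px: float
    score: float

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("detection score must be positive")


@dataclass(frozen=True)
class CarrierCrop:
    """A carrier's bounding-box subimage plus its in-circle mask.

    ``top_left`` maps subimage coordinates back to the parent image.
    """

    image: GrayImage
    mask: np.ndarray
    top_left: Tuple[int, int]
    circle: DetectedCircle


def _inside_fraction(shape: Tuple[int, int], circle: DetectedCircle) -> float:
    """Fraction of the circle's disk lying inside the image bounds."""
    h, w = shape
    r = circle.radius_px
    rows = np.arange(int(np.floor(circle.center_row - r)),
                     int(np.ceil(circle.center_row + r)) + 1)
    cols = np.arange(int(np.floor(circle.center_col - r)),
                     int(np.ceil(circle.center_col + r)) + 1)
    dr = rows[:, None] - circle.center_row
    dc = cols[None, :] - circle.center_col
    disk = dr * dr + dc * dc <= r * r
    if disk.sum() == 0:
        return 0.0
    in_bounds = ((rows >= 0) & (rows < h))[:, None] & ((cols >= 0) & (cols < w))[None, :]
    return float((disk & in_bounds).sum()) / float(disk.sum())


def detect_circles(
    image: GrayImage,
    radius_range_px: Optional[Tuple[int, int]] = None,
    max_circles: Optional[int] = None,
    min_separation_px: Optional[float] = None,
    config: AnalysisConfig | None = None,
) -> List[DetectedCircle]:
    """Detect microcarriers, strongest first.

    Returns at most ``max_circles`` detections whose normalized Hough
    accumulator exceeds ``config.hough_score_min``, any two centers at
    least ``min_separation_px`` apart.  A featureless image yields an
    empty list.  Ties in score break by (row, col, radius) so results
    are deterministic.
    """
    config = config or AnalysisConfig()
    rmin, rmax = radius_range_px or config.hough_radius_range_px
    if not 0 < rmin < rmax:
        raise ValueError("radius range must satisfy 0 < min < max")
    if rmax > min(image.pixels.shape) // 2:
        raise ValueError("max radius exceeds half the smaller image dimension")
    if max_circles is None:
        max_circles = config.hough_max_circles
    if min_separation_px is None:
        min_separation_px = config.min_separation_px

    grad = sobel(image.pixels)
    gmax = grad.max()
    if gmax <= 1e-12:
        return []
    # Percentile among pixels with non-negligible gradient: a mostly
    # flat field otherwise drags the threshold to ~0 and the whole rim
    # band (not just the sharp outer step) floods the accumulator.
    meaningful = grad[grad > 0.02 * gmax]
    edge_thresh = np.percentile(meaningful, config.edge_percentile)
    edges = grad > edge_thresh
    if not edges.any():
        return []

    radii = np.arange(int(rmin), int(rmax) + 1)
    acc = hough_circle(edges, radii, normalize=True)

    # Candidate voxels above the score floor, strongest first.
    cand = np.argwhere(acc >= config.hough_score_min)
    if cand.size == 0:
        return []
    scores = acc[cand[:, 0], cand[:, 1], cand[:, 2]]
    # Sort by (-score, row, col, radius) for deterministic tie-breaking.
    order = np.lexsort((radii[cand[:, 0]], cand[:, 2], cand[:, 1], -scores))
    picked: List[DetectedCircle] = []
    sep2 = float(min_separation_px) ** 2
    for idx in order:
        r_i, row, col = cand[idx]
        if any(
            (row - c.center_row) ** 2 + (col - c.center_col) ** 2 < sep2
            for c in picked
        ):
            continue
        picked.append(
            DetectedCircle(
                center_row=float(row),
                center_col=float(col),
                radius_px=float(radii[r_i]),
                score=float(scores[idx]),
            )
        )
        if len(picked) >= max_circles:
            break
    return picked


def crop_to_circle(
    image: GrayImage, circle: DetectedCircle, margin_px: float = 0.0
) -> CarrierCrop:
    """Extract the circle's bounding box (plus margin) and in-circle mask.

    The box is clipped to the image bounds; the mask marks pixels whose
    center lies within ``radius_px`` of the circle center.  The circle
    must be at least half inside the image.
    """
    if _inside_fraction(image.pixels.shape, circle) < 0.5:
        raise ValueError("circle lies less than half inside the image")
    h, w = image.pixels.shape
    r = circle.radius_px + margin_px
    r0 = max(0, int(np.floor(circle.center_row - r)))
    r1 = min(h - 1, int(np.ceil(circle.center_row + r)))
    c0 = max(0, int(np.floor(circle.center_col - r)))
    c1 = min(w - 1, int(np.ceil(circle.center_col + r)))
    sub = image.pixels[r0:r1 + 1, c0:c1 + 1]
    rows = np.arange(r0, r1 + 1)[:, None] - circle.center_row
    cols = np.arange(c0, c1 + 1)[None, :] - circle.center_col
    mask = rows * rows + cols * cols <= circle.radius_px**2
    return CarrierCrop(
        image=GrayImage(sub, pixel_scale_um=image.pixel_scale_um,
                        image_id=image.image_id),
        mask=mask,
        top_left=(r0, c0),
        circle=circle,
    )
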