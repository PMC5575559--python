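"""Confluence segmentation by local intensity variability.

Adherent cells show strong local grayscale variation while the culture
background is nearly flat.  A square analysis kernel (default 15 x 15
px, 93% overlap between successive positions, i.e. stride 1) is slid
across the image; a window whose population standard deviation reaches
the threshold marks every pixel it covers as "cell".  The threshold is
adaptive — a fixed fraction (default 0.35) of the standard deviation of
the whole analyzed image — which keeps the segmentation invariant to
linear changes of illumination and contrast.  A constant-threshold mode
is retained for comparison with the classic fixed rule (0.4 x 21.1).

Confluence is the percentage of analyzed pixels classified as cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .io import GrayImage


@dataclass(frozen=True)
class ConfluenceResult:
    """Binary cell mask plus the scalar confluence of the analyzed region.

    ``mask`` has the shape of the analyzed raster (1 = cell); for
    carrier-restricted analysis, pixels outside the carrier disk are 0
    and excluded from the percentage.  ``sigma_image`` is the population
    standard deviation of the analyzed pixels and ``threshold_used`` the
    local-std threshold actually applied, both in intensity units.
    """

    mask: np.ndarray
    confluence_pct: float
    sigma_image: float
    threshold_used: float


def local_std_map(
    pixels: np.ndarray, kernel_px: int, overlap_fraction: float
) -> np.ndarray:
    """Sliding-window population-standard-deviation raster.

    Windows are fully interior (no padding) and placed on a grid of
    stride ``max(1, round(kernel_px * (1 - overlap_fraction)))``; with
    the defaults (15, 0.93) the stride is 1.  Each window's std is
    written to every pixel the window covers, overlapping windows
    combining by maximum.  With stride > 1 the last row/column of
    windows is anchored to the image edge so the whole image is covered.

    Returns an array of the input's shape.
    """
    img = np.asarray(pixels, dtype=float)
    k = int(kernel_px)
    if k < 1 or k > min(img.shape):
        raise ValueError(
            f"kernel {k} does not fit inside image of shape {img.shape}"
        )
    stride = max(1, round(k * (1.0 - overlap_fraction)))
    h, w = img.shape

    # Exact window sums via integral images (inputs are small integers or
    # floats <= 255, so float64 accumulation is effectively exact).
    s1 = np.zeros((h + 1, w + 1))
    s2 = np.zeros((h + 1, w + 1))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=s1[1:, 1:])
    np.cumsum(np.cumsum(img * img, axis=0), axis=1, out=s2[1:, 1:])

    def window_sum(s):
        return (s[k:, k:] - s[:-k, k:] - s[k:, :-k] + s[:-k, :-k])

    n = float(k * k)
    mean = window_sum(s1) / n
    var = window_sum(s2) / n - mean * mean
    v = np.sqrt(np.clip(var, 0.0, None))  # (h-k+1, w-k+1) window-std grid

    rows = np.arange(0, h - k + 1, stride)
    cols = np.arange(0, w - k + 1, stride)
    if rows[-1] != h - k:
        rows = np.append(rows, h - k)
    if cols[-1] != w - k:
        cols = np.append(cols, w - k)
    out = np.full((h, w), -np.inf)
    if stride == 1:
        nr, nc = v.shape
        for di in range(k):
            for dj in range(k):
                sub = out[di:di + nr, dj:dj + nc]
                np.maximum(sub, v, out=sub)
    else:
        vg = v[np.ix_(rows, cols)]
        for di in range(k):
            for dj in range(k):
                idx = np.ix_(rows + di, cols + dj)
                out[idx] = np.maximum(out[idx], vg)
    # Full coverage is guaranteed by the edge-anchored last windows.
    assert np.isfinite(out).all()
    return out


def masked_local_std_map(
    pixels: np.ndarray,
    mask: np.ndarray,
    kernel_px: int,
    overlap_fraction: float,
) -> np.ndarray:
    """Sliding-window std restricted to windows fully inside ``mask``.

    Windows containing any out-of-mask pixel are discarded, so
    intensities outside the region (carrier rim, background) cannot
    leak into the statistic.  In-mask pixels covered by no valid window
    (a band of less than one kernel along the region boundary) inherit
    the value of the nearest covered pixel.
    """
    from scipy.ndimage import distance_transform_edt

    img = np.asarray(pixels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    k = int(kernel_px)
    if k > min(img.shape):
        raise ValueError("kernel does not fit inside image")
    stride = max(1, round(k * (1.0 - overlap_fraction)))

    # Window validity: all k x k pixels inside the mask.
    mi = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=mi[1:, 1:])
    win_count = mi[k:, k:] - mi[:-k, k:] - mi[k:, :-k] + mi[:-k, :-k]
    valid = win_count == k * k
    if not valid.any():
        raise ValueError("mask holds no full analysis window")

    s1 = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    s2 = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=s1[1:, 1:])
    np.cumsum(np.cumsum(img * img, axis=0), axis=1, out=s2[1:, 1:])

    def wsum(s):
        return s[k:, k:] - s[:-k, k:] - s[k:, :-k] + s[:-k, :-k]

    n = float(k * k)
    mean = wsum(s1) / n
    var = wsum(s2) / n - mean * mean
    v = np.sqrt(np.clip(var, 0.0, None))
    v = np.where(valid, v, -np.inf)

    h, w = img.shape
    rows = np.arange(0, h - k + 1, stride)
    cols = np.arange(0, w - k + 1, stride)
    if rows[-1] != h - k:
        rows = np.append(rows, h - k)
    if cols[-1] != w - k:
        cols = np.append(cols, w - k)
    out = np.full((h, w), -np.inf)
    if stride == 1:
        nr, nc = v.shape
        for di in range(k):
            for dj in range(k):
                sub = out[di:di + nr, dj:dj + nc]
                np.maximum(sub, v, out=sub)
    else:
        vg = v[np.ix_(rows, cols)]
        for di in range(k):
            for dj in range(k):
                idx = np.ix_(rows + di, cols + dj)
                out[idx] = np.maximum(out[idx], vg)

    covered = np.isfinite(out)
    if not covered.all():
        _, (ir, ic) = distance_transform_edt(~covered, return_indices=True)
        out = out[ir, ic]
    return out


def segment_confluence(
    image: GrayImage,
    config: AnalysisConfig | None = None,
    mode: str = "adaptive",
) -> ConfluenceResult:
    """Segment cells from background and compute percent confluence.

    ``mode`` is ``"adaptive"`` (threshold = factor x sigma of the whole
    image) or ``"constant"`` (the configured fixed threshold).  A
    featureless image (sigma = 0) in adaptive mode yields 0% with a
    warning rather than an all-foreground mask.
    """
    config = config or AnalysisConfig()
    px = image.pixels
    sigma = float(np.std(px))
    if mode == "adaptive":
        threshold = config.confluence_threshold_factor * sigma
        if sigma == 0.0:
            warnings.warn(
                "featureless image (sigma = 0): confluence reported as 0%",
                stacklevel=2,
            )
            return ConfluenceResult(
                mask=np.zeros_like(px, dtype=np.uint8),
                confluence_pct=0.0,
                sigma_image=0.0,
                threshold_used=0.0,
            )
    elif mode == "constant":
        threshold = float(config.constant_threshold)
    else:
        raise ValueError(f"unknown confluence mode: {mode!r}")

    stds = local_std_map(
        px, config.confluence_kernel_px, config.confluence_overlap_fraction
    )
    mask = (stds >= threshold).astype(np.uint8)
    pct = 100.0 * float(mask.sum()) / mask.size
    return ConfluenceResult(
        mask=mask, confluence_pct=pct, sigma_image=sigma, threshold_used=threshold
    )


def confluence_on_carrier(
    image: GrayImage,
    circle,
    config: AnalysisConfig | None = None,
    mode: str = "adaptive",
) -> ConfluenceResult:
    """Confluence restricted to one detected microcarrier's interior.

    Sigma, the threshold and the percentage are computed over in-circle
    pixels only, and only analysis windows lying fully inside the disk
    contribute (the bright carrier rim and the background would
    otherwise read as spurious texture).  The returned mask has the
    crop's shape with out-of-circle pixels forced to 0.
    """
    from .carriers import crop_to_circle  # local import: avoid cycle

    config = config or AnalysisConfig()
    crop = crop_to_circle(image, circle, margin_px=config.confluence_kernel_px)
    px = crop.image.pixels
    inside = crop.mask
    if not inside.any():
        raise ValueError("circle lies fully outside the image")
    sigma = float(np.std(px[inside]))
    if mode == "adaptive":
        threshold = config.confluence_threshold_factor * sigma
        if sigma == 0.0:
            warnings.warn(
                "featureless carrier (sigma = 0): confluence reported as 0%",
                stacklevel=2,
            )
            return ConfluenceResult(
                mask=np.zeros_like(px, dtype=np.uint8),
                confluence_pct=0.0,
                sigma_image=0.0,
                threshold_used=0.0,
            )
    elif mode == "constant":
        threshold = float(config.constant_threshold)
    else:
        raise ValueError(f"unknown confluence mode: {mode!r}")

    stds = masked_local_std_map(
        px, inside, config.confluence_kernel_px,
        config.confluence_overlap_fraction,
    )
    mask = ((stds >= threshold) & inside).astype(np.uint8)
    pct = 100.0 * float(mask.sum()) / float(inside.sum())
    return ConfluenceResult(
        mask=mask, confluence_pct=pct, sigma_image=sigma, threshold_used=threshold
    )
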