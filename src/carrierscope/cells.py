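"""Per-carrier cell detection and counting.

Cells image as compact bright blobs on the carrier surface.  They are
detected with a Laplacian-of-Gaussian (LoG) filter sized to the blob
scale, gated by a raw-grayscale high-pass (cells are distinguishable by
their relatively high pixel value), binarized, labeled (8-connected)
and filtered by pixel area.  Only the upper hemisphere of a carrier is
visible to the camera, so the visible count is doubled to estimate the
whole-carrier cell number; multiplying the per-carrier mean by the
carrier concentration converts it to a culture density in cells/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import convolve
from skimage.measure import label, regionprops

from .carriers import CarrierCrop, DetectedCircle
from .config import AnalysisConfig
from .io import GrayImage


@dataclass(frozen=True)
class CellDetection:
    """One accepted blob on a carrier subimage."""

    centroid_row: float
    centroid_col: float
    area_px2: int
    peak_response: float


@dataclass(frozen=True)
class CarrierAnalysis:
    """Everything measured on one microcarrier."""

    circle: DetectedCircle
    confluence_pct: Optional[float]
    cells_visible: int
    cells_corrected: int

    def __post_init__(self) -> None:
        if self.cells_corrected != 2 * self.cells_visible:
            raise ValueError("cells_corrected must be 2 x cells_visible")


def log_kernel(sigma_px: float, kernel_px: int) -> np.ndarray:
    """Discrete blob-positive LoG kernel.

    The raw negated Laplacian-of-Gaussian is mean-corrected so the
    kernel sums exactly to zero: a constant image then yields an exactly
    zero response, and bright blobs on a dark background yield positive
    peaks.
    """
    if sigma_px <= 0:
        raise ValueError("sigma must be positive")
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    half = kernel_px // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    r2 = x * x + y * y
    s2 = sigma_px * sigma_px
    g = np.exp(-r2 / (2.0 * s2))
    k = -(r2 - 2.0 * s2) / (s2 * s2) * g  # negated LoG: blob-positive
    k -= k.mean()
    return k


def log_filter(
    image: GrayImage | np.ndarray, sigma_px: float, kernel_px: int
) -> np.ndarray:
    """Convolve with the LoG kernel (reflective border padding).

    Output has the input's shape, positive at bright compact blobs.
    """
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    if kernel_px > min(px.shape):
        raise ValueError("LoG kernel does not fit inside the image")
    return convolve(px, log_kernel(sigma_px, kernel_px), mode="reflect")


def detect_cells(
    crop: CarrierCrop | GrayImage,
    mask: Optional[np.ndarray] = None,
    config: AnalysisConfig | None = None,
) -> List[CellDetection]:
    """Detect cells on an isolated carrier.

    Pipeline: (1) LoG filter; (2) zero responses where the raw grayscale
    is below ``cell_intensity_threshold``; (3) binarize responses above
    ``log_response_fraction`` x the maximum gated response; (4) label
    8-connected components; (5) keep components whose area lies in
    ``cell_area_range_px2`` and whose centroid falls inside the carrier
    mask.  Detections are returned sorted by (row, col).
    """
    config = config or AnalysisConfig()
    if isinstance(crop, CarrierCrop):
        px = crop.image.pixels
        mask = crop.mask if mask is None else mask
    else:
        px = crop.pixels
    if mask is None:
        mask = np.ones_like(px, dtype=bool)
    if not mask.any():
        raise ValueError("carrier mask is empty")

    resp = log_filter(px, config.log_sigma_px, config.log_kernel_px)
    resp = np.where(px >= config.cell_intensity_threshold, resp, 0.0)
    peak = resp.max()
    if peak <= 0.0:
        return []
    binary = resp > config.log_response_fraction * peak

    lab = label(binary, connectivity=2)
    lo, hi = config.cell_area_range_px2
    out: List[CellDetection] = []
    for region in regionprops(lab, intensity_image=resp):
        if not lo <= region.area <= hi:
            continue
        cr, cc = region.centroid
        ir, ic = int(round(cr)), int(round(cc))
        ir = min(max(ir, 0), mask.shape[0] - 1)
        ic = min(max(ic, 0), mask.shape[1] - 1)
        if not mask[ir, ic]:
            continue
        out.append(
            CellDetection(
                centroid_row=float(cr),
                centroid_col=float(cc),
                area_px2=int(region.area),
                peak_response=float(region.intensity_max),
            )
        )
    out.sort(key=lambda d: (d.centroid_row, d.centroid_col))
    return out


def hemisphere_corrected_count(cells_visible: int) -> int:
    """Double the visible count: only the upper hemisphere is imaged."""
    if cells_visible < 0:
        raise ValueError("cell count cannot be negative")
    return 2 * cells_visible


def cell_density(mean_cells_per_carrier: float, carriers_per_ml: float) -> float:
    """Cells per mL of culture = mean cells/carrier x carriers/mL."""
    if mean_cells_per_carrier < 0 or carriers_per_ml < 0:
        raise ValueError("arguments must be non-negative")
    return mean_cells_per_carrier * carriers_per_ml


def analyze_carrier(
    image: GrayImage,
    circle: DetectedCircle,
    config: AnalysisConfig | None = None,
    with_confluence: bool = True,
) -> CarrierAnalysis:
    """Isolate one carrier, then measure confluence and cell count."""
    from .carriers import crop_to_circle
    from .confluence import confluence_on_carrier

    config = config or AnalysisConfig()
    crop = crop_to_circle(image, circle, margin_px=config.log_kernel_px // 2)
    detections = detect_cells(crop, config=config)
    visible = len(detections)
    confluence = None
    if with_confluence:
        confluence = confluence_on_carrier(image, circle, config).confluence_pct
    return CarrierAnalysis(
        circle=circle,
        confluence_pct=confluence,
        cells_visible=visible,
        cells_corrected=hemisphere_corrected_count(visible),
    )
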