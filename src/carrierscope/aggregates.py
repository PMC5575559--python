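"""Microcarrier aggregate detection.

Aggregation (clumps of carriers bridged by cells) degrades nutrient
transfer and optical counting, so its onset is worth flagging.  The
detector binarizes the image (Otsu by default), dilates with a disk to
agglomerate each carrier's bright regions, labels 8-connected objects
and keeps those whose pixel area and eccentricity look like a single
carrier.  An image containing more than two such carriers is flagged as
an aggregate, and the aggregation frequency of a run is reported per 50
images acquired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk

from .config import AnalysisConfig
from .io import GrayImage


@dataclass(frozen=True)
class LabeledObject:
    """One connected component of the dilated binary image."""

    label_id: int
    area_px2: int
    eccentricity: float
    centroid_row: float
    centroid_col: float


@dataclass(frozen=True)
class AggregateReport:
    """Per-image carrier counts/flags and per-group rates per 50 images."""

    image_flags: Dict[str, Tuple[int, bool]]
    rate_per_50: Dict[object, Optional[float]]


def binarize_and_dilate(
    image: GrayImage,
    threshold: Optional[float] = None,
    dilation_radius_px: int = 5,
) -> np.ndarray:
    """Threshold to binary (intensity >= threshold), then dilate.

    ``threshold=None`` selects Otsu's method on the image histogram.
    Dilation uses a disk structuring element; radius 0 means none.
    """
    px = image.pixels
    if threshold is None:
        if px.min() == px.max():
            return np.zeros_like(px, dtype=bool)
        threshold = float(threshold_otsu(px))
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    if dilation_radius_px < 0:
        raise ValueError("dilation radius must be >= 0")
    binary = px >= threshold
    if dilation_radius_px > 0:
        binary = dilation(binary, disk(dilation_radius_px))
    return binary.astype(bool)


def label_and_filter(
    binary: np.ndarray,
    carrier_area_range_px2: Tuple[float, float],
    eccentricity_max: float,
) -> List[LabeledObject]:
    """Label 8-connected components; keep carrier-like ones.

    A component is kept iff its area lies in ``carrier_area_range_px2``
    and the eccentricity of its equivalent ellipse (from second-order
    central moments) is at most ``eccentricity_max``.  Returned sorted
    by area descending (ties by label id).
    """
    lo, hi = carrier_area_range_px2
    lab = label(np.asarray(binary, dtype=bool), connectivity=2)
    kept: List[LabeledObject] = []
    for region in regionprops(lab):
        if not lo <= region.area <= hi:
            continue
        if region.eccentricity > eccentricity_max:
            continue
        cr, cc = region.centroid
        kept.append(
            LabeledObject(
                label_id=int(region.label),
                area_px2=int(region.area),
                eccentricity=float(region.eccentricity),
                centroid_row=float(cr),
                centroid_col=float(cc),
            )
        )
    kept.sort(key=lambda o: (-o.area_px2, o.label_id))
    return kept


def flag_aggregate(objects: Sequence[LabeledObject]) -> bool:
    """True iff strictly more than two carrier-like objects are present."""
    return len(objects) > 2


def detect_aggregate(
    image: GrayImage, config: AnalysisConfig | None = None
) -> Tuple[int, bool]:
    """Full per-image pipeline: (carrier object count, aggregate flag).

    With ``config.aggregate_oversize_factor`` set, an image is also
    flagged when any raw component's area exceeds that multiple of the
    carrier area maximum — catching fused clumps that merge into one
    object and would otherwise evade the count rule.
    """
    config = config or AnalysisConfig()
    binary = binarize_and_dilate(
        image,
        threshold=config.aggregate_binarize_threshold,
        dilation_radius_px=config.aggregate_dilation_radius_px,
    )
    objects = label_and_filter(
        binary, config.carrier_area_range_px2, config.carrier_eccentricity_max
    )
    flagged = flag_aggregate(objects)
    if config.aggregate_oversize_factor is not None and not flagged:
        limit = config.aggregate_oversize_factor * config.carrier_area_range_px2[1]
        lab = label(binary, connectivity=2)
        areas = np.bincount(lab.ravel())[1:]
        flagged = bool((areas > limit).any())
    return len(objects), flagged


def aggregate_rate(
    flags: Sequence[bool], group_labels: Optional[Sequence[object]] = None
) -> Dict[object, Optional[float]]:
    """Aggregates per 50 images, overall or per group.

    Returns ``{group: 50 * flagged / total}``; ungrouped input uses the
    single key ``None``.  An empty group maps to ``None`` (undefined).
    """
    if len(flags) == 0:
        raise ValueError("flags must be non-empty")
    if group_labels is None:
        group_labels = [None] * len(flags)
    if len(group_labels) != len(flags):
        raise ValueError("group_labels must match flags in length")
    totals: Dict[object, int] = {}
    hits: Dict[object, int] = {}
    for flag, grp in zip(flags, group_labels):
        totals[grp] = totals.get(grp, 0) + 1
        hits[grp] = hits.get(grp, 0) + bool(flag)
    return {
        grp: (50.0 * hits[grp] / totals[grp]) if totals[grp] else None
        for grp in totals
    }


def build_report(
    images: Sequence[GrayImage],
    config: AnalysisConfig | None = None,
    group_labels: Optional[Sequence[object]] = None,
) -> AggregateReport:
    """Run aggregate detection over an acquisition run."""
    config = config or AnalysisConfig()
    image_flags: Dict[str, Tuple[int, bool]] = {}
    flags: List[bool] = []
    for i, img in enumerate(images):
        count, flagged = detect_aggregate(img, config)
        image_flags[img.image_id or f"image_{i}"] = (count, flagged)
        flags.append(flagged)
    return AggregateReport(
        image_flags=image_flags,
        rate_per_50=aggregate_rate(flags, group_labels),
    )
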