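"""Analysis configuration.

All tunable parameters of the processing pipeline live in one flat
:class:`AnalysisConfig` so a whole run is reproducible from a single
YAML file.  Every field has a working default: the CLI runs with zero
configuration.

Intensities are always on the 8-bit [0, 255] scale (images of higher
bit depth are rescaled at load time), because the classic thresholds of
this pipeline — e.g. the constant confluence threshold 0.4 x 21.1 — are
stated in 8-bit grayscale units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Tuple

import yaml

#: Default physical pixel scale, micrometers per pixel.  Derived from a
#: 598 um field of view imaged onto a 1280 px detector row (598/1280).
DEFAULT_PIXEL_SCALE_UM = 598.0 / 1280.0

#: Nominal adherent-cell radius used to size the blob filter, um.
NOMINAL_CELL_RADIUS_UM = 10.0


@dataclass
class AnalysisConfig:
    """Tunable parameters for every pipeline stage.

    Fields left as ``None`` are derived at construction time from the
    pixel scale (blob-filter sizing, area gates) so that the defaults
    stay consistent when the magnification changes.
    """

    # --- geometry ---
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM

    # --- confluence segmentation ---
    confluence_kernel_px: int = 15
    confluence_overlap_fraction: float = 0.93
    confluence_threshold_factor: float = 0.35
    #: Constant-mode threshold in intensity-std units (0.4 x 21.1 is the
    #: classic fixed value the adaptive rule is compared against).
    constant_threshold: float = 0.4 * 21.1

    # --- microcarrier detection (circular Hough transform) ---
    hough_radius_range_px: Tuple[int, int] = (139, 268)
    hough_max_circles: int = 5
    #: Euclidean non-maximum-suppression distance; None = 1.2 x min radius.
    hough_min_separation_px: Optional[float] = None
    #: Minimum normalized accumulator score for a detection to count.
    hough_score_min: float = 0.25
    #: Gradient-magnitude percentile used to pick edge pixels.
    edge_percentile: float = 90.0

    # --- per-carrier cell counting (LoG blob detection) ---
    log_sigma_px: Optional[float] = None
    log_kernel_px: Optional[int] = None
    #: Raw-grayscale gate: LoG responses at darker pixels are discarded.
    cell_intensity_threshold: float = 170.0
    #: Fraction of the maximum positive (gated) LoG response used to
    #: binarize the response raster.
    log_response_fraction: float = 0.2
    cell_area_range_px2: Optional[Tuple[float, float]] = None

    # --- aggregate detection ---
    #: None = Otsu's method per image; otherwise a fixed 8-bit value.
    aggregate_binarize_threshold: Optional[float] = None
    aggregate_dilation_radius_px: int = 5
    carrier_area_range_px2: Optional[Tuple[float, float]] = None
    carrier_eccentricity_max: float = 0.8
    #: Optional extension: also flag an image when one merged component
    #: exceeds this multiple of carrier_area_range_px2 max (fused clumps
    #: evade the object-count rule).  None disables it (exact classic
    #: behaviour).
    aggregate_oversize_factor: Optional[float] = None

    # --- culture-level statistics ---
    carriers_per_ml: Optional[float] = None
    convergence_tolerance: float = 0.05
    histogram_bin_width: int = 5

    def __post_init__(self) -> None:
        if self.confluence_kernel_px < 3 or self.confluence_kernel_px % 2 == 0:
            raise ValueError("confluence_kernel_px must be odd and >= 3")
        if not 0.0 < self.confluence_overlap_fraction < 1.0:
            raise ValueError("confluence_overlap_fraction must be in (0, 1)")
        if self.confluence_threshold_factor < 0 or self.constant_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        rmin, rmax = self.hough_radius_range_px
        if not 0 < rmin < rmax:
            raise ValueError("hough_radius_range_px must satisfy 0 < min < max")
        if self.log_sigma_px is None:
            # Blob-matched sizing: LoG peak response for a Gaussian blob of
            # radius r occurs at sigma = r / sqrt(2).
            cell_radius_px = NOMINAL_CELL_RADIUS_UM / self.pixel_scale_um
            self.log_sigma_px = cell_radius_px / math.sqrt(2.0)
        if self.log_sigma_px <= 0:
            raise ValueError("log_sigma_px must be positive")
        if self.log_kernel_px is None:
            self.log_kernel_px = 2 * math.ceil(3.0 * self.log_sigma_px) + 1
        if self.log_kernel_px % 2 == 0:
            raise ValueError("log_kernel_px must be odd")
        if self.cell_area_range_px2 is None:
            # Accept components from ~1/4 to ~8x the nominal blob footprint.
            footprint = math.pi * self.log_sigma_px**2
            self.cell_area_range_px2 = (
                max(3.0, 0.25 * footprint),
                8.0 * footprint,
            )
        if self.carrier_area_range_px2 is None:
            grow = self.aggregate_dilation_radius_px
            self.carrier_area_range_px2 = (
                0.6 * math.pi * rmin**2,
                1.5 * math.pi * (rmax + grow) ** 2,
            )
        for name in ("cell_area_range_px2", "carrier_area_range_px2"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must have min < max")
        if not 0 <= self.carrier_eccentricity_max < 1:
            raise ValueError("carrier_eccentricity_max must be in [0, 1)")

    @property
    def min_separation_px(self) -> float:
        if self.hough_min_separation_px is not None:
            return self.hough_min_separation_px
        return 1.2 * self.hough_radius_range_px[0]

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        """Load a flat key/value YAML file; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hough_radius_range_px", "cell_area_range_px2",
                    "carrier_area_range_px2"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        out = {}
        for f in fields(self):
            val = getattr(self, f.name)
            if isinstance(val, tuple):
                val = list(val)
            out[f.name] = val
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
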