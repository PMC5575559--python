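"""Image and report I/O.

Images enter the pipeline as :class:`GrayImage`: a 2-D float raster on
the 8-bit [0, 255] scale regardless of source bit depth, with an
optional physical pixel scale.  TIFF (including multi-page stacks) and
PNG are supported; color frames are converted to luminance before
rescaling.

Per-image / per-carrier results are written as CSV or JSON via
:func:`write_report` and round-trip losslessly through
:func:`read_report`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .config import DEFAULT_PIXEL_SCALE_UM

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}

# ITU-R BT.601 luma weights for color -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """2-D grayscale raster with intensities on the [0, 255] scale.

    Parameters
    ----------
    pixels
        2-D float array; every value must be finite and in [0, 255].
    pixel_scale_um
        Physical size of one pixel in micrometers, if known.
    image_id
        Provenance label (filename / page), carried into reports.
    """

    pixels: np.ndarray
    pixel_scale_um: Optional[float] = DEFAULT_PIXEL_SCALE_UM
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("GrayImage requires a 2-D array")
        if min(px.shape) < 15:
            raise ValueError(
                "image must be at least 15 px on each side (one analysis "
                f"kernel must fit); got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]; rescale on load")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def _to_gray255(arr: np.ndarray, *, rescale: bool, source: str) -> np.ndarray:
    """Convert one decoded frame to float [0, 255]."""
    a = np.asarray(arr)
    if a.ndim == 3:  # color (H, W, C) -> luminance
        if a.shape[2] == 4:
            a = a[:, :, :3]
        a = a.astype(float) @ _LUMA
    elif a.ndim != 2:
        raise ValueError(f"{source}: unsupported image dimensionality {a.ndim}")
    a = a.astype(float)
    if rescale and arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer):
            full = float(np.iinfo(arr.dtype).max)
        else:
            full = float(a.max()) if a.max() > 0 else 1.0
        a = a * (255.0 / full)
    return np.clip(a, 0.0, 255.0)


def read_images(
    path,
    *,
    rescale: bool = True,
    pixel_scale_um: Optional[float] = DEFAULT_PIXEL_SCALE_UM,
) -> List[GrayImage]:
    """Load a file or a directory of TIFF/PNG images.

    Files are returned in lexicographic filename order; pages of a
    multi-page TIFF in page order.  16-bit inputs are linearly mapped to
    [0, 255] by dtype range when ``rescale`` is on.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist or a directory holds no images.
    ValueError
        Per-file, naming the file, if it cannot be decoded.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no images found in directory {p}")
    else:
        files = [p]

    images: List[GrayImage] = []
    for f in files:
        try:
            if f.suffix.lower() in (".tif", ".tiff"):
                pages = tifffile.imread(f)
                if pages.ndim == 2 or (pages.ndim == 3 and pages.shape[-1] in (3, 4)):
                    pages = pages[None]
            else:
                pages = iio.imread(f)[None]
        except Exception as exc:  # noqa: BLE001 - re-raise with filename
            raise ValueError(f"unreadable image file {f}: {exc}") from exc
        multi = pages.shape[0] > 1
        for i, page in enumerate(pages):
            image_id = f"{f.name}#{i}" if multi else f.name
            images.append(
                GrayImage(
                    _to_gray255(page, rescale=rescale, source=str(f)),
                    pixel_scale_um=pixel_scale_um,
                    image_id=image_id,
                )
            )
    return images


def write_image(image: GrayImage, path) -> None:
    """Write a GrayImage (or a binary mask scaled to 0/255) as 8-bit."""
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, arr)
    else:
        iio.imwrite(p, arr)


# ---------------------------------------------------------------------------
# Reports


@dataclass(frozen=True)
class CarrierRow:
    """One analyzed microcarrier inside one image."""

    center_row: float
    center_col: float
    radius_px: float
    score: float
    confluence_pct: Optional[float] = None
    cells_visible: Optional[int] = None
    cells_corrected: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cells_visible is not None:
            if self.cells_corrected != 2 * self.cells_visible:
                raise ValueError(
                    "cells_corrected must equal 2 x cells_visible "
                    f"(got {self.cells_corrected} vs 2 x {self.cells_visible})"
                )


@dataclass(frozen=True)
class ReportRecord:
    """All results for one image: carrier rows plus the aggregate flag."""

    image_id: str
    culture_day: Optional[int] = None
    carriers: Tuple[CarrierRow, ...] = ()
    is_aggregate: Optional[bool] = None


_CSV_COLUMNS = [
    "image_id", "culture_day", "is_aggregate", "carrier_index",
    "center_row", "center_col", "radius_px", "score",
    "confluence_pct", "cells_visible", "cells_corrected",
]


def _records_to_frame(records: Sequence[ReportRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        base = {
            "image_id": rec.image_id,
            "culture_day": rec.culture_day,
            "is_aggregate": rec.is_aggregate,
        }
        if not rec.carriers:
            rows.append({**base, "carrier_index": None})
            continue
        for i, c in enumerate(rec.carriers):
            rows.append({
                **base,
                "carrier_index": i,
                "center_row": c.center_row,
                "center_col": c.center_col,
                "radius_px": c.radius_px,
                "score": c.score,
                "confluence_pct": c.confluence_pct,
                "cells_visible": c.cells_visible,
                "cells_corrected": c.cells_corrected,
            })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_report(records: Sequence[ReportRecord], path, format: str = "csv") -> None:
    """Write one row per (image, carrier); carrier-free images get one
    image-level row with empty carrier fields.

    ``format`` is ``"csv"`` or ``"json"``; both round-trip losslessly
    through :func:`read_report`.
    """
    if not records:
        raise ValueError("write_report requires at least one record")
    p = Path(path)
    try:
        if format == "csv":
            _records_to_frame(records).to_csv(p, index=False)
        elif format == "json":
            payload = []
            for rec in records:
                payload.append({
                    "image_id": rec.image_id,
                    "culture_day": rec.culture_day,
                    "is_aggregate": rec.is_aggregate,
                    "carriers": [vars(c) for c in rec.carriers],
                })
            p.write_text(json.dumps(payload, indent=1))
        else:
            raise ValueError(f"unknown report format: {format!r}")
    except OSError as exc:
        raise OSError(f"cannot write report to {p}: {exc}") from exc


def _opt(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return cast(value)


def read_report(path, format: str = "csv") -> List[ReportRecord]:
    """Inverse of :func:`write_report` (order-preserving)."""
    p = Path(path)
    records: List[ReportRecord] = []
    if format == "json":
        for rec in json.loads(p.read_text()):
            carriers = tuple(CarrierRow(**c) for c in rec["carriers"])
            records.append(ReportRecord(
                image_id=rec["image_id"],
                culture_day=_opt(rec["culture_day"], int),
                carriers=carriers,
                is_aggregate=rec["is_aggregate"],
            ))
        return records
    if format != "csv":
        raise ValueError(f"unknown report format: {format!r}")
    df = pd.read_csv(p)
    for image_id, group in df.groupby("image_id", sort=False):
        first = group.iloc[0]
        carriers = []
        for _, row in group.iterrows():
            if _opt(row.get("carrier_index"), int) is None:
                continue
            carriers.append(CarrierRow(
                center_row=float(row["center_row"]),
                center_col=float(row["center_col"]),
                radius_px=float(row["radius_px"]),
                score=float(row["score"]),
                confluence_pct=_opt(row.get("confluence_pct"), float),
                cells_visible=_opt(row.get("cells_visible"), int),
                cells_corrected=_opt(row.get("cells_corrected"), int),
            ))
        records.append(ReportRecord(
            image_id=str(image_id),
            culture_day=_opt(first.get("culture_day"), int),
            carriers=tuple(carriers),
            is_aggregate=_opt(first.get("is_aggregate"), bool),
        ))
    return records
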