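"""Ground-truthed synthetic epi-illumination scenes.

The renderer emulates the three image classes the analysis pipeline
consumes — 2-D monolayers, single colonized microcarriers, and
multi-carrier fields — well enough to exercise every algorithm against
exact ground truth, with no optical physics: carriers are shaded disks
with a brighter rim, cells are additive Gaussian blobs (cells image
bright against the mid-gray carrier body and dark background), sensor
noise is i.i.d. Gaussian added last.  All randomness flows through
numpy's default PCG64 generator seeded from the scene seed, so scenes
are bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import GrayImage

# Default appearance (8-bit intensity units).  Chosen as plausible
# epi-illumination contrast: dark background, mid-gray carrier body,
# bright rim, cells clearly brighter than everything under them.
BACKGROUND_LEVEL = 30.0
CARRIER_BODY = 90.0
CARRIER_RIM = 150.0
CELL_AMPLITUDE = 130.0
CELL_SIGMA_PX = 2.5
MONOLAYER_BACKGROUND = 110.0
MONOLAYER_TEXTURE_STD = 45.0


@dataclass(frozen=True)
class CarrierSpec:
    center_row: float
    center_col: float
    radius_px: float
    rim_brightness: float = CARRIER_RIM
    body_brightness: float = CARRIER_BODY
    #: Fraction of the disk to fill with confluent high-variance texture.
    texture_fraction: float = 0.0


@dataclass(frozen=True)
class CellSpec:
    center_row: float
    center_col: float
    blob_sigma_px: float = CELL_SIGMA_PX
    amplitude: float = CELL_AMPLITUDE
    #: Index into the scene's carrier list the cell must sit on, or None
    #: for monolayer-style free placement.
    carrier_index: Optional[int] = None


@dataclass(frozen=True)
class SceneSpec:
    image_size_px: Tuple[int, int]
    carriers: Tuple[CarrierSpec, ...] = ()
    cells: Tuple[CellSpec, ...] = ()
    background_level: float = BACKGROUND_LEVEL
    noise_std: float = 0.0
    texture_std: float = MONOLAYER_TEXTURE_STD
    seed: int = 0


@dataclass(frozen=True)
class SceneTruth:
    """Exact ground truth for a rendered scene."""

    circles: Tuple[Tuple[float, float, float], ...]
    cell_centroids: Tuple[Tuple[float, float], ...]
    cell_footprint_areas_px2: Tuple[int, ...]
    true_foreground_fraction: Optional[float]
    is_aggregate: bool


def _validate(spec: SceneSpec) -> None:
    h, w = spec.image_size_px
    for i, c in enumerate(spec.carriers):
        if (c.center_row - c.radius_px < 0 or c.center_row + c.radius_px > h - 1
                or c.center_col - c.radius_px < 0
                or c.center_col + c.radius_px > w - 1):
            raise ValueError(f"carrier {i} extends outside the image bounds")
        if not 0.0 <= c.texture_fraction <= 1.0:
            raise ValueError(f"carrier {i} texture_fraction outside [0, 1]")
    for j, cell in enumerate(spec.cells):
        if cell.carrier_index is not None:
            if not 0 <= cell.carrier_index < len(spec.carriers):
                raise ValueError(f"cell {j} names a nonexistent carrier")
            carrier = spec.carriers[cell.carrier_index]
            d = math.hypot(cell.center_row - carrier.center_row,
                           cell.center_col - carrier.center_col)
            if d > carrier.radius_px:
                raise ValueError(f"cell {j} lies outside carrier "
                                 f"{cell.carrier_index}")
        elif not (0 <= cell.center_row < h and 0 <= cell.center_col < w):
            raise ValueError(f"cell {j} lies outside the image bounds")


def render_scene(spec: SceneSpec) -> Tuple[GrayImage, SceneTruth]:
    """Render a scene and its exact ground truth (deterministic per seed)."""
    _validate(spec)
    h, w = spec.image_size_px
    rng = np.random.default_rng(spec.seed)
    canvas = np.full((h, w), float(spec.background_level))

    textured_px = 0
    in_circle_px = 0
    for c in spec.carriers:
        rows = np.arange(h)[:, None] - c.center_row
        cols = np.arange(w)[None, :] - c.center_col
        d = np.sqrt(rows * rows + cols * cols)
        inside = d <= c.radius_px
        rim_w = max(2.0, 0.05 * c.radius_px)
        shade = c.body_brightness + (c.rim_brightness - c.body_brightness) * \
            np.exp(-((c.radius_px - d) / rim_w) ** 2)
        canvas[inside] = shade[inside]
        in_circle_px += int(inside.sum())
        if c.texture_fraction > 0:
            # Confluent texture over a chord segment covering exactly the
            # requested fraction of in-disk pixels (random orientation).
            phi = rng.uniform(0, 2 * np.pi)
            s = np.cos(phi) * rows + np.sin(phi) * cols
            s_in = s[inside]
            n_tex = int(round(c.texture_fraction * s_in.size))
            if n_tex > 0:
                order = np.argsort(s_in, kind="stable")[::-1][:n_tex]
                tex_mask = np.zeros(s_in.size, dtype=bool)
                tex_mask[order] = True
                full = np.zeros_like(inside)
                full[inside] = tex_mask
                canvas[full] += rng.normal(0.0, spec.texture_std,
                                           size=n_tex)
                textured_px += n_tex

    centroids: List[Tuple[float, float]] = []
    footprints: List[int] = []
    for cell in spec.cells:
        s = cell.blob_sigma_px
        half = int(math.ceil(4 * s))
        r0 = max(0, int(math.floor(cell.center_row)) - half)
        r1 = min(h - 1, int(math.ceil(cell.center_row)) + half)
        c0 = max(0, int(math.floor(cell.center_col)) - half)
        c1 = min(w - 1, int(math.ceil(cell.center_col)) + half)
        rows = np.arange(r0, r1 + 1)[:, None] - cell.center_row
        cols = np.arange(c0, c1 + 1)[None, :] - cell.center_col
        blob = cell.amplitude * np.exp(-(rows * rows + cols * cols) / (2 * s * s))
        canvas[r0:r1 + 1, c0:c1 + 1] += blob
        centroids.append((cell.center_row, cell.center_col))
        footprints.append(int((blob >= cell.amplitude / 2.0).sum()))

    canvas = np.clip(canvas, 0.0, 255.0)
    if spec.noise_std > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_std, size=canvas.shape)
        canvas = np.clip(canvas, 0.0, 255.0)

    fraction = textured_px / in_circle_px if in_circle_px and textured_px else None
    truth = SceneTruth(
        circles=tuple((c.center_row, c.center_col, c.radius_px)
                      for c in spec.carriers),
        cell_centroids=tuple(centroids),
        cell_footprint_areas_px2=tuple(footprints),
        true_foreground_fraction=fraction,
        is_aggregate=len(spec.carriers) > 2,
    )
    return GrayImage(canvas, image_id=f"scene_{spec.seed}"), truth


def render_monolayer(
    target_foreground_fraction: float,
    image_size_px: Tuple[int, int] = (768, 768),
    seed: int = 0,
    background_level: float = MONOLAYER_BACKGROUND,
    texture_std: float = MONOLAYER_TEXTURE_STD,
    noise_std: float = 0.0,
) -> Tuple[GrayImage, SceneTruth]:
    """Render a monolayer: a cell-textured region on flat background.

    The region is the super-level set of a randomly oriented, wavy
    near-axis ramp (a spatially correlated random field), thresholded at
    the exact pixel quantile so the realized fraction equals the target
    to within one pixel; the realized value is recorded exactly in the
    truth.  The near-axis orientation bounds the boundary length, which
    keeps the kernel-edge bias of window-based segmentation small and
    roughly independent of the target fraction.
    """
    if not 0.0 <= target_foreground_fraction <= 1.0:
        raise ValueError("target fraction must lie in [0, 1]")
    h, w = image_size_px
    rng = np.random.default_rng(seed)
    n_total = h * w
    n_fg = int(round(target_foreground_fraction * n_total))

    canvas = np.full((h, w), float(background_level))
    region = np.zeros((h, w), dtype=bool)
    if n_fg > 0:
        theta = math.radians(rng.integers(0, 4) * 90 + rng.uniform(-20, 20))
        y, x = np.mgrid[0:h, 0:w].astype(float)
        ramp = math.cos(theta) * x + math.sin(theta) * y
        wave = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 8)
        wstd = wave.std()
        if wstd > 0:
            wave *= (0.05 * min(h, w)) / wstd
        fld = ramp + wave
        order = np.argsort(fld.ravel(), kind="stable")[::-1][:n_fg]
        region.ravel()[order] = True
        canvas[region] += rng.normal(0.0, texture_std, size=n_fg)
    if noise_std > 0:
        canvas += rng.normal(0.0, noise_std, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)

    truth = SceneTruth(
        circles=(),
        cell_centroids=(),
        cell_footprint_areas_px2=(),
        true_foreground_fraction=n_fg / n_total,
        is_aggregate=False,
    )
    return GrayImage(canvas, image_id=f"monolayer_{seed}"), truth


def _place_cells(
    rng: np.random.Generator,
    carrier: CarrierSpec,
    n_cells: int,
    carrier_index: int,
    min_separation_px: float = 12.0,
    placement_fraction: float = 0.78,
    hemisphere: bool = False,
) -> List[CellSpec]:
    """Dart-throw ``n_cells`` well-separated blobs onto a carrier disk.

    With ``hemisphere`` on, cells go only on the upper half-disk, making
    the x2 hemisphere correction exact by construction.
    """
    rmax = placement_fraction * carrier.radius_px
    placed: List[Tuple[float, float]] = []
    attempts = 0
    while len(placed) < n_cells:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError(
                f"could not place {n_cells} cells with separation "
                f"{min_separation_px} on radius {carrier.radius_px}"
            )
        rho = rmax * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        rr = carrier.center_row + rho * math.sin(phi)
        cc = carrier.center_col + rho * math.cos(phi)
        if hemisphere and rr > carrier.center_row:
            continue
        if all((rr - p[0]) ** 2 + (cc - p[1]) ** 2 >= min_separation_px**2
               for p in placed):
            placed.append((rr, cc))
    return [CellSpec(center_row=p[0], center_col=p[1],
                     carrier_index=carrier_index) for p in placed]


def make_carrier_scene(
    seed: int,
    n_cells: int = 0,
    n_carriers: int = 1,
    image_size_px: Tuple[int, int] = (320, 320),
    radius_range_px: Tuple[float, float] = (60, 100),
    noise_std: float = 0.0,
    texture_fraction: float = 0.0,
    hemisphere: bool = False,
) -> SceneSpec:
    """Build a SceneSpec with ``n_carriers`` non-touching carriers.

    Carriers are placed in close proximity (gaps wide enough that a
    5 px dilation cannot merge them) with the first ``n_cells`` cells on
    the first carrier.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size_px
    margin = 6.0
    gap = 18.0  # > 2 x default dilation radius + rasterization slack
    carriers: List[CarrierSpec] = []
    attempts = 0
    while len(carriers) < n_carriers:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place carriers without contact")
        r = rng.uniform(*radius_range_px)
        if not carriers:
            rr = rng.uniform(r + margin, h - 1 - r - margin)
            cc = rng.uniform(r + margin, w - 1 - r - margin)
        else:
            anchor = carriers[rng.integers(len(carriers))]
            phi = rng.uniform(0, 2 * np.pi)
            d = anchor.radius_px + r + rng.uniform(gap, gap + 30)
            rr = anchor.center_row + d * math.sin(phi)
            cc = anchor.center_col + d * math.cos(phi)
        ok = (r + margin <= rr <= h - 1 - r - margin
              and r + margin <= cc <= w - 1 - r - margin)
        ok = ok and all(
            math.hypot(rr - c.center_row, cc - c.center_col)
            >= r + c.radius_px + gap
            for c in carriers
        )
        if ok:
            carriers.append(CarrierSpec(
                center_row=rr, center_col=cc, radius_px=r,
                texture_fraction=texture_fraction if not carriers else 0.0,
            ))
    cells: List[CellSpec] = []
    if n_cells:
        cells = _place_cells(rng, carriers[0], n_cells, 0,
                             hemisphere=hemisphere)
    return SceneSpec(
        image_size_px=image_size_px,
        carriers=tuple(carriers),
        cells=tuple(cells),
        noise_std=noise_std,
        seed=seed,
    )


_SUITE_KINDS = ("monolayer", "single-carrier", "pair", "aggregate")


def render_suite(
    kind: str, n_scenes: int, seed: int, **kwargs
) -> List[Tuple[GrayImage, SceneTruth]]:
    """Render a parameter-randomized suite, reproducible end-to-end.

    ``kind`` is one of ``monolayer`` (random target fraction),
    ``single-carrier`` (one colonized carrier), ``pair`` (two separated
    carriers) or ``aggregate`` (3-4 carriers in close proximity, flagged
    as aggregates).  Scene i uses seed ``seed + i``.
    """
    if kind not in _SUITE_KINDS:
        raise ValueError(f"unknown suite kind {kind!r}; expected one of "
                         f"{_SUITE_KINDS}")
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out = []
    for i in range(n_scenes):
        scene_seed = seed + i
        if kind == "monolayer":
            rng = np.random.default_rng(scene_seed)
            frac = kwargs.get("target_foreground_fraction",
                              float(rng.uniform(0.1, 0.9)))
            out.append(render_monolayer(
                frac, seed=scene_seed,
                image_size_px=kwargs.get("image_size_px", (768, 768)),
            ))
        else:
            n_carriers = {"single-carrier": 1, "pair": 2}.get(kind)
            if n_carriers is None:  # aggregate: 3 or 4 carriers
                n_carriers = 3 + (scene_seed % 2)
            params = dict(kwargs)
            params.setdefault("image_size_px",
                              (320, 320) if n_carriers == 1 else (560, 560))
            params.setdefault("radius_range_px",
                              (60, 100) if n_carriers == 1 else (55, 75))
            if kind == "single-carrier":
                rng = np.random.default_rng(scene_seed ^ 0x5EED)
                params.setdefault("n_cells", int(rng.integers(5, 31)))
            spec = make_carrier_scene(
                seed=scene_seed, n_carriers=n_carriers, **params
            )
            out.append(render_scene(spec))
    return out
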