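import numpy as np
import pytest

from carrierscope import AnalysisConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scene_config():
    """Config matched to the synthetic renderer's default appearance."""
    return AnalysisConfig(
        hough_radius_range_px=(55, 105),
        log_sigma_px=2.5,
        cell_intensity_threshold=170.0,
    )


def window_std_oracle(pixels: np.ndarray, k: int, stride: int = 1) -> np.ndarray:
    """Exhaustive any-window max-accumulated population-std raster."""
    h, w = pixels.shape
    rows = list(range(0, h - k + 1, stride))
    cols = list(range(0, w - k + 1, stride))
    if rows[-1] != h - k:
        rows.append(h - k)
    if cols[-1] != w - k:
        cols.append(w - k)
    out = np.full(pixels.shape, -np.inf)
    for i in rows:
        for j in cols:
            s = np.std(pixels[i:i + k, j:j + k])
            out[i:i + k, j:j + k] = np.maximum(out[i:i + k, j:j + k], s)
    return out


def flood_fill_labels(binary: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components as pixel sets, by iterative flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    h, w = binary.shape
    for sr in range(h):
        for sc in range(w):
            if not binary[sr, sc] or seen[sr, sc]:
                continue
            stack, comp = [(sr, sc)], set()
            seen[sr, sc] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w
                                and binary[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
    return comps
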