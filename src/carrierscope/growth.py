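"""Culture-level growth statistics.

Per-carrier corrected cell counts feed three summaries: the running
mean of cells per carrier versus the number of carriers analyzed (to
decide how many images a statistically stable count needs — typically a
few tens of carriers), colonization histograms normalized to each day's
maximum bin (bead-to-bead transfer), and the day-by-day growth profile
in cells per carrier and cells per mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cells import CarrierAnalysis, cell_density


@dataclass(frozen=True)
class GrowthPoint:
    """One culture day's summary."""

    culture_day: int
    n_carriers_analyzed: int
    mean_cells_per_carrier: float
    cell_density_per_ml: Optional[float]


@dataclass(frozen=True)
class ColonizationHistogram:
    """Cells-per-carrier histogram, max-bin normalized to 1."""

    bin_edges: np.ndarray
    normalized_frequency: np.ndarray


def running_mean(counts: Sequence[float]) -> np.ndarray:
    """Partial means: element k is the mean of the first k+1 counts."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("counts must be non-empty")
    return np.cumsum(c) / np.arange(1, c.size + 1)


def convergence_index(
    partial_means: Sequence[float], tolerance_fraction: float = 0.05
) -> int:
    """Carriers needed before the running mean settles.

    Returns the smallest 1-based k such that every partial mean from
    position k onward lies within ``tolerance_fraction`` (relative) of
    the final mean, or the sequence length if that never happens before
    the end.  When the final mean is 0 the rule degenerates to absolute
    deviation <= tolerance_fraction.
    """
    m = np.asarray(partial_means, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 partial means")
    if not 0.0 < tolerance_fraction < 1.0:
        raise ValueError("tolerance_fraction must be in (0, 1)")
    final = m[-1]
    band = abs(final) * tolerance_fraction if final != 0.0 else tolerance_fraction
    ok = np.abs(m - final) <= band
    # smallest k with ok[k-1:] all true
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return 1
    return min(int(bad[-1]) + 2, m.size)


def colonization_histogram(
    counts: Sequence[float], bin_width: int = 5
) -> ColonizationHistogram:
    """Histogram of cells per carrier, normalized to the maximum bin.

    Bins of the given width cover [0, max count]; frequencies are
    divided by the largest bin count so the fullest bin reads 1.0.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("counts must be non-empty")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n_bins = int(c.max() // bin_width) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width, dtype=float)
    freq, _ = np.histogram(c, bins=edges)
    peak = freq.max()
    return ColonizationHistogram(
        bin_edges=edges,
        normalized_frequency=freq / peak,
    )


def build_growth_profile(
    per_day_analyses: Dict[int, Sequence[CarrierAnalysis]],
    carriers_per_ml: Optional[float] = None,
) -> List[GrowthPoint]:
    """One GrowthPoint per culture day, days ascending.

    The mean is taken over the hemisphere-corrected counts of that
    day's analyzed carriers; density is omitted (None) when the carrier
    concentration is unknown.  Days with no analyzable carriers are
    skipped rather than reported as zero.
    """
    points: List[GrowthPoint] = []
    for day in sorted(per_day_analyses):
        analyses = per_day_analyses[day]
        if not analyses:
            continue
        corrected = [a.cells_corrected for a in analyses]
        mean = float(np.mean(corrected))
        density = (
            cell_density(mean, carriers_per_ml)
            if carriers_per_ml is not None
            else None
        )
        points.append(
            GrowthPoint(
                culture_day=int(day),
                n_carriers_analyzed=len(corrected),
                mean_cells_per_carrier=mean,
                cell_density_per_ml=density,
            )
        )
    if not points:
        raise ValueError("no day has any analyzed carriers")
    return points
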