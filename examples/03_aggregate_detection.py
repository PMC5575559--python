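"""Flag microcarrier aggregates over a simulated acquisition run.

Renders 15 scenes (5 singles, 5 pairs, 5 clumps of 3-4 carriers) and
reports which images are flagged and the rate per 50 images — the unit
used to track aggregation over a culture.
"""

from carrierscope import AnalysisConfig, detect_aggregate, render_suite
from carrierscope.aggregates import aggregate_rate

config = AnalysisConfig(hough_radius_range_px=(55, 105))

flags, truth_flags = [], []
for kind in ("single-carrier", "pair", "aggregate"):
    for image, truth in render_suite(kind, 5, seed=11):
        n_objects, flagged = detect_aggregate(image, config)
        flags.append(flagged)
        truth_flags.append(truth.is_aggregate)
        print(f"{kind:15s} carriers={len(truth.circles)} "
              f"objects={n_objects} flagged={flagged}")

rate = aggregate_rate(flags)[None]
correct = sum(a == b for a, b in zip(flags, truth_flags))
print(f"\naggregate rate: {rate:.2f} per 50 images "
      f"({correct}/{len(flags)} images classified correctly)")
# An image is an aggregate when more than two carrier-like objects
# (area and eccentricity within carrier bounds) appear after
# binarization and dilation.
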