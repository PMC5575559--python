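"""Detect a microcarrier, count the cells on it, correct for the
hidden hemisphere, and convert to a culture density.

The scene renderer places a known number of cells, so the printed
detection count can be checked against the truth.
"""

from carrierscope import (
    AnalysisConfig,
    cell_density,
    crop_to_circle,
    detect_cells,
    detect_circles,
    hemisphere_corrected_count,
    make_carrier_scene,
    render_scene,
)

config = AnalysisConfig(hough_radius_range_px=(55, 105), log_sigma_px=2.5,
                        cell_intensity_threshold=170.0)

image, truth = render_scene(
    make_carrier_scene(seed=5, n_cells=18, noise_std=5.0,
                       radius_range_px=(80, 100)))

(circle,) = detect_circles(image, max_circles=1, config=config)
print(f"carrier at ({circle.center_row:.0f}, {circle.center_col:.0f}), "
      f"radius {circle.radius_px:.0f} px "
      f"(true radius {truth.circles[0][2]:.0f} px)")

crop = crop_to_circle(image, circle, margin_px=config.log_kernel_px // 2)
cells = detect_cells(crop, config=config)
visible = len(cells)
corrected = hemisphere_corrected_count(visible)
print(f"cells visible: {visible} (rendered: {len(truth.cell_centroids)})")
print(f"hemisphere-corrected count: {corrected}")
print(f"at 1,000 carriers/mL -> {cell_density(corrected, 1000.0):.0f} cells/mL")
# Only the upper hemisphere faces the camera, hence the x2 correction;
# the density is simply mean cells/carrier times carrier concentration.
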