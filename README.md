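# carrierscope

Non-invasive image analysis for adherent cell cultures on microcarriers.

Anchorage-dependent cells such as mesenchymal stem cells are expanded at
scale on small (~100–300 µm) spherical microcarriers suspended in stirred
vessels. The standard way to follow such a culture — sampling, lysing or
detaching the cells, and counting off-line — destroys the sample and adds
handling error. When the culture is instead imaged in situ (epi-illumination
grayscale microscopy, where attached cells appear as locally bright,
high-texture regions), the monitoring problem becomes an image-analysis
problem. `carrierscope` implements that analysis as a tested Python library
with a thin CLI:

- **Confluence** — cells are separated from background by local intensity
  variability: a 15×15 px kernel slides across the image (93% overlap,
  i.e. stride 1) and a window is "cell" when its population standard
  deviation reaches an adaptive threshold, `0.35 · σ_image`. Confluence is
  the percentage of pixels classified as cell. A constant-threshold mode
  (`0.4 × 21.1`) is kept for comparison.
- **Carrier isolation** — microcarriers are found with a circular Hough
  transform over Sobel edges and cropped to their bounding disk.
- **Cell counting** — cells on an isolated carrier are detected by a
  Laplacian-of-Gaussian blob filter, gated by raw grayscale value,
  binarized and filtered by component area. Because only the upper
  hemisphere faces the camera the visible count is doubled
  (`cells_corrected = 2 × cells_visible`); multiplying the per-carrier
  mean by the carrier concentration gives cells/mL.
- **Aggregate detection** — binarize (Otsu), dilate, label, keep
  carrier-like objects by area and eccentricity; an image with more than
  two carriers is flagged, and rates are reported per 50 images.
- **Growth statistics** — running-mean convergence of cells per carrier,
  day-normalized colonization histograms, and day-by-day growth profiles.
- **Synthetic scenes** — a seeded renderer produces monolayers, colonized
  carriers and multi-carrier fields with exact ground truth, so every
  stage above is validated quantitatively without a microscope.

## Worked example

`examples/02_count_cells_on_carrier.py` renders a carrier bearing 18
cells with sensor noise, finds it, and counts:

```
carrier at (195, 161), radius 96 px (true radius 96 px)
cells visible: 18 (rendered: 18)
hemisphere-corrected count: 36
at 1,000 carriers/mL -> 36000 cells/mL
```

The Hough detection recovers the carrier's position and radius to the
pixel, all 18 rendered blobs are found, and the corrected count doubles
the visible one before conversion to a culture density. The other
examples cover confluence (`01`), aggregates (`03`), growth statistics
(`04`) and the batch CLI (`05`).

The same analyses run from the shell on TIFF/PNG folders:

```bash
carrierscope --config cfg.yaml count images/ --output counts.csv --day 4
carrierscope aggregates images/ --output agg.csv --group-by-day
carrierscope growth counts.csv --output growth.csv --carriers-per-ml 1000
carrierscope simulate --kind aggregate --n 10 --seed 1 --out-dir scenes/
```

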