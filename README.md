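# perimt

Quantification of peripheral microtubule (MT) organization and
motor-driven MT sliding in pancreatic β cells.

In β cells, kinesin-1 (KIF5B) slides microtubules along one another,
and this sliding builds and remodels the sub-membrane MT array — the
bundle of filaments running parallel to the plasma membrane within
1–2 µm of the cell border. Assessing that biology needs four
quantitative readouts, which this package implements as a tested,
reusable library with synthetic-data generators that provide ground
truth for every stage:

1. **Border-relative MT directionality.** Per-pixel orientation from
   the structure tensor (inconclusive pixels gated by coherence),
   compared with the tangent of the nearest cell border; the acute
   angle α ∈ [0°, 90°] is histogrammed in 10° bins within the outer
   1 µm, the 0–10° bin being the border-parallel share. Preceded by
   Richardson–Lucy deconvolution and isodata thresholding (standard,
   peripheral-optimized "perfect", or population variants).
2. **Belt-FRAP sliding.** Two large regions are photobleached, leaving
   a central fluorescent belt; the thresholded area of high-signal MTs
   appearing in the bleached zones, read out after 5 min of recovery,
   is the sliding measure (µm² per cell).
3. **Fiducial-mark motility.** Marks bound to the MT lattice are
   tracked; tracks are resampled in time, segmented into 5 s windows,
   and each window's net displacement is classified — stationary
   < 0.15 µm, motile > 0.3 µm — and binned at 0.05 µm.
4. **Intensity statistics.** Mean tubulin intensity in the outer 2 µm
   band; depletion folds normalized to marker-negative cells of the
   same field of view; per-bin Welch t-tests and pooled
   Kolmogorov–Smirnov comparison between cell groups.

See `docs/methods.md` for the models, conventions, and calibration
choices, and `analysis/01…05_*.py` for the narrative drivers that
exercise each readout and write tables under `results/`.

## Worked example

```python
import numpy as np
from perimt import (angle_to_border, bin_directionality, compute_border_geometry,
                    compute_orientation_field, per_cell_perfect_threshold,
                    richardson_lucy_deconvolve)
from perimt.synthetic import FilamentSpec, generate_cell_mask, render_mt_image

cell = generate_cell_mask(shape="ellipse", size_um=(9.5, 8.0), seed=1)
image, truth = render_mt_image(
    cell, FilamentSpec(n_filaments=90, orientation_model="parallel_to_border"), seed=2)

img = richardson_lucy_deconvolve(image, psf_sigma_um=0.15, iterations=30)
thr = per_cell_perfect_threshold(img, cell, band_width_um=1.0)
field = compute_orientation_field(img, thr.mt_mask)
geom = compute_border_geometry(cell)
hist = bin_directionality(angle_to_border(field, geom), geom, band_um=(0.0, 1.0))
print(f"{hist.n_pixels} valid pixels, parallel (0-10°) fraction {hist.parallel_fraction:.3f}")
```

prints

```
483 valid pixels, parallel (0-10°) fraction 0.965
```

— the cell was rendered with every filament along its local border
tangent, and 96% of conclusive outer-1µm pixels land in the 0–10° bin
(the remainder reflects filament chord-vs-curved-border geometry and
estimator noise at filament ends). Running the same chain on an
isotropic render gives a flat histogram (~1/9 per bin).

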