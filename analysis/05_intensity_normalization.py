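#!/usr/bin/env python
"""Peripheral intensity and marker-normalized depletion folds.

Measures mean tubulin intensity in the outer 2 µm band of a synthetic
cell, then recovers a known 0.3 depletion fold from a noisy field of
view by normalizing marker-positive cells to the marker-negative mean.
Writes the per-cell fold table to results/intensity/.
"""

from pathlib import Path

import pandas as pd

from perimt import build_report, depletion_fold, peripheral_mean_intensity
from perimt.synthetic import generate_fov_intensity, render_mt_image
from perimt.workflows import PARALLEL_SPEC, intensity_study, make_cell

OUT = Path(__file__).resolve().parent.parent / "results" / "intensity"
SEED = 1


def main() -> None:
    cell = make_cell(SEED)
    image, _ = render_mt_image(cell, PARALLEL_SPEC, seed=SEED + 1)
    band_mean = peripheral_mean_intensity(image, cell, 2.0)
    cell_mean = image.pixels[cell.mask].mean()
    print(f"peripheral (outer 2 µm) mean intensity {band_mean:.1f} vs "
          f"whole-cell mean {cell_mean:.1f} "
          f"(peripheral array enriches the band: {band_mean > cell_mean})")

    study = intensity_study(seed=SEED, fold=0.3, n=50)
    print(f"depletion fold: true {study['true_fold']:.2f}, recovered "
          f"{study['mean_fold']:.3f} ± {study['sem_fold']:.3f} SEM "
          f"(n = {study['n_positive']} positive cells)")

    fov, _ = generate_fov_intensity(50, 50, fold=0.3, noise_cv=0.1, seed=SEED)
    folds = depletion_fold(fov)
    table = fov.cells.merge(folds[["cell_id", "fold"]], on="cell_id", how="left")
    build_report(OUT, intensity=table)
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
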