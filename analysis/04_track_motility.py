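#!/usr/bin/env python
"""Fiducial-mark motility: 5 s displacement classification and binning.

Simulates static (localization noise only) and directed track panels,
classifies 5 s window displacements with the 0.15 / 0.3 µm cut-offs,
recovers mixture fractions, and checks the 0.05 µm displacement
histogram against the closed-form Rayleigh law. Writes per-cell motility
fractions and the binned distribution to results/motility/.
"""

from pathlib import Path

import pandas as pd

from perimt import build_report
from perimt.synthetic import simulate_tracks
from perimt.track_motility import bin_displacements, classify_motility, five_second_displacements
from perimt.workflows import displacement_binning_study, motility_study

OUT = Path(__file__).resolve().parent.parent / "results" / "motility"
SEED = 1


def main() -> None:
    study = motility_study(seed=SEED, n_tracks=1000)
    print(f"static tracks  : {study['f_stationary_static']:.1%} of "
          f"{study['n_windows_static']} windows stationary (< 0.15 µm / 5 s)")
    print(f"directed tracks: {study['f_motile_directed']:.1%} of "
          f"{study['n_windows_directed']} windows motile (> 0.3 µm / 5 s)")
    print("mixture recovery (true -> measured motile fraction):")
    for truth, est in study["mixtures"].items():
        print(f"  {truth:.2f} -> {est:.3f}")

    ray = displacement_binning_study(seed=SEED)
    print(f"Rayleigh law: max per-0.05µm-bin deviation "
          f"{ray['max_bin_deviation']:.4f} over {ray['n_windows']} displacements "
          f"(mean {ray['mean_displacement_um']:.4f} µm vs closed form "
          f"{ray['rayleigh_mean_um']:.4f} µm)")

    ts, _ = simulate_tracks(n_tracks=500, f_stationary=0.5, f_motile=0.5,
                            seed=SEED + 1)
    rec = five_second_displacements(ts)
    summary = classify_motility(rec)
    per_cell_bins, population_bins = bin_displacements(rec)
    build_report(OUT, motility=summary.per_cell)
    per_cell_bins.to_csv(OUT / "displacement_bins_per_cell.csv", index=False)
    population_bins.to_csv(OUT / "displacement_bins_population.csv", index=False)
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
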