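#!/usr/bin/env python
"""Generate one example of each synthetic input and write it to disk.

Produces, under results/example_data/: a tubulin-like image + mask of a
cell with a border-parallel peripheral MT array (TIFF), a belt-FRAP time
series (TIFF), a fiducial-mark track table (CSV), and the scene
parameters (YAML). These files are what the downstream drivers and any
external viewer consume; every quantitative analysis regenerates its own
inputs in memory, so this driver is illustrative, not load-bearing.
"""

from pathlib import Path

import yaml

from perimt import save_mask_tiff, save_tiff
from perimt.params import PixelCalibration
from perimt.synthetic import simulate_frap_series, simulate_tracks
from perimt.synthetic import render_mt_image
from perimt.track_motility import write_tracks_csv
from perimt.workflows import PARALLEL_SPEC, make_cell

OUT = Path(__file__).resolve().parent.parent / "results" / "example_data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cell = make_cell(SEED)
    image, truth = render_mt_image(cell, PARALLEL_SPEC, seed=SEED + 1)
    save_tiff(OUT / "cell_tubulin.tif", image)
    save_mask_tiff(OUT / "cell_mask.tif", cell)
    print(f"cell image: {image.pixels.shape} px, mask area {cell.area_um2:.1f} µm², "
          f"{len(truth.filament_angles_deg)} filaments (all border-parallel)")

    frap_cal = PixelCalibration(pixel_size_um=0.1, frame_interval_s=10.0)
    series, frap_truth, _ = simulate_frap_series(
        cell, n_translocating=5, calibration=frap_cal, seed=SEED + 2)
    save_tiff(OUT / "frap_series.tif", series)
    print(f"FRAP series: {series.pixels.shape[0]} frames at 10 s; true displaced "
          f"area at 300 s = {frap_truth.translocated_area_um2[30]:.2f} µm²")

    tracks, track_truth = simulate_tracks(
        n_tracks=200, f_stationary=0.5, f_motile=0.5, seed=SEED + 3)
    write_tracks_csv(tracks, OUT / "tracks.csv")
    n_mot = sum(1 for v in track_truth.track_labels.values() if v == "motile")
    print(f"tracks: {len(tracks)} tracks ({n_mot} motile), 120 s at 1 s sampling")

    scene = {
        "seed": SEED,
        "pixel_size_um": 0.1,
        "frap_frame_interval_s": 10.0,
        "filaments": {"n": PARALLEL_SPEC.n_filaments,
                      "model": PARALLEL_SPEC.orientation_model,
                      "length_um": PARALLEL_SPEC.length_um},
    }
    (OUT / "scene.yaml").write_text(yaml.safe_dump(scene, sort_keys=True))
    print(f"wrote example data to {OUT}")


if __name__ == "__main__":
    main()
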