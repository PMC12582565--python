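#!/usr/bin/env python
"""Belt-FRAP sliding quantification across known translocation levels.

Simulates post-bleach series with 0/1/3/5/10 sliding MTs in one fixed
cell geometry, measures the displaced MT area at the 300 s readout, and
reports recovery against the rendered ground truth. Writes the per-frame
area curve of the 5-MT condition and the level summary to results/frap/.
"""

from pathlib import Path

import pandas as pd

from perimt import build_report
from perimt.workflows import frap_study

OUT = Path(__file__).resolve().parent.parent / "results" / "frap"
SEED = 1


def main() -> None:
    study = frap_study(seed=SEED)
    rows = []
    for n, level in study["levels"].items():
        m = level["measure"]
        rows.append({"n_translocating": n,
                     "readout_area_um2": m.readout_area_um2,
                     "truth_area_um2": level["truth_area_um2"],
                     "threshold": m.threshold,
                     "belt_area_um2": m.belt_area_um2})
        print(f"n={n:2d} sliding MTs: readout {m.readout_area_um2:5.2f} µm² "
              f"(truth {level['truth_area_um2']:5.2f} µm²)")
    print(f"strictly increasing readout: {study['strictly_increasing']}; "
          f"worst relative error {study['max_relative_error']:.1%}")

    m5 = study["levels"][5]["measure"]
    curve = pd.DataFrame({"frame": range(len(m5.area_um2)), "t_s": m5.times_s,
                          "area_um2": m5.area_um2})
    build_report(OUT, frap=curve)
    pd.DataFrame(rows).to_csv(OUT / "levels.csv", index=False)
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
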