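"""Synthetic fields of view with marker-positive and -negative cells.

Emulates depletion quantification: marker-negative cells are drawn around
a base mean intensity M, marker-positive cells around ``fold * M``, each
with a Gaussian coefficient of variation. Per-cell means and positivity
flags are recorded; the downstream normalized fold is the per-positive
mean divided by the mean of negatives in the same field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .truth import GroundTruth


@dataclass
class FieldOfView:
    """Per-cell mean intensities of one imaged field."""

    cells: pd.DataFrame  # columns: cell_id, positive (bool), mean_intensity
    fov_id: str = "fov_0"

    def __post_init__(self) -> None:
        missing = [c for c in ("cell_id", "positive", "mean_intensity") if c not in self.cells.columns]
        if missing:
            raise ValueError(f"FOV table missing columns: {missing}")
        if not (~self.cells["positive"]).any():
            raise ValueError("field of view has no marker-negative cells (normalizer undefined)")


def generate_fov_intensity(
    n_positive: int,
    n_negative: int,
    fold: float,
    noise_cv: float = 0.1,
    seed: int = 0,
    base_mean: float = 100.0,
    fov_id: str = "fov_0",
) -> tuple[FieldOfView, GroundTruth]:
    if n_negative < 1:
        raise ValueError("need at least one marker-negative cell")
    if fold <= 0:
        raise ValueError("fold must be > 0")
    rng = np.random.default_rng(seed)

    neg = base_mean * np.ones(n_negative)
    pos = fold * base_mean * np.ones(n_positive)
    if noise_cv > 0:
        neg = neg * (1 + rng.normal(0, noise_cv, n_negative))
        pos = pos * (1 + rng.normal(0, noise_cv, n_positive))

    cells = pd.DataFrame(
        {
            "cell_id": [f"{fov_id}_c{i}" for i in range(n_positive + n_negative)],
            "positive": [True] * n_positive + [False] * n_negative,
            "mean_intensity": np.concatenate([pos, neg]),
        }
    )
    return FieldOfView(cells, fov_id=fov_id), GroundTruth(intensity_fold=fold)
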