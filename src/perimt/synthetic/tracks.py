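"""Synthetic fiducial-mark trajectories.

Stationary marks are a fixed point plus i.i.d. Gaussian localization
noise per coordinate; motile marks add constant-velocity straight motion
in a random fixed direction. The motile/stationary split is assigned by
fixed count (``round(n * f_motile)`` motile tracks), not by Bernoulli
draw, so recovered fractions have exact targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .truth import GroundTruth

TRACK_COLUMNS = ["track_id", "t_s", "x_um", "y_um", "cell_id"]


@dataclass
class TrackSet:
    """Fiducial-mark trajectories as a tidy table.

    ``data`` has columns ``track_id, t_s, x_um, y_um[, cell_id]``, sorted
    by (track_id, t_s), with strictly increasing times within each track.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("track_id", "t_s", "x_um", "y_um") if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        if "cell_id" not in self.data.columns:
            self.data = self.data.assign(cell_id="cell_0")
        self.data = self.data.sort_values(["track_id", "t_s"], kind="mergesort").reset_index(
            drop=True
        )
        if self.data.duplicated(["track_id", "t_s"]).any():
            raise ValueError("duplicate (track_id, t_s) samples")

    @property
    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def __len__(self) -> int:
        return len(self.track_ids)


def simulate_tracks(
    n_tracks: int = 100,
    f_stationary: float = 0.5,
    f_motile: float = 0.5,
    stationary_sigma_um: float = 0.02,
    motile_speed_um_s: float = 0.1,
    duration_s: float = 120.0,
    dt_s: float = 1.0,
    seed: int = 0,
    field_um: float = 20.0,
    cell_id: str = "cell_0",
) -> tuple[TrackSet, GroundTruth]:
    """Simulate a mixed population of stationary and motile marks.

    Samples run from t=0 to t=duration inclusive on a dt grid, so a
    gap-free track supports ``floor(duration / 5)`` 5-s windows.
    """
    if not (dt_s > 0):
        raise ValueError("dt_s must be > 0")
    if duration_s < 5:
        raise ValueError("duration_s must be >= 5 s")
    if f_stationary < 0 or f_motile < 0 or abs(f_stationary + f_motile - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")

    rng = np.random.default_rng(seed)
    n_motile = int(round(n_tracks * f_motile))
    labels = np.array(["motile"] * n_motile + ["stationary"] * (n_tracks - n_motile))
    rng.shuffle(labels)

    times = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    rows = []
    truth_labels: dict[int, str] = {}
    for tid in range(n_tracks):
        origin = rng.uniform(0, field_um, size=2)
        if labels[tid] == "motile":
            theta = rng.uniform(0, 2 * np.pi)
            vel = motile_speed_um_s * np.array([np.cos(theta), np.sin(theta)])
        else:
            vel = np.zeros(2)
        pos = origin[None, :] + times[:, None] * vel[None, :]
        if stationary_sigma_um > 0:
            pos = pos + rng.normal(0, stationary_sigma_um, size=pos.shape)
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "t_s": times,
                    "x_um": pos[:, 0],
                    "y_um": pos[:, 1],
                    "cell_id": cell_id,
                }
            )
        )
        truth_labels[tid] = str(labels[tid])

    data = pd.concat(rows, ignore_index=True)
    return TrackSet(data), GroundTruth(track_labels=truth_labels)
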