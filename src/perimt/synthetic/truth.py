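"""Ground-truth records emitted by the synthetic generators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GroundTruth:
    """Known truth attached to a synthetic dataset.

    Only the fields relevant to the generator that produced it are set:
    filament renders carry per-filament border angles (degrees in [0, 90]),
    a noiseless per-pixel orientation map (degrees in [0, 180), NaN off
    filaments) and the geometric filament mask; FRAP series carry the
    per-frame filament area inside the bleached zones (µm²); track sets
    carry per-track motility labels; intensity fields carry the true fold.
    """

    filament_angles_deg: np.ndarray | None = None
    orientation_map_deg: np.ndarray | None = None
    filament_mask: np.ndarray | None = None
    translocated_area_um2: np.ndarray | None = None
    track_labels: dict[int, str] | None = None
    intensity_fold: float | None = None

    def __post_init__(self) -> None:
        if self.filament_angles_deg is not None:
            a = np.asarray(self.filament_angles_deg, dtype=float)
            if a.size and (a.min() < -1e-9 or a.max() > 90 + 1e-9):
                raise ValueError("filament angles must lie in [0, 90] degrees")
            self.filament_angles_deg = a
        if self.translocated_area_um2 is not None:
            t = np.asarray(self.translocated_area_um2, dtype=float)
            if t.size and t.min() < 0:
                raise ValueError("translocated area must be >= 0")
            self.translocated_area_um2 = t
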