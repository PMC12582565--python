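"""Acquisition calibration and analysis constants.

All spatial quantities are in micrometres, all times in seconds. The
defaults in :class:`AnalysisParameters` are the constants used throughout
the peripheral-microtubule analyses: a 1 µm border band and 10° bins for
directionality histograms, a 2 µm band for peripheral intensity, 5 s
displacement windows binned at 0.05 µm with 0.15/0.3 µm stationary/motile
cut-offs, and a 300 s FRAP readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PixelCalibration:
    """Physical calibration of an image or image series.

    Parameters
    ----------
    pixel_size_um : float
        Lateral pixel size in µm per pixel (strictly positive).
    frame_interval_s : float, optional
        Time between frames in seconds, for time-lapse data.
    z_step_um : float, optional
        Axial step between optical slices in µm, for z-stacks.
    """

    pixel_size_um: float
    frame_interval_s: float | None = None
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.frame_interval_s is not None and not (self.frame_interval_s > 0):
            raise ValueError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")
        if self.z_step_um is not None and not (self.z_step_um > 0):
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um

    def px_to_um(self, length_px: float) -> float:
        return length_px * self.pixel_size_um

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


#: Default synthetic-imaging calibration (0.1 µm pixels).
DEFAULT_CALIBRATION = PixelCalibration(pixel_size_um=0.1)

#: Acquisition-matched presets: fast single-plane tracking vs slow FRAP stacks.
SUNTAG_CALIBRATION = PixelCalibration(pixel_size_um=0.1, frame_interval_s=0.1)
FRAP_CALIBRATION = PixelCalibration(pixel_size_um=0.1, frame_interval_s=10.0, z_step_um=0.4)


@dataclass(frozen=True)
class AnalysisParameters:
    """The printed analysis constants, in one place.

    ``band_hist_um``
        Width of the peripheral band used for directionality histograms (µm).
    ``band_intensity_um``
        Width of the peripheral band for mean tubulin intensity (µm).
    ``angle_bin_deg``
        Directionality histogram bin width; must divide 90.
    ``displacement_window_s``
        Length of the displacement window for fiducial-mark tracks (s).
    ``displacement_bin_um``
        Bin width of the displacement histogram (µm).
    ``stationary_max_um``
        Displacements strictly below this (per window) are stationary (µm).
    ``motile_min_um``
        Displacements strictly above this (per window) are motile (µm).
    ``frap_readout_time_s``
        Recovery time at which displaced MT area is read out (s).
    ``coherence_min``
        Minimum structure-tensor coherence for a pixel to count as
        conclusive in orientation analysis (unitless, in [0, 1]).
    """

    band_hist_um: float = 1.0
    band_intensity_um: float = 2.0
    angle_bin_deg: float = 10.0
    displacement_window_s: float = 5.0
    displacement_bin_um: float = 0.05
    stationary_max_um: float = 0.15
    motile_min_um: float = 0.3
    frap_readout_time_s: float = 300.0
    coherence_min: float = 0.8

    def __post_init__(self) -> None:
        for name in ("band_hist_um", "band_intensity_um", "angle_bin_deg",
                     "displacement_window_s", "displacement_bin_um"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.stationary_max_um < self.motile_min_um):
            raise ValueError("require 0 < stationary_max_um < motile_min_um")
        if abs(90.0 / self.angle_bin_deg - round(90.0 / self.angle_bin_deg)) > 1e-9:
            raise ValueError("angle_bin_deg must divide 90")
        if not (0 <= self.coherence_min <= 1):
            raise ValueError("coherence_min must be in [0, 1]")

    @property
    def n_angle_bins(self) -> int:
        return int(round(90.0 / self.angle_bin_deg))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisParameters":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


DEFAULT_PARAMETERS = AnalysisParameters()
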