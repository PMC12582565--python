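"""Calibrated image containers and TIFF input/output.

An :class:`ImageStack` is a plain numpy array of nonnegative intensities
plus a :class:`~perimt.params.PixelCalibration` and an axes string in the
tifffile convention (``"YX"``, ``"ZYX"``, ``"TYX"``). A :class:`CellMask`
is a single-component binary footprint of one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .params import PixelCalibration

_VALID_AXES = {"YX", "ZYX", "TYX"}


@dataclass
class ImageStack:
    pixels: np.ndarray
    calibration: PixelCalibration
    axes: str = "YX"
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.axes not in _VALID_AXES:
            raise ValueError(f"axes must be one of {_VALID_AXES}, got {self.axes!r}")
        if self.pixels.ndim != len(self.axes):
            raise ValueError(
                f"pixels ndim {self.pixels.ndim} does not match axes {self.axes!r}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]

    @property
    def n_planes(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    def plane(self, i: int) -> np.ndarray:
        return self.pixels if self.pixels.ndim == 2 else self.pixels[i]


@dataclass
class CellMask:
    mask: np.ndarray
    calibration: PixelCalibration
    provenance: str = "derived"  # {"supplied", "derived"}

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("cell mask must be 2D")
        if not self.mask.any():
            raise ValueError("cell mask is empty")
        n = ndimage.label(self.mask)[1]
        if n != 1:
            raise ValueError(f"cell mask must be a single connected component, found {n}")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.calibration.pixel_area_um2


def save_tiff(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as (multi-page) TIFF with µm/frame-interval metadata."""
    cal = stack.calibration
    res = 1.0 / cal.pixel_size_um
    metadata = {"axes": stack.axes, "unit": "um"}
    if cal.frame_interval_s is not None:
        metadata["finterval"] = cal.frame_interval_s
    if cal.z_step_um is not None:
        metadata["spacing"] = cal.z_step_um
    tifffile.imwrite(
        Path(path),
        stack.pixels.astype(np.float32),
        imagej=True,
        resolution=(res, res),
        metadata=metadata,
    )


def load_tiff(path: str | Path, axes: str | None = None) -> ImageStack:
    """Read a TIFF written by :func:`save_tiff`, recovering calibration."""
    with tifffile.TiffFile(Path(path)) as tf:
        arr = tf.asarray()
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        pixel_size = 0.1
        if xres is not None:
            num, den = xres.value
            if num > 0:
                pixel_size = den / num
        meta = tf.imagej_metadata or {}
        file_axes = (tf.series[0].axes if tf.series else "YX")
    cal = PixelCalibration(
        pixel_size_um=pixel_size,
        frame_interval_s=meta.get("finterval"),
        z_step_um=meta.get("spacing"),
    )
    if axes is None:
        axes = file_axes if file_axes in _VALID_AXES else ("YX" if arr.ndim == 2 else "TYX")
    return ImageStack(pixels=np.asarray(arr, dtype=float), calibration=cal, axes=axes)


def save_mask_tiff(path: str | Path, mask: CellMask) -> None:
    res = 1.0 / mask.calibration.pixel_size_um
    tifffile.imwrite(
        Path(path),
        (mask.mask.astype(np.uint8) * 255),
        imagej=True,
        resolution=(res, res),
        metadata={"axes": "YX", "unit": "um"},
    )


def load_mask_tiff(path: str | Path, provenance: str = "supplied") -> CellMask:
    stack = load_tiff(path)
    return CellMask(stack.pixels > 0, stack.calibration, provenance=provenance)
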