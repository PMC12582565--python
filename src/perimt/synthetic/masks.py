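"""Synthetic single-cell footprint masks.

Cells are star-convex shapes defined by a polar radius function around the
frame centre: ellipses, superellipses (squarish, exponent 4), or smoothly
perturbed ellipses ("smoothed_polygon") whose boundary radius is modulated
by a few low-order Fourier modes with seeded random phases. Star-convexity
guarantees a single 4-connected, hole-free component.
"""

from __future__ import annotations

import numpy as np

from ..images import CellMask
from ..params import PixelCalibration

_SHAPES = ("ellipse", "superellipse", "smoothed_polygon")


def generate_cell_mask(
    shape: str = "ellipse",
    size_um: tuple[float, float] = (10.0, 8.0),
    calibration: PixelCalibration | None = None,
    seed: int = 0,
    frame_um: tuple[float, float] = (25.6, 25.6),
    roughness: float = 0.08,
    center_um: tuple[float, float] | None = None,
) -> CellMask:
    """Rasterize a synthetic cell footprint.

    Parameters
    ----------
    shape : {"ellipse", "superellipse", "smoothed_polygon"}
    size_um : (a, b)
        Semi-axes of the base shape in µm.
    frame_um : (height, width)
        Physical size of the image frame in µm.
    roughness : float
        Relative amplitude of the boundary perturbation for
        ``smoothed_polygon`` (ignored otherwise).
    """
    if shape not in _SHAPES:
        raise ValueError(f"shape must be one of {_SHAPES}, got {shape!r}")
    cal = calibration or PixelCalibration(pixel_size_um=0.1)
    a_um, b_um = size_um
    if a_um <= 0 or b_um <= 0:
        raise ValueError("size_um must be strictly positive")

    rng = np.random.default_rng(seed)
    h_px = int(round(frame_um[0] / cal.pixel_size_um))
    w_px = int(round(frame_um[1] / cal.pixel_size_um))

    max_scale = 1.0 + (2.0 * roughness if shape == "smoothed_polygon" else 0.0)
    if 2 * a_um * max_scale >= min(frame_um) or 2 * b_um * max_scale >= min(frame_um):
        raise ValueError(
            f"cell of semi-axes {size_um} µm does not fit inside a {frame_um} µm frame"
        )

    if center_um is None:
        cy, cx = h_px / 2.0, w_px / 2.0
    else:
        cy = center_um[0] / cal.pixel_size_um
        cx = center_um[1] / cal.pixel_size_um

    a = a_um / cal.pixel_size_um
    b = b_um / cal.pixel_size_um
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    dx = xx - cx
    dy = yy - cy
    theta = np.arctan2(dy, dx)
    r = np.hypot(dx, dy)

    if shape == "ellipse":
        r_boundary = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    elif shape == "superellipse":
        n = 4.0
        r_boundary = (
            np.abs(np.cos(theta) / a) ** n + np.abs(np.sin(theta) / b) ** n
        ) ** (-1.0 / n)
    else:  # smoothed_polygon
        r_ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        modulation = np.ones_like(theta)
        for k in (2, 3, 4, 5):
            amp = roughness * rng.uniform(0.2, 1.0) / 2.0
            phase = rng.uniform(0, 2 * np.pi)
            modulation += amp * np.cos(k * theta + phase)
        r_boundary = r_ell * modulation

    mask = r <= r_boundary
    return CellMask(mask=mask, calibration=cal, provenance="derived")
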