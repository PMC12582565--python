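"""Cell-border geometry: distance maps, border tangents, peripheral bands.

Distance to the border is measured from each in-mask pixel centre to the
nearest border pixel centre (border pixels themselves are at distance 0).
The border tangent field is derived from the gradient of the signed
distance map: the gradient points along the outward/inward normal, and the
tangent is that direction rotated by 90°, reported modulo 180°.

A slower contour-fit tangent estimator (:func:`boundary_tangent_oracle`)
is provided as an independent reference: for each pixel it finds the
nearest border pixel by exhaustive nearest-neighbour search and fits a
straight line to the border points within a fixed radius of it.

Angle convention: degrees in [0, 180), measured from the +x (column) axis
towards the +y (row) axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .images import CellMask
from .params import PixelCalibration


def acute_angle_difference(a_deg: np.ndarray | float, b_deg: np.ndarray | float) -> np.ndarray | float:
    """Acute difference between two orientations (mod 180), in [0, 90]."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def border_pixels(mask: np.ndarray) -> np.ndarray:
    """In-mask pixels with at least one 4-neighbour outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~interior


@dataclass
class BorderGeometry:
    """Distance-to-border map (µm) and border-tangent orientation field.

    ``distance_um`` is NaN outside the mask and exactly 0 on border pixels;
    ``tangent_deg`` is defined (in [0, 180)) for every in-mask pixel.
    """

    distance_um: np.ndarray
    tangent_deg: np.ndarray
    mask: np.ndarray
    calibration: PixelCalibration


def compute_border_geometry(
    cell: CellMask,
    smooth_sigma_px: float = 2.0,
) -> BorderGeometry:
    """Distance transform and tangent field for a single-component mask.

    The tangent is the normal direction (gradient of the smoothed signed
    distance map) rotated by 90°, modulo 180°. Smoothing stabilises the
    gradient against the stair-step discretization of the border.
    """
    mask = cell.mask  # CellMask already guarantees one component
    px = cell.calibration.pixel_size_um

    border = border_pixels(mask)
    dist_px = ndimage.distance_transform_edt(~border)
    distance_um = np.where(mask, dist_px * px, np.nan)

    # Signed distance (positive inside) is smooth across the border, so its
    # gradient gives a stable normal even on border pixels.
    signed = ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(~mask)
    signed = ndimage.gaussian_filter(signed.astype(float), smooth_sigma_px)
    gy, gx = np.gradient(signed)
    normal_deg = np.degrees(np.arctan2(gy, gx)) % 180.0
    tangent_deg = (normal_deg + 90.0) % 180.0

    return BorderGeometry(
        distance_um=distance_um,
        tangent_deg=tangent_deg,
        mask=mask,
        calibration=cell.calibration,
    )


def peripheral_band_mask(
    mask: np.ndarray, width_um: float, calibration: PixelCalibration
) -> np.ndarray:
    """In-mask pixels within ``width_um`` of the cell edge (monotone in width).

    Distance is measured from each pixel centre to the continuous mask
    edge, taken to run midway between the outermost in-mask pixels and
    the background (outside-EDT minus half a pixel); this keeps band
    areas faithful to their continuous-geometry values.
    """
    if not (width_um > 0):
        raise ValueError(f"band width must be > 0, got {width_um}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    d_out_px = ndimage.distance_transform_edt(mask)
    return mask & ((d_out_px - 0.5) * calibration.pixel_size_um <= width_um)


def boundary_tangent_oracle(
    cell: CellMask,
    fit_radius_um: float = 0.5,
    region: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference tangent estimate by nearest-border-point contour fitting.

    For every pixel of ``region`` (default: the mask), finds the exactly
    nearest border pixel and fits a total-least-squares line (principal
    component) to all border pixels within ``fit_radius_um`` of that
    point. Returns ``(tangent_deg, nearest_index)`` where ``tangent_deg``
    is NaN outside the region and ``nearest_index`` maps each pixel to
    its border pixel.
    """
    mask = cell.mask
    px = cell.calibration.pixel_size_um
    by, bx = np.nonzero(border_pixels(mask))
    bpts = np.column_stack([bx, by]).astype(float)
    tree = cKDTree(bpts)

    yy, xx = np.nonzero(mask if region is None else np.asarray(region, dtype=bool))
    _, nearest = tree.query(np.column_stack([xx, yy]).astype(float))

    # Tangent per border pixel: PCA of border points within the fit radius.
    r_px = fit_radius_um / px
    tangent_per_border = np.empty(len(bpts))
    for j, p in enumerate(bpts):
        idx = tree.query_ball_point(p, r_px)
        pts = bpts[idx] - bpts[idx].mean(axis=0)
        cov = pts.T @ pts
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]  # direction of largest spread
        tangent_per_border[j] = np.degrees(np.arctan2(v[1], v[0])) % 180.0

    tangent_deg = np.full(mask.shape, np.nan)
    tangent_deg[yy, xx] = tangent_per_border[nearest]
    nearest_map = np.full(mask.shape, -1, dtype=int)
    nearest_map[yy, xx] = nearest
    return tangent_deg, nearest_map
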