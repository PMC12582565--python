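"""Synthetic belt-FRAP time-lapses with known translocated filament area.

Frame 0 emulates the first post-bleach frame: filamentous signal exists
only inside the central fluorescent belt (static filaments lie along the
belt axis; translocating filaments along the belt normal, fully inside
the belt), and the bleached zones carry at most a configurable residual
level. Translocating filaments then move along the belt normal at a
constant speed, alternating sides, carrying their fluorescence into the
bleached zones. Ground truth records, per frame, the geometric filament
area inside the bleached zones (pixel count of the noiseless filament
mask intersected with the bleach ROIs, in µm²).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..frap import FrapRois, define_frap_rois
from ..images import CellMask, ImageStack
from ..params import PixelCalibration
from .filaments import draw_segments
from .truth import GroundTruth


def simulate_frap_series(
    cell: CellMask,
    belt_width_um: float = 5.0,
    belt_axis_deg: float = 90.0,
    n_translocating: int = 5,
    speed_um_s: float = 0.02,
    n_frames: int = 31,
    calibration: PixelCalibration | None = None,
    seed: int = 0,
    n_static: int = 40,
    filament_length_um: float = 3.0,
    thickness_um: float = 0.35,
    intensity: float = 200.0,
    belt_background: float = 20.0,
    residual_level: float = 0.0,
    read_noise_sigma: float = 2.0,
    noise: bool = True,
) -> tuple[ImageStack, GroundTruth, FrapRois]:
    """Simulate a post-bleach time series over a belt-FRAP geometry.

    Returns the noisy calibrated series (TYX), the ground truth with
    ``translocated_area_um2`` per frame, and the ROI partition used.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    cal = calibration or PixelCalibration(
        pixel_size_um=cell.calibration.pixel_size_um, frame_interval_s=10.0
    )
    if cal.frame_interval_s is None:
        raise ValueError("calibration must define frame_interval_s")
    px = cal.pixel_size_um
    rng = np.random.default_rng(seed)
    mask = cell.mask

    rois = define_frap_rois(cell, belt_axis_deg=belt_axis_deg, belt_width_um=belt_width_um)

    if filament_length_um >= belt_width_um - thickness_um:
        raise ValueError("translocating filaments must fit inside the belt width")

    # Capsules must fit inside the cell: erode by the capsule half-extent.
    half_len_px = filament_length_um / (2 * px)
    half_th_px = thickness_um / (2 * px)
    interior = ndimage.distance_transform_edt(mask) > (half_len_px + half_th_px + 1)

    ux = np.cos(np.radians(belt_axis_deg))
    uy = np.sin(np.radians(belt_axis_deg))
    nx, ny = -uy, ux  # belt normal

    yy, xx = np.nonzero(mask)
    cy, cx = yy.mean(), xx.mean()
    gy, gx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    proj_n_um = ((gx - cx) * nx + (gy - cy) * ny) * px

    # static filaments: along the belt axis, capsule fully inside the belt
    static_region = interior & rois.belt & (np.abs(proj_n_um) <= belt_width_um / 2 - thickness_um)
    sy, sx = np.nonzero(static_region)
    if len(sy) == 0:
        raise ValueError("belt too narrow to place filaments")
    pick = rng.integers(0, len(sy), size=n_static)
    static_centers = np.column_stack(
        [sx[pick] + rng.uniform(-0.5, 0.5, n_static), sy[pick] + rng.uniform(-0.5, 0.5, n_static)]
    )
    static_angles = np.full(n_static, belt_axis_deg % 180.0) + rng.normal(0, 3.0, n_static)

    # translocating filaments: along the belt normal, starting fully inside
    trans_margin = (belt_width_um - filament_length_um) / 2 - thickness_um / 2
    trans_region = interior & rois.belt & (np.abs(proj_n_um) <= max(trans_margin, px))
    ty, tx = np.nonzero(trans_region)
    if n_translocating > 0 and len(ty) == 0:
        raise ValueError("belt too narrow for translocating filaments")
    if n_translocating > 0:
        # spread starting points along the belt's long axis
        proj_axis = (tx - cx) * ux + (ty - cy) * uy
        order = np.argsort(proj_axis)
        # central quantiles: sliding filaments stay within the cell body
        # over the full recovery time instead of exiting at a narrow pole
        picks = order[
            np.linspace(0.25 * len(order), 0.75 * len(order), n_translocating).astype(int)
        ]
        trans_start = np.column_stack([tx[picks], ty[picks]]).astype(float)
    else:
        trans_start = np.empty((0, 2))
    sides = np.where(np.arange(n_translocating) % 2 == 0, 1.0, -1.0)
    trans_angle = np.degrees(np.arctan2(ny, nx)) % 180.0

    length_px = filament_length_um / px
    th_px = thickness_um / px
    dt = cal.frame_interval_s
    psf_sigma_px = 0.15 / px

    background = np.where(rois.belt, belt_background, 0.0) + np.where(
        rois.zones, residual_level, 0.0
    )

    static_ink, _, _ = draw_segments(
        mask.shape, static_centers, static_angles, length_px, th_px, intensity
    )

    frames = np.empty((n_frames,) + mask.shape)
    truth_area = np.empty(n_frames)
    zones = rois.zones
    for k in range(n_frames):
        shift_px = speed_um_s * k * dt / px
        centers_k = trans_start + np.column_stack(
            [sides * shift_px * nx, sides * shift_px * ny]
        ) if n_translocating else trans_start
        trans_ink, trans_geo, _ = draw_segments(
            mask.shape,
            centers_k,
            np.full(n_translocating, trans_angle),
            length_px,
            th_px,
            intensity,
        )
        ink = (static_ink + trans_ink) * mask
        geo = trans_geo & mask
        truth_area[k] = float((geo & zones).sum()) * cal.pixel_area_um2

        expected = ndimage.gaussian_filter(ink, psf_sigma_px) + background
        if noise:
            noisy = rng.poisson(expected).astype(float)
            if read_noise_sigma > 0:
                noisy += rng.normal(0.0, read_noise_sigma, size=noisy.shape)
        else:
            noisy = expected
        frames[k] = np.clip(noisy, 0.0, None)

    series = ImageStack(frames, cal, axes="TYX", channel="tubulin")
    truth = GroundTruth(translocated_area_um2=truth_area)
    return series, truth, rois
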