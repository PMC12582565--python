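"""Rendering of filamentous microtubule signal inside a cell mask.

Filaments are straight, anti-aliased capsules (segments of fixed
thickness). Orientation models:

``parallel_to_border``
    each filament lies along the border tangent at its seed point's
    nearest boundary point (emulating the peripheral sub-membrane array);
``isotropic``
    orientations uniform on [0, 180);
``fixed_angle``
    each filament at a fixed acute angle to the local border tangent.

The image model is rendered ink, clipped to the cell mask, convolved with
an isotropic Gaussian PSF, with Poisson shot noise and Gaussian read
noise on top of a uniform cytoplasmic background. Ground truth records
the analytic angle of each filament to the border tangent at its nearest
boundary point (the same tangent used to orient it), the noiseless
per-pixel orientation map, and the geometric filament mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..geometry import acute_angle_difference, boundary_tangent_oracle, peripheral_band_mask
from ..images import CellMask, ImageStack
from .truth import GroundTruth

_ORIENTATION_MODELS = ("parallel_to_border", "isotropic", "fixed_angle")


@dataclass(frozen=True)
class FilamentSpec:
    """Parameters of a synthetic filament render."""

    n_filaments: int = 80
    orientation_model: str = "parallel_to_border"
    fixed_angle_deg: float = 0.0
    length_um: float = 1.5
    thickness_um: float = 0.35
    intensity: float = 200.0
    psf_sigma_um: float = 0.15
    background: float = 5.0
    poisson: bool = True
    read_noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.n_filaments < 0:
            raise ValueError("n_filaments must be >= 0")
        if self.orientation_model not in _ORIENTATION_MODELS:
            raise ValueError(
                f"orientation_model must be one of {_ORIENTATION_MODELS}, "
                f"got {self.orientation_model!r}"
            )
        if self.length_um <= 0 or self.thickness_um <= 0:
            raise ValueError("length_um and thickness_um must be > 0")
        if not (0.0 <= self.fixed_angle_deg <= 90.0):
            raise ValueError("fixed_angle_deg must be in [0, 90]")
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")


def draw_segments(
    shape: tuple[int, int],
    centers_xy_px: np.ndarray,
    angles_deg: np.ndarray,
    length_px: float,
    thickness_px: float,
    intensity: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize capsules; returns (ink, geometric_mask, orientation_map).

    Anti-aliasing ramps the ink linearly over one pixel at the capsule
    edge; the geometric mask is the exact pixel-centre-in-capsule test.
    Overlaps sum in ink; the orientation map keeps the last-drawn angle.
    """
    ink = np.zeros(shape, dtype=float)
    geo = np.zeros(shape, dtype=bool)
    omap = np.full(shape, np.nan)
    half_len = length_px / 2.0
    half_th = thickness_px / 2.0
    pad = int(np.ceil(half_len + half_th + 2))

    for (cx, cy), ang in zip(np.atleast_2d(centers_xy_px), np.atleast_1d(angles_deg)):
        ux, uy = np.cos(np.radians(ang)), np.sin(np.radians(ang))
        y0 = max(int(cy) - pad, 0)
        y1 = min(int(cy) + pad + 1, shape[0])
        x0 = max(int(cx) - pad, 0)
        x1 = min(int(cx) + pad + 1, shape[1])
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx = xx - cx
        dy = yy - cy
        t = np.clip(dx * ux + dy * uy, -half_len, half_len)
        d = np.hypot(dx - t * ux, dy - t * uy)
        aa = np.clip(half_th + 0.5 - d, 0.0, 1.0)
        ink[y0:y1, x0:x1] += intensity * aa
        inside = d <= half_th
        geo[y0:y1, x0:x1] |= inside
        region = omap[y0:y1, x0:x1]
        region[inside] = ang % 180.0
    return ink, geo, omap


def render_mt_image(
    cell: CellMask,
    spec: FilamentSpec,
    seed: int = 0,
    seed_band_um: tuple[float, float] | None = None,
    clip_to_mask: bool = False,
) -> tuple[ImageStack, GroundTruth]:
    """Render a noisy MT image over a cell mask with known ground truth.

    Filament seed points lie inside the mask; the drawn capsules may
    overhang the border (as real filaments overhang a drawn cell outline)
    unless ``clip_to_mask`` is set, which guillotines the ink at the
    border and is kept only for stress tests — the hard step it creates
    is itself a border-parallel structure.

    Parameters
    ----------
    seed_band_um : (lo, hi), optional
        Restrict filament seed points to border distances in [lo, hi) µm;
        by default seeds are uniform over the whole mask.
    """
    if spec.psf_sigma_um <= 0:
        raise ValueError("psf_sigma_um must be > 0")
    mask = cell.mask
    cal = cell.calibration
    px = cal.pixel_size_um
    rng = np.random.default_rng(seed)

    if seed_band_um is not None:
        lo, hi = seed_band_um
        band_hi = peripheral_band_mask(mask, hi, cal)
        region = band_hi & ~peripheral_band_mask(mask, max(lo, 1e-9), cal) if lo > 0 else band_hi
        if not region.any():
            raise ValueError("seed band contains no pixels")
    elif spec.orientation_model == "isotropic":
        # The isotropic model emulates a stationary isotropic line process
        # observed through the cell-footprint window: seeds extend half a
        # filament beyond the border so in-window pixel counts carry no
        # angle preference at the boundary.
        halo_px = (spec.length_um / 2 + spec.thickness_um / 2) / px
        region = ndimage.binary_dilation(
            mask, structure=ndimage.generate_binary_structure(2, 2),
            iterations=max(int(np.ceil(halo_px)), 1),
        )
    else:
        region = mask

    oracle_tangent, _ = boundary_tangent_oracle(cell, region=region)

    ys, xs = np.nonzero(region)
    n = spec.n_filaments
    if n > 0:
        pick = rng.integers(0, len(ys), size=n)
        jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
        centers = np.column_stack([xs[pick] + jitter[:, 0], ys[pick] + jitter[:, 1]])
        tangents = oracle_tangent[ys[pick], xs[pick]]

        if spec.orientation_model == "parallel_to_border":
            angles = tangents.copy()
        elif spec.orientation_model == "isotropic":
            angles = rng.uniform(0.0, 180.0, size=n)
        else:  # fixed_angle
            angles = (tangents + spec.fixed_angle_deg) % 180.0

        gt_angles = np.asarray(acute_angle_difference(angles, tangents))
        ink, geo, omap = draw_segments(
            mask.shape,
            centers,
            angles,
            spec.length_um / px,
            spec.thickness_um / px,
            spec.intensity,
        )
    else:
        centers = np.empty((0, 2))
        gt_angles = np.empty(0)
        ink = np.zeros(mask.shape)
        geo = np.zeros(mask.shape, dtype=bool)
        omap = np.full(mask.shape, np.nan)

    if clip_to_mask:
        # hard clip: creates an artificial border-parallel step, off by default
        ink[~mask] = 0.0
        geo &= mask
        omap[~mask] = np.nan

    expected = ndimage.gaussian_filter(ink, spec.psf_sigma_um / px) + spec.background
    if spec.poisson:
        noisy = rng.poisson(expected).astype(float)
    else:
        noisy = expected.copy()
    if spec.read_noise_sigma > 0:
        noisy += rng.normal(0.0, spec.read_noise_sigma, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None)

    image = ImageStack(pixels=noisy, calibration=cal, axes="YX", channel="tubulin")
    truth = GroundTruth(
        filament_angles_deg=gt_angles,
        orientation_map_deg=omap,
        filament_mask=geo,
    )
    return image, truth
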