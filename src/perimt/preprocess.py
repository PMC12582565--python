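"""Image conditioning upstream of directionality analysis.

The chain mirrors the standard workflow for peripheral-MT quantification:
Richardson-Lucy deconvolution with a Gaussian PSF, maximum-intensity
projection over a ventral slice range, intermeans (isodata) thresholding
of the masked cell — either a standard threshold or one optimized for the
peripheral MT array ("perfect" threshold: isodata restricted to the outer
band) — and extraction of peripheral distance bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import richardson_lucy as _skimage_rl

from .geometry import peripheral_band_mask
from .images import CellMask, ImageStack


@dataclass
class ThresholdResult:
    mt_mask: np.ndarray
    method: str  # {"isodata_global", "per_cell_perfect", "population", "fixed"}
    threshold: float

    def __post_init__(self) -> None:
        self.mt_mask = np.asarray(self.mt_mask, dtype=bool)


def _gaussian_psf(sigma_px: float) -> np.ndarray:
    radius = max(int(np.ceil(4 * sigma_px)), 1)
    x = np.arange(-radius, radius + 1)
    g = np.exp(-(x**2) / (2 * sigma_px**2))
    psf = np.outer(g, g)
    return psf / psf.sum()


def richardson_lucy_deconvolve(
    image: ImageStack, psf_sigma_um: float, iterations: int = 30
) -> ImageStack:
    """Richardson-Lucy deconvolution with an isotropic Gaussian PSF.

    The iteration preserves nonnegativity and (approximately) total flux.
    Applied plane-wise for stacks and time series.
    """
    if not (psf_sigma_um > 0):
        raise ValueError("psf_sigma_um must be > 0")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not np.all(np.isfinite(image.pixels)):
        raise ValueError("image contains non-finite pixels")

    psf = _gaussian_psf(psf_sigma_um / image.calibration.pixel_size_um)
    pixels = image.pixels
    if pixels.ndim == 2:
        out = _skimage_rl(pixels, psf, num_iter=iterations, clip=False)
    else:
        out = np.stack(
            [_skimage_rl(plane, psf, num_iter=iterations, clip=False) for plane in pixels]
        )
    out = np.clip(out, 0.0, None)
    return ImageStack(out, image.calibration, axes=image.axes, channel=image.channel)


def max_intensity_projection(
    stack: ImageStack, z_range_um: tuple[float, float] | None = None
) -> ImageStack:
    """Per-pixel maximum over the z slices whose start depth lies in range.

    Slice ``i`` is taken to start at depth ``i * z_step_um``; with a
    ``(0, 1.2)`` µm range over a 0.4 µm-step stack the projection covers
    exactly three slices. ``None`` projects the whole stack.
    """
    if stack.axes != "ZYX":
        if stack.axes == "YX":
            if z_range_um is not None:
                raise ValueError("2D image has no z dimension to select")
            return stack
        raise ValueError("max_intensity_projection expects a ZYX stack")
    nz = stack.pixels.shape[0]
    if z_range_um is None:
        sel = np.arange(nz)
    else:
        dz = stack.calibration.z_step_um
        if dz is None:
            raise ValueError("calibration must define z_step_um to select a z range")
        lo, hi = z_range_um
        depths = np.arange(nz) * dz
        sel = np.nonzero((depths >= lo) & (depths < hi))[0]
    if sel.size == 0:
        raise ValueError(f"z range {z_range_um} selects no slices")
    proj = stack.pixels[sel].max(axis=0)
    return ImageStack(proj, stack.calibration, axes="YX", channel=stack.channel)


def isodata_value(values: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> float:
    """Intermeans (isodata) threshold of a 1D sample of intensities.

    Iterates ``T <- (mean(values < T) + mean(values >= T)) / 2`` from the
    midrange until convergence. Raises on (near-)constant input, where no
    two classes exist.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("no values to threshold")
    vmin, vmax = v.min(), v.max()
    if vmax - vmin <= tol * max(1.0, abs(vmax)):
        raise ValueError("constant image: isodata threshold undefined")
    t = 0.5 * (vmin + vmax)
    for _ in range(max_iter):
        below = v[v < t]
        above = v[v >= t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t)


def isodata_threshold(image: ImageStack | np.ndarray, cell: CellMask) -> ThresholdResult:
    """Standard isodata threshold computed on in-mask pixels only."""
    pixels = image.pixels if isinstance(image, ImageStack) else np.asarray(image, dtype=float)
    t = isodata_value(pixels[cell.mask])
    return ThresholdResult(mt_mask=cell.mask & (pixels >= t), method="isodata_global", threshold=t)


def per_cell_perfect_threshold(
    image: ImageStack | np.ndarray, cell: CellMask, band_width_um: float
) -> ThresholdResult:
    """Threshold optimized for the peripheral MT array of one cell.

    Isodata restricted to the outer ``band_width_um`` band, then applied
    over the whole mask. With a band wider than the cell radius this
    degenerates to the standard per-cell isodata threshold.
    """
    pixels = image.pixels if isinstance(image, ImageStack) else np.asarray(image, dtype=float)
    band = peripheral_band_mask(cell.mask, band_width_um, cell.calibration)
    if not band.any():
        raise ValueError("peripheral band is empty")
    t = isodata_value(pixels[band])
    return ThresholdResult(mt_mask=cell.mask & (pixels >= t), method="per_cell_perfect", threshold=t)


def fixed_threshold(image: ImageStack | np.ndarray, cell: CellMask, value: float) -> ThresholdResult:
    """Manual threshold override (parity with interactive use)."""
    pixels = image.pixels if isinstance(image, ImageStack) else np.asarray(image, dtype=float)
    return ThresholdResult(mt_mask=cell.mask & (pixels >= value), method="fixed", threshold=float(value))


def population_isodata_threshold(
    images: list[ImageStack | np.ndarray], cells: list[CellMask]
) -> float:
    """One standard threshold for a cell population: isodata on the pooled
    in-mask intensities of every cell in the batch."""
    pooled = np.concatenate(
        [
            (im.pixels if isinstance(im, ImageStack) else np.asarray(im, dtype=float))[c.mask]
            for im, c in zip(images, cells)
        ]
    )
    return isodata_value(pooled)


def peripheral_band(cell: CellMask, width_um: float) -> np.ndarray:
    """Binary band of in-mask pixels within ``width_um`` of the border."""
    return peripheral_band_mask(cell.mask, width_um, cell.calibration)
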