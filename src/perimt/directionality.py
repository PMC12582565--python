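"""Border-relative microtubule directionality.

Per-pixel MT orientation is estimated with the structure tensor
(Gaussian-derivative gradients, Gaussian tensor smoothing); the
along-ridge direction is the tensor's minor eigenvector. Pixels are kept
only where they are MT-positive and the tensor coherence
(λ1-λ2)/(λ1+λ2) exceeds a floor — the operational reading of
"inconclusive pixels disregarded". Each valid pixel's orientation is then
compared with the tangent of the nearest cell border and the acute angle
(0° = parallel, 90° = perpendicular) is histogrammed in 10° bins within
peripheral distance bands, the 0-10° bin being the "parallel" share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import BorderGeometry, acute_angle_difference
from .images import ImageStack
from .params import AnalysisParameters, DEFAULT_PARAMETERS


@dataclass
class OrientationField:
    """Per-pixel orientation (degrees in [0,180)), coherence, validity."""

    orientation_deg: np.ndarray
    coherence: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class DirectionalityHistogram:
    """Angle-to-border histogram for one cell and one distance band.

    Bins are ``[0,10), [10,20), ..., [80,90]`` degrees by default (the last
    bin closed above). ``fractions`` is NaN-filled when the band holds no
    valid pixels (flagged via ``n_pixels == 0``).
    """

    counts: np.ndarray
    band_um: tuple[float, float]
    bin_edges: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        n = self.n_pixels
        if n == 0:
            return np.full(len(self.counts), np.nan)
        return self.counts / n

    @property
    def parallel_fraction(self) -> float:
        """Share of pixels in the first (0-10°, border-parallel) bin."""
        return float(self.fractions[0])


def compute_orientation_field(
    image: ImageStack | np.ndarray,
    mt_mask: np.ndarray,
    gradient_sigma_px: float = 1.0,
    window_sigma_px: float = 2.0,
    coherence_min: float = DEFAULT_PARAMETERS.coherence_min,
) -> OrientationField:
    """Structure-tensor orientation restricted to MT-positive pixels.

    Orientation is the along-ridge direction (minor eigenvector of the
    smoothed gradient outer-product tensor), in degrees [0, 180) from the
    +x axis. Coherence is (λ1-λ2)/(λ1+λ2+eps). A field with zero valid
    pixels is returned with a warning rather than raising.
    """
    pixels = image.pixels if isinstance(image, ImageStack) else np.asarray(image, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("orientation analysis expects a single 2D plane")
    if gradient_sigma_px <= 0 or window_sigma_px <= 0:
        raise ValueError("sigmas must be > 0")

    gx = ndimage.gaussian_filter(pixels, gradient_sigma_px, order=(0, 1))
    gy = ndimage.gaussian_filter(pixels, gradient_sigma_px, order=(1, 0))
    jxx = ndimage.gaussian_filter(gx * gx, window_sigma_px)
    jxy = ndimage.gaussian_filter(gx * gy, window_sigma_px)
    jyy = ndimage.gaussian_filter(gy * gy, window_sigma_px)

    # gradient (across-ridge) direction from the major eigenvector
    theta_grad = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
    orientation = (theta_grad + 90.0) % 180.0

    trace = jxx + jyy
    diff = np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2)
    coherence = diff / (trace + 1e-12)

    valid = np.asarray(mt_mask, dtype=bool) & (coherence >= coherence_min)
    if not valid.any():
        warnings.warn("orientation field has zero valid pixels", stacklevel=2)
    return OrientationField(orientation_deg=orientation, coherence=coherence, valid=valid)


def angle_to_border(field: OrientationField, geom: BorderGeometry) -> np.ndarray:
    """Acute angle (degrees, [0, 90]) between MT orientation and the border
    tangent, NaN where the field is invalid."""
    if field.orientation_deg.shape != geom.tangent_deg.shape:
        raise ValueError("orientation field and border geometry shapes differ")
    alpha = np.asarray(acute_angle_difference(field.orientation_deg, geom.tangent_deg))
    out = np.full(alpha.shape, np.nan)
    out[field.valid] = alpha[field.valid]
    return out


def bin_directionality(
    angles: np.ndarray,
    geom: BorderGeometry,
    band_um: tuple[float, float] = (0.0, 1.0),
    bin_width_deg: float = DEFAULT_PARAMETERS.angle_bin_deg,
    cell_id: str = "",
) -> DirectionalityHistogram:
    """Histogram valid pixels with border distance in ``[lo, hi)``.

    Angles are binned in ``bin_width_deg`` bins over [0, 90]; an angle of
    exactly 90° goes to the last bin, and a tie on an interior edge goes
    to the upper bin.
    """
    lo, hi = band_um
    if not (hi > lo >= 0):
        raise ValueError(f"invalid band {band_um}")
    n_bins = int(round(90.0 / bin_width_deg))
    edges = np.linspace(0.0, 90.0, n_bins + 1)

    dist = geom.distance_um
    in_band = np.isfinite(angles) & np.isfinite(dist) & (dist >= lo) & (dist < hi)
    vals = angles[in_band]
    idx = np.minimum((vals // bin_width_deg).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return DirectionalityHistogram(counts=counts, band_um=(lo, hi), bin_edges=edges, cell_id=cell_id)


def directionality_vs_distance(
    angles: np.ndarray,
    geom: BorderGeometry,
    band_edges_um: np.ndarray | list[float] = (0, 1, 2, 3, 4, 5),
    bin_width_deg: float = DEFAULT_PARAMETERS.angle_bin_deg,
    cell_id: str = "",
) -> list[DirectionalityHistogram]:
    """One histogram per distance band ``[e_i, e_{i+1})``.

    Bands are disjoint, so their pixel counts sum to the number of valid
    pixels closer to the border than the outermost edge.
    """
    edges = np.asarray(band_edges_um, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("band_edges_um must be strictly increasing with >= 2 edges")
    return [
        bin_directionality(angles, geom, (edges[i], edges[i + 1]), bin_width_deg, cell_id)
        for i in range(len(edges) - 1)
    ]


def pooled_histogram(hists: list[DirectionalityHistogram]) -> DirectionalityHistogram:
    """Population histogram: per-cell counts summed (pixel-weighted), as in
    pooled 'detectable tubulin-positive pixels' presentations."""
    if not hists:
        raise ValueError("no histograms to pool")
    counts = np.sum([h.counts for h in hists], axis=0)
    return DirectionalityHistogram(
        counts=counts, band_um=hists[0].band_um, bin_edges=hists[0].bin_edges, cell_id="pooled"
    )


def mean_fraction_histogram(hists: list[DirectionalityHistogram]) -> np.ndarray:
    """Cell-weighted population summary: mean of per-cell bin fractions."""
    fr = np.array([h.fractions for h in hists if h.n_pixels > 0])
    if fr.size == 0:
        raise ValueError("no non-empty histograms")
    return fr.mean(axis=0)
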