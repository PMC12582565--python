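# Methods

`perimt` quantifies how motor-driven sliding organizes the microtubule
(MT) cytoskeleton of insulin-secreting β cells. Four readouts are
implemented, each validated end-to-end on synthetic data with known
ground truth: border-relative MT directionality, belt-FRAP displaced
area, fiducial-mark motility, and marker-normalized intensity. This note
records the models, the parameter choices that matter, and what the
synthetic validation does and does not establish.

## Coordinate and angle conventions

Images are `(y, x)` arrays with the pixel size in µm carried by a
`PixelCalibration`. Orientations are degrees in `[0, 180)` measured from
the +x (column) axis toward +y (row); angles *to the border* are the
acute difference between an orientation and the local border tangent,
in `[0, 90]` — 0° is border-parallel, 90° perpendicular.

## Border geometry

The distance map assigns 0 to border pixels (in-mask pixels with a
4-neighbour outside) and the Euclidean distance to the nearest border
pixel elsewhere. The tangent field is the gradient of the *signed*
distance map (positive inside, smoothed with a 2 px Gaussian) rotated by
90°, modulo 180°; the signed form is smooth across the border, so the
gradient is stable even on border pixels. An independent reference —
exhaustive nearest-border search plus a total-least-squares line fit to
border pixels within 0.5 µm — is kept as the test oracle; on smooth
masks the two agree within 5° for ≥ 97% of outer-1 µm pixels.

Peripheral bands (the outer 1 µm for directionality, 2 µm for
intensity) use a half-pixel-corrected distance (outside-EDT − ½ px, i.e.
distance to the continuous cell edge) so band areas match their
continuous values; a 2 µm band on a 10 µm disk lands within 0.5% of the
113.1 µm² annulus. The histogram distance bands use the border-pixel
map, whose 0-on-border convention the band edges inherit; the two
conventions differ by at most ~0.07 µm.

## Image conditioning

Richardson–Lucy deconvolution with an isotropic Gaussian PSF
(σ given in µm; default 0.15 µm, 30 iterations) precedes thresholding
and orientation analysis; RL preserves nonnegativity and total flux
(within 1% in the tests). Thresholding is intermeans (isodata) iteration
`T ← (mean below + mean above)/2` on in-mask intensities, in three
variants: per-cell standard, per-cell "perfect" (isodata restricted to
the outer band, optimizing the threshold for the peripheral array), and
a population threshold pooling all cells of a batch. A constant region
raises rather than silently returning a threshold.

## Directionality estimation

Per-pixel orientation comes from the structure tensor: Gaussian-
derivative gradients (σ_g = 1 px), tensor smoothing (σ_w = 2 px),
along-ridge direction from the minor eigenvector, and coherence
(λ₁−λ₂)/(λ₁+λ₂). A pixel is *conclusive* when it is MT-positive
(thresholded) and its coherence reaches `coherence_min`.

`coherence_min` defaults to **0.8**, calibrated on synthetic renders:
filament end-caps and crossings yield orientations with ~20° median
error at low coherence while filament-body pixels are accurate to ~2°,
and 0.8 separates the two populations. With this gate the full chain
recovers a border-parallel array at 0.92–0.95 pooled 0–10° fraction and
leaves an isotropic network flat to within ±0.05 per 10° bin (10-cell
panels). This gate is a property of the estimator, not of the data; a
lower gate admits more pixels at the cost of angular accuracy.

Angles of valid pixels within each distance band are binned in 10° bins
over [0, 90]; the last bin is closed (α = 90 included) and ties on
interior edges go up. Population histograms are reported both
pixel-weighted (summed counts, as when pooling detectable
tubulin-positive pixels across cells) and cell-weighted (mean of
per-cell fractions).

## Synthetic cells and filaments

Cells are star-convex polar shapes: ellipses, superellipses, or
Fourier-roughened ellipses. Default study masks are smooth (roughness is
reserved for stress tests) with semi-axes ~7–10 µm at 0.1 µm/px — the
scale of an isolated β cell. Filaments are straight anti-aliased
capsules (default 1.5 µm × 0.35 µm apparent width) convolved with a
0.15 µm Gaussian PSF, with Poisson shot noise (plateau ≈ 200 photons
over a 5-photon background) and 2-photon read noise.

Orientation models: `parallel_to_border` draws each filament along the
contour-fit tangent at its seed's nearest border point (ground-truth
angle exactly 0); `fixed_angle(α)` offsets that tangent by α (ground
truth exactly α); `isotropic` draws uniform orientations with seeds in
the mask *dilated by the filament half-length*, i.e. a stationary
isotropic line process observed through the cell window — confining
seeds to the mask would under-weight steep filaments near the border.
Rendered ink is not guillotined at the mask edge (a hard clip creates a
spurious border-parallel step); the analysis is restricted to in-mask
pixels regardless.

What the renders do not emulate: filament curvature, 3-D structure,
photobleaching during acquisition, uneven background, or the dense
bundling of real sub-membrane arrays. Passing tests therefore establish
that the estimator chain is unbiased and well-calibrated for
diffraction-limited filament images of realistic SNR — not that any
particular biological effect size will be recovered in real data.

## Belt-FRAP sliding

ROIs split the cell through its centroid into a central belt stripe
(default 5 µm wide, so the two bleached zones are ~5 µm apart) and two
bleached zones that together partition the mask exactly. The displaced
area at frame *t* is the pixel area above threshold inside the zones,
minus the frame-0 residual, floored at 0; the readout is the frame
nearest 300 s (10 s intervals → frame 30). Series shorter than the
readout return the last frame, flagged.

Thresholds: `belt_frac:f` (f × mean belt intensity at frame 0, the
simplest rule), `isodata`, `fixed:V`, and the default used by the study
pipelines, `edge:width:psf` — the value a PSF-blurred bar of apparent
width *t* takes at its geometric edge, `(Φ(t/σ)−½)/(2Φ(t/2σ)−1)` of its
peak, with the peak estimated from the 50 brightest zone pixels at
readout. The edge level is *area-faithful*: thresholding there recovers
the unblurred bar width, so measured areas track the geometric filament
area within ~10% regardless of how densely the belt fluoresces. The
belt-mean rule is retained but is sensitive to belt coverage (over- to
under-estimating by ±50% across plausible densities).

The simulator places static filaments along the belt axis (fully inside
the belt, so frame 0 has zero zone signal) and translocating filaments
along the belt normal, sliding at 0.02 µm/s (1.2 µm/min — within the
range of kinesin-driven MT transport, and slow enough that a filament
remains inside an ~11 µm cell over the 300 s readout). Ground truth is
the per-frame pixel count of the noiseless geometric filament masks
inside the zones.

## Track motility

Track tables (`track_id, t, x, y[, intensity, cell_id]`) are read from
CSV with declared units, resampled onto a uniform grid by
nearest-sample selection within dt/2 (gaps left absent, never
interpolated), and segmented into non-overlapping 5 s windows; the
displacement is the net Euclidean start→end distance. Windows missing
an endpoint are skipped. Classification uses strict thresholds —
stationary < 0.15 µm/5 s (the resolution limit), motile > 0.3 µm/5 s,
exact threshold values intermediate — and each window is one
observation, so the three fractions sum to 1 by construction. A
sliding-window mode exists behind a flag; per-cell 0.05 µm histograms
report percentages with population mean ± SEM across cells.

The simulator draws stationary marks as a fixed point plus i.i.d.
Gaussian localization noise (σ = 0.02 µm per coordinate; the 5 s
displacement is then Rayleigh with scale σ√2, giving the closed-form
checks) and motile marks as constant-velocity motion at 0.1 µm/s in a
random fixed direction. The motile count is assigned deterministically
(`round(n·f)`) so fraction-recovery tests have exact targets. The
Rayleigh-law check uses one window per track (10⁴ tracks) to keep the
binned displacements independent draws.

## Intensity statistics

Peripheral intensity is the mean over the outer 2 µm band. Depletion
folds divide each marker-positive cell's mean intensity by the mean of
marker-negative cells in the same field of view; the measure is exactly
scale-invariant. Group comparisons of directionality use Welch t-tests
per 10° bin with per-cell bin fractions as observations (uncorrected
p-values as the headline, a Bonferroni column alongside) plus a
two-sample K-S test on the pooled per-pixel angles; a per-cell-median
K-S variant is also provided. Groups with a single cell refuse the
t-tests (recorded, not raised) while the K-S test still runs.

## Problem sizes and determinism

Study panels use 10 cells of ~224² px per condition, 31-frame FRAP
series at 256² px, and 10³–10⁴ tracks; these sizes put the Monte-Carlo
noise floor comfortably below every tolerance the tests assert while a
full suite run stays under a minute of simulation time. Every generator
is deterministic for a fixed seed, and the acceptance script derives all
sub-seeds from its single `--seed` argument.

## Known limitations

- The directionality estimator discards roughly half of MT-positive
  pixels at the 0.8 coherence gate; in dense real arrays the surviving
  pixel set is biased toward isolated filament bodies.
- The isotropic-uniformity check is noise-limited: with 10 cells the
  max-bin deviation fluctuates around 0.03, so occasional panels
  approach the 0.05 band.
- The belt-mean FRAP threshold is retained for parity but should not be
  used when belt coverage varies between conditions; the edge-level
  mode assumes the apparent MT width and PSF are known.
- 2-D analysis throughout; z-stacks are reduced by maximum-intensity
  projection before any orientation or area measurement.
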