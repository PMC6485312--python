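# Methods

## Model

A labeled sarcomere appears in a fluorescence frame as two parallel
bright ridges. The detection template is a *double wavelet*: two real
2-D Morlet wavelets

    w(x, y) = exp(−(x′−o)²/(2s²) − y′²/(2(s·e)²)) · cos(2π(x′−o)/λ)

(s = scale, e = stretch, λ = wavelength, o = displacement; x′, y′ the
coordinates rotated by α) placed at displacements ±d/2, rotated
together by α about their center of mass, then normalized to mean 0 and
Frobenius norm 1. Zero mean makes the filter blind to background
offsets; unit norm makes responses comparable across the bank and
bounded by the image patch norm (Cauchy–Schwarz). The rotation is
applied analytically inside the coordinates, not by raster resampling,
so kernels carry no interpolation error and construction is
bit-deterministic. Because the pair is symmetric under a half turn,
angles only need to cover [0, π), and correlation equals convolution
for these kernels (no flip ambiguity).

The bank is a P×Q grid: P evenly spaced distances on [dmin, dmax] and
Q angles kπ/Q. Per frame, responses are computed by FFT correlation
with symmetric boundary padding; kernel FFTs are computed once per
movie. On a subgrid with spacing `hopsize`, the best (d, α, position)
within a square neighborhood of half-side `halfwindowsize` is recorded
per grid point. Ties break toward the smallest distance index, then
angle index, then raster position, so runs are platform-reproducible.
The constraint `2·halfwindowsize < hopsize + dmin` keeps two adjacent
grid points from snapping onto the same sarcomere from opposite sides.
Grid points whose neighborhood overlaps the padding-influenced border
are flagged and excluded from statistics.

A sarcomere's identity is its fixed grid point; the per-frame best
distance at that point forms the trace d(t). A grid point is kept only
if the **median** of its response magnitude across frames reaches the
`magnitude_quantile` quantile of all grid points' medians — a
whole-trace rule, so a sarcomere cannot flicker in and out of the
retained set.

## Kinetics fitting

The beat frequency f is estimated once per movie from the registered
average trace by scanning f over 0.2–4 Hz in 0.01 Hz steps and solving
the linear least-squares sinusoid A·sin + B·cos + C at each step
(closed form, deterministic). Registration circularly shifts each trace
by the integer lag maximizing its circular cross-correlation with a
running reference (first trace seeds it; one refinement pass realigns
against the provisional mean). Traces are near-periodic over a clip, so
circular shifts discard no samples.

Each trace is then fitted with the periodic plateau–valley curve (period
T = fps/f frames, plateau L = T − c − r, phase u = (t − δ) mod T):

    s(u) = 1                              relaxed plateau, u ∈ [0, L)
    s(u) = (1 + cos(π(u−L)/c)) / 2        contraction fall, u ∈ [L, L+c)
    s(u) = (1 − cos(π(u−L−c)/r)) / 2      relaxation rise,  u ∈ [L+c, T)

The half-cosine fall/rise gives a continuous curve with exact plateau
value 1 and valley floor 0, which makes closed-form checks trivial.
Only (c, r, δ) are optimized per sarcomere — f is frozen from the
sinusoid fit, and the amplitude does not enter the objective, which is
the Pearson correlation between trace and model (invariant to the
affine scale/offset of the spacing signal, so absolute calibration
cannot bias kinetics). δ is a temporal phase offset: a vertical offset
would be invisible to the correlation and hence unidentifiable, and the
temporal reading is what lets asynchronous sarcomeres each find their
own phase. c and r are the full fall and rise durations of the model;
no attempt is made to define a partial "onset" point on the smooth
valley.

Optimization is a deterministic coarse-to-fine search: a coarse grid
over (c, r) (±50% around the average-trace fit when used as init,
otherwise the whole feasible wedge) crossed with every integer δ in one
period; then a shrinking-step pattern search (steps 2 → 0.05 frames);
then a Nelder–Mead polish, because the correlation surface has diagonal
ridges in (c, r, δ) that axis-aligned moves stall on. Durations are
bounded below by 0.5 frames (phase unobservable below half a frame) and
above by c + r ≤ T; a fit pinned at a bound is flagged unreliable and
excluded from reporting. On noise-free model-generated traces the
optimizer recovers (c, r, δ) to < 0.1 frame with correlation 1.

Fits are selected by goodness of fit: RMSE (after least-squares affine
mapping of the model onto the data) at or below the `rmse_quantile`
quantile of all fits (default 0.75), and correlation ≥
`min_correlation` (default 0.5). A relative (quantile) RMSE rule was
chosen over an absolute threshold so the rule transfers across
magnitudes and calibrations; both knobs are exposed.

Per-sarcomere spacing extremes d_max/d_min are means of per-period
maxima/minima of the **raw** trace (periods cut by the fitted beat
period), robust to residual model misfit. Percent shortening is
100·(d_max − d_min)/d_max; times convert to seconds via fps and
spacings to microns via microns_per_pixel, both of which must be given
explicitly (calibration is hardware-specific; there are no silent
defaults).

## Parameters

| parameter | default | meaning |
|---|---|---|
| scale | 3 px | ridge width (Gaussian SD along oscillation axis) |
| stretch | 3 | ridge elongation; SD along ridge = scale·stretch |
| wavelength | 4·scale | one bright lobe with negative side lobes |
| support | 41 px | kernel raster side; ≥ 4·scale·stretch and ≥ dmax + 4·scale |
| dmin–dmax | 14–22 px | spacing search range (~1.8–2.2 µm at 0.1 µm/px) |
| ndistances / nangles | 17 / 4 | bank density; distance step sets trace quantization |
| hopsize | 10 px | subgrid spacing |
| halfwindowsize | 5 px | snap neighborhood half-side (square/Chebyshev) |
| magnitude_quantile | 0.25 | dim-grid-point cutoff on median magnitude |
| rmse_quantile / min_correlation | 0.75 / 0.5 | fit-quality selection |
| freq scan | 0.2–4 Hz, 0.01 Hz | beat-frequency search |

Detection parameters are meant to be tuned per imaging configuration on
a single frame with `sarctrack check-frame` (overlay of fitted pairs),
exactly as one would on real data.

## Synthetic benchmark

`synth.generate_movie` renders rows of single wavelets whose pairwise
spacing follows the same sawtooth waveform, between d_relaxed = 20 px
and d_contracted = 18 px (10% shortening, the physiological magnitude),
over 150 frames at 30 fps with a 45-frame beat period — a 5-second clip
at the method's minimum acquisition rate. The default scene is 5 rows
of 9 wavelets; rows below the field midline can be phase-delayed
(default half, by 11 frames ≈ a quarter period) to emulate asynchronous
contraction. Rows are anchored at their centroid so contraction is
symmetric about the row center (exposed as `anchor`; a left anchor is
also available). Wavelets are drawn at exact sub-pixel positions via
the analytic displacement parameter, frames are clipped at 0 so they
behave like fluorescence images, and optional additive Gaussian noise
is seeded. Ground truth records every adjacent pair's spacing on every
frame.

The scene is an idealization: no photon noise by default, no PSF blur,
photobleaching, focus drift or whole-cell translation, perfectly
straight and periodic rows, and a single global beat frequency. Passing
the benchmark therefore demonstrates correctness of detection and
kinetics recovery under the model's own assumptions — including
asynchrony and duration scaling — not robustness to every real-world
artifact.

`synth.benchmark_configs()` is the analysis configuration for this
scene, chosen by the check-frame QC procedure: distances 16–22 px in
0.25 px steps (the step bounds trace quantization at 1/8 of the 2 px
oscillation), 4 angles, hopsize 10. `halfwindowsize` is 12 here rather
than the generic 5 because in a centroid-anchored 9-wavelet row the
outermost pair centers translate by (9−2)/2 × 2 px = 7 px during
contraction, and the snap neighborhood must cover that excursion (the
QC symptom of a too-small window is traces that break to the bank edges
exactly at the valley); 2·12 = 24 still satisfies the adjacency
constraint (< 10 + 16). The magnitude quantile is 0.75 because most
subgrid points of the sparse synthetic field lie on dark background.

## Problem sizes

The test suite and the acceptance script run the full pipeline on four
150-frame benchmark movies (~260×240 px) plus one smaller movie for
plumbing and determinism checks; noise-robustness statistics use 100
model-generated traces at noise SD = 10% of the oscillation amplitude.

## Known limitations

- No data association across space: a sarcomere translating farther
  than `halfwindowsize` between consecutive frames (or across the beat)
  is lost or produces a broken trace; broken traces are normally
  removed by the RMSE filter.
- Distances are reported on the bank grid (no sub-step interpolation);
  choose `ndistances` so the step is small relative to the expected
  shortening.
- One beat frequency per movie; arrhythmic clips violate the model.
- Several subgrid points may lock onto the same sarcomere; reported
  means are over retained grid points, not deduplicated sarcomeres.
- The registered average uses integer circular lags; sub-frame
  asynchrony is handled per sarcomere by δ, not in the average.
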