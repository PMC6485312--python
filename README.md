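# sarctrack

Per-sarcomere contraction kinetics from fluorescence movies of beating
cardiomyocytes.

Human iPSC-derived cardiomyocytes beat with disordered, non-linearly
oriented sarcomeres, which defeats FFT line-profile methods that assume
many aligned sarcomeres. `sarctrack` instead treats **each sarcomere as
a matched-filter target**: a pair of parallel bright ridges (fluorescently
labeled Z-discs or M-lines) at spacing *d* and orientation *α*. It
tracks every sarcomere in the field of view individually and fits each
one's spacing waveform to extract contraction time, relaxation time,
shortening and beat rate — including fields where sarcomeres contract
asynchronously.

## Method

1. **Detection.** Each frame is correlated with a bank of *double
   wavelets* `B_{P,Q} = { w(d_i, α_j) }`: two parallel real 2-D Morlet
   wavelets (cosine × anisotropic Gaussian) at separation *d*, rotated
   by *α* about their common center of mass, normalized to mean 0 and
   Frobenius norm 1. On a subgrid of pixels, the argmax of the response
   over all (d, α) and a small neighborhood snaps a template onto the
   nearest sarcomere; dim grid points (low median response over the
   movie) are discarded.
2. **Tracking.** Each retained grid point yields a spacing trace
   *d(t)*; the registered average trace (circularly aligned to handle
   asynchrony) gives the beat frequency *f* via a dense-scan sinusoid
   fit.
3. **Kinetics.** Each trace is fitted with a periodic plateau–valley
   ("sawtooth") curve: value 1 on the relaxed plateau, a half-cosine
   fall of duration *c* (contraction), a half-cosine rise of duration
   *r* (relaxation), with phase offset *δ*, period *T = fps/f*. Only
   (c, r, δ) are optimized per sarcomere, by maximizing the Pearson
   correlation with the raw trace; RMSE after affine rescaling selects
   trustworthy fits. Outputs are calibrated to microns and seconds.

A synthetic-movie generator renders rows of parallel wavelets whose
spacing follows the same sawtooth waveform (with an optionally
phase-delayed sub-population) and emits exact ground truth, so the
whole pipeline is testable without any microscope data.

## Worked example

```python
import sarctrack as st
from sarctrack.synth import benchmark_configs

# synthetic benchmark: 5 rows of 9 wavelets, 150 frames at 30 fps,
# spacing oscillating 20 -> 18 px, contraction 10 / relaxation 20 frames,
# bottom rows delayed 11 frames
spec = st.SyntheticSpec(t_contract=10, t_relax=20, delay=11,
                        delayed_fraction=0.5)
frames, truth = st.generate_movie(spec)

kc, dc, fc = benchmark_configs()
res = st.SarcTrack(frames, fps=30, microns_per_pixel=0.1,
                   kernel_config=kc, detection_config=dc,
                   fit_config=fc).fit()
print(res.summary())
```

prints

```
SarcTrack Results
==========================================================
frames analyzed        : 150
grid points retained   : 93
sarcomeres reported    : 93
beat frequency         : 0.670 Hz  (40.2 bpm)
beat period            : 44.8 frames
----------------------------------------------------------
parameter                 mean         SEM
shortening_pct         10.0000      0.0000
sl_min_um               1.8000      0.0000
sl_max_um               2.0000      0.0000
t_contract_s            0.3585      0.0000
t_relax_s               0.6430      0.0003
==========================================================
```

Reading: the beat period is recovered (45 frames prescribed), spacing
oscillates between 1.80 and 2.00 µm (10% shortening), and the fitted
contraction/relaxation times (0.36 s / 0.64 s ≈ 10.8 / 19.3 frames)
recover the prescribed 10/20-frame asymmetry — per sarcomere, despite
half the field beating out of phase. `res.stats_frame()` holds the
per-sarcomere table; `res.plot_overlay(0)` draws the detected pairs.

## Command line

```bash
sarctrack synth --out movie.tif --truth truth.csv      # benchmark movie
sarctrack check-frame movie.tif --frame 0              # QC overlay for tuning
sarctrack run movie.tif --out results/ --fps 30 --microns-per-pixel 0.1
sarctrack batch movies/ --out results/ --fps 30 --microns-per-pixel 0.1
sarctrack collate results/* --out summary.txt          # one row per movie
```

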