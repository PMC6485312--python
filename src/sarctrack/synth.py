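"""Synthetic sarcomere movies with known geometry and kinetics.

The benchmark scene is rows of parallel bright ridges: each row is a
line of single wavelets (one per Z-disc) whose pairwise spacing follows
the same plateau-valley waveform the fitter assumes, oscillating between
a relaxed and a contracted spacing.  A configurable fraction of the rows
beats with a phase delay, emulating the asynchronous contraction of real
cardiomyocyte fields.  Because every pair's spacing at every frame is
known exactly, the full detection + fitting pipeline can be validated
end to end without any microscope data.

The default spec renders 5 lines of 9 wavelets over a 5-second,
30 frames/s clip with a 1.5 s beat period, 10% shortening (20 -> 18 px)
and half the rows delayed -- the study conditions of the published
synthetic benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import DetectionConfig
from .fitcurves import FitConfig, sawtooth_model
from .kernels import KernelConfig, WaveletShape, make_single_wavelet

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "spacing_waveform",
    "render_frame",
    "generate_movie",
    "benchmark_configs",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic movie."""

    n_lines: int = 5
    wavelets_per_line: int = 9
    d_relaxed: float = 20.0  # px
    d_contracted: float = 18.0  # px (10% shortening)
    t_contract: float = 10.0  # frames
    t_relax: float = 10.0  # frames
    period: float = 45.0  # frames (1.5 s at 30 fps)
    delay: float = 11.0  # frames applied to the delayed rows
    delayed_fraction: float = 0.5
    n_frames: int = 150
    fps: float = 30.0
    line_spacing: float = 45.0  # px between rows
    noise_sd: float = 0.0  # additive Gaussian, image units
    seed: int = 0
    anchor: str = "centroid"  # "centroid" or "left"
    shape: WaveletShape = field(default_factory=WaveletShape)

    def __post_init__(self) -> None:
        if not self.d_contracted < self.d_relaxed:
            raise ValueError("require d_contracted < d_relaxed")
        if self.t_contract + self.t_relax > self.period:
            raise ValueError("t_contract + t_relax must be <= period")
        if not 0.0 <= self.delayed_fraction <= 1.0:
            raise ValueError("delayed_fraction must be in [0, 1]")
        if self.n_lines < 1 or self.wavelets_per_line < 2:
            raise ValueError("need >= 1 line of >= 2 wavelets")
        if self.anchor not in ("centroid", "left"):
            raise ValueError("anchor must be 'centroid' or 'left'")

    @property
    def margin(self) -> int:
        return self.shape.support  # keeps every raster inside the image

    @property
    def image_shape(self) -> tuple[int, int]:
        w = int(
            np.ceil(
                2 * self.margin
                + (self.wavelets_per_line - 1) * self.d_relaxed
            )
        )
        h = int(np.ceil(2 * self.margin + (self.n_lines - 1) * self.line_spacing))
        return h, w

    @property
    def n_pairs(self) -> int:
        return self.n_lines * (self.wavelets_per_line - 1)

    def row_is_delayed(self, line: int) -> bool:
        """Rows at the bottom of the field form the delayed population."""
        return (line + 1) > self.n_lines * (1.0 - self.delayed_fraction) + 1e-9


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-pair spacing for every frame, plus generating kinetics."""

    spacing: np.ndarray  # (n_frames, n_pairs), pixels
    line: np.ndarray  # (n_pairs,) row index of each pair
    delayed: np.ndarray  # (n_pairs,) bool
    t_contract: float
    t_relax: float
    period: float
    delay: float


def benchmark_configs() -> tuple[KernelConfig, DetectionConfig, FitConfig]:
    """Analysis configuration for the default synthetic scene.

    Chosen by the standard single-frame QC procedure (check-frame
    overlay) rather than from ground truth: the distance range brackets
    the 18-20 px spacing sweep with headroom; ``halfwindowsize`` covers
    the ~7 px translation of the outermost pair centers of a
    centroid-anchored 9-wavelet row during contraction (within the
    adjacency constraint 2*hw < hopsize + dmin); the magnitude quantile
    reflects that most subgrid points of the sparse synthetic field lie
    on dark background.
    """
    return (
        KernelConfig(dmin=16.0, dmax=22.0, ndistances=25, nangles=4),
        DetectionConfig(hopsize=10, halfwindowsize=12, magnitude_quantile=0.75),
        FitConfig(),
    )


def spacing_waveform(spec: SyntheticSpec, t, delayed: bool = False):
    """Inter-wavelet spacing (px) at frame(s) t for one population."""
    shift = spec.delay if delayed else 0.0
    s = sawtooth_model(
        np.asarray(t, dtype=float) - shift,
        f=spec.fps / spec.period,
        t_contract=spec.t_contract,
        t_relax=spec.t_relax,
        phase_offset=0.0,
        fps=spec.fps,
    )
    return spec.d_contracted + (spec.d_relaxed - spec.d_contracted) * s


def _wavelet_x_positions(spec: SyntheticSpec, spacing: float) -> np.ndarray:
    """Column positions of the wavelets in one line at a given spacing."""
    m = spec.wavelets_per_line
    k = np.arange(m, dtype=float)
    if spec.anchor == "centroid":
        center = spec.image_shape[1] / 2.0
        return center + (k - (m - 1) / 2.0) * spacing
    return spec.margin + k * spacing


def render_frame(
    spec: SyntheticSpec, t: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render one frame; deterministic for noise_sd=0.

    Each wavelet is drawn at its exact sub-pixel position by passing the
    fractional part of the position as the single-wavelet ``offset``
    (analytic shift, no resampling).  Noise, if any, is additive
    Gaussian; the frame is clipped to >= 0 so it behaves like a
    fluorescence image (the clip removes the Morlet's negative side
    lobes, leaving the bright central lobe of each Z-disc).
    """
    h, w = spec.image_shape
    img = np.zeros((h, w))
    half = spec.shape.support // 2
    for line in range(spec.n_lines):
        y = int(round(spec.margin + line * spec.line_spacing))
        s = float(spacing_waveform(spec, t, spec.row_is_delayed(line)))
        xs = _wavelet_x_positions(spec, s)
        if xs.min() < half or xs.max() > w - 1 - half:
            raise ValueError("layout exceeds image bounds")
        for x in xs:
            ic = int(round(x))
            raster = make_single_wavelet(spec.shape, 0.0, x - ic)
            img[y - half : y + half + 1, ic - half : ic + half + 1] += raster
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, int(t)])
            )
        img += spec.noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, None)


def generate_movie(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render all frames and the exact ground truth.

    Returns the stack as a (n_frames, H, W) float array plus a
    :class:`GroundTruth` table of every adjacent pair's spacing on every
    frame.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = np.stack(
        [render_frame(spec, t, rng=rng) for t in range(spec.n_frames)]
    )
    pair_line = np.repeat(
        np.arange(spec.n_lines), spec.wavelets_per_line - 1
    )
    delayed = np.array([spec.row_is_delayed(l) for l in pair_line])
    tt = np.arange(spec.n_frames, dtype=float)
    s_plain = spacing_waveform(spec, tt, delayed=False)
    s_delay = spacing_waveform(spec, tt, delayed=True)
    spacing = np.where(delayed[None, :], s_delay[:, None], s_plain[:, None])
    truth = GroundTruth(
        spacing=spacing,
        line=pair_line,
        delayed=delayed,
        t_contract=spec.t_contract,
        t_relax=spec.t_relax,
        period=spec.period,
        delay=spec.delay,
    )
    return frames, truth
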