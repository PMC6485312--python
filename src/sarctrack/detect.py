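"""Matched-filter detection of sarcomeres on single frames.

Each frame is correlated with every kernel in a :class:`~sarctrack.kernels.KernelBank`
(the kernels are symmetric under a half turn, so correlation and
convolution coincide).  A subgrid of pixels is then scanned: at every
grid point the maximum response over all (distance, angle) kernels and
over a small square neighborhood is recorded, yielding the locally
best-fitting sarcomere spacing and orientation plus its magnitude.
Grid points whose traces are dim (low median magnitude over the movie)
are discarded before kinetics fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import scipy.fft as sfft

from .kernels import KernelBank

__all__ = [
    "DetectionConfig",
    "FrameDetection",
    "BankConvolver",
    "subgrid_points",
    "convolve_with_bank",
    "select_grid_detections",
    "filter_by_magnitude",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Subgrid geometry and the dim-trace cutoff.

    ``hopsize`` is the pixel spacing of the subgrid; ``halfwindowsize``
    the half side of the square (Chebyshev) search neighborhood around
    each grid point.  The neighborhood must be small enough that two
    adjacent grid points cannot both snap onto the same sarcomere, which
    requires ``2*halfwindowsize < hopsize + d_min`` (checked against the
    bank at detection time).  ``magnitude_quantile`` is the fraction of
    grid points removed as dim by :func:`filter_by_magnitude`.
    """

    hopsize: int = 10
    halfwindowsize: int = 5
    magnitude_quantile: float = 0.25

    def __post_init__(self) -> None:
        if self.hopsize < 1:
            raise ValueError("hopsize must be >= 1")
        if self.halfwindowsize < 0:
            raise ValueError("halfwindowsize must be >= 0")
        if not 0.0 <= self.magnitude_quantile < 1.0:
            raise ValueError("magnitude_quantile must be in [0, 1)")

    def validate_against_bank(self, bank: KernelBank) -> None:
        d_min = float(bank.distances[0])
        if 2 * self.halfwindowsize >= self.hopsize + d_min:
            raise ValueError(
                "neighborhood too large: require 2*halfwindowsize < "
                f"hopsize + d_min ({2 * self.halfwindowsize} >= "
                f"{self.hopsize + d_min:g})"
            )


class FrameDetection(NamedTuple):
    """Best-fitting double wavelet at one subgrid point on one frame."""

    grid_row: int
    grid_col: int
    location: tuple[int, int]  # (row, col) of the maximizing pixel
    distance: float
    angle: float
    magnitude: float
    border: bool  # neighborhood influenced by boundary padding


def subgrid_points(
    frame_shape: tuple[int, int], cfg: DetectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Row and column pixel coordinates of the detection subgrid."""
    h, w = frame_shape
    rows = np.arange(cfg.hopsize // 2, h, cfg.hopsize)
    cols = np.arange(cfg.hopsize // 2, w, cfg.hopsize)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("image too small for hopsize: empty subgrid")
    return rows, cols


class BankConvolver:
    """FFT correlation of frames with a whole kernel bank.

    The kernel FFTs are computed once and reused for every frame of a
    movie, which dominates the runtime saving over per-frame
    convolution calls.  The kernels are 180-degree symmetric, so the
    correlation is computed as a convolution (no flip needed).
    """

    def __init__(self, bank: KernelBank) -> None:
        self.bank = bank
        self._rasters = bank.raster_stack()  # (P*Q, s, s)
        self._frame_shape: tuple[int, int] | None = None
        self._kernel_fft: np.ndarray | None = None
        self._fft_shape: tuple[int, int] | None = None

    def _prepare(self, frame_shape: tuple[int, int]) -> None:
        s = self.bank.shape.support
        h, w = frame_shape
        fh = sfft.next_fast_len(h + 2 * (s // 2) + s - 1)
        fw = sfft.next_fast_len(w + 2 * (s // 2) + s - 1)
        self._fft_shape = (fh, fw)
        self._kernel_fft = sfft.rfft2(self._rasters, s=(fh, fw))
        self._frame_shape = frame_shape

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        """Response stack (P, Q, H, W), "same" size, symmetric padding."""
        frame = np.asarray(frame, dtype=float)
        if frame.ndim != 2:
            raise ValueError("frame must be a single-channel 2-D array")
        if not np.all(np.isfinite(frame)):
            raise ValueError("frame contains non-finite values")
        s = self.bank.shape.support
        h, w = frame.shape
        if h < s or w < s:
            raise ValueError(
                f"frame {frame.shape} smaller than kernel support {s}"
            )
        if self._frame_shape != frame.shape:
            self._prepare(frame.shape)
        pad = s // 2
        padded = np.pad(frame, pad, mode="symmetric")
        ffts = sfft.rfft2(padded, s=self._fft_shape)
        full = sfft.irfft2(ffts[None] * self._kernel_fft, s=self._fft_shape)
        # "valid" part of the full convolution with the padded frame
        resp = full[:, s - 1 : s - 1 + h, s - 1 : s - 1 + w]
        p, q = self.bank.n_distances, self.bank.n_angles
        return np.ascontiguousarray(resp.reshape(p, q, h, w))


def convolve_with_bank(frame: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Correlate one frame with every kernel in the bank.

    Returns a response stack of shape ``(P, Q, H, W)`` -- one image per
    (distance, angle) kernel, spatially aligned with the frame ("same"
    output, symmetric boundary padding).  For whole movies prefer a
    single :class:`BankConvolver`, which caches the kernel FFTs.
    """
    return BankConvolver(bank)(frame)


def select_grid_detections(
    responses: np.ndarray, bank: KernelBank, cfg: DetectionConfig
) -> list[FrameDetection]:
    """Argmax over (distance, angle, neighborhood) at every subgrid point.

    Ties are broken toward the smallest distance index, then the
    smallest angle index, then raster order of position, so results are
    reproducible bit-for-bit across platforms.
    """
    cfg.validate_against_bank(bank)
    p, q, h, w = responses.shape
    rows, cols = subgrid_points((h, w), cfg)
    hw = cfg.halfwindowsize
    margin = bank.shape.support // 2 + hw  # padding influence + window
    out: list[FrameDetection] = []
    for gi, r in enumerate(rows):
        r0, r1 = max(0, r - hw), min(h, r + hw + 1)
        for gj, c in enumerate(cols):
            c0, c1 = max(0, c - hw), min(w, c + hw + 1)
            win = responses[:, :, r0:r1, c0:c1]
            # C-order argmax = first occurrence = spec tie-break order
            flat = int(np.argmax(win))
            di, ai, wr, wc = np.unravel_index(flat, win.shape)
            border = (
                r < margin or c < margin or r >= h - margin or c >= w - margin
            )
            out.append(
                FrameDetection(
                    grid_row=gi,
                    grid_col=gj,
                    location=(int(r0 + wr), int(c0 + wc)),
                    distance=float(bank.distances[di]),
                    angle=float(bank.angles[ai]),
                    magnitude=float(win[di, ai, wr, wc]),
                    border=bool(border),
                )
            )
    return out


def filter_by_magnitude(
    detections_per_frame: Sequence[Sequence[FrameDetection]],
    cfg: DetectionConfig,
) -> list[int]:
    """Indices of grid points bright enough to keep, in stable order.

    A grid point's brightness is the *median* of its detection magnitude
    across frames, so a sarcomere cannot flicker in and out of the
    retained set.  A point is kept iff its median is >= the
    ``magnitude_quantile`` quantile of all (non-border) grid points'
    medians.  Border grid points, whose responses are influenced by the
    boundary padding, are always dropped.
    """
    if len(detections_per_frame) == 0:
        raise ValueError("need detections for at least one frame")
    n_points = len(detections_per_frame[0])
    mags = np.array(
        [[d.magnitude for d in frame] for frame in detections_per_frame]
    )  # (n_frames, n_points)
    medians = np.median(mags, axis=0)
    interior = np.array(
        [not d.border for d in detections_per_frame[0]], dtype=bool
    )
    if not interior.any():
        return []
    cutoff = np.quantile(medians[interior], cfg.magnitude_quantile)
    return [
        i
        for i in range(n_points)
        if interior[i] and medians[i] >= cutoff
    ]
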