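"""Morlet-wavelet templates for sarcomere detection.

A fluorescently labeled Z-disc appears in a movie frame as a short bright
ridge.  A single real 2-D Morlet wavelet -- a cosine oscillating along one
axis under an anisotropic Gaussian envelope -- is a matched filter for one
such ridge.  A sarcomere is a *pair* of parallel ridges, so the detection
template is a "double wavelet": two single wavelets at separation
``distance``, rotated together by ``angle`` about their common center of
mass, then normalized to mean 0 and Frobenius norm 1 so that convolution
responses are comparable across templates.

A :class:`KernelBank` holds the grid of double wavelets over all candidate
(distance, angle) pairs used by :mod:`sarctrack.detect`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveletShape",
    "DoubleWaveletKernel",
    "KernelBank",
    "KernelConfig",
    "make_single_wavelet",
    "make_double_wavelet",
    "build_kernel_bank",
]


@dataclass(frozen=True)
class WaveletShape:
    """Geometry of one single wavelet.

    Parameters
    ----------
    scale : float
        Gaussian envelope standard deviation along the oscillation axis,
        in pixels.  Sets the width of the bright central lobe.
    stretch : float
        Dimensionless elongation of the envelope along the ridge axis;
        the envelope SD there is ``scale * stretch``.  Must be >= 1.
    wavelength : float
        Pixels per cosine period.  The default ``4 * scale`` gives one
        bright central lobe flanked by negative side lobes.
    support : int
        Odd side length of the square raster, in pixels.  Must be at
        least ``4 * scale * stretch`` so the template is not truncated.
    """

    scale: float = 3.0
    stretch: float = 3.0
    wavelength: float = field(default=None)  # type: ignore[assignment]
    support: int = 41

    def __post_init__(self) -> None:
        if self.wavelength is None:
            object.__setattr__(self, "wavelength", 4.0 * self.scale)
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.stretch < 1:
            raise ValueError("stretch must be >= 1")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.support < 3 or self.support % 2 == 0:
            raise ValueError("support must be odd and >= 3")
        if self.support < 4 * self.scale * self.stretch:
            raise ValueError(
                f"support {self.support} truncates the template; need "
                f">= 4*scale*stretch = {4 * self.scale * self.stretch:g}"
            )


@dataclass(frozen=True)
class DoubleWaveletKernel:
    """One normalized double-wavelet raster for a (distance, angle) pair."""

    raster: np.ndarray
    distance: float
    angle: float
    shape: WaveletShape


@dataclass(frozen=True)
class KernelBank:
    """P x Q grid of double wavelets over distances x angles."""

    distances: np.ndarray  # strictly increasing, pixels
    angles: np.ndarray  # strictly increasing, radians in [0, pi)
    kernels: tuple  # tuple of P tuples of Q DoubleWaveletKernel
    shape: WaveletShape

    @property
    def n_distances(self) -> int:
        return len(self.distances)

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    def raster_stack(self) -> np.ndarray:
        """All rasters as one (P*Q, support, support) array, row-major in
        (distance, angle)."""
        return np.stack(
            [k.raster for row in self.kernels for k in row], axis=0
        )


@dataclass(frozen=True)
class KernelConfig:
    """User-facing bank parameters (file / CLI flags).

    ``dmin``..``dmax`` should bracket the Z-disc spacings seen in the
    data with some headroom for contraction; the defaults suit
    ~1.8-2.2 um sarcomeres imaged at ~0.1 um/px (18-22 px relaxed).
    """

    scale: float = 3.0
    stretch: float = 3.0
    wavelength: float | None = None  # default 4*scale
    support: int = 41
    dmin: float = 14.0
    dmax: float = 22.0
    ndistances: int = 17
    nangles: int = 4

    def wavelet_shape(self) -> WaveletShape:
        return WaveletShape(
            scale=self.scale,
            stretch=self.stretch,
            wavelength=self.wavelength,
            support=self.support,
        )

    def build(self) -> "KernelBank":
        return build_kernel_bank(
            self.wavelet_shape(),
            self.dmin,
            self.dmax,
            self.ndistances,
            self.nangles,
        )


def _coordinate_grids(support: int) -> tuple[np.ndarray, np.ndarray]:
    half = (support - 1) // 2
    c = np.arange(-half, half + 1, dtype=float)
    # x runs along columns, y along rows
    y, x = np.meshgrid(c, c, indexing="ij")
    return x, y


def make_single_wavelet(
    shape: WaveletShape, angle: float = 0.0, offset: float = 0.0
) -> np.ndarray:
    """Raster of one real Morlet wavelet.

    In coordinates rotated by ``angle`` (x' along the oscillation axis,
    y' along the ridge), the value at each pixel is::

        exp(-(x'-offset)^2 / (2 scale^2) - y'^2 / (2 (scale*stretch)^2))
          * cos(2 pi (x'-offset) / wavelength)

    The rotation is applied analytically inside the coordinates, so no
    raster resampling (and no interpolation error) occurs.  At
    ``angle=0`` the bright ridge is vertical (oscillation along columns).

    Parameters
    ----------
    shape : WaveletShape
    angle : float
        Rotation in radians.
    offset : float
        Displacement of the peak from the raster center along the
        oscillation axis, in pixels.  ``|offset|`` must keep the peak
        inside the raster.

    Returns
    -------
    ndarray of shape ``(support, support)``, peak value 1 at x' = offset.
    """
    if abs(offset) >= shape.support / 2:
        raise ValueError(
            f"offset {offset} places the peak outside the raster "
            f"(support {shape.support})"
        )
    x, y = _coordinate_grids(shape.support)
    ca, sa = np.cos(angle), np.sin(angle)
    xr = x * ca + y * sa
    yr = -x * sa + y * ca
    u = xr - offset
    envelope = np.exp(
        -(u**2) / (2.0 * shape.scale**2)
        - yr**2 / (2.0 * (shape.scale * shape.stretch) ** 2)
    )
    return envelope * np.cos(2.0 * np.pi * u / shape.wavelength)


def make_double_wavelet(
    shape: WaveletShape, distance: float, angle: float = 0.0
) -> DoubleWaveletKernel:
    """Two parallel single wavelets at +/- distance/2, rotated, normalized.

    The pair's center of mass sits at the raster center.  Normalization
    subtracts the raster mean and divides by the Frobenius norm, so the
    kernel has mean 0 and norm 1: a flat image region gives response 0,
    and the response to any patch is bounded by the patch's norm.
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    if distance + 4 * shape.scale > shape.support:
        raise ValueError(
            f"distance {distance:g} too large for support {shape.support}; "
            f"need support >= distance + 4*scale = "
            f"{distance + 4 * shape.scale:g}"
        )
    raster = make_single_wavelet(shape, angle, +distance / 2.0)
    raster = raster + make_single_wavelet(shape, angle, -distance / 2.0)
    raster = raster - raster.mean()
    raster = raster / np.linalg.norm(raster)
    raster.flags.writeable = False
    return DoubleWaveletKernel(
        raster=raster, distance=float(distance), angle=float(angle), shape=shape
    )


def build_kernel_bank(
    shape: WaveletShape,
    d_min: float,
    d_max: float,
    n_distances: int,
    n_angles: int,
) -> KernelBank:
    """Bank of double wavelets over a (distance, angle) grid.

    Distances are ``n_distances`` evenly spaced values on [d_min, d_max];
    angles are ``k*pi/n_angles`` for k = 0..n_angles-1.  The half-turn
    range suffices because the pair is symmetric under 180 degree
    rotation.
    """
    if not d_min < d_max:
        raise ValueError("require d_min < d_max")
    if n_distances < 2:
        raise ValueError("n_distances must be >= 2")
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    if d_max + 4 * shape.scale > shape.support:
        raise ValueError(
            f"d_max {d_max:g} infeasible for support {shape.support}; "
            f"increase support to >= {d_max + 4 * shape.scale:g}"
        )
    distances = np.linspace(d_min, d_max, n_distances)
    angles = np.arange(n_angles) * np.pi / n_angles
    kernels = tuple(
        tuple(make_double_wavelet(shape, d, a) for a in angles)
        for d in distances
    )
    return KernelBank(
        distances=distances, angles=angles, kernels=kernels, shape=shape
    )
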