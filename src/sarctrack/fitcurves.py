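"""Kinetics fitting: beat frequency, and the periodic sawtooth model.

The spacing d(t) of a beating sarcomere is constant while the sarcomere
is relaxed and dips through a smooth valley while it contracts and
re-lengthens.  Two fits extract kinetics from the traces:

1. A sinusoid ``A sin(2 pi f t) + B cos(2 pi f t) + C`` fitted to the
   registered average trace by a dense scan over frequency.  This pins
   down the beat frequency f (hence beat rate) for the whole movie.

2. A periodic plateau-valley ("sawtooth") curve fitted to each
   sarcomere's raw trace independently.  With period T = fps/f frames,
   plateau length L = T - c - r and phase u = (t - delta) mod T::

       s(u) = 1                                    u in [0, L)      relaxed
       s(u) = (1 + cos(pi (u-L)/c)) / 2            u in [L, L+c)    contraction
       s(u) = (1 - cos(pi (u-L-c)/r)) / 2          u in [L+c, T)    relaxation

   The half-cosine fall and rise make the curve continuous with exact
   plateau value 1 and valley floor 0.  Only c (contraction frames),
   r (relaxation frames) and delta (phase offset, frames) are optimized
   per sarcomere -- f is frozen from the sinusoid fit -- by maximizing
   the Pearson correlation between trace and model, which is invariant
   to the affine scale and offset of the spacing signal.  Goodness of
   fit (RMSE after affine rescaling of the model onto the data) and the
   correlation itself then select trustworthy sarcomeres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace import AverageTrace, SarcomereTrace

__all__ = [
    "FitConfig",
    "SinusoidFit",
    "SawtoothFit",
    "SarcomereStats",
    "fit_sinusoid",
    "sawtooth_model",
    "fit_sawtooth",
    "filter_by_rmse",
    "summarize_sarcomere",
]


@dataclass(frozen=True)
class FitConfig:
    """Knobs for frequency scanning and fit-quality selection."""

    freq_scan_lo: float = 0.2  # Hz
    freq_scan_hi: float = 4.0  # Hz
    freq_scan_step: float = 0.01  # Hz
    rmse_quantile: float = 0.75
    min_correlation: float = 0.5


@dataclass(frozen=True)
class SinusoidFit:
    """Beat-frequency estimate from the average trace."""

    frequency: float  # Hz
    amplitude: float  # pixels
    phase: float  # radians
    fps: float

    @property
    def period_frames(self) -> float:
        return self.fps / self.frequency

    @property
    def bpm(self) -> float:
        return 60.0 * self.frequency


@dataclass(frozen=True)
class SawtoothFit:
    """Per-sarcomere kinetic parameters from the sawtooth fit."""

    t_contract: float  # frames (fall duration c)
    t_relax: float  # frames (rise duration r)
    phase_offset: float  # frames (delta)
    frequency: float  # Hz, inherited from the sinusoid fit
    fps: float
    correlation: float  # Pearson r of model vs data
    rmse: float  # pixels, after affine rescale of model onto data
    at_bounds: bool = False  # optimizer pinned at a parameter bound

    @property
    def period_frames(self) -> float:
        return self.fps / self.frequency


@dataclass(frozen=True)
class SarcomereStats:
    """Calibrated per-sarcomere outputs."""

    grid_id: int
    d_min: float  # pixels, contracted spacing
    d_max: float  # pixels, relaxed spacing
    shortening_pct: float
    t_contract_s: float
    t_relax_s: float
    sl_min_um: float
    sl_max_um: float


def fit_sinusoid(
    avg: AverageTrace | np.ndarray,
    fps: float | None = None,
    cfg: FitConfig = FitConfig(),
) -> SinusoidFit:
    """Dense frequency scan of a 3-parameter sinusoid least-squares fit.

    For each candidate f on [freq_scan_lo, freq_scan_hi] (step
    freq_scan_step) the model ``A sin + B cos + C`` is solved in closed
    form; the f with the smallest residual wins.  Deterministic: no
    iterative optimizer, no starting point.
    """
    if isinstance(avg, AverageTrace):
        y = np.asarray(avg.distances, dtype=float)
        fps = avg.fps
    else:
        y = np.asarray(avg, dtype=float)
        if fps is None:
            raise ValueError("fps required when passing a bare array")
    if np.ptp(y) < 1e-12:
        raise ValueError("constant trace: no oscillation to fit")
    n = len(y)
    t = np.arange(n)
    freqs = np.arange(
        cfg.freq_scan_lo, cfg.freq_scan_hi + cfg.freq_scan_step / 2,
        cfg.freq_scan_step,
    )
    best = None
    for f in freqs:
        w = 2.0 * np.pi * f / fps
        design = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones(n)])
        coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(res[0]) if res.size else float(
            np.sum((y - design @ coef) ** 2)
        )
        if best is None or rss < best[0]:
            best = (rss, f, coef)
    _, f, (a, b, _) = best
    return SinusoidFit(
        frequency=float(f),
        amplitude=float(np.hypot(a, b)),
        phase=float(np.arctan2(b, a)),
        fps=float(fps),
    )


def sawtooth_model(
    t: np.ndarray | float,
    f: float,
    t_contract: float,
    t_relax: float,
    phase_offset: float,
    fps: float,
) -> np.ndarray:
    """Evaluate the plateau-valley curve at frame indices ``t``.

    Returns values in [0, 1]: 1 on the relaxed plateau, 0 at the valley
    floor, periodic with period ``fps/f`` frames and continuous
    everywhere.
    """
    T = fps / f
    c, r = float(t_contract), float(t_relax)
    if c <= 0 or r <= 0:
        raise ValueError("t_contract and t_relax must be > 0")
    if c + r > T + 1e-9:
        raise ValueError(
            f"t_contract + t_relax = {c + r:g} exceeds period {T:g} frames"
        )
    u = np.mod(np.asarray(t, dtype=float) - phase_offset, T)
    L = T - c - r
    out = np.ones_like(u)
    fall = (u >= L) & (u < L + c)
    rise = u >= L + c
    out[fall] = 0.5 * (1.0 + np.cos(np.pi * (u[fall] - L) / c))
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * (u[rise] - L - c) / r))
    return out


def _model_matrix(
    t: np.ndarray, T: float, c: float, r: float, deltas: np.ndarray
) -> np.ndarray:
    """sawtooth_model evaluated for many phase offsets at once."""
    u = np.mod(t[None, :] - deltas[:, None], T)
    L = T - c - r
    out = np.ones_like(u)
    fall = (u >= L) & (u < L + c)
    rise = u >= L + c
    out[fall] = 0.5 * (1.0 + np.cos(np.pi * (u[fall] - L) / c))
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * (u[rise] - L - c) / r))
    return out


def _correlations(models: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each model row with y (0 where degenerate)."""
    yc = y - y.mean()
    ys = np.linalg.norm(yc)
    mc = models - models.mean(axis=1, keepdims=True)
    ms = np.linalg.norm(mc, axis=1)
    denom = ms * ys
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, mc @ yc / np.where(denom > 0, denom, 1), 0.0)
    return corr


_MIN_DURATION = 0.5  # frames; below half a frame the phase is unobservable


def fit_sawtooth(
    trace: SarcomereTrace | np.ndarray,
    sine: SinusoidFit,
    init: "SawtoothFit | None" = None,
) -> SawtoothFit:
    """Fit (c, r, delta) to one trace by correlation maximization.

    A deterministic coarse-to-fine search: a coarse grid over (c, r)
    (spanning +/-50% around ``init`` when given, otherwise the whole
    feasible wedge) crossed with every integer phase offset in one
    period, followed by a shrinking-step pattern search refining all
    three parameters continuously.  No stochastic restarts, so results
    are bit-reproducible.
    """
    y = (
        np.asarray(trace.distances, dtype=float)
        if isinstance(trace, SarcomereTrace)
        else np.asarray(trace, dtype=float)
    )
    fps = sine.fps
    T = sine.period_frames
    t = np.arange(len(y), dtype=float)

    if init is not None:
        c_grid = np.linspace(0.5 * init.t_contract, 1.5 * init.t_contract, 9)
        r_grid = np.linspace(0.5 * init.t_relax, 1.5 * init.t_relax, 9)
    else:
        c_grid = np.linspace(max(_MIN_DURATION, 0.05 * T), 0.5 * T, 12)
        r_grid = np.linspace(max(_MIN_DURATION, 0.05 * T), 0.5 * T, 12)
    c_grid = np.clip(c_grid, _MIN_DURATION, T - _MIN_DURATION)
    r_grid = np.clip(r_grid, _MIN_DURATION, T - _MIN_DURATION)
    deltas = np.arange(int(np.ceil(T)), dtype=float)

    best_corr, best = -2.0, None
    for c in c_grid:
        for r in r_grid:
            if c + r > T:
                continue
            corr = _correlations(_model_matrix(t, T, c, r, deltas), y)
            k = int(np.argmax(corr))
            if corr[k] > best_corr:
                best_corr, best = float(corr[k]), (float(c), float(r), float(deltas[k]))
    if best is None:
        raise ValueError("no feasible (c, r) candidates for this period")

    def objective(c: float, r: float, d: float) -> float:
        if c < _MIN_DURATION or r < _MIN_DURATION or c + r > T:
            return -2.0
        m = _model_matrix(t, T, c, r, np.array([d]))
        return float(_correlations(m, y)[0])

    c, r, d = best
    for step in (2.0, 1.0, 0.5, 0.25, 0.1, 0.05):
        improved = True
        while improved:
            improved = False
            for dc, dr, dd in (
                (step, 0, 0), (-step, 0, 0),
                (0, step, 0), (0, -step, 0),
                (0, 0, step), (0, 0, -step),
            ):
                cand = objective(c + dc, r + dr, (d + dd) % T)
                if cand > best_corr + 1e-12:
                    best_corr = cand
                    c, r, d = c + dc, r + dr, (d + dd) % T
                    improved = True

    # simplex polish: the correlation surface has diagonal ridges in
    # (c, r, delta) that axis-aligned moves cannot follow to the top
    from scipy.optimize import minimize

    res = minimize(
        lambda x: -objective(x[0], x[1], x[2] % T),
        x0=np.array([c, r, d]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400},
    )
    if -res.fun > best_corr:
        best_corr = float(-res.fun)
        c, r, d = float(res.x[0]), float(res.x[1]), float(res.x[2]) % T

    at_bounds = (
        c <= _MIN_DURATION + 1e-9
        or r <= _MIN_DURATION + 1e-9
        or c + r >= T - 1e-9
    )
    model = sawtooth_model(t, sine.frequency, c, r, d, fps)
    design = np.column_stack([model, np.ones_like(model)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rmse = float(np.sqrt(np.mean((y - design @ coef) ** 2)))
    return SawtoothFit(
        t_contract=float(c),
        t_relax=float(r),
        phase_offset=float(d),
        frequency=sine.frequency,
        fps=fps,
        correlation=best_corr,
        rmse=rmse,
        at_bounds=at_bounds,
    )


def filter_by_rmse(
    fits: Sequence[SawtoothFit],
    rmse_quantile: float = 0.75,
    min_correlation: float = 0.5,
) -> list[int]:
    """Indices of fits passing the goodness-of-fit selection, stable order.

    A fit survives iff its RMSE is <= the ``rmse_quantile`` quantile of
    all RMSE values, its correlation is >= ``min_correlation``, and the
    optimizer did not pin a parameter at a bound.  Duplicate fits share
    a fate (the rule depends only on values, not order).
    """
    if len(fits) == 0:
        return []
    rmses = np.array([f.rmse for f in fits])
    cutoff = np.quantile(rmses, rmse_quantile)
    return [
        i
        for i, f in enumerate(fits)
        if f.rmse <= cutoff
        and f.correlation >= min_correlation
        and not f.at_bounds
    ]


def summarize_sarcomere(
    trace: SarcomereTrace,
    fit: SawtoothFit,
    microns_per_pixel: float,
    fps: float,
) -> SarcomereStats:
    """Calibrated spacing extremes and kinetic times for one sarcomere.

    d_max / d_min are means of the per-period maxima / minima of the
    *raw* trace (periods cut by the fitted beat period), which is robust
    to residual model misfit.  Times convert frames to seconds via fps;
    spacings convert pixels to microns via microns_per_pixel.
    """
    y = np.asarray(trace.distances, dtype=float)
    T = fit.period_frames
    n_periods = int(len(y) // T)
    if n_periods < 1:
        edges = [0, len(y)]
    else:
        edges = [int(round(k * T)) for k in range(n_periods + 1)]
    maxima = [y[a:b].max() for a, b in zip(edges[:-1], edges[1:]) if b > a]
    minima = [y[a:b].min() for a, b in zip(edges[:-1], edges[1:]) if b > a]
    d_max = float(np.mean(maxima))
    d_min = float(np.mean(minima))
    if d_max <= 0:
        raise ValueError("non-positive relaxed spacing")
    return SarcomereStats(
        grid_id=trace.grid_id,
        d_min=d_min,
        d_max=d_max,
        shortening_pct=100.0 * (d_max - d_min) / d_max,
        t_contract_s=fit.t_contract / fps,
        t_relax_s=fit.t_relax / fps,
        sl_min_um=d_min * microns_per_pixel,
        sl_max_um=d_max * microns_per_pixel,
    )
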