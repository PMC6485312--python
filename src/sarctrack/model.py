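"""Model / Results objects tying the whole pipeline together.

:class:`SarcTrack` is constructed from an image stack plus calibration
and configuration; :meth:`SarcTrack.fit` runs detection, trace
assembly, frequency estimation and per-sarcomere sawtooth fitting, and
returns a :class:`SarcTrackResults` carrying every intermediate, the
per-sarcomere estimates with diagnostics, and a ``summary()`` table of
field-of-view means with standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import detect as _detect
from . import fitcurves as _fit
from . import trace as _trace
from .detect import DetectionConfig
from .fitcurves import FitConfig, SarcomereStats, SawtoothFit, SinusoidFit
from .kernels import KernelBank, KernelConfig
from .trace import AverageTrace, SarcomereTrace

logger = logging.getLogger("sarctrack")

__all__ = ["SarcTrack", "SarcTrackResults"]

_STAT_COLUMNS = [
    "shortening_pct",
    "sl_min_um",
    "sl_max_um",
    "t_contract_s",
    "t_relax_s",
]


class SarcTrack:
    """Per-sarcomere contraction-kinetics model for one movie.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Grayscale movie, >= 2 frames.
    fps : float
        Acquisition rate, frames per second.  No default: calibration
        is hardware-specific and must be supplied.
    microns_per_pixel : float
        Spatial calibration.  No default, for the same reason.
    kernel_config, detection_config, fit_config : optional
        Detection-template, subgrid and fitting parameters.
    register : bool
        Register traces before averaging (recommended: sarcomeres do
        not beat in synchrony, and an unregistered average broadens the
        valley and overestimates contraction/relaxation times).
    """

    def __init__(
        self,
        frames: np.ndarray,
        fps: float,
        microns_per_pixel: float,
        kernel_config: KernelConfig | None = None,
        detection_config: DetectionConfig | None = None,
        fit_config: FitConfig | None = None,
        register: bool = True,
    ) -> None:
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise ValueError("frames must be a (n_frames >= 2, H, W) stack")
        if fps <= 0 or microns_per_pixel <= 0:
            raise ValueError("fps and microns_per_pixel must be positive")
        self.frames = frames
        self.fps = float(fps)
        self.microns_per_pixel = float(microns_per_pixel)
        self.kernel_config = kernel_config or KernelConfig()
        self.detection_config = detection_config or DetectionConfig()
        self.fit_config = fit_config or FitConfig()
        self.register = register

    @classmethod
    def from_tiff(
        cls,
        path,
        fps: float,
        microns_per_pixel: float,
        channel: int | None = None,
        **kwargs,
    ) -> "SarcTrack":
        from .pipeline_io import read_stack

        frames, meta = read_stack(path, channel=channel)
        return cls(frames, fps=fps, microns_per_pixel=microns_per_pixel, **kwargs)

    # ------------------------------------------------------------------

    def detect_frames(self, bank: KernelBank | None = None):
        """Run matched-filter detection on every frame."""
        bank = bank or self.kernel_config.build()
        convolver = _detect.BankConvolver(bank)
        per_frame = []
        for t in range(self.frames.shape[0]):
            resp = convolver(self.frames[t])
            per_frame.append(
                _detect.select_grid_detections(resp, bank, self.detection_config)
            )
        return bank, per_frame

    def fit(self) -> "SarcTrackResults":
        """Run the full pipeline and return the results object."""
        bank, per_frame = self.detect_frames()
        n_grid = len(per_frame[0])
        retained = _detect.filter_by_magnitude(per_frame, self.detection_config)
        logger.info(
            "grid points: %d total, %d retained after magnitude filter",
            n_grid,
            len(retained),
        )
        traces = _trace.extract_traces(per_frame, retained, self.fps)
        empty = SarcTrackResults(
            model=self,
            bank=bank,
            detections_per_frame=per_frame,
            retained_grid_ids=list(retained),
            traces=traces,
        )
        if not traces:
            logger.warning("no sarcomeres retained; empty results")
            return empty

        avg = _trace.average_trace(traces, register=self.register)
        avg_raw = _trace.average_trace(traces, register=False)
        try:
            sine = _fit.fit_sinusoid(avg, cfg=self.fit_config)
        except ValueError:
            logger.warning("no oscillation detected; empty results")
            return empty
        avg_fit = _fit.fit_sawtooth(avg.distances, sine)
        fits = [_fit.fit_sawtooth(tr, sine, init=avg_fit) for tr in traces]
        selected = _fit.filter_by_rmse(
            fits,
            rmse_quantile=self.fit_config.rmse_quantile,
            min_correlation=self.fit_config.min_correlation,
        )
        logger.info(
            "sawtooth fits: %d traces, %d pass goodness-of-fit selection",
            len(fits),
            len(selected),
        )
        stats = [
            _fit.summarize_sarcomere(
                traces[i], fits[i], self.microns_per_pixel, self.fps
            )
            for i in selected
        ]
        return SarcTrackResults(
            model=self,
            bank=bank,
            detections_per_frame=per_frame,
            retained_grid_ids=list(retained),
            traces=traces,
            average=avg,
            unregistered_average=avg_raw,
            sinusoid=sine,
            average_fit=avg_fit,
            fits=fits,
            selected=list(selected),
            stats=stats,
        )


@dataclass
class SarcTrackResults:
    """Everything the fit produced, with summary and plotting helpers."""

    model: SarcTrack
    bank: KernelBank
    detections_per_frame: list
    retained_grid_ids: list[int]
    traces: list[SarcomereTrace]
    average: AverageTrace | None = None
    unregistered_average: AverageTrace | None = None
    sinusoid: SinusoidFit | None = None
    average_fit: SawtoothFit | None = None
    fits: list[SawtoothFit] = field(default_factory=list)
    selected: list[int] = field(default_factory=list)  # indices into traces
    stats: list[SarcomereStats] = field(default_factory=list)

    @property
    def n_sarcomeres(self) -> int:
        """Sarcomeres surviving all filters (the reporting population)."""
        return len(self.stats)

    @property
    def bpm(self) -> float:
        return self.sinusoid.bpm if self.sinusoid is not None else float("nan")

    def stats_frame(self) -> pd.DataFrame:
        """Per-sarcomere calibrated estimates and diagnostics, tidy."""
        rows = []
        for idx, st in zip(self.selected, self.stats):
            f = self.fits[idx]
            rows.append(
                {
                    "sarcomere_id": st.grid_id,
                    "t_contract_frames": f.t_contract,
                    "t_relax_frames": f.t_relax,
                    "d_min_px": st.d_min,
                    "d_max_px": st.d_max,
                    "correlation": f.correlation,
                    "rmse": f.rmse,
                    "t_contract_s": st.t_contract_s,
                    "t_relax_s": st.t_relax_s,
                    "sl_min_um": st.sl_min_um,
                    "sl_max_um": st.sl_max_um,
                    "shortening_pct": st.shortening_pct,
                }
            )
        cols = [
            "sarcomere_id",
            "t_contract_frames",
            "t_relax_frames",
            "d_min_px",
            "d_max_px",
            "correlation",
            "rmse",
            "t_contract_s",
            "t_relax_s",
            "sl_min_um",
            "sl_max_um",
            "shortening_pct",
        ]
        return pd.DataFrame(rows, columns=cols)

    def distances_frame(self) -> pd.DataFrame:
        """All retained traces, long format (frame, sarcomere_id, ...)."""
        rows = []
        for tr in self.traces:
            for t in range(len(tr.distances)):
                rows.append(
                    {
                        "frame": t,
                        "sarcomere_id": tr.grid_id,
                        "distance_px": tr.distances[t],
                        "magnitude": tr.magnitudes[t],
                    }
                )
        return pd.DataFrame(
            rows, columns=["frame", "sarcomere_id", "distance_px", "magnitude"]
        )

    def mean_sem(self) -> pd.DataFrame:
        """Mean and SEM (sd/sqrt(n)) of each calibrated parameter."""
        df = self.stats_frame()
        n = len(df)
        out = {}
        for c in _STAT_COLUMNS:
            vals = df[c].to_numpy()
            mean = float(np.mean(vals)) if n else float("nan")
            sem = (
                float(np.std(vals, ddof=1) / np.sqrt(n))
                if n > 1
                else float("nan")
            )
            out[c] = {"mean": mean, "sem": sem}
        return pd.DataFrame(out).T

    def summary(self) -> str:
        """Human-readable field-of-view summary table."""
        lines = []
        lines.append("SarcTrack Results")
        lines.append("=" * 58)
        lines.append(f"frames analyzed        : {self.model.frames.shape[0]}")
        lines.append(f"grid points retained   : {len(self.retained_grid_ids)}")
        lines.append(f"sarcomeres reported    : {self.n_sarcomeres}")
        if self.sinusoid is not None:
            lines.append(
                f"beat frequency         : {self.sinusoid.frequency:.3f} Hz"
                f"  ({self.bpm:.1f} bpm)"
            )
            lines.append(
                f"beat period            : {self.sinusoid.period_frames:.1f}"
                " frames"
            )
        lines.append("-" * 58)
        if self.n_sarcomeres:
            ms = self.mean_sem()
            lines.append(f"{'parameter':<18}{'mean':>12}{'SEM':>12}")
            for name, row in ms.iterrows():
                lines.append(
                    f"{name:<18}{row['mean']:>12.4f}{row['sem']:>12.4f}"
                )
        else:
            lines.append("no sarcomeres passed selection")
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------

    def plot_average(self, ax=None):
        """Registered average trace with the sinusoid and sawtooth fits."""
        import matplotlib.pyplot as plt

        if self.average is None:
            raise ValueError("no average trace (empty results)")
        if ax is None:
            _, ax = plt.subplots()
        y = self.average.distances
        t = np.arange(len(y))
        ax.plot(t, y, "k.", ms=3, label="registered average d(t)")
        if self.sinusoid is not None and self.average_fit is not None:
            af = self.average_fit
            model = _fit.sawtooth_model(
                t, af.frequency, af.t_contract, af.t_relax,
                af.phase_offset, af.fps,
            )
            a = y.max() - y.min()
            ax.plot(t, y.min() + a * model, "r-", lw=1, label="sawtooth fit")
        ax.set_xlabel("frame")
        ax.set_ylabel("spacing (px)")
        ax.legend(fontsize=8)
        return ax

    def plot_overlay(self, frame_index: int, ax=None, cmap="cool"):
        """One frame with retained detections drawn as oriented segments.

        Segments join the two wavelet peaks of each detected pair and
        are colored by spacing: short spacings map to the blue end of
        the colormap, long spacings to the pink end.
        """
        import matplotlib.pyplot as plt
        from matplotlib import cm
        from matplotlib.colors import Normalize

        if ax is None:
            _, ax = plt.subplots()
        frame = self.model.frames[frame_index]
        ax.imshow(frame, cmap="gray", interpolation="nearest")
        dets = self.detections_per_frame[frame_index]
        norm = Normalize(
            vmin=float(self.bank.distances[0]),
            vmax=float(self.bank.distances[-1]),
        )
        mapper = cm.ScalarMappable(norm=norm, cmap=cmap)
        for gid in self.retained_grid_ids:
            d = dets[gid]
            row, col = d.location
            dx = 0.5 * d.distance * np.cos(d.angle)
            dy = 0.5 * d.distance * np.sin(d.angle)
            ax.plot(
                [col - dx, col + dx],
                [row - dy, row + dy],
                color=mapper.to_rgba(d.distance),
                lw=1.2,
            )
        ax.set_axis_off()
        return ax
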