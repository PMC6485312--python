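"""Movie I/O, per-movie output files, and batch collation.

Per movie, three CSV files mirror the classic outputs:

* ``DWDists.csv``  -- every retained sarcomere's spacing and response
  magnitude on every frame (long format).
* ``DWStats.csv``  -- per-sarcomere kinetics: contraction / relaxation
  times (frames and seconds), spacing extremes (pixels and microns),
  percent shortening, fit correlation and RMSE.
* ``DWPrdFrq.csv`` -- the movie-level beat period / frequency / rate
  plus the calibration used.

plus optional per-frame PNG overlays for quality control.  A batch of
processed movie directories collates into a single tab-separated
summary, one row per movie with means, SEMs and the sarcomere count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .detect import DetectionConfig
from .fitcurves import FitConfig
from .kernels import KernelConfig
from .model import _STAT_COLUMNS, SarcTrack, SarcTrackResults

logger = logging.getLogger("sarctrack")

__all__ = [
    "MovieSummary",
    "read_stack",
    "write_stack",
    "process_movie",
    "write_outputs",
    "collate_batch",
]


@dataclass(frozen=True)
class MovieSummary:
    """One collated row: field-of-view means, SEMs and counts."""

    movie_id: str
    n_sarcomeres: int
    means: dict  # parameter -> mean
    sems: dict  # parameter -> sd/sqrt(n)
    bpm: float
    fps: float
    microns_per_pixel: float


def read_stack(path, channel: int | None = None):
    """Read a multi-page TIFF as a (n_frames, H, W) float array.

    Multi-channel stacks require ``channel`` to pick one channel (the
    trailing or leading small axis).  Rejects single-frame files --
    kinetics need a time axis -- and non-grayscale data without a
    channel selection.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"unreadable TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 4:
        if channel is None:
            raise ValueError(
                f"{path}: multi-channel stack, pass a channel selection"
            )
        # channel axis is whichever non-time axis is small
        ax = int(np.argmin(arr.shape[1:])) + 1
        arr = np.take(arr, channel, axis=ax)
    if arr.ndim == 3 and channel is not None and arr.shape[-1] <= 4:
        arr = arr[..., channel]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page grayscale TIFF")
    if arr.shape[0] < 2:
        raise ValueError(f"{path}: need >= 2 frames for kinetics")
    meta = {"n_frames": arr.shape[0], "frame_shape": arr.shape[1:]}
    return arr.astype(float), meta


def write_stack(path, frames: np.ndarray) -> None:
    """Write a stack as a multi-page float32 TIFF."""
    tifffile.imwrite(
        Path(path),
        np.asarray(frames, dtype=np.float32),
        photometric="minisblack",
    )


def process_movie(
    stack: np.ndarray,
    fps: float,
    microns_per_pixel: float,
    kernel_config: KernelConfig | None = None,
    detection_config: DetectionConfig | None = None,
    fit_config: FitConfig | None = None,
) -> SarcTrackResults:
    """Run the full pipeline on a stack; see :class:`sarctrack.SarcTrack`."""
    return SarcTrack(
        stack,
        fps=fps,
        microns_per_pixel=microns_per_pixel,
        kernel_config=kernel_config,
        detection_config=detection_config,
        fit_config=fit_config,
    ).fit()


def write_outputs(
    results: SarcTrackResults,
    outdir,
    overlays: bool = True,
    overlay_every: int = 1,
) -> dict:
    """Write DWDists / DWStats / DWPrdFrq CSVs and QC overlays.

    Deterministic: the same results object always produces byte-wise
    identical CSV files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise ValueError(f"cannot write to {outdir}")
    paths = {}

    dists = results.distances_frame()
    paths["dists"] = outdir / "DWDists.csv"
    dists.to_csv(paths["dists"], index=False)

    stats = results.stats_frame()
    paths["stats"] = outdir / "DWStats.csv"
    stats.to_csv(paths["stats"], index=False)

    sine = results.sinusoid
    prdfrq = pd.DataFrame(
        [
            {
                "period_s": (1.0 / sine.frequency) if sine else np.nan,
                "frequency_hz": sine.frequency if sine else np.nan,
                "bpm": sine.bpm if sine else np.nan,
                "fps": results.model.fps,
                "microns_per_pixel": results.model.microns_per_pixel,
                "n_sarcomeres": results.n_sarcomeres,
            }
        ]
    )
    paths["prdfrq"] = outdir / "DWPrdFrq.csv"
    prdfrq.to_csv(paths["prdfrq"], index=False)

    if overlays:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ov_dir = outdir / "overlays"
        ov_dir.mkdir(exist_ok=True)
        n = results.model.frames.shape[0]
        for t in range(0, n, overlay_every):
            fig, ax = plt.subplots(figsize=(6, 6))
            results.plot_overlay(t, ax=ax)
            fig.savefig(ov_dir / f"frame_{t:04d}.png", dpi=100)
            plt.close(fig)
        paths["overlays"] = ov_dir
    return paths


def _summary_from_dir(d: Path) -> MovieSummary:
    stats = pd.read_csv(d / "DWStats.csv")
    prd = pd.read_csv(d / "DWPrdFrq.csv").iloc[0]
    n = len(stats)
    means, sems = {}, {}
    for c in _STAT_COLUMNS:
        if n:
            vals = stats[c].to_numpy(dtype=float)
            means[c] = float(np.mean(vals))
            sems[c] = (
                float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            )
        else:
            means[c], sems[c] = np.nan, np.nan
    return MovieSummary(
        movie_id=d.name,
        n_sarcomeres=n,
        means=means,
        sems=sems,
        bpm=float(prd["bpm"]),
        fps=float(prd["fps"]),
        microns_per_pixel=float(prd["microns_per_pixel"]),
    )


def collate_batch(movie_dirs: Sequence, out_path=None) -> pd.DataFrame:
    """Collate processed movie directories into one summary table.

    One row per movie: sarcomere count, mean and SEM of each calibrated
    parameter, and the beat rate.  Rows are ordered by movie id so
    collation is stable regardless of how the batch was scheduled.
    Movies whose output files are malformed are skipped with a warning;
    movies with zero sarcomeres appear with blank statistics.
    """
    rows = []
    for d in sorted(Path(p) for p in movie_dirs):
        try:
            s = _summary_from_dir(d)
        except Exception as exc:
            logger.warning("skipping %s: %s", d, exc)
            continue
        if s.n_sarcomeres == 0:
            logger.warning("movie %s has zero sarcomeres", s.movie_id)
        row = {"movie_id": s.movie_id, "n_sarcomeres": s.n_sarcomeres}
        for c in _STAT_COLUMNS:
            row[f"{c}_mean"] = s.means[c]
            row[f"{c}_sem"] = s.sems[c]
        row["bpm"] = s.bpm
        rows.append(row)
    cols = ["movie_id", "n_sarcomeres"]
    for c in _STAT_COLUMNS:
        cols += [f"{c}_mean", f"{c}_sem"]
    cols.append("bpm")
    df = pd.DataFrame(rows, columns=cols)
    if not len(df):
        logger.warning("no movies collated; writing header only")
    if out_path is not None:
        df.to_csv(Path(out_path), sep="\t", index=False)
    return df
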