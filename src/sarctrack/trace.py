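"""Per-sarcomere spacing time series and their registered average.

A sarcomere's identity is its fixed subgrid point: the detected spacing
at that point on frame t becomes d(t).  This assumes continuity of both
the contraction timing and the Z-disc spacing of neighboring sarcomeres
between frames, which holds for the <= 33 ms frame intervals the method
targets.  Because sarcomeres in a field of view do not beat in
synchrony, averaging raw traces washes out the valley; the average used
to seed curve fitting is therefore *registered* -- each trace is
circularly shifted to best align with a running reference before
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detect import FrameDetection

__all__ = ["SarcomereTrace", "AverageTrace", "extract_traces", "average_trace"]


@dataclass(frozen=True)
class SarcomereTrace:
    """Spacing-vs-frame series for one retained grid point."""

    grid_id: int
    distances: np.ndarray  # pixels, one per frame
    magnitudes: np.ndarray  # response values, one per frame
    fps: float


@dataclass(frozen=True)
class AverageTrace:
    """Per-frame mean spacing over (optionally registered) traces."""

    distances: np.ndarray
    n_traces: int
    fps: float


def extract_traces(
    detections_per_frame: Sequence[Sequence[FrameDetection]],
    retained: Sequence[int],
    fps: float,
) -> list[SarcomereTrace]:
    """One trace per retained grid point; empty list if none retained."""
    n_frames = len(detections_per_frame)
    if n_frames == 0:
        raise ValueError("no frames")
    n_points = len(detections_per_frame[0])
    if any(len(f) != n_points for f in detections_per_frame):
        raise ValueError("inconsistent detection counts across frames")
    traces = []
    for gid in retained:
        d = np.array(
            [detections_per_frame[t][gid].distance for t in range(n_frames)]
        )
        m = np.array(
            [detections_per_frame[t][gid].magnitude for t in range(n_frames)]
        )
        traces.append(
            SarcomereTrace(grid_id=int(gid), distances=d, magnitudes=m, fps=fps)
        )
    return traces


def _best_circular_lag(x: np.ndarray, ref: np.ndarray) -> int:
    """Lag k maximizing sum(ref[t] * x[t-k]) over circular shifts."""
    xc = x - x.mean()
    rc = ref - ref.mean()
    # circular cross-correlation via FFT
    cc = np.fft.irfft(np.fft.rfft(rc) * np.conj(np.fft.rfft(xc)), n=len(x))
    return int(np.argmax(cc))


def average_trace(
    traces: Sequence[SarcomereTrace], register: bool = True
) -> AverageTrace:
    """Mean trace, optionally after circular registration.

    Registration shifts each trace by the integer lag maximizing its
    circular cross-correlation with a reference (the first trace seeds
    it, then one refinement pass realigns everything to the provisional
    mean).  Traces are near-periodic over a clip, so circular shifts are
    appropriate and no samples are discarded.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    n = len(traces[0].distances)
    if any(len(t.distances) != n for t in traces):
        raise ValueError("traces have unequal lengths")
    arr = np.stack([t.distances for t in traces])
    if register and len(traces) > 1:
        ref = arr[0]
        aligned = np.stack(
            [np.roll(x, _best_circular_lag(x, ref)) for x in arr]
        )
        # one refinement pass against the provisional mean
        ref = aligned.mean(axis=0)
        aligned = np.stack(
            [np.roll(x, _best_circular_lag(x, ref)) for x in arr]
        )
        mean = aligned.mean(axis=0)
    else:
        mean = arr.mean(axis=0)
    return AverageTrace(
        distances=mean, n_traces=len(traces), fps=traces[0].fps
    )
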