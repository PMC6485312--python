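"""Shared fixtures: synthetic benchmark movies run through the pipeline.

The three full-size movies (5 lines x 9 wavelets, 150 frames at 30 fps)
are expensive, so they are session-scoped and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import sarctrack as st
from sarctrack.synth import benchmark_configs

FPS = 30.0
MPP = 0.1  # microns per pixel, ~100x optics


def _run(spec: st.SyntheticSpec):
    frames, truth = st.generate_movie(spec)
    kc, dc, fc = benchmark_configs()
    res = st.SarcTrack(
        frames,
        fps=FPS,
        microns_per_pixel=MPP,
        kernel_config=kc,
        detection_config=dc,
        fit_config=fc,
    ).fit()
    return spec, truth, res


@pytest.fixture(scope="session")
def bench_equal():
    """Equal contraction and relaxation (10 + 10 frames), no delay."""
    return _run(
        st.SyntheticSpec(t_contract=10, t_relax=10, delayed_fraction=0.0)
    )


@pytest.fixture(scope="session")
def bench_async_1_2():
    """Relaxation twice contraction, half the rows delayed 11 frames."""
    return _run(
        st.SyntheticSpec(
            t_contract=10, t_relax=20, delayed_fraction=0.5, delay=11
        )
    )


@pytest.fixture(scope="session")
def bench_base_8():
    """Baseline durations 8 + 8 frames for the duration-scaling check."""
    return _run(
        st.SyntheticSpec(t_contract=8, t_relax=8, delayed_fraction=0.0)
    )


@pytest.fixture(scope="session")
def bench_doubled_16():
    """Both durations doubled relative to the 8 + 8 baseline."""
    return _run(
        st.SyntheticSpec(t_contract=16, t_relax=16, delayed_fraction=0.0)
    )


@pytest.fixture(scope="session")
def small_spec():
    """A quick 3-line, 4-wavelet, 2-second movie for plumbing tests."""
    return st.SyntheticSpec(
        n_lines=3,
        wavelets_per_line=4,
        n_frames=60,
        period=30.0,
        t_contract=6,
        t_relax=6,
        delayed_fraction=0.0,
    )


@pytest.fixture(scope="session")
def small_movie_results(small_spec):
    return _run(small_spec)
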