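"""Shared fixtures: synthetic runs, traces and peak segments built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from ionflow.feature_detection import MassTrace, PeakSegment
from ionflow.raw_io import MSRun, Scan


def make_scan(index: int, rt: float, mz, intensity, ms_level: int = 1,
              precursor_mz: float | None = None) -> Scan:
    return Scan(
        index=index, ms_level=ms_level, rt=rt,
        mz=np.asarray(mz, float), intensity=np.asarray(intensity, float),
        precursor_mz=precursor_mz,
    )


def make_run(scan_tuples, file_name="test") -> MSRun:
    """Build an MSRun from (rt, mz, intensity) tuples."""
    scans = [make_scan(i, rt, mz, it) for i, (rt, mz, it) in enumerate(scan_tuples)]
    return MSRun(scans=scans, file_name=file_name)


def make_trace(intensities, scan_indices=None, mz=500.0, trace_id=0,
               dt=0.01) -> MassTrace:
    """A single-channel trace with constant m/z and evenly spaced RTs."""
    intensities = np.asarray(intensities, float)
    if scan_indices is None:
        scan_indices = np.arange(intensities.size)
    scan_indices = np.asarray(scan_indices, dtype=np.int64)
    return MassTrace(
        trace_id=trace_id,
        mz_values=np.full(intensities.size, mz),
        intensities=intensities,
        rts=scan_indices * dt,
        scan_indices=scan_indices,
    )


def make_peak(trace_id, mz, shape, rt0=1.0, scan0=0, dt=0.01) -> PeakSegment:
    """A standalone PeakSegment with a given intensity profile."""
    shape = np.asarray(shape, float)
    n = shape.size
    rts = rt0 + np.arange(n) * dt
    apex = int(np.argmax(shape))
    return PeakSegment(
        trace_id=trace_id, left=0, right=n - 1,
        apex_rt=float(rts[apex]), apex_intensity=float(shape[apex]),
        height=float(shape.max()), area=float(np.trapezoid(shape, rts)),
        mz=mz, n_scans=n, is_peak=True,
        rt_left=float(rts[0]), rt_right=float(rts[-1]),
        rts=rts, intensities=shape,
        mz_values=np.full(n, mz), scan_indices=scan0 + np.arange(n),
    )


def gaussian_profile(n=30, height=1e6, sigma=5.0, center=None):
    x = np.arange(n, dtype=float)
    c = (n - 1) / 2 if center is None else center
    return height * np.exp(-((x - c) ** 2) / (2 * sigma**2))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def simple_run():
    """Three MS1 scans, two stable m/z channels."""
    return make_run(
        [
            (0.00, [100.0, 200.0], [1e4, 2e4]),
            (0.01, [100.002, 200.001], [1.2e4, 2.2e4]),
            (0.02, [100.001, 199.999], [1.1e4, 2.1e4]),
        ]
    )
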