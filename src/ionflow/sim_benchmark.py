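"""Synthetic chromatographic-peak simulation and detection benchmarking.

Single and double Gaussian peaks are generated over a factorial grid of
signal-to-noise (noise amplitude as a fraction of the larger peak height),
peak-height ratio, and chromatographic resolution, embedded as isolated m/z
channels in an (optionally blank) carrier run, and pushed through the real
trace-building + segmentation pipeline.  A single peak counts as correctly
detected iff exactly one peak is reported in its channel, a double iff
exactly two — so both splitting and merging errors are penalized.

Conventions (study conditions, fixed):

* S/N = larger peak height / noise standard deviation, so a noise fraction
  ``f`` gives S/N = 1/f and the smaller peak of a ratio-``r`` double has
  S/N = 1/(f*r).  Doubles whose smaller peak falls below S/N = 3 are
  excluded from the grid (below the limit of detection), and the
  single-peak grid mirrors the double grid so totals match.
* Chromatographic resolution Rs = (t2 - t1) / (2*(sigma1 + sigma2))
  (4-sigma base widths), so equal-width peaks sit 4*sigma*Rs apart.
* Each peak envelope spans 40 scans across +/- 4 sigma (sigma = 5 scan
  intervals, one scan every 0.5 s), larger peak height 1e6 counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .feature_detection import build_traces, segment_trace
from .raw_io import MSRun, Scan, write_synthetic_mzml

__all__ = [
    "SimSpec",
    "SimTruth",
    "NOISE_LEVELS",
    "HEIGHT_RATIOS",
    "RESOLUTIONS",
    "spec_is_valid",
    "build_grid",
    "simulate_signal",
    "insert_into_run",
    "score_accuracy",
    "run_detection_benchmark",
    "benchmark_accuracy",
    "optimize_params",
    "AccuracyReport",
    "OptimizationResult",
]

NOISE_LEVELS: tuple[float, ...] = (0.02, 0.04, 0.06, 0.08, 0.10)
HEIGHT_RATIOS: tuple[int, ...] = (1, 2, 3, 4, 5)
RESOLUTIONS: tuple[float, ...] = (1.00, 1.25, 1.50, 1.75, 2.00)

SIGMA_SCANS = 5.0  # chromatographic peak sd, in scan intervals
SCAN_INTERVAL_MIN = 0.5 / 60.0  # one MS1 scan every 0.5 s
BASE_HEIGHT = 1.0e6  # larger peak height, counts
DEFAULT_START_MZ = 1500.05
MIN_SMALL_PEAK_SN = 3.0


@dataclass(frozen=True)
class SimSpec:
    """Parameters for one simulated single- or double-peak replicate."""

    kind: str  # "single" | "double"
    noise_frac: float
    height_ratio: int
    resolution: float
    seed: tuple[int, int, int]  # (base_seed, combo index, replicate index)

    def __post_init__(self):
        if self.kind not in ("single", "double"):
            raise ValueError("kind must be 'single' or 'double'")

    @property
    def true_count(self) -> int:
        return 2 if self.kind == "double" else 1


@dataclass
class SimTruth:
    """Ground truth for one simulated replicate."""

    spec: SimSpec
    true_count: int
    apex_rts: tuple[float, ...]
    channel_mz: float | None = None


def spec_is_valid(noise_frac: float, height_ratio: int) -> bool:
    """Smaller-peak S/N = (1/noise_frac)/ratio must reach the detection limit."""
    if noise_frac == 0:
        return True
    return 1.0 / (noise_frac * height_ratio) >= MIN_SMALL_PEAK_SN - 1e-12


def build_grid(
    noise_levels: Sequence[float] = NOISE_LEVELS,
    ratios: Sequence[int] = HEIGHT_RATIOS,
    resolutions: Sequence[float] = RESOLUTIONS,
    replicates: int = 1000,
    include_zero_noise: bool = False,
    kind: str = "double",
    base_seed: int = 0,
) -> list[SimSpec]:
    """Cartesian parameter grid, filtered by the smaller-peak S/N >= 3 rule.

    Replicate seeds are deterministic functions of (combo index, replicate
    index); the same grid with the same ``base_seed`` is bit-reproducible.
    With the default 5x5x5 grid and 1000 replicates, 110 combinations
    survive (110,000 specs); adding the zero-noise level at 100 replicates
    gives 135 combinations (13,500 specs).
    """
    if not (len(noise_levels) and len(ratios) and len(resolutions)):
        raise ValueError("parameter lists must be non-empty")
    levels = list(noise_levels)
    if include_zero_noise and 0.0 not in levels:
        levels = [0.0] + levels
    specs: list[SimSpec] = []
    combo = 0
    for f, r, rs in product(levels, ratios, resolutions):
        if not spec_is_valid(f, r):
            combo += 1
            continue
        for rep in range(replicates):
            specs.append(
                SimSpec(
                    kind=kind,
                    noise_frac=f,
                    height_ratio=int(r),
                    resolution=float(rs),
                    seed=(base_seed, combo, rep),
                )
            )
        combo += 1
    return specs


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def simulate_signal(spec: SimSpec) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Sample one noisy single/double Gaussian signal on an even scan grid.

    Doubles place the larger peak first, apexes 4*sigma*Rs apart; additive
    Gaussian noise has standard deviation ``noise_frac`` x larger height and
    intensities are clamped at zero.  Fixed seeds make replicates
    bit-identical across reruns.
    """
    sig = SIGMA_SCANS
    c1 = 4.0 * sig
    if spec.kind == "double":
        c2 = c1 + 4.0 * sig * spec.resolution
        n = int(round(c2 + 4.0 * sig)) + 1
    else:
        c2 = None
        n = int(round(c1 + 4.0 * sig)) + 1
    x = np.arange(n, dtype=float)
    y = BASE_HEIGHT * _gauss(x, c1, sig)
    apexes = [c1 * SCAN_INTERVAL_MIN]
    if c2 is not None:
        y = y + (BASE_HEIGHT / spec.height_ratio) * _gauss(x, c2, sig)
        apexes.append(c2 * SCAN_INTERVAL_MIN)
    if spec.noise_frac > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_frac * BASE_HEIGHT, n)
    y = np.clip(y, 0.0, None)
    rts = x * SCAN_INTERVAL_MIN
    truth = SimTruth(spec=spec, true_count=spec.true_count, apex_rts=tuple(apexes))
    return rts, y, truth


def insert_into_run(
    signals: Sequence[tuple[np.ndarray, np.ndarray, SimTruth]],
    carrier: MSRun | None = None,
    start_mz: float = DEFAULT_START_MZ,
    spacing: float = 1.0,
    mz_tol: float = 0.01,
    out_path: str | Path | None = None,
) -> tuple[MSRun, list[SimTruth]]:
    """Embed each signal on its own m/z channel of a carrier run.

    The default carrier is a synthetic blank whose scan grid covers the
    longest signal; a user-supplied run must provide at least as many MS1
    scans as the longest signal.  Channels start at ``start_mz`` (above any
    real mass range) and step by ``spacing``, which must exceed twice the
    detection m/z tolerance so channels cannot interfere.  Zero-intensity
    points are dropped, as in centroided data.  Optionally also written as
    mzML.
    """
    if not signals:
        raise ValueError("no signals to insert")
    if spacing <= 2.0 * mz_tol:
        raise ValueError("channel spacing must exceed 2 x the detection m/z tolerance")
    n_max = max(len(s[0]) for s in signals)
    if carrier is None:
        scan_rts = np.arange(n_max) * SCAN_INTERVAL_MIN
        base_mz = [np.empty(0)] * n_max
        base_int = [np.empty(0)] * n_max
    else:
        ms1 = carrier.ms1_scans()
        if len(ms1) < n_max:
            raise ValueError("carrier run has fewer MS1 scans than the longest signal")
        scan_rts = np.array([s.rt for s in ms1])
        base_mz = [s.mz for s in ms1]
        base_int = [s.intensity for s in ms1]
        lo, hi = carrier.mz_range
        if np.isfinite(hi) and start_mz <= hi:
            raise ValueError("channel m/z values must lie outside the carrier range")

    truths: list[SimTruth] = []
    per_scan_mz: list[list[float]] = [[] for _ in range(len(scan_rts))]
    per_scan_int: list[list[float]] = [[] for _ in range(len(scan_rts))]
    for ch, (_rts, y, truth) in enumerate(signals):
        mz_ch = start_mz + ch * spacing
        truth.channel_mz = mz_ch
        truths.append(truth)
        for i in range(len(y)):
            if y[i] > 0:
                per_scan_mz[i].append(mz_ch)
                per_scan_int[i].append(y[i])

    scans: list[Scan] = []
    for i, rt in enumerate(scan_rts):
        mz = np.concatenate([base_mz[i], np.asarray(per_scan_mz[i])])
        inten = np.concatenate([base_int[i], np.asarray(per_scan_int[i])])
        scans.append(Scan(index=i, ms_level=1, rt=float(rt), mz=mz, intensity=inten))
    run = MSRun(scans=scans, file_name="synthetic_benchmark")
    if out_path is not None:
        write_synthetic_mzml(
            [(s.rt, s.mz, s.intensity) for s in scans], out_path
        )
    return run, truths


@dataclass
class AccuracyReport:
    """Stratified detection accuracy over a simulation set."""

    per_stratum: pd.DataFrame  # kind, noise_frac, n, accuracy
    per_spec: pd.DataFrame = field(repr=False, default=None)

    def _kind_mean(self, kind: str) -> float:
        rows = self.per_stratum[self.per_stratum["kind"] == kind]
        return float(rows["accuracy"].mean()) if len(rows) else float("nan")

    @property
    def double_mean(self) -> float:
        """Mean of the per-noise-level double-peak accuracies."""
        return self._kind_mean("double")

    @property
    def single_mean(self) -> float:
        return self._kind_mean("single")

    @property
    def average(self) -> float:
        """Mean of the single-peak and double-peak accuracies."""
        kinds = [k for k in ("single", "double")
                 if (self.per_stratum["kind"] == k).any()]
        return float(np.mean([self._kind_mean(k) for k in kinds]))


def score_accuracy(
    truths: Sequence[SimTruth],
    peaks: Iterable,
    mz_tol: float = 0.01,
) -> AccuracyReport:
    """Score detected peaks against ground truth, per channel.

    Each detected peak is assigned to the nearest truth channel within
    ``mz_tol``; a replicate is correct iff its channel holds exactly the
    true number of peaks.  Accuracy is reported per (kind, noise level)
    stratum; ``average`` is the mean of the single and double means.
    """
    channel_mz = np.array([t.channel_mz for t in truths], float)
    order = np.argsort(channel_mz)
    sorted_mz = channel_mz[order]
    counts = np.zeros(len(truths), dtype=int)
    for p in peaks:
        j = int(np.searchsorted(sorted_mz, p.mz))
        best, err = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < sorted_mz.size and abs(sorted_mz[k] - p.mz) < err:
                best, err = k, abs(sorted_mz[k] - p.mz)
        if best is not None and err <= mz_tol:
            counts[order[best]] += 1
    rows = []
    for t, c in zip(truths, counts):
        rows.append(
            {
                "kind": t.spec.kind,
                "noise_frac": t.spec.noise_frac,
                "height_ratio": t.spec.height_ratio,
                "resolution": t.spec.resolution,
                "n_detected": int(c),
                "correct": int(c == t.true_count),
            }
        )
    per_spec = pd.DataFrame(rows)
    strata = (
        per_spec.groupby(["kind", "noise_frac"])
        .agg(n=("correct", "size"), accuracy=("correct", "mean"))
        .reset_index()
    )
    return AccuracyReport(per_stratum=strata, per_spec=per_spec)


def _detect_counts_for_traces(
    traces, sigma: float, prominence_ratio: float, min_scans: int,
    sorted_channel_mz: np.ndarray, mz_tol: float,
) -> np.ndarray:
    """Segment traces and count reported peaks per truth channel."""
    counts = np.zeros(sorted_channel_mz.size, dtype=int)
    for t in traces:
        segs = segment_trace(
            t, sigma=sigma, prominence_ratio=prominence_ratio, min_scans=min_scans
        )
        n_pk = sum(1 for s in segs if s.is_peak)
        if not n_pk:
            continue
        mz = t.mz
        j = int(np.searchsorted(sorted_channel_mz, mz))
        best, err = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < sorted_channel_mz.size and abs(sorted_channel_mz[k] - mz) < err:
                best, err = k, abs(sorted_channel_mz[k] - mz)
        if best is not None and err <= mz_tol:
            counts[best] += n_pk
    return counts


def run_detection_benchmark(
    specs: Sequence[SimSpec],
    sigma: float = 1.2,
    prominence_ratio: float = 0.1,
    min_scans: int = 5,
    mz_tol: float = 0.01,
    gap_max: int = 30,
    block: int = 2000,
    spacing: float = 0.1,
) -> AccuracyReport:
    """Simulate, embed, detect (trace building + segmentation) and score.

    Signals are processed in blocks of independent channels; each block is a
    self-contained run pushed through :func:`build_traces` and
    :func:`segment_trace` with the given detection parameters.
    """
    all_truths: list[SimTruth] = []
    all_counts: list[np.ndarray] = []
    for lo in range(0, len(specs), block):
        chunk = specs[lo : lo + block]
        signals = [simulate_signal(s) for s in chunk]
        run, truths = insert_into_run(signals, spacing=spacing, mz_tol=mz_tol)
        traces = build_traces(run, mz_tol=mz_tol, gap_max=gap_max)
        channel_mz = np.array([t.channel_mz for t in truths])
        counts = _detect_counts_for_traces(
            traces, sigma, prominence_ratio, min_scans, channel_mz, mz_tol
        )
        all_truths.extend(truths)
        all_counts.append(counts)
    counts = np.concatenate(all_counts)
    rows = [
        {
            "kind": t.spec.kind,
            "noise_frac": t.spec.noise_frac,
            "height_ratio": t.spec.height_ratio,
            "resolution": t.spec.resolution,
            "n_detected": int(c),
            "correct": int(c == t.true_count),
        }
        for t, c in zip(all_truths, counts)
    ]
    per_spec = pd.DataFrame(rows)
    strata = (
        per_spec.groupby(["kind", "noise_frac"])
        .agg(n=("correct", "size"), accuracy=("correct", "mean"))
        .reset_index()
    )
    return AccuracyReport(per_stratum=strata, per_spec=per_spec)


def benchmark_accuracy(
    replicates: int = 100,
    base_seed: int = 0,
    include_zero_noise: bool = True,
    sigma: float = 1.2,
    prominence_ratio: float = 0.1,
    **detect_kw,
) -> AccuracyReport:
    """Full single + double benchmark at the default study grid."""
    specs = build_grid(
        replicates=replicates, include_zero_noise=include_zero_noise,
        kind="double", base_seed=base_seed,
    ) + build_grid(
        replicates=replicates, include_zero_noise=include_zero_noise,
        kind="single", base_seed=base_seed + 1,
    )
    return run_detection_benchmark(
        specs, sigma=sigma, prominence_ratio=prominence_ratio, **detect_kw
    )


@dataclass
class OptimizationResult:
    """Accuracy heatmaps over a (sigma, prominence-ratio) grid."""

    sigma_grid: np.ndarray
    prominence_grid: np.ndarray
    single: np.ndarray  # [sigma, prominence]
    double: np.ndarray
    average: np.ndarray
    best: tuple[float, float]  # argmax of average accuracy

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sigma_grid):
            for j, p in enumerate(self.prominence_grid):
                rows.append(
                    {
                        "sigma": s,
                        "prominence_ratio": p,
                        "single_accuracy": self.single[i, j],
                        "double_accuracy": self.double[i, j],
                        "average_accuracy": self.average[i, j],
                    }
                )
        return pd.DataFrame(rows)


def optimize_params(
    sigma_grid: Sequence[float],
    prominence_grid: Sequence[float],
    replicates: int = 100,
    base_seed: int = 0,
    include_zero_noise: bool = False,
    min_scans: int = 5,
    mz_tol: float = 0.01,
    gap_max: int = 30,
    block: int = 2000,
    spacing: float = 0.1,
) -> OptimizationResult:
    """Detection-accuracy heatmaps over a sigma x prominence-ratio grid.

    Signals are simulated and clustered into traces once; only the
    segmentation step is repeated per parameter setting, since trace
    building does not depend on sigma or prominence.
    """
    sigma_grid = np.asarray(list(sigma_grid), float)
    prominence_grid = np.asarray(list(prominence_grid), float)
    if sigma_grid.size == 0 or prominence_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    specs = build_grid(
        replicates=replicates, include_zero_noise=include_zero_noise,
        kind="double", base_seed=base_seed,
    ) + build_grid(
        replicates=replicates, include_zero_noise=include_zero_noise,
        kind="single", base_seed=base_seed + 1,
    )
    n_correct = {
        (i, j): {"single": 0, "double": 0}
        for i in range(sigma_grid.size)
        for j in range(prominence_grid.size)
    }
    totals = {"single": 0, "double": 0}
    for lo in range(0, len(specs), block):
        chunk = specs[lo : lo + block]
        signals = [simulate_signal(s) for s in chunk]
        run, truths = insert_into_run(signals, spacing=spacing, mz_tol=mz_tol)
        traces = build_traces(run, mz_tol=mz_tol, gap_max=gap_max)
        channel_mz = np.array([t.channel_mz for t in truths])
        expected = np.array([t.true_count for t in truths])
        kinds = [t.spec.kind for t in truths]
        for k in kinds:
            totals[k] += 1
        for i, s in enumerate(sigma_grid):
            for j, p in enumerate(prominence_grid):
                counts = _detect_counts_for_traces(
                    traces, float(s), float(p), min_scans, channel_mz, mz_tol
                )
                ok = counts == expected
                for t_idx, k in enumerate(kinds):
                    if ok[t_idx]:
                        n_correct[(i, j)][k] += 1
    single = np.zeros((sigma_grid.size, prominence_grid.size))
    double = np.zeros_like(single)
    for (i, j), d in n_correct.items():
        single[i, j] = d["single"] / max(totals["single"], 1)
        double[i, j] = d["double"] / max(totals["double"], 1)
    average = (single + double) / 2.0
    bi, bj = np.unravel_index(np.argmax(average), average.shape)
    return OptimizationResult(
        sigma_grid=sigma_grid,
        prominence_grid=prominence_grid,
        single=single,
        double=double,
        average=average,
        best=(float(sigma_grid[bi]), float(prominence_grid[bj])),
    )


def plot_accuracy_heatmaps(result: OptimizationResult):
    """Render the single / double / average accuracy heatmaps."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), constrained_layout=True)
    for ax, mat, title in zip(
        axes, (result.single, result.double, result.average),
        ("single-peak", "double-peak", "average"),
    ):
        im = ax.imshow(mat, origin="lower", aspect="auto", vmin=0, vmax=1)
        ax.set_xticks(range(result.prominence_grid.size),
                      [f"{p:g}" for p in result.prominence_grid])
        ax.set_yticks(range(result.sigma_grid.size),
                      [f"{s:g}" for s in result.sigma_grid])
        ax.set_xlabel("prominence ratio")
        ax.set_ylabel("sigma (scans)")
        ax.set_title(f"{title} accuracy")
        fig.colorbar(im, ax=ax)
    return fig
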