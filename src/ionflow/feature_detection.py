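"""Mass-trace construction and chromatographic peak segmentation.

MS1 centroids are clustered into mass traces (regions of interest): an m/z
channel followed across consecutive MS1 scans within a tolerance, with a
bounded number of consecutive missed scans.  Every MS1 point is assigned to
exactly one trace, so no signal is lost.  Each finalized trace is then cut
into chromatographic peaks by smoothing the intensity array with a 1-D
Gaussian filter, keeping local maxima whose prominence exceeds a fraction of
the smoothed maximum, and placing shared edges at the local minima between
adjacent retained maxima.  Heights and areas are always reported from the
raw (unsmoothed) intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .raw_io import MSRun

__all__ = [
    "MassTrace",
    "PeakSegment",
    "DetectionResult",
    "build_traces",
    "segment_trace",
    "detect_features",
]


@dataclass
class MassTrace:
    """One m/z channel followed across MS1 scans (a region of interest)."""

    trace_id: int
    mz_values: np.ndarray  # matched centroid m/z, one per matched scan
    intensities: np.ndarray
    rts: np.ndarray  # minutes
    scan_indices: np.ndarray  # indices into the MS1 scan sequence
    finalized: bool = True

    @property
    def mz(self) -> float:
        """Intensity-weighted mean m/z of the trace."""
        w = self.intensities
        if w.sum() > 0:
            return float(np.average(self.mz_values, weights=w))
        return float(self.mz_values.mean())

    def __len__(self) -> int:
        return len(self.scan_indices)


@dataclass
class PeakSegment:
    """One chromatographic peak cut from a trace.

    ``left``/``right`` index the trace's dense (gap-padded) scan grid,
    inclusive.  ``height`` and ``area`` come from the original intensities,
    never the smoothed array.
    """

    trace_id: int
    left: int
    right: int
    apex_rt: float
    apex_intensity: float
    height: float
    area: float
    mz: float
    n_scans: int
    is_peak: bool
    rt_left: float
    rt_right: float
    rts: np.ndarray = field(repr=False)  # matched scans only
    intensities: np.ndarray = field(repr=False)
    mz_values: np.ndarray = field(repr=False)
    scan_indices: np.ndarray = field(repr=False)
    quality: object | None = None
    annotation: object | None = None
    msms: object | None = None

    @property
    def peak_width(self) -> float:
        return self.rt_right - self.rt_left


class _TraceBuilder:
    __slots__ = ("trace_id", "mzs", "intens", "rts", "scans", "gap_run",
                 "_wsum", "_msum", "mz")

    def __init__(self, trace_id: int, mz: float, inten: float, rt: float, scan: int):
        self.trace_id = trace_id
        self.mzs = [mz]
        self.intens = [inten]
        self.rts = [rt]
        self.scans = [scan]
        self.gap_run = 0
        self._wsum = inten
        self._msum = mz * inten
        self.mz = mz

    def add(self, mz: float, inten: float, rt: float, scan: int) -> None:
        self.mzs.append(mz)
        self.intens.append(inten)
        self.rts.append(rt)
        self.scans.append(scan)
        self.gap_run = 0
        self._wsum += inten
        self._msum += mz * inten
        if self._wsum > 0:
            self.mz = self._msum / self._wsum
        else:
            self.mz = sum(self.mzs) / len(self.mzs)

    def finalize(self) -> MassTrace:
        return MassTrace(
            trace_id=self.trace_id,
            mz_values=np.asarray(self.mzs, float),
            intensities=np.asarray(self.intens, float),
            rts=np.asarray(self.rts, float),
            scan_indices=np.asarray(self.scans, dtype=np.int64),
        )


def build_traces(
    run: MSRun, mz_tol: float = 0.01, gap_max: int = 30
) -> list[MassTrace]:
    """Cluster every MS1 centroid into mass traces.

    Traces are initialized from the first MS1 scan and extended scan by scan;
    a centroid within ``mz_tol`` of a running trace m/z extends the nearest
    such trace (each centroid extends at most one trace, nearest wins, exact
    ties go to the lower trace id), any other centroid starts a new trace.
    A trace whose run of consecutive missed scans exceeds ``gap_max`` is
    finalized after that scan and never extended again.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    if gap_max < 0:
        raise ValueError("gap_max must be non-negative")
    ms1 = run.ms1_scans()
    active: list[_TraceBuilder] = []
    done: list[_TraceBuilder] = []
    next_id = 0

    for si, scan in enumerate(ms1):
        a = scan.mz
        inten = scan.intensity
        rt = scan.rt
        n_pts = a.size
        matched_trace = np.full(len(active), False)
        winners: dict[int, int] = {}
        if active and n_pts:
            # active traces sorted by running m/z for the nearest-match search
            b = np.fromiter((t.mz for t in active), dtype=float, count=len(active))
            order = np.argsort(b, kind="stable")
            active = [active[i] for i in order]
            b = b[order]
            ids = np.fromiter((t.trace_id for t in active), dtype=np.int64,
                              count=len(active))
            pos = np.searchsorted(b, a)
            left = np.clip(pos - 1, 0, len(b) - 1)
            right = np.clip(pos, 0, len(b) - 1)
            dl = np.abs(a - b[left])
            dr = np.abs(b[right] - a)
            take_left = (dl < dr) | ((dl == dr) & (ids[left] <= ids[right]))
            cand = np.where(take_left, left, right)
            dist = np.where(take_left, dl, dr)
            ok = np.flatnonzero(dist <= mz_tol)
            if ok.size:
                # resolve competing claims: per trace the nearest point wins,
                # exact distance ties break toward the lower-m/z point
                key = np.lexsort((a[ok], dist[ok], cand[ok]))
                ordp = ok[key]
                csort = cand[ordp]
                first = np.ones(csort.size, dtype=bool)
                first[1:] = csort[1:] != csort[:-1]
                for p in ordp[first]:
                    winners[int(p)] = int(cand[p])
        for p, t in winners.items():
            active[t].add(float(a[p]), float(inten[p]), rt, si)
            matched_trace[t] = True
        # points that matched no trace (or lost their claim) start new traces
        for p in range(n_pts):
            if p not in winners:
                active.append(
                    _TraceBuilder(next_id, float(a[p]), float(inten[p]), rt, si)
                )
                next_id += 1
        # gap bookkeeping, checked upon completion of each MS1 scan
        still_active = []
        for t_idx, t in enumerate(active):
            if t_idx < matched_trace.size and matched_trace[t_idx]:
                still_active.append(t)
                continue
            if t_idx >= matched_trace.size:  # freshly created this scan
                still_active.append(t)
                continue
            t.gap_run += 1
            if t.gap_run > gap_max:
                done.append(t)
            else:
                still_active.append(t)
        active = still_active

    done.extend(active)
    done.sort(key=lambda t: t.trace_id)
    return [t.finalize() for t in done]


def _dense_arrays(trace: MassTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-pad a trace onto its evenly indexed scan grid (gaps -> 0)."""
    s0 = int(trace.scan_indices[0])
    span = int(trace.scan_indices[-1]) - s0 + 1
    dense = np.zeros(span)
    pos = trace.scan_indices - s0
    dense[pos] = trace.intensities
    rts_dense = np.interp(np.arange(span), pos, trace.rts)
    return dense, rts_dense, pos


def segment_trace(
    trace: MassTrace,
    sigma: float = 1.2,
    prominence_ratio: float = 0.1,
    min_scans: int = 5,
) -> list[PeakSegment]:
    """Cut one trace into chromatographic peaks.

    The raw intensity array (gaps as zeros on an even scan grid) is smoothed
    with a Gaussian kernel of ``sigma`` scan units (truncated at 4 sigma,
    reflect padding).  Local maxima of the smoothed array with prominence at
    least ``prominence_ratio * max(smoothed)`` are retained; the leftmost
    local minimum of the smoothed array between two adjacent retained maxima
    becomes the shared edge (the edge scan belongs to the left segment so
    segments stay disjoint).  Traces with no sufficiently prominent maximum
    yield no segments.  Segments with fewer than ``min_scans`` matched scans
    are kept but flagged as sub-threshold (``is_peak=False``).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0 < prominence_ratio < 1:
        raise ValueError("prominence_ratio must lie in (0, 1)")
    dense, rts_dense, matched_pos = _dense_arrays(trace)
    if dense.max() <= 0:
        return []
    smoothed = gaussian_filter1d(dense, sigma, mode="reflect", truncate=4.0)
    maxima, _props = find_peaks(smoothed, prominence=prominence_ratio * smoothed.max())
    if maxima.size == 0:
        return []
    # shared edges at the (leftmost) smoothed local minimum between maxima
    bounds = [0]
    for p1, p2 in zip(maxima[:-1], maxima[1:]):
        edge = int(p1) + int(np.argmin(smoothed[p1 : p2 + 1]))
        bounds.append(edge)
    bounds.append(dense.size - 1)

    segments: list[PeakSegment] = []
    for j in range(len(maxima)):
        lft = bounds[j] if j == 0 else bounds[j] + 1
        rgt = bounds[j + 1]
        if rgt < lft:
            continue
        raw = dense[lft : rgt + 1]
        if raw.max() <= 0:
            continue
        apex = lft + int(np.argmax(raw))
        in_seg = (matched_pos >= lft) & (matched_pos <= rgt)
        n_scans = int(in_seg.sum())
        inten_m = trace.intensities[in_seg]
        w = inten_m if inten_m.sum() > 0 else None
        mz = float(np.average(trace.mz_values[in_seg], weights=w)) if n_scans else trace.mz
        segments.append(
            PeakSegment(
                trace_id=trace.trace_id,
                left=lft,
                right=rgt,
                apex_rt=float(rts_dense[apex]),
                apex_intensity=float(dense[apex]),
                height=float(raw.max()),
                area=float(np.trapezoid(raw, rts_dense[lft : rgt + 1])),
                mz=mz,
                n_scans=n_scans,
                is_peak=n_scans >= min_scans,
                rt_left=float(rts_dense[lft]),
                rt_right=float(rts_dense[rgt]),
                rts=trace.rts[in_seg],
                intensities=inten_m,
                mz_values=trace.mz_values[in_seg],
                scan_indices=trace.scan_indices[in_seg],
            )
        )
    return segments


@dataclass
class DetectionResult:
    """Exhaustive feature list (all segments) plus the filtered peak list."""

    traces: list[MassTrace]
    features: list[PeakSegment]

    @property
    def peaks(self) -> list[PeakSegment]:
        return [s for s in self.features if s.is_peak]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "traces": len(self.traces),
            "features": len(self.features),
            "peaks": len(self.peaks),
        }

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for s in self.features:
            row = {
                "trace_id": s.trace_id,
                "mz": s.mz,
                "rt_apex": s.apex_rt,
                "rt_left": s.rt_left,
                "rt_right": s.rt_right,
                "height": s.height,
                "area": s.area,
                "n_scans": s.n_scans,
                "is_peak": s.is_peak,
            }
            if s.quality is not None:
                row.update(s.quality.as_dict())
            if s.annotation is not None:
                row.update(
                    role=s.annotation.role,
                    partner_id=s.annotation.partner_id,
                    charge=s.annotation.charge,
                    detail=s.annotation.detail,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def detect_features(
    run: MSRun,
    mz_tol: float = 0.01,
    gap_max: int = 30,
    sigma: float = 1.2,
    prominence_ratio: float = 0.1,
    min_scans: int = 5,
) -> DetectionResult:
    """Run trace building plus segmentation over a whole run."""
    traces = build_traces(run, mz_tol=mz_tol, gap_max=gap_max)
    features: list[PeakSegment] = []
    for t in traces:
        features.extend(
            segment_trace(
                t, sigma=sigma, prominence_ratio=prominence_ratio, min_scans=min_scans
            )
        )
    return DetectionResult(traces=traces, features=features)
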