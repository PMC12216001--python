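"""Chromatographic peak-quality metadata.

Three core metrics per peak: the asymmetry factor (ratio of the apex-to-flank
distances at the 10 %-height crossings), the Gaussian similarity (cosine
between the raw signal and a least-squares Gaussian fit), and the noise score
(excess turning-point density).  Auxiliary metrics: top-3 average intensity,
m/z variance and peak width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .feature_detection import PeakSegment

__all__ = [
    "PeakQuality",
    "asymmetry_factor",
    "gaussian_similarity",
    "noise_score",
    "compute_quality",
    "quality_profile",
    "ASYMMETRY_SENTINEL",
]

# sentinel marking a peak whose apex sits on its own left flank
ASYMMETRY_SENTINEL = 99.0


@dataclass
class PeakQuality:
    asymmetry_factor: float
    gaussian_similarity: float
    noise_score: float
    top_average: float
    mz_variance: float
    peak_width: float
    fit_converged: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "asymmetry_factor": self.asymmetry_factor,
            "gaussian_similarity": self.gaussian_similarity,
            "noise_score": self.noise_score,
            "top_average": self.top_average,
            "mz_variance": self.mz_variance,
            "peak_width": self.peak_width,
        }


def asymmetry_factor(intensities: Sequence[float], rts: Sequence[float]) -> float:
    """Apex-centred flank-distance ratio ``(t_right - t_a) / (t_a - t_left)``.

    ``t_left`` (``t_right``) is the first scan, walking outward from the apex,
    whose intensity falls strictly below 10 % of the peak height; if no scan
    qualifies on a side the terminal scan is used.  A plateaued apex takes the
    leftmost maximal scan.  When ``t_left`` equals the apex time the factor is
    the sentinel 99 (the left flank *is* the apex).
    """
    s = np.asarray(intensities, float)
    t = np.asarray(rts, float)
    if s.size != t.size or s.size < 3:
        raise ValueError("need at least 3 matched points with matching rts")
    if s.max() <= 0:
        raise ValueError("asymmetry factor undefined for an all-zero signal")
    apex = int(np.argmax(s))
    thresh = 0.10 * s[apex]
    left = 0
    for i in range(apex - 1, -1, -1):
        if s[i] < thresh:
            left = i
            break
    else:
        left = 0
    right = s.size - 1
    for i in range(apex + 1, s.size):
        if s[i] < thresh:
            right = i
            break
    t_a, t_left, t_right = t[apex], t[left], t[right]
    if t_left == t_a:
        return ASYMMETRY_SENTINEL
    return float((t_right - t_a) / (t_a - t_left))


def _gaussian(t, amplitude, center, width):
    return amplitude * np.exp(-((t - center) ** 2) / (2.0 * width**2))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def gaussian_similarity(
    intensities: Sequence[float],
    rts: Sequence[float],
    return_flag: bool = False,
):
    """Cosine similarity between a signal and its least-squares Gaussian fit.

    A three-parameter Gaussian (amplitude, center, width) is fitted to
    ``(rts, intensities)``; the score is ``cosine(S, S')`` in [-1, 1].  A
    non-convergent fit yields score 0 with ``fit_converged=False`` (returned
    when ``return_flag`` is set) rather than an exception.
    """
    s = np.asarray(intensities, float)
    t = np.asarray(rts, float)
    if s.size < 4:
        raise ValueError("need at least 4 points for a Gaussian fit")
    if s.max() <= 0:
        raise ValueError("Gaussian similarity undefined without a positive maximum")
    span = max(t[-1] - t[0], 1e-9)
    p0 = (float(s.max()), float(t[int(np.argmax(s))]), span / 2.0)
    try:
        popt, _ = curve_fit(
            _gaussian,
            t,
            s,
            p0=p0,
            bounds=([0.0, t[0] - span, 1e-9], [np.inf, t[-1] + span, 10.0 * span]),
            maxfev=2000,
        )
        score = _cosine(s, _gaussian(t, *popt))
        ok = True
    except (RuntimeError, ValueError):
        score, ok = 0.0, False
    score = float(np.clip(score, -1.0, 1.0))
    return (score, ok) if return_flag else score


def noise_score(intensities: Sequence[float]) -> float:
    """Turning-point density ``max(0, (p - 1) / (n - 2))``.

    A point is a turning point when the signs of the adjacent first
    differences oppose.  A perfectly smooth unimodal peak has a single
    turning point at the apex and scores 0; monotone signals (no turning
    point) are clamped to 0.
    """
    s = np.asarray(intensities, float)
    n = s.size
    if n < 3:
        raise ValueError("noise score undefined for fewer than 3 points")
    d = np.diff(s)
    p = int(np.sum(d[:-1] * d[1:] < 0))
    return max(0.0, (p - 1) / (n - 2))


def compute_quality(segment: PeakSegment) -> PeakQuality:
    """Attach the full quality record to one peak segment."""
    s, t = segment.intensities, segment.rts
    try:
        af = asymmetry_factor(s, t)
    except ValueError:
        af = float("nan")
    if s.size >= 4 and s.max() > 0:
        gs, ok = gaussian_similarity(s, t, return_flag=True)
    else:
        gs, ok = float("nan"), False
    try:
        ns = noise_score(s)
    except ValueError:
        ns = float("nan")
    top = float(np.mean(np.sort(s)[-3:])) if s.size else float("nan")
    q = PeakQuality(
        asymmetry_factor=af,
        gaussian_similarity=gs,
        noise_score=ns,
        top_average=top,
        mz_variance=float(np.var(segment.mz_values)) if s.size else float("nan"),
        peak_width=segment.peak_width,
        fit_converged=ok,
    )
    segment.quality = q
    return q


def quality_profile(
    segments: Iterable[PeakSegment],
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Quantile summary of each quality metric over a set of segments."""
    segments = list(segments)
    if not segments:
        raise ValueError("need at least one segment to profile")
    rows = []
    for seg in segments:
        if seg.quality is None:
            compute_quality(seg)
        rows.append(seg.quality.as_dict())
    df = pd.DataFrame(rows)
    return df.quantile(list(quantiles))
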