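"""Retention-time correction, cross-sample alignment, gap filling, normalization.

RT correction is standard-free: unique, low-noise, high-intensity "anchor"
features are picked from the reference (highest-total-intensity QC) sample,
matched by m/z in every other sample, robustly de-outliered, and used to
build a monotone piecewise-linear map from observed to reference retention
time.  Aligned features are then assembled greedily from the tallest peaks,
missing cells are filled by forced extraction from the raw data, and
intensities are normalized by probabilistic quotient normalization (PQN)
and/or QC-anchored LOWESS drift correction in acquisition order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raw_io import MSRun

__all__ = [
    "AnchorSet",
    "RtModel",
    "FeatureTable",
    "select_rt_anchors",
    "fit_rt_model",
    "evaluate_rt_model",
    "align_features",
    "fill_gaps",
    "pqn_normalize",
    "sum_normalize",
    "qc_drift_correct",
]


@dataclass
class AnchorSet:
    """Top-ranked unique anchor features, partitioned train/test."""

    train: pd.DataFrame
    test: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.train) + len(self.test)


def select_rt_anchors(
    features: pd.DataFrame,
    mz_tol: float = 0.01,
    noise_tol: float = 0.3,
    top_k: int = 50,
) -> AnchorSet:
    """Select RT anchors from a reference feature list.

    A feature qualifies when its m/z is separated from *both* sorted
    neighbours by more than ``mz_tol`` (so the channel is unambiguous) and
    its noise score is below ``noise_tol``.  The ``top_k`` tallest survivors
    are kept and split alternately by height rank: even ranks train, odd
    ranks test.
    """
    df = features.sort_values("mz", kind="stable").reset_index(drop=True)
    mz = df["mz"].to_numpy()
    gap_prev = np.empty(len(df))
    gap_next = np.empty(len(df))
    gap_prev[0] = np.inf
    gap_next[-1] = np.inf
    if len(df) > 1:
        d = np.diff(mz)
        gap_prev[1:] = d
        gap_next[:-1] = d
    eligible = (gap_prev > mz_tol) & (gap_next > mz_tol)
    if "noise_score" in df.columns:
        eligible &= df["noise_score"].to_numpy() < noise_tol
    sel = df[eligible].sort_values("height", ascending=False, kind="stable")
    sel = sel.head(top_k).reset_index(drop=True)
    if len(sel) < 4:
        warnings.warn("fewer than 4 valid RT anchors; RT correction disabled")
    train = sel.iloc[0::2].reset_index(drop=True)
    test = sel.iloc[1::2].reset_index(drop=True)
    return AnchorSet(train=train, test=test)


@dataclass
class RtModel:
    """Monotone piecewise-linear map from observed to reference RT (minutes).

    Terminal segments are extended linearly beyond the anchor range; an
    empty model is the identity.
    """

    sample_rt: np.ndarray = field(default_factory=lambda: np.empty(0))
    reference_rt: np.ndarray = field(default_factory=lambda: np.empty(0))
    identity: bool = False

    def __call__(self, rt):
        rt = np.asarray(rt, float)
        scalar = rt.ndim == 0
        rt = np.atleast_1d(rt)
        if self.identity or self.sample_rt.size < 2:
            out = rt.copy()
        else:
            x, y = self.sample_rt, self.reference_rt
            out = np.interp(rt, x, y)
            lo = rt < x[0]
            hi = rt > x[-1]
            if lo.any():
                slope = (y[1] - y[0]) / (x[1] - x[0])
                out[lo] = y[0] + slope * (rt[lo] - x[0])
            if hi.any():
                slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
                out[hi] = y[-1] + slope * (rt[hi] - x[-1])
        return float(out[0]) if scalar else out

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "identity": self.identity,
                    "sample_rt": self.sample_rt.tolist(),
                    "reference_rt": self.reference_rt.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "RtModel":
        d = json.loads(Path(path).read_text())
        return cls(
            sample_rt=np.asarray(d["sample_rt"], float),
            reference_rt=np.asarray(d["reference_rt"], float),
            identity=bool(d["identity"]),
        )


def _match_anchors(
    anchors: pd.DataFrame, sample: pd.DataFrame, mz_tol: float
) -> pd.DataFrame:
    """Pair each anchor with the nearest-m/z sample feature within tolerance."""
    samp = sample.sort_values("mz", kind="stable").reset_index(drop=True)
    smz = samp["mz"].to_numpy()
    srt = samp["rt"].to_numpy()
    pairs = []
    for _, row in anchors.iterrows():
        if smz.size == 0:
            break
        j = int(np.searchsorted(smz, row["mz"]))
        best, err = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < smz.size and abs(smz[k] - row["mz"]) < err:
                best, err = k, abs(smz[k] - row["mz"])
        if best is not None and err <= mz_tol:
            pairs.append((row["rt"], srt[best]))
    return pd.DataFrame(pairs, columns=["ref_rt", "samp_rt"])


def fit_rt_model(
    anchors: AnchorSet | pd.DataFrame,
    sample_features: pd.DataFrame,
    mz_tol: float = 0.01,
) -> RtModel:
    """Fit the observed-to-reference RT map for one sample.

    Anchor m/z values are located in the sample; pairs with residuals beyond
    3x the (scaled) MAD of a first-pass linear fit, or violating
    monotonicity, are dropped.  Fewer than 4 surviving pairs disables
    correction (identity model, with a warning).
    """
    train = anchors.train if isinstance(anchors, AnchorSet) else anchors
    pairs = _match_anchors(train, sample_features, mz_tol)
    if len(pairs) < 4:
        warnings.warn("fewer than 4 matched anchor pairs; using identity RT model")
        return RtModel(identity=True)
    ref = pairs["ref_rt"].to_numpy()
    smp = pairs["samp_rt"].to_numpy()
    coef = np.polyfit(ref, smp, 1)
    resid = smp - np.polyval(coef, ref)
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= 3 * 1.4826 * mad
    else:  # over half the residuals identical; keep only those on the trend
        keep = np.abs(resid - np.median(resid)) <= 1e-9
    if keep.sum() < 4:
        keep = np.ones(resid.size, bool)
    ref, smp = ref[keep], smp[keep]
    order = np.argsort(ref, kind="stable")
    ref, smp = ref[order], smp[order]
    # enforce strict monotonicity: drop pairs that fall below the running max
    mono = np.ones(ref.size, bool)
    run_max = -np.inf
    for i in range(ref.size):
        if smp[i] <= run_max:
            mono[i] = False
        else:
            run_max = smp[i]
    ref, smp = ref[mono], smp[mono]
    if ref.size < 4:
        warnings.warn("monotone RT fit impossible; using identity RT model")
        return RtModel(identity=True)
    return RtModel(sample_rt=smp, reference_rt=ref)


@dataclass
class RtEvaluation:
    shift_before_s: float
    shift_after_s: float


def evaluate_rt_model(
    model: RtModel, test_pairs: pd.DataFrame
) -> RtEvaluation:
    """Median |RT shift| of held-out test anchors before vs after correction.

    ``test_pairs`` needs ``ref_rt``/``samp_rt`` columns (minutes); pairs with
    missing sample RTs are excluded.  Shifts are reported in seconds.
    """
    tp = test_pairs.dropna(subset=["ref_rt", "samp_rt"])
    if tp.empty:
        return RtEvaluation(0.0, 0.0)
    ref = tp["ref_rt"].to_numpy()
    smp = tp["samp_rt"].to_numpy()
    before = np.median(np.abs(smp - ref)) * 60.0
    after = np.median(np.abs(model(smp) - ref)) * 60.0
    return RtEvaluation(float(before), float(after))


@dataclass
class FeatureTable:
    """Aligned features x samples, with fill-status bookkeeping."""

    features: pd.DataFrame  # mz, rt, detection_rate
    intensities: pd.DataFrame  # rows align with features, columns = samples
    status: pd.DataFrame  # {detected, gap_filled, absent}

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def to_csv(self, path, flags_path=None) -> None:
        out = pd.concat([self.features, self.intensities], axis=1)
        out.to_csv(path, index=False)
        if flags_path is not None:
            pd.concat([self.features[["mz", "rt"]], self.status], axis=1).to_csv(
                flags_path, index=False
            )


def align_features(
    sample_tables: Mapping[str, pd.DataFrame],
    mz_tol: float = 0.01,
    rt_tol: float = 0.2,
    value_col: str = "height",
) -> FeatureTable:
    """Cluster per-sample peak lists into aligned feature rows.

    Greedy clustering seeded by descending peak height: the tallest unused
    peak opens a row and collects at most one unused peak per sample within
    ``mz_tol`` and ``rt_tol`` (nearest in m/z, then RT).  Consensus m/z and
    RT are intensity-weighted means over the members.
    """
    names = list(sample_tables)
    frames = []
    for name, df in sample_tables.items():
        f = df.reset_index(drop=True).copy()
        f["_sample"] = name
        frames.append(f)
    pool = pd.concat(frames, ignore_index=True)
    if pool.empty:
        return FeatureTable(
            pd.DataFrame(columns=["mz", "rt", "detection_rate"]),
            pd.DataFrame(columns=names),
            pd.DataFrame(columns=names),
        )
    pool = pool.sort_values(value_col, ascending=False, kind="stable").reset_index(
        drop=True
    )
    mz = pool["mz"].to_numpy()
    rt = pool["rt"].to_numpy()
    val = pool[value_col].to_numpy()
    sample = pool["_sample"].to_numpy()
    by_mz = np.argsort(mz, kind="stable")
    mz_sorted = mz[by_mz]
    used = np.zeros(len(pool), bool)

    rows = []
    inten_rows = []
    status_rows = []
    for seed in range(len(pool)):
        if used[seed]:
            continue
        lo = np.searchsorted(mz_sorted, mz[seed] - mz_tol)
        hi = np.searchsorted(mz_sorted, mz[seed] + mz_tol, side="right")
        cand = by_mz[lo:hi]
        cand = cand[~used[cand] & (np.abs(rt[cand] - rt[seed]) <= rt_tol)]
        members: dict[str, int] = {}
        for c in sorted(
            cand, key=lambda c: (abs(mz[c] - mz[seed]), abs(rt[c] - rt[seed]))
        ):
            members.setdefault(sample[c], int(c))
        idx = np.fromiter(members.values(), dtype=int)
        used[idx] = True
        w = val[idx]
        w = w if w.sum() > 0 else np.ones_like(w)
        rows.append(
            {
                "mz": float(np.average(mz[idx], weights=w)),
                "rt": float(np.average(rt[idx], weights=w)),
                "detection_rate": len(members) / len(names),
            }
        )
        inten_rows.append({s: val[i] for s, i in members.items()})
        status_rows.append({s: "detected" for s in members})

    features = pd.DataFrame(rows)
    intensities = pd.DataFrame(inten_rows, columns=names).fillna(0.0)
    status = pd.DataFrame(status_rows, columns=names).fillna("absent")
    return FeatureTable(features, intensities, status)


def fill_gaps(
    table: FeatureTable,
    runs: Mapping[str, MSRun],
    mz_tol: float = 0.01,
    rt_window: float = 0.05,
) -> FeatureTable:
    """Force-extract missing cells from the raw data.

    For each absent cell the maximum MS1 intensity at the row's m/z
    (+/- ``mz_tol``) within the consensus RT +/- ``rt_window`` is inserted
    and flagged ``gap_filled`` (zero when the window is blank).  Cells whose
    raw file is unavailable stay absent, with a warning.
    """
    for sample in table.samples:
        missing = table.status[sample] == "absent"
        if not missing.any():
            continue
        run = runs.get(sample)
        if run is None:
            warnings.warn(f"raw data for {sample!r} unavailable; gaps left absent")
            continue
        ms1 = run.ms1_scans()
        scan_rts = np.array([s.rt for s in ms1])
        for i in np.flatnonzero(missing.to_numpy()):
            mz0 = table.features.at[i, "mz"]
            rt0 = table.features.at[i, "rt"]
            s_lo = int(np.searchsorted(scan_rts, rt0 - rt_window))
            s_hi = int(np.searchsorted(scan_rts, rt0 + rt_window, side="right"))
            best = 0.0
            for s in ms1[s_lo:s_hi]:
                a = int(np.searchsorted(s.mz, mz0 - mz_tol))
                b = int(np.searchsorted(s.mz, mz0 + mz_tol, side="right"))
                if b > a:
                    best = max(best, float(s.intensity[a:b].max()))
            table.intensities.at[i, sample] = best
            table.status.at[i, sample] = "gap_filled"
    return table


def pqn_normalize(
    intensities: pd.DataFrame,
    qc_samples: Sequence[str] | None = None,
    reference: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Probabilistic quotient normalization.

    The reference spectrum is the feature-wise median over the QC samples
    (or all samples).  Each sample is divided by the median of its quotients
    against the reference over features positive in both; returns the scaled
    table and the per-sample factors.
    """
    if intensities.shape[1] < 2:
        raise ValueError("PQN needs at least 2 samples")
    if reference is None:
        ref_cols = list(qc_samples) if qc_samples else list(intensities.columns)
        reference = intensities[ref_cols].median(axis=1).to_numpy()
    reference = np.asarray(reference, float)
    factors = {}
    for col in intensities.columns:
        x = intensities[col].to_numpy(float)
        shared = (x > 0) & (reference > 0)
        if shared.sum() == 0:
            raise ValueError(f"no shared features between {col!r} and the reference")
        factors[col] = float(np.median(x[shared] / reference[shared]))
    factors = pd.Series(factors)
    return intensities / factors, factors


def sum_normalize(intensities: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Summed-intensity normalization (documented alternative to PQN)."""
    totals = intensities.sum(axis=0)
    factors = totals / totals.median()
    return intensities / factors, factors


def qc_drift_correct(
    intensities: pd.DataFrame,
    acquisition_order: Mapping[str, int] | pd.Series,
    qc_samples: Sequence[str],
    frac: float = 0.3,
    it: int = 2,
) -> tuple[pd.DataFrame, list[int]]:
    """LOWESS drift correction anchored on QC injections.

    Per feature, a LOWESS curve (span ``frac`` of the QC points, ``it``
    robustifying iterations) is fitted to QC intensity versus acquisition
    order; every sample is divided by the curve value at its order and
    rescaled to the QC median.  Features missing in more than half of the
    QCs (or whose curve is non-positive) are left uncorrected and their row
    indices returned.  Intensities never go negative.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    order = pd.Series(acquisition_order)
    qc_samples = [s for s in qc_samples if s in intensities.columns]
    if len(qc_samples) < 5:
        raise ValueError("QC drift correction needs at least 5 QC samples")
    qc_x = order[qc_samples].to_numpy(float)
    all_x = order[intensities.columns].to_numpy(float)
    corrected = intensities.copy().astype(float)
    skipped: list[int] = []
    for i in range(len(intensities)):
        y = intensities.iloc[i][qc_samples].to_numpy(float)
        present = y > 0
        if present.sum() <= len(qc_samples) / 2:
            skipped.append(i)
            continue
        sm = lowess(y[present], qc_x[present], frac=frac, it=it, return_sorted=True)
        curve = np.interp(all_x, sm[:, 0], sm[:, 1])
        med = float(np.median(y[present]))
        if np.any(curve <= 0) or med <= 0:
            skipped.append(i)
            continue
        corrected.iloc[i] = np.clip(
            intensities.iloc[i].to_numpy(float) / curve * med, 0.0, None
        )
    return corrected, skipped
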