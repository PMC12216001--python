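"""Grouping co-eluting peaks: isotopes, in-source fragments, adducts.

Annotation runs sequentially — isotopes first, then in-source fragments
(ISFs), then adducts — and a peak keeps at most one role: a peak annotated
as an isotope is never reconsidered as an ISF or adduct, and an ISF is never
reconsidered as an adduct.  Evidence combines m/z arithmetic, apex retention
times, scan-to-scan Pearson correlation over commonly detected scans (with a
retention-time fallback when fewer than five scans are shared), and, for
ISFs, the parent's MS/MS spectrum.  MS/MS preprocessing for downstream
spectral matching is also housed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .feature_detection import PeakSegment
from .raw_io import MSRun

__all__ = [
    "AdductRule",
    "GroupAnnotation",
    "POSITIVE_ADDUCTS",
    "NEGATIVE_ADDUCTS",
    "ISOTOPE_SPACING",
    "PROTON_MASS",
    "scan_correlation",
    "annotate_isotopes",
    "annotate_isf",
    "annotate_adducts",
    "annotate_all",
    "link_msms",
    "preprocess_msms",
    "read_msp",
]

ISOTOPE_SPACING = 1.003355  # 13C - 12C, Da
PROTON_MASS = 1.00728  # Da, 5 decimals


@dataclass(frozen=True)
class AdductRule:
    """m/z = (multimer * M + mass_shift) / |charge| for a neutral mass M."""

    name: str
    mass_shift: float  # Da applied to the (multimer-scaled) neutral mass
    charge: int
    multimer: int = 1

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge cannot be zero")
        if self.multimer < 1:
            raise ValueError("multimer count must be >= 1")

    def mz_from_neutral(self, neutral_mass: float) -> float:
        return (self.multimer * neutral_mass + self.mass_shift) / abs(self.charge)

    def neutral_from_mz(self, mz: float) -> float:
        return (mz * abs(self.charge) - self.mass_shift) / self.multimer


# mass shifts from standard atomic masses, electron mass included, 5 decimals
POSITIVE_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M+H]+", 1.00728, 1),
    AdductRule("[M+H-H2O]+", -17.00328, 1),
    AdductRule("[M+Na]+", 22.98922, 1),
    AdductRule("[M+K]+", 38.96316, 1),
    AdductRule("[M+NH4]+", 18.03383, 1),
    AdductRule("[2M+H]+", 1.00728, 1, 2),
    AdductRule("[3M+H]+", 1.00728, 1, 3),
    AdductRule("[M+2H]2+", 2.01456, 2),
)
NEGATIVE_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M-H]-", -1.00728, -1),
    AdductRule("[M-H-H2O]-", -19.01784, -1),
    AdductRule("[M+Cl]-", 34.96940, -1),
    AdductRule("[M+CH3COO]-", 59.01385, -1),
    AdductRule("[M+HCOO]-", 44.99820, -1),
    AdductRule("[2M-H]-", -1.00728, -1, 2),
    AdductRule("[3M-H]-", -1.00728, -1, 3),
    AdductRule("[M-2H]2-", -2.01456, -2),
)


@dataclass
class GroupAnnotation:
    role: str  # base | isotope | isf | adduct
    partner_id: int | None = None  # trace_id of the base/parent peak
    charge: int = 1
    detail: str = ""  # rule name or neutral-loss mass


def scan_correlation(
    peak_a: PeakSegment, peak_b: PeakSegment, min_common: int = 5
) -> float | None:
    """Pearson correlation of raw intensities over commonly detected scans.

    Returns ``None`` when fewer than ``min_common`` scans are shared or a
    series has zero variance; callers then fall back to retention-time
    matching.
    """
    common, ia, ib = np.intersect1d(
        peak_a.scan_indices, peak_b.scan_indices, return_indices=True
    )
    if common.size < min_common:
        return None
    xa = peak_a.intensities[ia]
    xb = peak_b.intensities[ib]
    if np.std(xa) == 0 or np.std(xb) == 0:
        return None
    return float(np.corrcoef(xa, xb)[0, 1])


def _coelute(a: PeakSegment, b: PeakSegment, corr_tol: float, rt_tol: float,
             min_common: int = 5) -> tuple[bool, float]:
    """Correlation criterion with RT fallback; returns (passes, score)."""
    r = scan_correlation(a, b, min_common=min_common)
    if r is not None:
        return r > corr_tol, r
    ok = abs(a.apex_rt - b.apex_rt) <= rt_tol
    return ok, 0.0 if not ok else corr_tol  # fallback scores at the threshold


def annotate_isotopes(
    peaks: Sequence[PeakSegment],
    mz_tol: float = 0.01,
    charges: Sequence[int] = (1, 2),
    corr_tol: float = 0.7,
    rt_tol: float = 0.05,
    max_isotopes: int = 8,
) -> list[GroupAnnotation]:
    """Label co-eluting peaks spaced by multiples of 1.003355/z as isotopes.

    Bases are examined in ascending m/z; the charge state is read off the
    isotope spacing (higher charges checked first, so a z=2 pattern is not
    mistaken for z=1 at even spacings).
    """
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].mz)
    mzs = np.array([peaks[i].mz for i in order])
    annotations: list[GroupAnnotation | None] = [None] * len(peaks)

    def find_partner(base_idx: int, target_mz: float) -> int | None:
        lo = np.searchsorted(mzs, target_mz - mz_tol)
        hi = np.searchsorted(mzs, target_mz + mz_tol, side="right")
        best, best_err = None, np.inf
        for k in range(lo, hi):
            j = order[k]
            if annotations[j] is not None or j == base_idx:
                continue
            ok, _score = _coelute(peaks[base_idx], peaks[j], corr_tol, rt_tol)
            if not ok:
                continue
            err = abs(peaks[j].mz - target_mz)
            if err < best_err:
                best, best_err = j, err
        return best

    for k in range(len(order)):
        i = order[k]
        if annotations[i] is not None:
            continue
        base = peaks[i]
        for z in sorted(charges, reverse=True):
            first = find_partner(i, base.mz + ISOTOPE_SPACING / z)
            if first is None:
                continue
            if annotations[i] is None:
                annotations[i] = GroupAnnotation("base", partner_id=base.trace_id,
                                                 charge=z)
            members = [first]
            for m in range(2, max_isotopes + 1):
                nxt = find_partner(i, base.mz + m * ISOTOPE_SPACING / z)
                if nxt is None:
                    break
                members.append(nxt)
            for m, j in enumerate(members, start=1):
                annotations[j] = GroupAnnotation(
                    "isotope", partner_id=base.trace_id, charge=z, detail=f"M+{m}"
                )
            break
    for i, ann in enumerate(annotations):
        peaks[i].annotation = ann
    return [a for a in annotations if a is not None]


def annotate_isf(
    peaks: Sequence[PeakSegment],
    corr_tol: float = 0.7,
    rt_tol: float = 0.05,
    mz_tol: float = 0.01,
) -> list[GroupAnnotation]:
    """Label in-source fragments of heavier co-eluting parents.

    A candidate (lighter, not an isotope) is an ISF of a parent iff its m/z
    appears among the parent's MS/MS fragments within ``mz_tol`` and the
    scan-to-scan correlation exceeds ``corr_tol`` (apex RT within ``rt_tol``
    when too few scans are shared).  Parents without an attached MS/MS
    spectrum cannot annotate fragments (a conservative miss).
    """
    new: list[GroupAnnotation] = []
    order = sorted(range(len(peaks)), key=lambda i: -peaks[i].mz)
    for pi in order:
        parent = peaks[pi]
        if parent.annotation is not None and parent.annotation.role != "base":
            continue
        if parent.msms is None:
            continue
        frag_mz = np.asarray(parent.msms[0], float)
        for ci in order:
            cand = peaks[ci]
            if cand is parent or cand.annotation is not None:
                continue
            if cand.mz >= parent.mz:
                continue
            if frag_mz.size == 0 or np.min(np.abs(frag_mz - cand.mz)) > mz_tol:
                continue
            ok, _score = _coelute(parent, cand, corr_tol, rt_tol)
            if not ok:
                continue
            loss = parent.mz - cand.mz
            ann = GroupAnnotation(
                "isf", partner_id=parent.trace_id, charge=1, detail=f"loss={loss:.5f}"
            )
            cand.annotation = ann
            new.append(ann)
            if parent.annotation is None:
                parent.annotation = GroupAnnotation("base", partner_id=parent.trace_id)
    return new


def annotate_adducts(
    peaks: Sequence[PeakSegment],
    rules: Sequence[AdductRule] = POSITIVE_ADDUCTS,
    corr_tol: float = 0.7,
    rt_tol: float = 0.05,
    mz_tol: float = 0.01,
) -> list[list[PeakSegment]]:
    """Group co-eluting peaks explainable as adduct forms of one neutral mass.

    Every unannotated pair is tested against every ordered rule pair; passing
    pairings are accepted greedily by descending correlation then ascending
    m/z error.  Each resulting group exports one base form — the tallest peak
    (protonated/deprotonated preferred on ties) — plus its alternates.
    """
    free = [i for i, p in enumerate(peaks)
            if p.annotation is None or p.annotation.role == "base"]
    candidates = []  # (corr, mz_err, i, j, rule_i, rule_j)
    for a_pos, i in enumerate(free):
        for j in free[a_pos + 1:]:
            pi, pj = peaks[i], peaks[j]
            ok, score = _coelute(pi, pj, corr_tol, rt_tol)
            if not ok:
                continue
            best = None
            for r1 in rules:
                neutral = r1.neutral_from_mz(pi.mz)
                if neutral <= 0:
                    continue
                for r2 in rules:
                    if r2 is r1:
                        continue
                    err = abs(r2.mz_from_neutral(neutral) - pj.mz)
                    if err <= mz_tol and (best is None or err < best[0]):
                        best = (err, r1, r2)
            if best is not None:
                candidates.append((score, best[0], i, j, best[1], best[2]))
    candidates.sort(key=lambda c: (-c[0], c[1], peaks[c[2]].mz))

    assigned_rule: dict[int, AdductRule] = {}
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for _score, _err, i, j, r1, r2 in candidates:
        if assigned_rule.get(i, r1) is not r1 or assigned_rule.get(j, r2) is not r2:
            continue  # keep the higher-correlation pairing already accepted
        assigned_rule.setdefault(i, r1)
        assigned_rule.setdefault(j, r2)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    groups: dict[int, list[int]] = {}
    for i in assigned_rule:
        groups.setdefault(find(i), []).append(i)
    out: list[list[PeakSegment]] = []
    for members in groups.values():
        def base_key(ix: int):
            preferred = assigned_rule[ix].name in ("[M+H]+", "[M-H]-")
            return (peaks[ix].height, preferred)

        base = max(members, key=base_key)
        peaks[base].annotation = GroupAnnotation(
            "base", partner_id=peaks[base].trace_id,
            charge=assigned_rule[base].charge, detail=assigned_rule[base].name,
        )
        for ix in members:
            if ix == base:
                continue
            peaks[ix].annotation = GroupAnnotation(
                "adduct", partner_id=peaks[base].trace_id,
                charge=assigned_rule[ix].charge, detail=assigned_rule[ix].name,
            )
        out.append([peaks[ix] for ix in sorted(members, key=lambda x: peaks[x].mz)])
    return out


def annotate_all(
    peaks: Sequence[PeakSegment],
    rules: Sequence[AdductRule] = POSITIVE_ADDUCTS,
    mz_tol: float = 0.01,
    corr_tol: float = 0.7,
    rt_tol: float = 0.05,
) -> dict[str, int]:
    """Run the sequential isotope -> ISF -> adduct pass; label leftovers base."""
    annotate_isotopes(peaks, mz_tol=mz_tol, corr_tol=corr_tol, rt_tol=rt_tol)
    annotate_isf(peaks, corr_tol=corr_tol, rt_tol=rt_tol, mz_tol=mz_tol)
    annotate_adducts(peaks, rules=rules, corr_tol=corr_tol, rt_tol=rt_tol,
                     mz_tol=mz_tol)
    counts = {"base": 0, "isotope": 0, "isf": 0, "adduct": 0}
    for p in peaks:
        if p.annotation is None:
            p.annotation = GroupAnnotation("base", partner_id=p.trace_id)
        counts[p.annotation.role] += 1
    return counts


def link_msms(peaks: Sequence[PeakSegment], run: MSRun, mz_tol: float = 0.01) -> int:
    """Attach each MS2 spectrum to the peak owning its precursor.

    A spectrum belongs to the peak whose m/z matches its precursor within
    ``mz_tol`` and whose segment RT window contains the MS2 retention time;
    when several spectra qualify the one nearest the apex is kept.
    """
    linked = 0
    best_dist: dict[int, float] = {}
    for ms2 in run.ms2_scans():
        if ms2.precursor_mz is None:
            continue
        for idx, p in enumerate(peaks):
            if abs(p.mz - ms2.precursor_mz) > mz_tol:
                continue
            if not (p.rt_left <= ms2.rt <= p.rt_right):
                continue
            d = abs(ms2.rt - p.apex_rt)
            if d < best_dist.get(idx, np.inf):
                best_dist[idx] = d
                if p.msms is None:
                    linked += 1
                p.msms = (ms2.mz, ms2.intensity)
    return linked


# intensity floors by analyser class for absolute MS/MS noise filtering
_ABS_INTENSITY_FLOOR = {"orbitrap": 10000.0, "qtof": 500.0}


def preprocess_msms(
    mz: Sequence[float],
    intensity: Sequence[float],
    precursor_mz: float,
    instrument_class: str = "unknown",
    acq_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Clean an MS/MS spectrum for spectral matching.

    Removes (a) fragments at or above the precursor m/z, (b) noise, using a
    relative floor of 1 % of the base peak and an absolute floor of 10,000
    (Orbitrap) or 500 (QTOF) counts, and (c) fragments outside the
    acquisition m/z range.  An emptied spectrum is a valid result.
    """
    mz = np.asarray(mz, float)
    intensity = np.asarray(intensity, float)
    if mz.size == 0:
        raise ValueError("cannot preprocess an empty spectrum")
    keep = mz < precursor_mz
    if keep.any():
        base = intensity[keep].max() if intensity[keep].size else 0.0
        keep &= intensity >= 0.01 * base
    floor = _ABS_INTENSITY_FLOOR.get(instrument_class)
    if floor is not None:
        keep &= intensity >= floor
    if acq_range is not None:
        keep &= (mz >= acq_range[0]) & (mz <= acq_range[1])
    return mz[keep], intensity[keep]


def read_msp(path) -> list[dict]:
    """Read an MSP spectral library into plain records for annotation hand-off."""
    from matchms.importing import load_from_msp

    records = []
    for spec in load_from_msp(str(path)):
        if spec is None:
            continue
        meta = spec.metadata
        records.append(
            {
                "name": meta.get("compound_name") or meta.get("name", ""),
                "precursor_mz": meta.get("precursor_mz"),
                "mz": np.asarray(spec.peaks.mz, float),
                "intensity": np.asarray(spec.peaks.intensities, float),
            }
        )
    return records


def cosine_similarity_hook(spec_a, spec_b, mz_tol: float = 0.015) -> float:
    """Trivial pluggable spectral similarity (greedy m/z matching + cosine).

    Stands behind the annotation hand-off where an external entropy-based
    search engine would normally be plugged in.
    """
    mza, ia = np.asarray(spec_a[0], float), np.asarray(spec_a[1], float)
    mzb, ib = np.asarray(spec_b[0], float), np.asarray(spec_b[1], float)
    if mza.size == 0 or mzb.size == 0:
        return 0.0
    va, vb = [], []
    used = np.zeros(mzb.size, bool)
    for m, x in zip(mza, ia):
        j = int(np.argmin(np.abs(mzb - m)))
        if abs(mzb[j] - m) <= mz_tol and not used[j]:
            va.append(x)
            vb.append(ib[j])
            used[j] = True
        else:
            va.append(x)
            vb.append(0.0)
    for j in range(mzb.size):
        if not used[j]:
            va.append(0.0)
            vb.append(ib[j])
    va, vb = np.asarray(va), np.asarray(vb)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    return float(np.dot(va, vb) / denom) if denom else 0.0
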