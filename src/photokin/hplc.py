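"""HPLC chromatogram integration and retinal-isomer composition.

Retinal is extracted from the pigment as retinal oxime and separated on a
silica column; each isomer elutes as up to two peaks (the syn and anti oxime
stereoisomers), and the molar fraction of each isomer is the ratio of its
summed peak areas to the total assigned area.  Equal molar detector response
across oxime species is assumed, as is standard when areas are ratioed
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .spectra import IsomerFractions

__all__ = [
    "Chromatogram",
    "PeakTable",
    "detect_and_integrate",
    "molar_fractions",
    "replicate_stats",
]


@dataclass
class Chromatogram:
    """Detector signal versus retention time with isomer assignment windows.

    ``windows`` maps an isomer label ("all-trans", "13-cis") to its list of
    retention windows (min); two windows per isomer accommodate the syn and
    anti oxime peaks.  Windows must not overlap.
    """

    times: np.ndarray                 # retention time, min
    signal: np.ndarray                # detector response, arbitrary units
    windows: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("retention-time grid must be strictly increasing")
        if self.signal.shape != self.times.shape:
            raise ValueError("signal and time grid differ in shape")
        spans = sorted(
            (lo, hi) for wins in self.windows.values() for lo, hi in wins
        )
        for (lo, hi), (lo2, _) in zip(spans, spans[1:]):
            if lo2 < hi:
                raise ValueError("assignment windows overlap")


@dataclass
class PeakTable:
    """Detected peaks: apex time, baseline-corrected area, isomer label."""

    peaks: pd.DataFrame               # columns: apex_time, area, isomer, merged
    warnings: list[str] = field(default_factory=list)

    def total_area(self, isomer: str) -> float:
        sel = self.peaks[self.peaks["isomer"] == isomer]
        return float(sel["area"].sum())


def _noise_sd(signal: np.ndarray) -> float:
    """Robust noise estimate from the median absolute first difference."""
    d = np.diff(signal)
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def detect_and_integrate(
    chrom: Chromatogram,
    min_prominence: float | None = None,
    baseline_mode: str = "linear",
) -> PeakTable:
    """Detect peaks and integrate them over their assignment windows.

    Peaks are found by prominence (default threshold: 3x the robust noise
    level) on a lightly smoothed copy of the signal, so white detector
    noise does not register as peaks.  Each assignment window is integrated
    by the trapezoidal rule after subtracting a linear baseline anchored at
    short medians of the signal around the window edges (single-sample
    anchors would propagate noise into small peak areas).  Multiple
    detected peaks inside one window are merged into a single area and
    flagged; peaks outside every window are integrated over their
    prominence base and labelled "unassigned".
    """
    if baseline_mode != "linear":
        raise ValueError("only linear baseline subtraction is supported")
    t, s = chrom.times, chrom.signal
    if s.size < 10:
        raise ValueError("signal too short (< 10 samples)")
    if min_prominence is None:
        min_prominence = 3.0 * _noise_sd(s)
    smooth_len = int(np.clip(s.size // 500, 1, 21))
    s_det = uniform_filter1d(s, smooth_len) if smooth_len > 1 else s
    idx, props = find_peaks(s_det, prominence=max(min_prominence, 1e-300))

    warn: list[str] = []
    rows = []
    claimed = np.zeros(idx.size, dtype=bool)
    for isomer, wins in chrom.windows.items():
        for lo, hi in wins:
            inside = np.where((t[idx] >= lo) & (t[idx] <= hi))[0]
            if inside.size == 0:
                continue
            claimed[inside] = True
            merged = inside.size > 1
            if merged:
                warn.append(
                    f"{inside.size} peaks merged in window [{lo}, {hi}] ({isomer})"
                )
            apex = t[idx[inside][np.argmax(s[idx[inside]])]]
            rows.append(
                {
                    "apex_time": float(apex),
                    "area": _window_area(t, s, lo, hi),
                    "isomer": isomer,
                    "merged": merged,
                }
            )
    for k in np.where(~claimed)[0]:
        lo, hi = t[props["left_bases"][k]], t[props["right_bases"][k]]
        rows.append(
            {
                "apex_time": float(t[idx[k]]),
                "area": _window_area(t, s, lo, hi),
                "isomer": "unassigned",
                "merged": False,
            }
        )
    if not rows:
        warn.append("no peaks found above prominence threshold")
    table = pd.DataFrame(rows, columns=["apex_time", "area", "isomer", "merged"])
    if not table.empty:
        table = table.sort_values("apex_time", ignore_index=True)
    for w in warn:
        warnings.warn(w, stacklevel=2)
    return PeakTable(peaks=table, warnings=warn)


def _edge_level(t: np.ndarray, s: np.ndarray, at: float) -> float:
    """Median signal over a short neighbourhood of ``at`` (robust anchor)."""
    half = max((t[-1] - t[0]) / s.size * 5, 1e-12)
    m = (t >= at - half) & (t <= at + half)
    return float(np.median(s[m])) if m.any() else float(np.interp(at, t, s))


def _window_area(t: np.ndarray, s: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area over [lo, hi] minus the linear baseline anchored at
    the window edges."""
    m = (t >= lo) & (t <= hi)
    tw, sw = t[m], s[m]
    if tw.size < 2:
        return 0.0
    b0, b1 = _edge_level(t, s, lo), _edge_level(t, s, hi)
    base = b0 + (b1 - b0) * (tw - tw[0]) / (tw[-1] - tw[0])
    return float(max(np.trapezoid(sw - base, tw), 0.0))


def molar_fractions(peaks: PeakTable, condition: str = "dark") -> IsomerFractions:
    """Isomer molar fractions from the ratio of summed assigned peak areas."""
    assigned = peaks.peaks[peaks.peaks["isomer"] != "unassigned"]
    if assigned.empty:
        raise ValueError("no assigned peaks")
    total = float(assigned["area"].sum())
    if total <= 0:
        raise ValueError("total assigned area is zero")
    f_at = float(assigned.loc[assigned["isomer"] == "all-trans", "area"].sum()) / total
    return IsomerFractions(f_at=f_at, condition=condition)


def replicate_stats(fractions: list[IsomerFractions]) -> IsomerFractions:
    """Mean and sample s.d. (n-1 denominator) of replicate compositions."""
    if len(fractions) < 2:
        raise ValueError("need >= 2 replicates")
    labels = {f.condition for f in fractions}
    if len(labels) != 1:
        raise ValueError(f"mixed condition labels: {sorted(labels)}")
    vals = np.array([f.f_at for f in fractions])
    return IsomerFractions(
        f_at=float(vals.mean()), sd=float(vals.std(ddof=1)), condition=fractions[0].condition
    )
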