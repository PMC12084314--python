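"""CRISPR mutagenesis efficiency from fragment-analysis electropherograms.

A fluorescent PCR product run on a capillary sequencer yields a trace of
fluorescence (RFU) against fragment size (bp).  Indels shift product size
away from the wildtype peak, so guide-RNA cutting efficiency can be read off
as the fraction of total peak area remaining at the wildtype size: a guide
is called efficient when that fraction drops below 0.5 (strict inequality),
and a larva is included in downstream analysis if at least one of its guides
is efficient.

Input is a generic (size_bp, rfu) table; proprietary binary trace formats
are out of scope (a CSV loader hook is provided in `zfmorph.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d
from scipy.signal import find_peaks

from .simulate import Electropherogram

__all__ = ["Peak", "PeakSet", "detect_peaks", "wildtype_fraction", "classify_efficiency"]


@dataclass
class Peak:
    apex_bp: float
    height: float
    area: float
    window: tuple[int, int]  # inclusive index bounds on the trace axis


@dataclass
class PeakSet:
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.peaks))

    def area_fractions(self) -> np.ndarray:
        tot = self.total_area
        return np.array([p.area / tot for p in self.peaks]) if tot > 0 else np.array([])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"apex_bp": p.apex_bp, "height": p.height, "area": p.area,
                 "window_lo": p.window[0], "window_hi": p.window[1]}
                for p in self.peaks
            ]
        )


def _rolling_min_baseline(rfu: np.ndarray, window: int) -> np.ndarray:
    """Rolling-minimum baseline; window should be much wider than a peak."""
    return minimum_filter1d(rfu, size=window, mode="nearest")


def detect_peaks(
    trace: Electropherogram,
    min_prominence: float = 0.02,
    min_area_fraction: float = 0.01,
    baseline_window_bp: float = 20.0,
) -> PeakSet:
    """Find peaks in a trace and integrate their areas.

    Baseline is a rolling minimum over ``baseline_window_bp`` (clamped at 0
    after subtraction).  Local maxima with prominence above
    ``min_prominence * max(signal)`` are peaks; each peak's window runs to the
    flanking signal minima (or trace ends), and its area is the trapezoidal
    integral of the baseline-subtracted signal over the window.  Peaks whose
    area is below ``min_area_fraction`` of the total are discarded.

    An all-zero (or flat) trace yields an empty PeakSet.
    """
    size, rfu = trace.size_bp, trace.rfu
    step = float(np.median(np.diff(size)))
    win = max(3, int(round(baseline_window_bp / step)))
    signal = np.clip(rfu - _rolling_min_baseline(rfu, win), 0.0, None)
    top = signal.max()
    if top <= 0:
        return PeakSet([])
    idx, _ = find_peaks(signal, prominence=min_prominence * top)
    if len(idx) == 0:
        return PeakSet([])

    # window bounds: minimum of the signal between adjacent apexes
    bounds = [0]
    for a, b in zip(idx[:-1], idx[1:]):
        bounds.append(a + int(np.argmin(signal[a:b + 1])))
    bounds.append(len(signal) - 1)

    peaks = []
    for p, lo, hi in zip(idx, bounds[:-1], bounds[1:]):
        area = float(np.trapezoid(signal[lo : hi + 1], size[lo : hi + 1]))
        peaks.append(Peak(apex_bp=float(size[p]), height=float(signal[p]), area=area, window=(lo, hi)))
    total = sum(p.area for p in peaks)
    if total > 0 and min_area_fraction > 0:
        peaks = [p for p in peaks if p.area >= min_area_fraction * total]
    return PeakSet(peaks)


def wildtype_fraction(peaks: PeakSet, expected_size_bp: float, tol_bp: float = 2.0) -> float:
    """Fraction of total peak area at the wildtype product size.

    A peak counts as wildtype when its apex lies within
    ``expected_size_bp +/- tol_bp``.  Returns 0 when no peak falls in the
    window; raises if there is no peak area at all.
    """
    if tol_bp <= 0:
        raise ValueError("tol_bp must be > 0")
    total = peaks.total_area
    if total <= 0:
        raise ValueError("no peak area in trace")
    wt = sum(p.area for p in peaks if abs(p.apex_bp - expected_size_bp) <= tol_bp)
    return float(wt / total)


def classify_efficiency(
    fractions: pd.DataFrame | dict,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Apply the inclusion rule to per-guide wildtype fractions.

    ``fractions`` is a DataFrame with columns (larva, guide, wt_fraction), or
    a mapping larva -> {guide: fraction}.  A guide is efficient iff its
    wildtype fraction is strictly below ``threshold``; a larva is included iff
    at least one of its guides is efficient.  Missing (NaN) fractions are
    excluded from the rule for that larva.

    Returns one row per (larva, guide) with ``efficient`` and the per-larva
    ``included`` flag.
    """
    if isinstance(fractions, dict):
        rows = [
            {"larva": larva, "guide": guide, "wt_fraction": frac}
            for larva, guides in fractions.items()
            for guide, frac in guides.items()
        ]
        df = pd.DataFrame(rows)
    else:
        df = fractions.copy()
    required = {"larva", "guide", "wt_fraction"}
    if not required.issubset(df.columns):
        raise ValueError(f"fractions table needs columns {sorted(required)}")
    if df.groupby("larva").size().min() < 1:
        raise ValueError("each larva needs at least one guide")
    measured = df["wt_fraction"].notna()
    df["efficient"] = measured & (df["wt_fraction"] < threshold)
    included = df.groupby("larva")["efficient"].any()
    df["included"] = df["larva"].map(included)
    return df
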