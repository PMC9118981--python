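"""Simple headspace-GC trace handling: peak windows and baseline-corrected areas.

The headspace method separates N₂/O₂/Ar (retention ~1.84 min) from CO₂
(~2.62 min) and N₂O (~2.88 min); per-ion integrated areas feed the
isotopomer estimators.  Integration is deliberately minimal: trapezoid area
above a straight baseline drawn between the window edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default retention times (min) for the species resolved by the method.
DEFAULT_RETENTION_MIN = {"n2": 1.84, "co2": 2.62, "n2o": 2.88}


@dataclass(frozen=True)
class Chromatogram:
    time_min: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("time axis must be strictly increasing with >=2 points")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class PeakWindow:
    name: str
    retention_min: float
    half_width_min: float

    def __post_init__(self) -> None:
        if self.half_width_min <= 0:
            raise ValueError("window half-width must be positive")


@dataclass(frozen=True)
class PeakArea:
    name: str
    area: float
    clipped: bool  # negative raw area floored at zero


def integrate_peaks(chrom: Chromatogram, windows: list[PeakWindow]) -> dict[str, PeakArea]:
    """Trapezoidal peak areas above a linear edge-to-edge baseline.

    For each window the trace between ``rt ± half_width`` is integrated and
    the area of the straight line joining the two window-edge intensities is
    subtracted.  Negative net areas (baseline drift) are clipped to zero and
    flagged.
    """
    t, y = chrom.time_min, chrom.intensity
    out: dict[str, PeakArea] = {}
    for w in windows:
        lo, hi = w.retention_min - w.half_width_min, w.retention_min + w.half_width_min
        if hi <= t[0] or lo >= t[-1]:
            raise ValueError(f"window {w.name!r} [{lo}, {hi}] outside the time axis")
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 2:
            raise ValueError(f"window {w.name!r} covers fewer than two samples")
        tw, yw = t[mask], y[mask]
        raw = np.trapezoid(yw, tw)
        baseline = 0.5 * (yw[0] + yw[-1]) * (tw[-1] - tw[0])
        net = raw - baseline
        out[w.name] = PeakArea(name=w.name, area=max(net, 0.0), clipped=net < 0)
    return out
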