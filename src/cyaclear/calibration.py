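"""Linear plate-assay calibration and activity normalization.

Two colorimetric assays share the same linear-calibration machinery: the
melamine-cyanurate turbidity assay for cyanuric acid (OD600 against CYA
standards, refit on every plate because temperature and matrix shift the
precipitation) and the DPD assay for free/total chlorine (A530 against a
hypochlorite standard series, with KI extending the readout to total
chlorine).

Negative estimated concentrations are preserved rather than clipped:
a total-chlorine reading below the deionized-water blank is interpreted as
a more reduced redox state, which is exactly the signal used to confirm
complete neutralization of hypochlorite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

R2_WARNING_THRESHOLD = 0.98


@dataclass(frozen=True)
class StandardSeries:
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    assay: str = "melamine_cyanurate_OD600"  # or "dpd_A530"

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses differ in length")
        if len(set(self.concentrations)) < 2:
            raise ValueError("need at least two distinct standard concentrations")
        if not all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]
    assay: str = ""
    low_quality: bool = False  # R² below the warning threshold


def fit_standard(series: StandardSeries) -> CalibrationCurve:
    """Ordinary least-squares line through a standard series."""
    res = stats.linregress(series.concentrations, series.responses)
    r2 = float(res.rvalue) ** 2
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        conc_range=(min(series.concentrations), max(series.concentrations)),
        assay=series.assay,
        low_quality=r2 < R2_WARNING_THRESHOLD,
    )


@dataclass(frozen=True)
class ConcentrationEstimate:
    value: float
    extrapolated: bool
    negative: bool


def estimate_conc(curve: CalibrationCurve, response: float) -> ConcentrationEstimate:
    """Invert the calibration: concentration = (response - intercept)/slope.

    Values outside the standards' concentration range are flagged
    ``extrapolated``; negatives are flagged but returned as-is.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    value = (response - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    return ConcentrationEstimate(
        value=value,
        extrapolated=not lo <= value <= hi,
        negative=value < 0,
    )


@dataclass(frozen=True)
class ActivityResult:
    initial_ppm: float
    remaining_ppm: float
    consumed_ppm: float
    negative_consumption: bool


def consumed_cya(initial_ppm: float, remaining_ppm: float) -> ActivityResult:
    """CYA consumed by the enzyme: initial minus remaining (flag if < 0)."""
    if initial_ppm < 0:
        raise ValueError("initial concentration must be non-negative")
    consumed = initial_ppm - remaining_ppm
    return ActivityResult(
        initial_ppm=initial_ppm,
        remaining_ppm=remaining_ppm,
        consumed_ppm=consumed,
        negative_consumption=consumed < 0,
    )


@dataclass(frozen=True)
class ChlorinePanel:
    free_ppm: float
    total_ppm: float
    combined_ppm: float  # total - free (chloramines etc.)
    flags: tuple[str, ...] = ()


def dpd_panel(
    a530_free: float, a530_after_ki: float, curve: CalibrationCurve
) -> ChlorinePanel:
    """Free/total/combined chlorine from the two-step DPD readout.

    The first reading (DPD only) gives free chlorine; after KI addition the
    same well reads total chlorine.  Combined chlorine is the difference.
    Sub-blank readings yield negative concentrations, kept and flagged.
    """
    free = estimate_conc(curve, a530_free)
    total = estimate_conc(curve, a530_after_ki)
    flags = []
    if free.negative:
        flags.append("negative_free")
    if total.negative:
        flags.append("negative_total")
    if free.extrapolated or total.extrapolated:
        flags.append("extrapolated")
    return ChlorinePanel(
        free_ppm=free.value,
        total_ppm=total.value,
        combined_ppm=total.value - free.value,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class StabilityPanel:
    """Raw activities per condition label, with a designated reference."""

    activities: tuple[tuple[str, float], ...]
    reference: str

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.activities]
        if self.reference not in labels:
            raise ValueError(f"reference condition {self.reference!r} not in panel")


def normalize_activity(panel: StabilityPanel) -> dict[str, float]:
    """Activities as percentages of the reference condition (reference = 100%)."""
    ref = dict(panel.activities)[panel.reference]
    if ref <= 0:
        raise ValueError("reference activity must be positive")
    return {label: 100.0 * act / ref for label, act in panel.activities}
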