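"""Isotopomer model for N-N bond formation during amide oxidation.

When a 1:1 mixture of ¹⁴N- and ¹⁵N-labeled urea (or biuret) is oxidized by
hypochlorite, the isotopomer pattern of the evolved dinitrogen (m/z 28 =
¹⁴N¹⁴N, 29 = ¹⁴N¹⁵N, 30 = ¹⁵N¹⁵N) reports on where the two atoms of each N₂
came from:

* **intermolecular** route — the nitrogen pool is fully scrambled before
  pairing, so N₂ assembles binomially: 1:2:1 at 28:29:30 for a 50/50 pool.
* **intramolecular** route — both atoms stay within one molecule.  Urea
  (two N) then yields only 28 and 30 (no mixed-mass N₂).  Biuret has three
  N: one intramolecular N₂ per molecule plus the leftover atom pairing from
  the scrambled pool gives 5:2:5 overall.

Only the 29/30 ratio ``x`` is needed to estimate the fraction ``f`` of
molecules reacting intramolecularly:

    urea:   x(f) = 2(1-f)/(1+f)      =>  %intra = 100(2-x)/(2+x)
    biuret: x(f) = (6-4f)/(3+2f)     =>  %intra = 150(2-x)/(2+x)

Both reduce to x = 2 for the pure intermolecular limit.  Measured m/z 29
carries a contribution from air N₂ (natural-abundance ¹⁴N¹⁵N ≈ 0.73% of
air N₂), removed before the ratio is taken; see :func:`correct_background`.

The closed forms assume ideal labeling (50/50 mix, perfect isotopic
purity); purities enter only the background correction and the atom-level
Monte-Carlo generator used as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N2_CHANNELS = (28, 29, 30)
N2O_CHANNELS = (44, 45, 46)

#: Natural abundance of ¹⁵N (used for the air-N₂ background).
NATURAL_15N = 0.00364


@dataclass(frozen=True)
class IsotopeConfig:
    """Labeling-design parameters for the tracer experiment."""

    label_mix_fraction: float = 0.5  # fraction of molecules fully 15N-labeled
    light_purity: float = 0.9963  # fraction 14N in the unlabeled material
    heavy_purity: float = 0.99  # fraction 15N in the labeled material
    background_correction: str = "symmetric_excess"  # or "total_28"

    def __post_init__(self) -> None:
        for name in ("label_mix_fraction", "light_purity", "heavy_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_correction not in ("symmetric_excess", "total_28"):
            raise ValueError(f"unknown background correction {self.background_correction!r}")


@dataclass(frozen=True)
class IonTable:
    """Integrated ion areas for the N₂ (28/29/30) and N₂O (44/45/46) channels."""

    area28: float = 0.0
    area29: float = 0.0
    area30: float = 0.0
    area44: float = 0.0
    area45: float = 0.0
    area46: float = 0.0

    def __post_init__(self) -> None:
        for ch in (28, 29, 30, 44, 45, 46):
            a = getattr(self, f"area{ch}")
            if not np.isfinite(a) or a < 0:
                raise ValueError(f"area{ch} must be finite and non-negative")


@dataclass(frozen=True)
class IsotopomerDistribution:
    compound: str
    mechanism: str  # "intramolecular", "intermolecular", or "mixture"
    probabilities: dict[int, float]  # over the 28/29/30 channels

    def ratio_29_30(self) -> float:
        p30 = self.probabilities[30]
        if p30 == 0:
            raise ZeroDivisionError("m/z 30 probability is zero")
        return self.probabilities[29] / p30


_COMPOUND_NITROGENS = {"urea": 2, "biuret": 3}


def _check_compound(compound: str) -> None:
    if compound not in _COMPOUND_NITROGENS:
        raise ValueError(f"unknown compound {compound!r}; expected 'urea' or 'biuret'")


def expected_distribution(
    compound: str,
    mechanism: str,
    config: IsotopeConfig = IsotopeConfig(),
    *,
    f_intra: float | None = None,
) -> IsotopomerDistribution:
    """Expected N₂ isotopomer probabilities (ideal purities).

    ``mechanism`` is "intramolecular", "intermolecular", or "mixture" (which
    requires ``f_intra``, the fraction of molecules taking the
    intramolecular route).
    """
    _check_compound(compound)
    p = config.label_mix_fraction

    inter = {28: (1 - p) ** 2, 29: 2 * p * (1 - p), 30: p**2}
    if compound == "urea":
        # Intact molecules: all-light -> 28, all-heavy -> 30; one N2 each.
        intra = {28: 1 - p, 29: 0.0, 30: p}
        intra_n2, inter_n2_per_intra_mol = 1.0, 0.0
    else:
        # One intramolecular N2 per molecule; the third N pairs from the pool.
        intra = {28: 1 - p, 29: 0.0, 30: p}
        intra_n2, inter_n2_per_intra_mol = 1.0, 0.5

    def mixture(f: float) -> dict[int, float]:
        # Weights are N2 molecules per substrate molecule for each route.
        n_per_mol = {"urea": 1.0, "biuret": 1.5}[compound]
        w: dict[int, float] = {}
        for ch in N2_CHANNELS:
            w[ch] = f * (intra_n2 * intra[ch] + inter_n2_per_intra_mol * inter[ch]) + (
                1 - f
            ) * n_per_mol * inter[ch]
        total = sum(w.values())
        return {ch: v / total for ch, v in w.items()}

    if mechanism == "intermolecular":
        probs = dict(inter)
    elif mechanism == "intramolecular":
        probs = mixture(1.0)
    elif mechanism == "mixture":
        if f_intra is None or not 0.0 <= f_intra <= 1.0:
            raise ValueError("mixture mechanism requires f_intra in [0, 1]")
        probs = mixture(f_intra)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return IsotopomerDistribution(compound=compound, mechanism=mechanism, probabilities=probs)


def expected_n2o_distribution(config: IsotopeConfig = IsotopeConfig()) -> dict[int, float]:
    """Expected N₂O isotopomer probabilities (44/45/46) for a scrambled pool.

    N₂O assembled from two independent draws out of the mixed nitrogen pool
    is binomial, exactly like intermolecular N₂: 1:2:1 for a 1:1 mix, so the
    predicted 45/46 ratio is 2.
    """
    p = config.label_mix_fraction
    return {44: (1 - p) ** 2, 45: 2 * p * (1 - p), 46: p**2}


def expected_ratio(compound: str, f_intra: float) -> float:
    """m/z 29/30 ratio for a given intramolecular fraction (1:1 label mix)."""
    _check_compound(compound)
    if not 0.0 <= f_intra <= 1.0:
        raise ValueError(f"f_intra must be in [0, 1], got {f_intra}")
    if compound == "urea":
        return 2.0 * (1.0 - f_intra) / (1.0 + f_intra)
    return (6.0 - 4.0 * f_intra) / (3.0 + 2.0 * f_intra)


@dataclass(frozen=True)
class FractionResult:
    compound: str
    x: float
    percent_intramolecular: float  # clamped to [0, 100]
    raw_percent: float
    clamped: bool


def fraction_intramolecular(compound: str, x: float) -> FractionResult:
    """Percent of molecules reacting intramolecularly from the 29/30 ratio.

    Algebraic inverse of :func:`expected_ratio`:

        urea:   100·(2-x)/(2+x)
        biuret: 150·(2-x)/(2+x)

    Measured ratios slightly above 2 (pure-intermolecular value) are
    physically plausible noise; the raw estimate is then negative and the
    reported percentage is clamped to [0, 100] with ``clamped`` set.
    """
    _check_compound(compound)
    if x < 0:
        raise ValueError(f"ion ratio must be non-negative, got {x}")
    scale = 100.0 if compound == "urea" else 150.0
    raw = scale * (2.0 - x) / (2.0 + x)
    clamped = not 0.0 <= raw <= 100.0
    return FractionResult(
        compound=compound,
        x=x,
        percent_intramolecular=min(max(raw, 0.0), 100.0),
        raw_percent=raw,
        clamped=clamped,
    )


@dataclass(frozen=True)
class BackgroundCorrection:
    corrected: IonTable
    air28_estimate: float
    background29: float
    method: str


def correct_background(
    ions: IonTable, config: IsotopeConfig = IsotopeConfig()
) -> BackgroundCorrection:
    """Remove the air-N₂ contribution from the m/z 29 channel.

    Air N₂ is almost entirely ¹⁴N¹⁴N but carries 2·(1-q)/q natural-abundance
    ¹⁴N¹⁵N per unit of m/z 28 (q = fraction ¹⁴N).  Two estimates of the
    air-derived 28 signal are supported:

    * ``symmetric_excess`` (default): air28 = max(area28 - area30, 0).
      Under a 1:1 label mix the reaction contributes equal 28 and 30, so
      any excess 28 over 30 is attributed to air.
    * ``total_28``: the whole 28 channel is treated as air (upper bound on
      the background; appropriate when reaction-derived 28 is negligible).

    The corrected 29 area is floored at zero; with q = 1 the correction is
    the identity.
    """
    q = config.light_purity
    if config.background_correction == "symmetric_excess":
        air28 = max(ions.area28 - ions.area30, 0.0)
    else:
        air28 = ions.area28
    background29 = air28 * 2.0 * (1.0 - q) / q if q > 0 else 0.0
    corrected29 = max(ions.area29 - background29, 0.0)
    corrected = IonTable(
        area28=ions.area28,
        area29=corrected29,
        area30=ions.area30,
        area44=ions.area44,
        area45=ions.area45,
        area46=ions.area46,
    )
    return BackgroundCorrection(
        corrected=corrected,
        air28_estimate=air28,
        background29=background29,
        method=config.background_correction,
    )


def n2o_ratio(ions: IonTable) -> float:
    """Plain m/z 45/46 area ratio (model prediction for a 1:1 pool: 2)."""
    if ions.area46 == 0:
        raise ZeroDivisionError("m/z 46 area is zero; 45/46 ratio undefined")
    return ions.area45 / ions.area46


@dataclass(frozen=True)
class MechanismEstimate:
    compound: str
    x_corrected: float
    percent_intramolecular: float
    raw_percent: float
    clamped: bool
    correction: BackgroundCorrection
    config: IsotopeConfig


def estimate_mechanism(
    ions: IonTable, compound: str, config: IsotopeConfig = IsotopeConfig()
) -> MechanismEstimate:
    """Full pipeline: background-correct, form x = 29/30, invert to %intra."""
    _check_compound(compound)
    corr = correct_background(ions, config)
    if corr.corrected.area30 == 0:
        raise ZeroDivisionError("corrected m/z 30 area is zero; ratio undefined")
    x = corr.corrected.area29 / corr.corrected.area30
    frac = fraction_intramolecular(compound, x)
    return MechanismEstimate(
        compound=compound,
        x_corrected=x,
        percent_intramolecular=frac.percent_intramolecular,
        raw_percent=frac.raw_percent,
        clamped=frac.clamped,
        correction=corr,
        config=config,
    )
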