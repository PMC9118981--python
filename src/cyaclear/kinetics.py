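"""Michaelis-Menten kinetics, progress-curve simulation, remediation planning.

The hydrolase obeys a plain Michaelis-Menten rate law
``v = kcat·E0·S/(Km + S)`` with no product (biuret) inhibition, and the
forward reaction is effectively irreversible because the CO₂ released on
carboxybiuret decarboxylation leaves solution.  Pool-relevant CYA levels
(200-6000 ppm, i.e. 1.5-46 mM) sit far above Km (~100 μM), which is why
depletion looks linear (zero-order) over most of a treatment.

Enzyme loadings are quoted in mg/L; converting to molar active-site
concentration requires a subunit molar mass, which is a configurable
assumption (default 40 kg/mol) — absolute depletion slopes therefore depend
on that choice, while the shape of the curve does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.integrate import solve_ivp

from . import chem

#: Assumed CAH subunit molar mass (g/mol) for mg/L -> molar conversion.
DEFAULT_ENZYME_MOLAR_MASS = 40_000.0

CYA_MOLAR_MASS = chem.SPECIES["cyanuric_acid"].molar_mass
BIURET_MOLAR_MASS = chem.SPECIES["biuret"].molar_mass


class FitError(RuntimeError):
    """Raised when kinetic fitting fails or lands on a constraint boundary."""


@dataclass(frozen=True)
class KineticParams:
    kcat: float  # 1/s
    km_uM: float
    kcat_se: float = float("nan")
    km_se: float = float("nan")
    enzyme_molar_mass: float = DEFAULT_ENZYME_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.km_uM <= 0:
            raise ValueError("kcat and Km must be positive")


#: Published parameter sets for the two application-grade hydrolases.
CAH_PR = KineticParams(kcat=10.1, km_uM=115.0, kcat_se=2.7, km_se=36.0)
CAH_BD = KineticParams(kcat=10.6, km_uM=103.0, kcat_se=1.9, km_se=29.0)


@dataclass(frozen=True)
class RateObservation:
    substrate_uM: float
    rate_uM_per_s: float

    def __post_init__(self) -> None:
        if self.substrate_uM < 0 or self.rate_uM_per_s < 0:
            raise ValueError("substrate and rate must be non-negative")


def enzyme_mgL_to_uM(mg_per_L: float, molar_mass: float = DEFAULT_ENZYME_MOLAR_MASS) -> float:
    """Convert an enzyme loading in mg/L to μM using the subunit molar mass."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return mg_per_L / molar_mass * 1e3


def cya_ppm_to_uM(ppm: float) -> float:
    return ppm / CYA_MOLAR_MASS * 1e3


def cya_uM_to_ppm(uM: float) -> float:
    return uM * CYA_MOLAR_MASS / 1e3


def mm_rate(params: KineticParams, e0_uM: float, substrate_uM: float) -> float:
    """Michaelis-Menten initial rate in μM/s."""
    if substrate_uM < 0 or e0_uM < 0:
        raise ValueError("concentrations must be non-negative")
    return params.kcat * e0_uM * substrate_uM / (params.km_uM + substrate_uM)


def fit_mm(observations: list[RateObservation], e0_uM: float) -> KineticParams:
    """Nonlinear least-squares kcat/Km from initial-rate data.

    Starting values come from the Hanes-Woolf linearization (S/v vs S);
    the optimization constrains both parameters positive, and standard
    errors come from the Jacobian at the optimum.  Designs that cannot
    bracket Km (fewer than four points, or a boundary-pinned solution) are
    rejected.
    """
    if len(observations) < 4:
        raise FitError("need at least four observations spanning around Km")
    if e0_uM <= 0:
        raise ValueError("enzyme concentration must be positive")
    s = np.array([o.substrate_uM for o in observations])
    v = np.array([o.rate_uM_per_s for o in observations])
    if len(np.unique(s)) < 3:
        raise FitError("degenerate design: need at least three distinct substrate levels")

    # Hanes-Woolf: S/v = S/Vmax + Km/Vmax (only points with v > 0 usable).
    ok = v > 0
    if ok.sum() < 2:
        raise FitError("too few non-zero rates for initialization")
    hw = stats.linregress(s[ok], s[ok] / v[ok])
    vmax0 = 1.0 / hw.slope if hw.slope > 0 else v.max()
    km0 = hw.intercept * vmax0 if hw.intercept > 0 else np.median(s)
    kcat0 = max(vmax0 / e0_uM, 1e-12)
    km0 = max(km0, 1e-9)

    def model(s_, kcat, km):
        return kcat * e0_uM * s_ / (km + s_)

    try:
        popt, pcov = optimize.curve_fit(
            model, s, v, p0=[kcat0, km0], bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10_000
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    kcat_hat, km_hat = popt
    if kcat_hat <= 0 or km_hat <= 0:
        raise FitError("fit pinned at the positivity boundary")
    if km_hat > 100 * s.max():
        raise FitError("Km unidentifiable: estimate far above the sampled substrate range")
    ses = np.sqrt(np.diag(pcov))
    return KineticParams(
        kcat=float(kcat_hat), km_uM=float(km_hat), kcat_se=float(ses[0]), km_se=float(ses[1])
    )


@dataclass(frozen=True)
class TimeCourse:
    time_hr: np.ndarray
    cya_ppm: np.ndarray
    biuret_ppm: np.ndarray
    enzyme_active: np.ndarray  # bool per time point


def simulate_progress(
    params: KineticParams,
    e0_uM: float,
    s0_ppm: float,
    t_grid_hr: np.ndarray,
    inactivation_times_hr: tuple[float, ...] = (),
) -> TimeCourse:
    """Integrate CYA depletion, with optional hypochlorite-inactivation events.

    Solves dS/dt = -kcat·E0·S/(Km+S) in μM; CYA consumed maps 1:1 (molar)
    onto biuret produced.  A hypochlorite shock fully and instantly kills
    the enzyme, so the rate is zero from the first event time onward.
    """
    t = np.asarray(t_grid_hr, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be non-negative and strictly increasing")
    if any(ev < 0 for ev in inactivation_times_hr):
        raise ValueError("inactivation times must be non-negative")
    if s0_ppm < 0 or e0_uM < 0:
        raise ValueError("initial concentrations must be non-negative")
    s0_uM = cya_ppm_to_uM(s0_ppm)
    t_off = min(inactivation_times_hr) if inactivation_times_hr else math.inf

    def rhs(_t, y):
        return [-3600.0 * params.kcat * e0_uM * y[0] / (params.km_uM + y[0])]

    # Effective times: frozen at t_off once the shock kills the enzyme.
    t_eff = np.minimum(t, t_off)
    if e0_uM == 0 or t_eff[-1] == 0:
        s_uM = np.full_like(t, s0_uM)
    else:
        sol = solve_ivp(
            rhs,
            (0.0, float(t_eff[-1])),
            [s0_uM],
            dense_output=True,
            method="LSODA",
            rtol=1e-10,
            atol=1e-10,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"integration failed: {sol.message}")
        s_uM = np.clip(sol.sol(t_eff)[0], 0.0, None)
    active_until = t <= t_off

    consumed_uM = s0_uM - s_uM
    return TimeCourse(
        time_hr=t,
        cya_ppm=cya_uM_to_ppm(s_uM),
        biuret_ppm=consumed_uM * BIURET_MOLAR_MASS / 1e3,
        enzyme_active=active_until,
    )


def time_to_target_hr(
    params: KineticParams, e0_uM: float, s0_ppm: float, target_ppm: float
) -> float:
    """Hours to reach a target CYA level, from the implicit integrated rate law.

    Km·ln(S0/S) + (S0 - S) = kcat·E0·t, in μM and seconds.
    """
    if target_ppm < 0 or s0_ppm < 0:
        raise ValueError("concentrations must be non-negative")
    if target_ppm >= s0_ppm:
        return 0.0
    if e0_uM <= 0:
        raise ValueError("target unreachable with zero enzyme")
    if target_ppm == 0:
        raise ValueError("S = 0 is reached only asymptotically; pick a positive target")
    s0, st = cya_ppm_to_uM(s0_ppm), cya_ppm_to_uM(target_ppm)
    t_s = (params.km_uM * math.log(s0 / st) + (s0 - st)) / (params.kcat * e0_uM)
    return t_s / 3600.0


@dataclass(frozen=True)
class RemediationPlan:
    """Three-stage plan: reduce residual chlorine, hydrolyze CYA, shock."""

    reductant_dose: chem.DoseRecommendation | None
    enzyme_uM: float
    hydrolysis_time_hr: float
    biuret_produced_ppm: float
    shock_clo_equivalents: float
    shock_clo_ppm: float
    shock_clo_grams: float


def plan_remediation(
    volume_L: float,
    cya_ppm: float,
    free_chlorine_ppm: float,
    params: KineticParams,
    enzyme_mg_per_L: float,
    target_cya_ppm: float,
    *,
    reductant: str = "sodium_thiosulfate",
    reductant_equivalents: float | None = None,
) -> RemediationPlan:
    """Compose the reduce -> hydrolyze -> oxidize treatment sequence.

    Stage 1 neutralizes residual free chlorine with a reductant (preset
    effective ratios unless overridden); stage 2 predicts the hydrolysis
    time to the CYA target from the integrated rate law; stage 3 sizes the
    hypochlorite shock to oxidize the biuret produced (4.5 ClO⁻ per biuret
    for N(-3) -> N₂), which simultaneously inactivates the enzyme.
    """
    if volume_L <= 0:
        raise ValueError("pool volume must be positive")
    if min(cya_ppm, free_chlorine_ppm, target_cya_ppm) < 0:
        raise ValueError("concentrations must be non-negative")

    if free_chlorine_ppm > 0:
        eq = (
            reductant_equivalents
            if reductant_equivalents is not None
            else chem.REDUCTANT_EQUIVALENT_PRESETS[reductant]
        )
        dose = chem.reductant_dose(free_chlorine_ppm, reductant, eq)
    else:
        dose = None

    e0_uM = enzyme_mgL_to_uM(enzyme_mg_per_L, params.enzyme_molar_mass)
    if cya_ppm <= target_cya_ppm:
        t_hr, consumed_ppm = 0.0, 0.0
    else:
        if e0_uM <= 0:
            raise ValueError("CYA above target but no enzyme dosed: target unreachable")
        t_hr = time_to_target_hr(params, e0_uM, cya_ppm, target_cya_ppm)
        consumed_ppm = cya_ppm - target_cya_ppm

    biuret_mM = chem.ppm_to_mM(consumed_ppm, "cyanuric_acid")  # 1:1 molar
    biuret_ppm = chem.mM_to_ppm(biuret_mM, "biuret")
    eq_per_biuret = chem.electron_equivalents("biuret", 0).hypochlorite_equivalents
    shock_mM = eq_per_biuret * biuret_mM
    shock_ppm = chem.mM_to_ppm(shock_mM, "hypochlorite")
    return RemediationPlan(
        reductant_dose=dose,
        enzyme_uM=e0_uM,
        hydrolysis_time_hr=t_hr,
        biuret_produced_ppm=biuret_ppm,
        shock_clo_equivalents=eq_per_biuret,
        shock_clo_ppm=shock_ppm,
        shock_clo_grams=shock_ppm * volume_L / 1e3,
    )
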