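"""Pool-chlorine chemistry: units, speciation, dosing and nitrogen balance.

Covers the arithmetic a pool remediation workflow needs around the enzyme
step: ppm (mg/L) to molar conversions, HOCl/OCl⁻ speciation as a function
of pH and temperature, electron-balance bookkeeping for hypochlorite
oxidation of amide nitrogen, reductant dosing to neutralize free chlorine,
and an empirical piecewise-linear model of how much nitrogen stays in
solution as biuret is oxidized.

Oxidation-state bookkeeping: amide/amine nitrogen starts at -3; each ClO⁻
accepts two electrons (ClO⁻ + 2H⁺ + 2e⁻ → Cl⁻ + H₂O), so taking one
nitrogen from -3 to 0 (N₂) costs 1.5 hypochlorite equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass

ELECTRONS_PER_HYPOCHLORITE = 2


@dataclass(frozen=True)
class Species:
    name: str
    formula: str
    molar_mass: float  # g/mol
    n_nitrogen: int = 0
    nitrogen_oxidation_state: int = -3  # initial OS of amide/amine N

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if self.n_nitrogen < 0:
            raise ValueError(f"{self.name}: negative nitrogen count")


#: Editable registry of the species the calculators know about.
SPECIES: dict[str, Species] = {
    s.name: s
    for s in [
        Species("cyanuric_acid", "C3H3N3O3", 129.07, n_nitrogen=3),
        # Uniformly 13C3/15N3-labeled cyanuric acid (tracer standard).
        Species("cyanuric_acid_13C3_15N3", "[13C]3H3[15N]3O3", 135.04, n_nitrogen=3),
        Species("biuret", "C2H5N3O2", 103.08, n_nitrogen=3),
        Species("urea", "CH4N2O", 60.06, n_nitrogen=2),
        Species("hypochlorite", "ClO-", 51.45),
        Species("sodium_hypochlorite", "NaClO", 74.44),
        Species("sodium_sulfite", "Na2SO3", 126.04),
        Species("sodium_thiosulfate", "Na2S2O3", 158.11),
    ]
}

#: Effective molar-equivalent presets observed for full neutralization of
#: free chlorine in simulated pool water (~1:1 thiosulfate, ~2:1 sulfite).
#: These are documented empirical operating ratios, not clean stoichiometry.
REDUCTANT_EQUIVALENT_PRESETS: dict[str, float] = {
    "sodium_thiosulfate": 1.0,
    "sodium_sulfite": 2.0,
}


def get_species(name_or_species: str | Species) -> Species:
    if isinstance(name_or_species, Species):
        return name_or_species
    try:
        return SPECIES[name_or_species]
    except KeyError:
        raise KeyError(f"unknown species {name_or_species!r}; register it in chem.SPECIES") from None


def ppm_to_mM(ppm: float, species: str | Species) -> float:
    """Convert mg/L (ppm in dilute water) to mmol/L."""
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    return ppm / get_species(species).molar_mass


def mM_to_ppm(mM: float, species: str | Species) -> float:
    """Convert mmol/L to mg/L (ppm in dilute water)."""
    return mM * get_species(species).molar_mass


def hocl_pKa(temperature_c: float) -> float:
    """pKa of hypochlorous acid at a given temperature (°C).

    Empirical form pKa = 3000/T - 10.0686 + 0.0253·T with T in kelvin;
    gives ~7.54 at 25 °C.
    """
    t_k = temperature_c + 273.15
    return 3000.0 / t_k - 10.0686 + 0.0253 * t_k


@dataclass(frozen=True)
class SpeciationProfile:
    pH: float
    temperature_c: float
    pKa: float
    fractions: dict[str, float]  # {"HOCl": ..., "OCl-": ...}, summing to 1


def speciation(pH: float, temperature_c: float = 25.0) -> SpeciationProfile:
    """HOCl/OCl⁻ fractions of free chlorine at a given pH and temperature.

    Two-species acid/base model: fraction(HOCl) = 1/(1 + 10^(pH - pKa(T))).
    Molecular Cl₂ (relevant only below pH ~4 at pool chloride levels) is
    deliberately not modeled.
    """
    if not 0 < pH < 14:
        raise ValueError(f"pH {pH} out of range (0, 14)")
    if not 0 <= temperature_c <= 45:
        raise ValueError(f"temperature {temperature_c} °C out of range [0, 45]")
    pka = hocl_pKa(temperature_c)
    f_hocl = 1.0 / (1.0 + 10.0 ** (pH - pka))
    return SpeciationProfile(
        pH=pH,
        temperature_c=temperature_c,
        pKa=pka,
        fractions={"HOCl": f_hocl, "OCl-": 1.0 - f_hocl},
    )


@dataclass(frozen=True)
class ElectronBalance:
    species: Species
    delta_os_per_nitrogen: int
    electrons_total: int | float
    hypochlorite_equivalents: float


def electron_equivalents(species: str | Species, target_oxidation_state: int) -> ElectronBalance:
    """Hypochlorite equivalents to oxidize all nitrogen of one molecule.

    Nitrogen starts at the species' initial oxidation state (-3 for amides);
    target 0 corresponds to N₂, +5 to nitrate.  Each ClO⁻ transfers two
    electrons, so equivalents = n_N · |ΔOS| / 2.
    """
    sp = get_species(species)
    if sp.n_nitrogen == 0:
        raise ValueError(f"{sp.name} contains no nitrogen")
    if target_oxidation_state not in (0, 5):
        raise ValueError("target oxidation state must be 0 (N2) or +5 (nitrate)")
    delta = target_oxidation_state - sp.nitrogen_oxidation_state
    electrons = sp.n_nitrogen * abs(delta)
    return ElectronBalance(
        species=sp,
        delta_os_per_nitrogen=delta,
        electrons_total=electrons,
        hypochlorite_equivalents=electrons / ELECTRONS_PER_HYPOCHLORITE,
    )


@dataclass(frozen=True)
class DoseRecommendation:
    oxidant_ppm: float
    oxidant_basis: Species
    reductant: Species
    molar_equivalents: float
    reductant_ppm: float


def reductant_dose(
    oxidant_ppm: float,
    reductant: str | Species,
    molar_equivalents: float,
    *,
    oxidant_basis: str | Species = "hypochlorite",
) -> DoseRecommendation:
    """Reductant dose (ppm) to neutralize an oxidant at a given molar ratio.

    ``oxidant_basis`` states which species the ppm figure is expressed as
    (ClO⁻ by default; "ppm chlorine" figures are standard-dependent, so the
    basis is explicit and echoed in the result).
    """
    if oxidant_ppm <= 0:
        raise ValueError("oxidant ppm must be positive")
    if molar_equivalents < 0:
        raise ValueError("molar equivalents must be non-negative")
    ox = get_species(oxidant_basis)
    red = get_species(reductant)
    dose = molar_equivalents * (oxidant_ppm / ox.molar_mass) * red.molar_mass
    return DoseRecommendation(
        oxidant_ppm=oxidant_ppm,
        oxidant_basis=ox,
        reductant=red,
        molar_equivalents=molar_equivalents,
        reductant_ppm=dose,
    )


@dataclass(frozen=True)
class NitrogenBalanceModel:
    """Empirical soluble-nitrogen model for biuret oxidation by bleach.

    Roughly 10% of the initial nitrogen (as nitrate) stays in solution once
    six or more molar equivalents of hypochlorite have been added; the
    decline from 100% is treated as linear in equivalents.
    """

    completion_equivalents: float = 6.0
    terminal_soluble_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.terminal_soluble_fraction <= 1:
            raise ValueError("terminal soluble fraction must be in [0, 1]")
        if self.completion_equivalents <= 0:
            raise ValueError("completion equivalents must be positive")


def nitrogen_remaining(
    equivalents_added: float, model: NitrogenBalanceModel = NitrogenBalanceModel()
) -> float:
    """Fraction of initial nitrogen still in solution after oxidant addition."""
    if equivalents_added < 0:
        raise ValueError("equivalents must be non-negative")
    frac_done = min(equivalents_added / model.completion_equivalents, 1.0)
    return 1.0 - (1.0 - model.terminal_soluble_fraction) * frac_done
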