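"""Pool-chlorine arithmetic: speciation, reductant dosing, nitrogen balance.

All quantities here are closed-form chemistry; no data files are needed.
"""

from cyaclear import (
    electron_equivalents,
    nitrogen_remaining,
    ppm_to_mM,
    reductant_dose,
    speciation,
)

# Chlorine lock: the CYA level where disinfection stalls, in molar units.
print(f"100 ppm CYA = {ppm_to_mM(100, 'cyanuric_acid'):.2f} mM  (over-stabilization level)")

# Free-chlorine speciation at pool pH.
prof = speciation(pH=7.33, temperature_c=25.0)
print(
    f"pH 7.33, 25 C: HOCl {prof.fractions['HOCl']:.1%}, OCl- {prof.fractions['OCl-']:.1%} "
    f"(pKa {prof.pKa:.2f})"
)

# Reductant needed before the enzyme goes in (2x the ideal chlorine level).
for red, eq in (("sodium_thiosulfate", 1.0), ("sodium_sulfite", 2.0)):
    rec = reductant_dose(5.72, red, eq)
    print(f"{rec.reductant_ppm:5.1f} ppm {red} neutralizes 5.72 ppm ClO- at {eq} eq")

# Electron bookkeeping for the final oxidation shock.
for species in ("biuret", "urea"):
    bal = electron_equivalents(species, 0)
    print(f"{species}: N(-3)->N2 takes {bal.hypochlorite_equivalents} ClO- equivalents")

# Soluble nitrogen left after the shock (the rest leaves as N2/N2O gas).
for eq in (0, 3, 6, 10):
    print(f"{eq:>2} eq bleach -> {nitrogen_remaining(eq):.0%} of nitrogen still in solution")
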