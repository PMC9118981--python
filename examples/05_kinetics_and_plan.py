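"""Enzyme kinetics and the three-stage pool remediation plan.

Fits kcat/Km from synthetic initial-rate data, simulates CYA depletion
(linear at pool-relevant concentrations, S >> Km), and composes the full
reduce -> hydrolyze -> shock treatment for a small pool.
"""

import numpy as np

from cyaclear import CAH_PR, fit_mm, plan_remediation, simulate_progress, synth
from cyaclear.kinetics import enzyme_mgL_to_uM

# --- fit kcat/Km from initial rates -------------------------------------
e0 = 0.01  # uM enzyme in the rate assay
obs = synth.gen_rate_data(CAH_PR, e0, (10, 25, 50, 100, 200, 400, 700, 1000),
                          cv=0.01, seed=3)
fit = fit_mm(obs, e0)
print(f"fitted kcat = {fit.kcat:.2f} /s (true {CAH_PR.kcat}), "
      f"Km = {fit.km_uM:.0f} uM (true {CAH_PR.km_uM:.0f})")

# --- progress curve at a high CYA load ----------------------------------
t = np.linspace(0, 5, 6)
tc = simulate_progress(CAH_PR, enzyme_mgL_to_uM(7.5), 6000.0, t)
consumed = 6000.0 - tc.cya_ppm
print("hours:", " ".join(f"{x:5.0f}" for x in t))
print("CYA consumed (ppm):", " ".join(f"{c:6.0f}" for c in consumed))
print("(constant hourly consumption: zero-order regime, CYA >> Km)")

# --- full remediation plan ----------------------------------------------
plan = plan_remediation(
    volume_L=50_000,  # a typical residential pool
    cya_ppm=200.0,
    free_chlorine_ppm=5.72,
    params=CAH_PR,
    enzyme_mg_per_L=0.45,
    target_cya_ppm=50.0,
)
print(f"\nstage 1: dose {plan.reductant_dose.reductant_ppm:.1f} ppm "
      f"{plan.reductant_dose.reductant.name} to neutralize chlorine")
print(f"stage 2: {plan.hydrolysis_time_hr:.0f} h of hydrolysis to reach 50 ppm CYA "
      f"(produces {plan.biuret_produced_ppm:.0f} ppm biuret)")
print(f"stage 3: shock with {plan.shock_clo_ppm:.0f} ppm ClO- "
      f"({plan.shock_clo_grams / 1000:.1f} kg; {plan.shock_clo_equivalents} eq per biuret) "
      f"to oxidize biuret and kill the enzyme")
# Stage-2 time scales with the assumed enzyme subunit mass (40 kg/mol default).
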