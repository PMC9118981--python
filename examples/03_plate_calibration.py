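"""Melamine-cyanurate plate assay: standard curve, inversion, consumption.

Simulates one plate (standards plus two reaction wells with known remaining
CYA), refits the standard curve as every real plate requires, and reports
how much CYA the enzyme consumed.
"""

from cyaclear import StandardSeries, consumed_cya, estimate_conc, fit_standard, synth

INITIAL_CYA = 200.0  # ppm at reaction start

truth = synth.gen_plate(
    slope=0.002,  # OD600 per ppm CYA
    intercept=0.10,  # blank OD
    standard_concs=(0, 25, 50, 100, 150, 200),
    sample_concs={"enzyme_A": 55.0, "enzyme_B": 140.0},  # true remaining ppm
    noise_sd=0.004,
    seed=7,
)

std = truth.plate[truth.plate.role == "standard"]
curve = fit_standard(StandardSeries(tuple(std.concentration), tuple(std.response)))
print(
    f"standard curve: OD = {curve.intercept:.3f} + {curve.slope:.4f} x ppm, "
    f"R2 = {curve.r_squared:.4f}"
)

for _, row in truth.plate[truth.plate.role == "sample"].iterrows():
    est = estimate_conc(curve, row.response)
    result = consumed_cya(INITIAL_CYA, est.value)
    true_remaining = truth.sample_concentrations[row.well]
    print(
        f"{row.well}: remaining {result.remaining_ppm:6.1f} ppm "
        f"(truth {true_remaining:5.1f}), consumed {result.consumed_ppm:6.1f} ppm"
    )
# Consumed CYA is the enzyme-activity readout; read noise propagates as
# noise_sd / slope, i.e. a few ppm here.
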