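"""Rate law, parameter fitting, progress simulation and remediation plans."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from cyaclear import chem, kinetics, synth
from cyaclear.kinetics import (
    CAH_PR,
    FitError,
    KineticParams,
    RateObservation,
    cya_ppm_to_uM,
    enzyme_mgL_to_uM,
    fit_mm,
    mm_rate,
    plan_remediation,
    simulate_progress,
    time_to_target_hr,
)

GRID_UM = (10, 25, 50, 100, 200, 400, 700, 1000)


def implicit_solution_uM(params, e0_uM, s0_uM, t_hr):
    """Independent oracle: solve Km·ln(S0/S) + (S0-S) = kcat·E0·t for S."""
    if t_hr == 0:
        return s0_uM
    rhs = params.kcat * e0_uM * t_hr * 3600.0

    def g(s):
        return params.km_uM * math.log(s0_uM / s) + (s0_uM - s) - rhs

    return brentq(g, 1e-300, s0_uM, rtol=1e-14)


class TestRateLaw:
    def test_zero_substrate_zero_rate(self):
        assert mm_rate(CAH_PR, 0.01, 0.0) == 0.0

    def test_half_saturation(self):
        assert mm_rate(CAH_PR, 0.01, CAH_PR.km_uM) == pytest.approx(CAH_PR.kcat * 0.01 / 2)

    def test_near_vmax_at_100_km(self):
        vmax = CAH_PR.kcat * 0.01
        assert mm_rate(CAH_PR, 0.01, 100 * CAH_PR.km_uM) == pytest.approx(vmax, rel=0.01)


class TestFit:
    def test_noiseless_recovery_exact(self):
        obs = synth.gen_rate_data(CAH_PR, 0.01, GRID_UM, cv=0.0)
        fit = fit_mm(obs, 0.01)
        assert fit.kcat == pytest.approx(CAH_PR.kcat, rel=1e-8)
        assert fit.km_uM == pytest.approx(CAH_PR.km_uM, rel=1e-8)

    def test_recovery_study_median_error_under_5pct(self):
        errs = []
        for seed in range(50):
            obs = synth.gen_rate_data(CAH_PR, 0.01, GRID_UM, cv=0.01, seed=seed)
            fit = fit_mm(obs, 0.01)
            errs.append(
                (
                    abs(fit.kcat - CAH_PR.kcat) / CAH_PR.kcat,
                    abs(fit.km_uM - CAH_PR.km_uM) / CAH_PR.km_uM,
                )
            )
        med = np.median(np.array(errs), axis=0)
        assert med[0] < 0.05 and med[1] < 0.05

    def test_degenerate_two_point_design_rejected(self):
        obs = [RateObservation(10, 0.005), RateObservation(1000, 0.09)]
        with pytest.raises(FitError):
            fit_mm(obs, 0.01)

    def test_order_invariance(self):
        obs = synth.gen_rate_data(CAH_PR, 0.01, GRID_UM, cv=0.02, seed=4)
        a = fit_mm(obs, 0.01)
        b = fit_mm(list(reversed(obs)), 0.01)
        assert a.kcat == pytest.approx(b.kcat, rel=1e-9)
        assert a.km_uM == pytest.approx(b.km_uM, rel=1e-9)

    def test_unit_rescaling_invariance(self):
        # Rescaling rates and E0 together (e.g. nM instead of uM) leaves
        # kcat untouched; Km follows the substrate units, which are fixed.
        obs = synth.gen_rate_data(CAH_PR, 0.01, GRID_UM, cv=0.01, seed=8)
        scaled = [
            RateObservation(o.substrate_uM, o.rate_uM_per_s * 1e3) for o in obs
        ]
        a = fit_mm(obs, 0.01)
        b = fit_mm(scaled, 0.01 * 1e3)
        assert a.kcat == pytest.approx(b.kcat, rel=1e-5)
        assert a.km_uM == pytest.approx(b.km_uM, rel=1e-5)


class TestSimulate:
    def test_no_enzyme_no_depletion(self):
        tc = simulate_progress(CAH_PR, 0.0, 200.0, np.linspace(0, 8, 9))
        assert np.all(tc.cya_ppm == 200.0)

    def test_matches_implicit_integrated_rate_law(self):
        e0 = enzyme_mgL_to_uM(7.5)
        t = np.linspace(0, 6, 25)
        tc = simulate_progress(CAH_PR, e0, 1500.0, t)
        s0 = cya_ppm_to_uM(1500.0)
        for ti, s_ppm in zip(t, tc.cya_ppm):
            expected = implicit_solution_uM(CAH_PR, e0, s0, ti)
            assert cya_ppm_to_uM(s_ppm) == pytest.approx(expected, rel=1e-6, abs=1e-6)

    def test_zero_order_regime_linear_depletion(self):
        # At 6000 ppm (~46 mM) CYA, S >> Km for the whole window, so the
        # depletion slope should sit within 5% of Vmax throughout.
        e0 = enzyme_mgL_to_uM(7.5)
        t = np.linspace(0, 5, 11)
        tc = simulate_progress(CAH_PR, e0, 6000.0, t)
        s_uM = cya_ppm_to_uM(tc.cya_ppm)
        assert s_uM[-1] >= 20 * CAH_PR.km_uM  # still zero-order at the end
        slopes = -np.diff(s_uM) / np.diff(t) / 3600.0  # uM/s
        vmax = CAH_PR.kcat * e0
        assert np.all(np.abs(slopes - vmax) / vmax < 0.05)

    def test_inactivation_freezes_concentration(self):
        e0 = enzyme_mgL_to_uM(7.5)
        t = np.linspace(0, 1.5, 31)
        tc = simulate_progress(CAH_PR, e0, 1500.0, t, inactivation_times_hr=(1.0,))
        after = tc.cya_ppm[t > 1.0]
        assert np.allclose(after, after[0])
        live = simulate_progress(CAH_PR, e0, 1500.0, t)
        assert live.cya_ppm[-1] < tc.cya_ppm[-1]

    def test_molar_mass_balance_cya_to_biuret(self):
        e0 = enzyme_mgL_to_uM(7.5)
        tc = simulate_progress(CAH_PR, e0, 1000.0, np.linspace(0, 8, 9))
        consumed_mM = chem.ppm_to_mM(1000.0, "cyanuric_acid") - np.array(
            [chem.ppm_to_mM(s, "cyanuric_acid") for s in tc.cya_ppm]
        )
        biuret_mM = np.array([chem.ppm_to_mM(b, "biuret") for b in tc.biuret_ppm])
        assert np.allclose(consumed_mM, biuret_mM, rtol=1e-9, atol=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_progress(CAH_PR, 0.1, 200.0, np.array([-1.0, 1.0]))


class TestPlan:
    def test_no_chlorine_no_reductant_stage(self):
        plan = plan_remediation(1000, 200, 0.0, CAH_PR, 0.45, 50)
        assert plan.reductant_dose is None

    def test_already_at_target_zero_time(self):
        plan = plan_remediation(1000, 40, 2.0, CAH_PR, 0.45, 50)
        assert plan.hydrolysis_time_hr == 0.0
        assert plan.biuret_produced_ppm == 0.0

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            plan_remediation(1000, 200, 0.0, CAH_PR, 0.0, 50)

    def test_plan_composes_independent_stage_calls(self):
        plan = plan_remediation(1000, 200, 5.72, CAH_PR, 0.45, 50)
        # Stage 1: preset thiosulfate dose.
        dose = chem.reductant_dose(5.72, "sodium_thiosulfate", 1.0)
        assert plan.reductant_dose.reductant_ppm == pytest.approx(dose.reductant_ppm)
        # Stage 2: implicit-rate-law inversion.
        e0 = enzyme_mgL_to_uM(0.45)
        assert plan.hydrolysis_time_hr == pytest.approx(
            time_to_target_hr(CAH_PR, e0, 200, 50)
        )
        # Stage 3: 4.5 ClO- per biuret produced (150 ppm CYA consumed, 1:1).
        biuret_mM = chem.ppm_to_mM(150, "cyanuric_acid")
        shock_ppm = chem.mM_to_ppm(4.5 * biuret_mM, "hypochlorite")
        assert plan.shock_clo_equivalents == 4.5
        assert plan.shock_clo_ppm == pytest.approx(shock_ppm)
        assert plan.shock_clo_grams == pytest.approx(shock_ppm * 1000 / 1e3)

    def test_time_to_target_inverts_simulation(self):
        e0 = enzyme_mgL_to_uM(0.45)
        t_hr = time_to_target_hr(CAH_PR, e0, 200, 50)
        tc = simulate_progress(CAH_PR, e0, 200.0, np.array([0.0, t_hr]))
        assert tc.cya_ppm[-1] == pytest.approx(50.0, rel=1e-6)
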