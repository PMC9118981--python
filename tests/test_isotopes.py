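"""Isotopomer model, mechanism estimators, background correction, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyaclear import gcms, synth
from cyaclear.isotopes import (
    IonTable,
    IsotopeConfig,
    correct_background,
    estimate_mechanism,
    expected_distribution,
    expected_n2o_distribution,
    expected_ratio,
    fraction_intramolecular,
    n2o_ratio,
)

IDEAL = IsotopeConfig(light_purity=1.0, heavy_purity=1.0)


class TestExpectedDistribution:
    def test_intermolecular_is_1_2_1(self):
        for compound in ("urea", "biuret"):
            d = expected_distribution(compound, "intermolecular").probabilities
            assert d == pytest.approx({28: 0.25, 29: 0.5, 30: 0.25})

    def test_urea_intramolecular_no_mixed_mass(self):
        d = expected_distribution("urea", "intramolecular").probabilities
        assert d == pytest.approx({28: 0.5, 29: 0.0, 30: 0.5})

    def test_biuret_intramolecular_is_5_2_5(self):
        d = expected_distribution("biuret", "intramolecular").probabilities
        assert d == pytest.approx({28: 5 / 12, 29: 2 / 12, 30: 5 / 12})

    def test_fully_labeled_pool_is_all_mass_30(self):
        cfg = IsotopeConfig(label_mix_fraction=1.0)
        for compound in ("urea", "biuret"):
            for mech in ("intermolecular", "intramolecular"):
                d = expected_distribution(compound, mech, cfg).probabilities
                assert d[30] == pytest.approx(1.0)

    @given(
        st.sampled_from(["urea", "biuret"]),
        st.sampled_from(["intermolecular", "intramolecular"]),
        st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, derandomize=True)
    def test_probabilities_sum_to_one_and_label_swap_symmetry(self, compound, mech, p):
        d = expected_distribution(compound, mech, IsotopeConfig(label_mix_fraction=p))
        assert sum(d.probabilities.values()) == pytest.approx(1.0, abs=1e-12)
        if p == 0.5:
            assert d.probabilities[28] == pytest.approx(d.probabilities[30])

    def test_unknown_compound_rejected(self):
        with pytest.raises(ValueError):
            expected_distribution("melamine", "intermolecular")


class TestRatioAndInverse:
    def test_pure_intermolecular_ratio_is_two(self):
        assert expected_ratio("urea", 0.0) == pytest.approx(2.0)
        assert expected_ratio("biuret", 0.0) == pytest.approx(2.0)

    def test_pure_intramolecular_limits(self):
        assert expected_ratio("urea", 1.0) == pytest.approx(0.0)
        assert expected_ratio("biuret", 1.0) == pytest.approx(0.4)

    def test_ratio_consistent_with_mixture_distribution(self):
        # The closed-form x(f) must agree with the 29/30 ratio of the full
        # mixture distribution - two independent derivations.
        for compound in ("urea", "biuret"):
            for f in (0.1, 0.3, 0.7, 0.9):
                d = expected_distribution(compound, "mixture", f_intra=f)
                assert expected_ratio(compound, f) == pytest.approx(d.ratio_29_30())

    def test_inverse_examples(self):
        assert fraction_intramolecular("urea", 2.0).percent_intramolecular == pytest.approx(0.0)
        assert fraction_intramolecular("biuret", 0.4).percent_intramolecular == pytest.approx(100.0)

    def test_round_trip_identity_on_grid(self):
        # Central consistency: fraction -> ratio -> fraction is the identity.
        for compound in ("urea", "biuret"):
            for f in np.linspace(0.0, 1.0, 101):
                x = expected_ratio(compound, f)
                back = fraction_intramolecular(compound, x).percent_intramolecular
                assert back == pytest.approx(100.0 * f, abs=1e-9)

    def test_strictly_decreasing_in_x(self):
        for compound in ("urea", "biuret"):
            xs = np.linspace(0.0, 2.0, 50)
            pcts = [fraction_intramolecular(compound, x).raw_percent for x in xs]
            assert all(a > b for a, b in zip(pcts, pcts[1:]))

    def test_ratio_above_two_clamped_with_flag(self):
        res = fraction_intramolecular("biuret", 2.05)
        assert res.percent_intramolecular == 0.0
        assert res.clamped and res.raw_percent < 0

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            fraction_intramolecular("urea", -0.1)


class TestTable2:
    """Published ion ratios against the estimators (±0.3 points)."""

    @pytest.mark.parametrize(
        "compound,x,printed",
        [
            ("urea", 1.78, 5.8),
            ("urea", 1.76, 6.3),
            ("urea", 0.93, 36.6),
            ("biuret", 1.97, 1.1),
            ("biuret", 1.44, 24.6),
        ],
    )
    def test_printed_ratios_reproduce_printed_percentages(self, compound, x, printed):
        res = fraction_intramolecular(compound, x)
        assert res.percent_intramolecular == pytest.approx(printed, abs=0.3)


class TestBackgroundCorrection:
    def test_no_air_excess_is_identity_on_29(self):
        ions = IonTable(area28=500, area29=900, area30=500)
        corr = correct_background(ions)
        assert corr.corrected.area29 == ions.area29
        assert corr.air28_estimate == 0.0

    def test_total_28_mode_matches_hand_calculation(self):
        cfg = IsotopeConfig(background_correction="total_28")
        ions = IonTable(area28=1000, area29=7.43, area30=0)
        corr = correct_background(ions, cfg)
        # 2(1-q)/q * 1000 = 7.4287...
        assert corr.background29 == pytest.approx(7.43, abs=0.01)
        assert corr.corrected.area29 == pytest.approx(0.0, abs=0.01)

    def test_perfect_purity_is_identity(self):
        cfg = IsotopeConfig(light_purity=1.0)
        ions = IonTable(area28=5000, area29=100, area30=10)
        assert correct_background(ions, cfg).corrected.area29 == ions.area29

    def test_never_negative(self):
        ions = IonTable(area28=1e6, area29=1.0, area30=0.0)
        cfg = IsotopeConfig(background_correction="total_28")
        assert correct_background(ions, cfg).corrected.area29 == 0.0

    def test_recovers_airfree_ratio_from_contaminated_table(self):
        truth = synth.gen_ion_table("urea", 0.3, 500_000, air_fraction=0.4, seed=21)
        corr = correct_background(truth.ions)
        x = corr.corrected.area29 / corr.corrected.area30
        assert x == pytest.approx(truth.airfree_x, rel=0.01)


class TestN2O:
    def test_scrambled_pool_predicts_ratio_two(self):
        d = expected_n2o_distribution()
        assert d == pytest.approx({44: 0.25, 45: 0.5, 46: 0.25})
        assert d[45] / d[46] == pytest.approx(2.0)

    def test_plain_ratio(self):
        assert n2o_ratio(IonTable(area44=1, area45=2, area46=1)) == pytest.approx(2.0)
        assert n2o_ratio(IonTable(area45=5, area46=5)) == pytest.approx(1.0)

    def test_zero_46_rejected(self):
        with pytest.raises(ZeroDivisionError):
            n2o_ratio(IonTable(area45=5, area46=0))

    def test_sampled_distribution_converges_to_two(self, rng):
        probs = expected_n2o_distribution()
        n = 100_000
        counts = rng.multinomial(n, [probs[44], probs[45], probs[46]])
        ratio = counts[1] / counts[2]
        # 3 sigma of the ratio under multinomial sampling
        assert ratio == pytest.approx(2.0, abs=3 * 2.0 * np.sqrt(1 / counts[1] + 1 / counts[2]))


class TestEstimateMechanism:
    def test_pure_intermolecular_table_gives_zero_percent(self):
        ions = IonTable(area28=2500, area29=5000, area30=2500)
        est = estimate_mechanism(ions, "biuret", IDEAL)
        assert est.percent_intramolecular == pytest.approx(0.0, abs=1e-9)

    def test_zero_corrected_30_rejected(self):
        with pytest.raises(ZeroDivisionError):
            estimate_mechanism(IonTable(area28=10, area29=10, area30=0), "urea")

    def test_metadata_records_method(self):
        ions = IonTable(area28=2500, area29=5000, area30=2500)
        est = estimate_mechanism(ions, "urea")
        assert est.correction.method == "symmetric_excess"
        assert est.config.light_purity == pytest.approx(0.9963)


class TestPeakIntegration:
    def test_flat_trace_zero_areas(self):
        chrom = gcms.Chromatogram(np.linspace(1, 3, 500), np.zeros(500))
        areas = gcms.integrate_peaks(chrom, [gcms.PeakWindow("n2", 1.84, 0.1)])
        assert areas["n2"].area == 0.0

    def test_rectangular_peak_area_equals_width(self):
        t = np.linspace(0, 1, 2001)
        y = np.where(np.abs(t - 0.5) <= 0.05, 1.0, 0.0)
        areas = gcms.integrate_peaks(
            gcms.Chromatogram(t, y), [gcms.PeakWindow("p", 0.5, 0.2)]
        )
        assert areas["p"].area == pytest.approx(0.1, rel=0.02)

    def test_gaussian_peak_closed_form(self):
        amp, sigma, rt = 40.0, 0.02, 2.62
        t = np.linspace(2.0, 3.2, 6001)
        y = amp * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
        areas = gcms.integrate_peaks(
            gcms.Chromatogram(t, y), [gcms.PeakWindow("co2", rt, 5 * sigma)]
        )
        assert areas["co2"].area == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_planted_generator_areas_recovered(self):
        chrom = synth.gen_chromatogram(
            [(1.84, 0.02, 50.0), (2.62, 0.02, 20.0), (2.88, 0.02, 2.0)], noise_sd=0.0
        )
        windows = [
            gcms.PeakWindow("n2", 1.84, 0.1),
            gcms.PeakWindow("co2", 2.62, 0.1),
            gcms.PeakWindow("n2o", 2.88, 0.1),
        ]
        areas = gcms.integrate_peaks(chrom, windows)
        assert areas["n2"].area == pytest.approx(50.0, rel=0.02)
        assert areas["co2"].area == pytest.approx(20.0, rel=0.02)
        assert areas["n2o"].area == pytest.approx(2.0, rel=0.02)

    def test_window_outside_axis_rejected(self):
        chrom = gcms.Chromatogram(np.linspace(1, 3, 100), np.zeros(100))
        with pytest.raises(ValueError):
            gcms.integrate_peaks(chrom, [gcms.PeakWindow("x", 5.0, 0.1)])
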