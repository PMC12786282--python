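"""Resonance physics and analyte-response model."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmokan.plasmonics import (
    BindingState,
    ChipGeometry,
    ConvergenceError,
    DiffractionOrder,
    MaterialModel,
    NoiseModel,
    OpticalMode,
    Spectrum,
    absorbance_attenuation,
    add_noise,
    apply_binding,
    beer_lambert_fraction,
    binding_response_curves,
    default_modes,
    default_wavelength_grid,
    effective_index,
    fit_langmuir_constant,
    langmuir_coverage,
    refractometric_shift,
    spp_wavelength,
    synthesize_spectrum,
    wood_anomaly_wavelength,
)
from plasmokan.features import ModeWindows, detect_mode_troughs

GEOM = ChipGeometry(period_nm=500.0)
WATER = MaterialModel(eps_metal=-20.0, n_medium=1.33)


class TestResonanceConditions:
    @pytest.mark.parametrize(
        "order, material, expected",
        [
            ((1, 0), WATER, 665.0),  # first-order anomaly in water
            ((1, 0), MaterialModel(eps_metal=-20.0, n_medium=1.0), 500.0),  # vacuum: the period
            ((1, 1), WATER, 665.0 / math.sqrt(2)),
        ],
    )
    def test_wood_anomaly(self, order, material, expected):
        wl = wood_anomaly_wavelength(GEOM, DiffractionOrder(*order), material)
        assert wl == pytest.approx(expected, abs=1e-9)

    def test_zero_order_rejected(self):
        with pytest.raises(ValueError):
            DiffractionOrder(0, 0)

    def test_non_positive_dielectric_rejected(self):
        with pytest.raises(ValueError):
            MaterialModel(eps_metal=-20.0, n_medium=1.33, eps_dielectric=-1.0)

    def test_spp_constant_metal_closed_form(self):
        # 500 * sqrt(1.7689 * 20 / (20 - 1.7689))
        wl = spp_wavelength(GEOM, DiffractionOrder(1, 0), WATER)
        assert wl == pytest.approx(500.0 * math.sqrt(35.378 / 18.2311), abs=1e-9)
        assert wl == pytest.approx(696.5, abs=0.1)
        wl11 = spp_wavelength(GEOM, DiffractionOrder(1, 1), WATER)
        assert wl11 == pytest.approx(wl / math.sqrt(2), abs=1e-9)

    def test_spp_approaches_wood_anomaly_for_ideal_metal(self):
        ideal = MaterialModel(eps_metal=-1e12, n_medium=1.33)
        wl = spp_wavelength(GEOM, DiffractionOrder(1, 0), ideal)
        assert wl == pytest.approx(665.0, abs=1e-3)

    def test_spp_exceeds_wood_anomaly(self):
        order = DiffractionOrder(1, 0)
        assert spp_wavelength(GEOM, order, WATER) > wood_anomaly_wavelength(GEOM, order, WATER)

    def test_bound_mode_condition_enforced(self):
        shallow = MaterialModel(eps_metal=-1.5, n_medium=1.33)  # |eps_m| < eps_d
        with pytest.raises(ValueError, match="bound-mode"):
            spp_wavelength(GEOM, DiffractionOrder(1, 0), shallow)

    def test_spp_dispersive_fixed_point(self):
        # Drude-like gold: eps = 1 - (lambda/lambda_p)^2, lambda_p = 150 nm
        drude = MaterialModel(eps_metal=lambda wl: 1.0 - (wl / 150.0) ** 2, n_medium=1.33)
        wl = spp_wavelength(GEOM, DiffractionOrder(1, 0), drude)
        eps_at = 1.0 - (wl / 150.0) ** 2
        closed = spp_wavelength(
            GEOM, DiffractionOrder(1, 0), MaterialModel(eps_metal=eps_at, n_medium=1.33)
        )
        assert wl == pytest.approx(closed, abs=1e-5)  # self-consistent to tolerance

    def test_spp_dispersive_non_convergence_reports_last_iterate(self):
        drude = MaterialModel(eps_metal=lambda wl: 1.0 - (wl / 150.0) ** 2, n_medium=1.33)
        with pytest.raises(ConvergenceError) as err:
            spp_wavelength(GEOM, DiffractionOrder(1, 0), drude, max_iter=1)
        assert err.value.last_iterate > 0

    def test_wood_anomaly_decreasing_in_order(self):
        mags = [(1, 0), (1, 1), (2, 0), (2, 1)]
        wls = [wood_anomaly_wavelength(GEOM, DiffractionOrder(*m), WATER) for m in mags]
        assert all(a > b for a, b in zip(wls, wls[1:]))


class TestBindingResponse:
    @pytest.mark.parametrize(
        "K, x, expected", [(1.0, 1.0, 0.5), (5.0, 0.0, 0.0), (2.0, 3.0, 6.0 / 7.0)]
    )
    def test_langmuir_examples(self, K, x, expected):
        assert langmuir_coverage(K, x) == pytest.approx(expected, abs=1e-12)

    def test_langmuir_rejects_negative(self):
        with pytest.raises(ValueError):
            langmuir_coverage(-1.0, 2.0)
        with pytest.raises(ValueError):
            langmuir_coverage(1.0, -2.0)

    @settings(derandomize=True, max_examples=50)
    @given(K=st.floats(0.01, 100), xs=st.lists(st.floats(0.0, 1e3), min_size=3, max_size=10))
    def test_langmuir_monotone_concave_bounded(self, K, xs):
        x = np.sort(np.unique(np.asarray(xs)))
        theta = langmuir_coverage(K, x)
        assert np.all(theta >= 0) and np.all(theta < 1)
        assert np.all(np.diff(theta) >= 0)
        if x.size >= 3:  # concavity: secant slopes non-increasing
            slopes = np.diff(theta) / np.diff(x)
            assert np.all(np.diff(slopes) <= 1e-12)

    @pytest.mark.parametrize(
        "theta, expected", [(0.0, 1.33), (1.0, 1.60), (0.5, 1.465)]
    )
    def test_effective_index_examples(self, theta, expected):
        assert effective_index(theta, WATER) == pytest.approx(expected, abs=1e-12)

    def test_effective_index_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            effective_index(1.2, WATER)

    @settings(derandomize=True, max_examples=50)
    @given(theta=st.floats(0.0, 1.0))
    def test_effective_index_convex_combination(self, theta):
        n = effective_index(theta, WATER)
        assert WATER.n_medium <= n <= WATER.n_analyte
        assert n == pytest.approx(WATER.n_medium + theta * 0.27, abs=1e-12)

    def test_refractometric_shift(self):
        spp = OpticalMode("P4", "SPP", 728.0, 22.0, 0.4, 500.0, "medium")
        assert refractometric_shift(spp, 0.01) == pytest.approx(5.0)
        assert refractometric_shift(dataclasses.replace(spp, bulk_sensitivity_nm_per_RIU=0.0), 0.3) == 0.0
        assert refractometric_shift(spp, 0.0) == 0.0

    def test_wood_anomaly_insensitive_to_binding(self):
        wa = OpticalMode("P2", "WA", 665.0, 12.0, 0.25, 500.0, "medium")
        assert refractometric_shift(wa, 0.05) == 0.0

    def test_beer_lambert_examples(self):
        assert beer_lambert_fraction(2.0, 0.0, 1.0) == pytest.approx(1.0)
        assert beer_lambert_fraction(2.0, 0.5, 1.0) == pytest.approx(0.1)
        # doubling c halves the log-fraction
        f1 = beer_lambert_fraction(1.0, 0.3, 1.0)
        f2 = beer_lambert_fraction(1.0, 0.6, 1.0)
        assert math.log10(f2) == pytest.approx(2 * math.log10(f1), abs=1e-12)
        with pytest.raises(ValueError):
            beer_lambert_fraction(-1.0, 0.5, 1.0)

    def test_attenuation_identity_at_zero_concentration(self):
        assert absorbance_attenuation(BindingState(K=1.0, x=0.0)) == pytest.approx(1.0)


class TestApplyBinding:
    def test_no_analyte_leaves_modes_unchanged(self):
        modes = default_modes()
        out = apply_binding(modes, BindingState(K=1.0, x=0.0), WATER)
        assert out == modes
        pre = synthesize_spectrum(modes)
        post = synthesize_spectrum(out)
        assert pre == post

    def test_half_coverage_shift(self):
        mode = OpticalMode("P4", "SPP", 700.0, 22.0, 0.4, 100.0, "medium")
        out = apply_binding([mode], BindingState(K=1.0, x=1.0), WATER)[0]
        # theta = 0.5 -> n_eff = 1.465 -> delta_n = 0.135 -> shift 13.5 nm
        assert out.center_wavelength_nm - 700.0 == pytest.approx(13.5, abs=1e-9)

    def test_saturation_plateau(self):
        mode = OpticalMode("P4", "SPP", 700.0, 22.0, 0.4, 100.0, "medium")
        out = apply_binding([mode], BindingState(K=1.0, x=1e9), WATER)[0]
        assert out.center_wavelength_nm - 700.0 == pytest.approx(100.0 * 0.27, rel=1e-6)

    def test_non_binding_modes_untouched(self):
        modes = default_modes()
        out = apply_binding(modes, BindingState(K=1.0, x=5.0), WATER)
        by_label = {m.label: m for m in out}
        assert by_label["P2"] == modes[1]  # Wood anomaly
        assert by_label["P3"] == modes[2]  # substrate SPP

    def test_crossover_between_shift_and_intensity_channels(self):
        """Normalized shift dominates at low concentration, intensity at high.

        The difference of the two normalized response curves over a log
        concentration sweep must change sign exactly once.
        """
        mode = default_modes()[3]
        x = np.logspace(-3, 3, 121)
        shifts, drs = binding_response_curves(mode, WATER, BindingState(K=1.0, x=0.0), x)
        s_norm = shifts / shifts.max()
        r_norm = drs / drs.max()
        diff = s_norm - r_norm
        signs = np.sign(diff[np.abs(diff) > 1e-12])
        n_changes = int(np.sum(np.diff(signs) != 0))
        assert n_changes == 1
        assert diff[np.abs(diff) > 1e-12][0] > 0  # shift leads at low concentration


class TestSpectrumSynthesis:
    def test_no_modes_flat_baseline(self):
        s = synthesize_spectrum([], baseline_reflectance=0.9)
        assert np.all(s.reflectance == 0.9)

    def test_single_mode_depth_at_center(self):
        mode = OpticalMode("P4", "SPP", 700.0, 20.0, 0.4, 100.0, "medium")
        s = synthesize_spectrum([mode], baseline_reflectance=0.9)
        idx = np.argmin(np.abs(s.wavelength_nm - 700.0))
        assert s.reflectance[idx] == pytest.approx(0.5, abs=1e-6)

    def test_duplicate_labels_rejected(self):
        mode = default_modes()[0]
        with pytest.raises(ValueError, match="duplicate"):
            synthesize_spectrum([mode, mode])

    def test_synthesis_detection_round_trip_isolated_modes(self):
        """Centers of well-separated modes (gap > 3 FWHM) recovered within one grid step."""
        modes = [
            OpticalMode("A", "SPP", 560.0, 15.0, 0.3, 50.0, "medium"),
            OpticalMode("B", "WA", 660.0, 12.0, 0.25, 500.0, "medium"),
            OpticalMode("C", "SPP", 760.0, 18.0, 0.4, 100.0, "medium"),
        ]
        windows = ModeWindows({"A": (530.0, 590.0), "B": (630.0, 690.0), "C": (730.0, 790.0)})
        s = synthesize_spectrum(modes)
        for t in detect_mode_troughs(s, windows):
            assert t.found
            center = {"A": 560.0, "B": 660.0, "C": 760.0}[t.label]
            assert abs(t.wavelength_nm - center) <= 0.5

    def test_synthesis_detection_round_trip_default_chip(self):
        """Default-chip centers recovered within two grid steps.

        P2 (665 nm) and P3 (680 nm) overlap (gap ~ 1 FWHM), so their apparent
        minima are pulled toward each other by the neighbour's Lorentzian tail;
        the bias is below 1 nm and cancels in pre/post shift readouts.
        """
        s = synthesize_spectrum(default_modes())
        troughs = detect_mode_troughs(s, ModeWindows())
        expected = {"P1": 580.0, "P2": 665.0, "P3": 680.0, "P4": 728.0}
        for t in troughs:
            assert t.found
            assert abs(t.wavelength_nm - expected[t.label]) <= 1.0

    def test_spectrum_validation(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([1.0, 1.0, 2.0]), np.array([0.5, 0.5, 0.5]))
        with pytest.raises(ValueError):
            Spectrum(np.array([1.0, 2.0]), np.array([0.5, 1.5]))


class TestNoise:
    def test_zero_noise_is_identity(self):
        s = synthesize_spectrum(default_modes())
        assert add_noise(s, NoiseModel(0.0, 0.0, seed=1)) == s

    def test_same_seed_same_realization(self):
        s = synthesize_spectrum(default_modes())
        n = NoiseModel(0.01, 0.02, seed=7)
        assert add_noise(s, n) == add_noise(s, n)

    def test_residual_standard_deviation(self):
        grid = np.linspace(500.0, 800.0, 10_000)
        s = Spectrum(grid, np.full_like(grid, 0.5))
        noisy = add_noise(s, NoiseModel(0.005, 0.0, seed=3))
        sd = float(np.std(noisy.reflectance - s.reflectance))
        assert abs(sd - 0.005) / 0.005 < 0.05


class TestBindingConstantRecovery:
    def test_noiseless_recovery_exact(self):
        x = np.logspace(-1.5, 1.5, 12)
        shifts = 10.8 * x / (1.0 + x)  # K = 1, A_max = 10.8
        k_fit, a_fit = fit_langmuir_constant(x, shifts)
        assert k_fit == pytest.approx(1.0, rel=1e-6)
        assert a_fit == pytest.approx(10.8, rel=1e-6)
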