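import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p450kit.binding import (
    BindingFit,
    Spectrum,
    TitrationSeries,
    difference_signal,
    fit_tight_binding,
    highspin_fraction,
    tight_binding_model,
)
from p450kit.errors import (
    DegenerateBasisError,
    DomainError,
    InsufficientDataError,
)
from p450kit.synthgen import DEFAULT_LIGAND_GRID, TitrationSpec, gen_titration


def _gaussian_spectrum(center, width=12.0, amp=1.0):
    wl = np.arange(300.0, 501.0)
    return Spectrum(wl, amp * np.exp(-0.5 * ((wl - center) / width) ** 2))


class TestDifferenceSignal:
    def test_flat_spectrum_is_zero(self):
        s = Spectrum(np.arange(300, 501), np.full(201, 0.4))
        assert difference_signal(s) == pytest.approx(0.0)

    def test_on_grid_values(self):
        wl = np.arange(300.0, 501.0)
        a = np.zeros_like(wl)
        a[wl == 386.0] = 0.30
        a[wl == 420.0] = 0.10
        assert difference_signal(Spectrum(wl, a)) == pytest.approx(0.20)

    def test_off_grid_linear_interpolation(self):
        wl = np.array([380.0, 385.0, 387.0, 415.0, 425.0])
        a = np.array([0.0, 0.10, 0.30, 0.05, 0.15])
        s = Spectrum(wl, a)
        # hand interpolation: 386 is midway between 385 and 387,
        # 420 midway between 415 and 425
        expected = (0.10 + 0.30) / 2 - (0.05 + 0.15) / 2
        assert difference_signal(s) == pytest.approx(expected)

    def test_out_of_range_probe(self):
        s = Spectrum(np.arange(400, 501), np.zeros(101))
        with pytest.raises(DomainError):
            difference_signal(s, peak_nm=386.0)


class TestTightBindingModel:
    def test_zero_ligand_gives_zero(self):
        assert tight_binding_model(0.0, 3.0, 0.2, 0.1) == 0.0

    def test_stoichiometric_limit_at_zero_kd(self):
        E, amp = 3.0, 0.1
        for L in (0.0, 1.0, 2.9, 3.0, 10.0, 150.0):
            assert tight_binding_model(L, E, 0.0, amp) == pytest.approx(
                amp * min(L, E) / E, abs=1e-12
            )

    def test_weak_binding_matches_langmuir(self):
        E = 3.0
        kd = 1000.0 * E
        L = np.linspace(0.0, 150.0, 40)
        quad = tight_binding_model(L, E, kd, 1.0)
        langmuir = L / (L + kd)
        mask = L > 0
        assert np.all(
            np.abs(quad[mask] - langmuir[mask]) / langmuir[mask] < 0.005
        )

    def test_monotone_in_ligand_and_kd(self):
        L = np.linspace(0.0, 150.0, 100)
        for kd in (0.0, 0.05, 1.0, 50.0):
            y = tight_binding_model(L, 3.0, kd, 1.0)
            assert np.all(np.diff(y) >= -1e-12)
        for ell in (1.0, 5.0, 80.0):
            ys = [tight_binding_model(ell, 3.0, kd, 1.0)
                  for kd in (0.0, 0.1, 1.0, 10.0, 100.0)]
            assert np.all(np.diff(ys) <= 1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        L=st.floats(0.0, 500.0),
        E=st.floats(0.1, 20.0),
        kd=st.floats(0.0, 1000.0),
        amp=st.floats(0.0, 2.0),
    )
    def test_bounded_fraction_property(self, L, E, kd, amp):
        """The bound fraction always lies in [0, 1]: 0 <= dA <= dA_max."""
        y = tight_binding_model(L, E, kd, amp)
        assert -1e-12 <= y <= amp + 1e-9

    def test_negative_arguments_rejected(self):
        with pytest.raises(DomainError):
            tight_binding_model(-1.0, 3.0, 1.0, 0.1)
        with pytest.raises(DomainError):
            tight_binding_model(1.0, 3.0, -1.0, 0.1)


class TestFitTightBinding:
    def test_noiseless_recovery_of_moderate_kd(self):
        series, truth = gen_titration(
            TitrationSpec(kd_nM=209.0, delta_A_max=0.1, seed=0, noise_sigma=0.0)
        )
        fit = fit_tight_binding(series)
        assert fit.status == "ok"
        assert fit.kd_nM == pytest.approx(209.0, rel=0.01)
        assert fit.delta_A_max == pytest.approx(0.1, rel=0.01)

    def test_all_zero_series_is_no_shift(self):
        L = np.array([0.0, 5.0, 20.0, 80.0, 150.0])
        fit = fit_tight_binding(TitrationSeries(L, np.zeros(5)))
        assert fit.status == "no_shift"

    def test_kd_far_below_enzyme_is_upper_bound_only(self):
        series, _ = gen_titration(
            TitrationSpec(kd_nM=1.0, delta_A_max=0.1, seed=0, noise_sigma=0.0)
        )
        fit = fit_tight_binding(series)
        assert fit.status == "upper_bound_only"
        assert fit.kd_upper_nM is not None and fit.kd_upper_nM > 0
        assert "<" in fit.summary()

    def test_scale_invariance_of_kd(self):
        series, _ = gen_titration(
            TitrationSpec(kd_nM=500.0, delta_A_max=0.08, seed=3,
                          noise_sigma=0.01)
        )
        fit1 = fit_tight_binding(series)
        scaled = TitrationSeries(
            series.ligand_total, 7.0 * series.delta_A, series.enzyme_total
        )
        fit2 = fit_tight_binding(scaled)
        assert fit2.kd_nM == pytest.approx(fit1.kd_nM, rel=1e-3)
        assert fit2.delta_A_max == pytest.approx(7.0 * fit1.delta_A_max,
                                                 rel=1e-3)

    def test_noisy_recovery_median_error(self):
        # reduced version of the recovery experiment (full grid of K_D
        # values and 100 seeds runs in the acceptance suite)
        errs = []
        for seed in range(30):
            series, _ = gen_titration(
                TitrationSpec(kd_nM=1000.0, delta_A_max=0.1, seed=seed,
                              noise_sigma=0.01)
            )
            fit = fit_tight_binding(series)
            errs.append(abs(fit.kd_nM - 1000.0) / 1000.0)
        assert np.median(errs) <= 0.25

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_tight_binding(
                TitrationSeries(np.array([0.0, 5.0, 10.0]), np.zeros(3))
            )


class TestHighspinFraction:
    def test_pure_high_spin(self):
        ls = _gaussian_spectrum(420.0)
        hs = _gaussian_spectrum(390.0)
        assert highspin_fraction(hs, ls, hs) == pytest.approx(1.0)

    def test_even_mixture(self):
        ls = _gaussian_spectrum(420.0)
        hs = _gaussian_spectrum(390.0)
        mix = Spectrum(ls.wavelengths, 0.5 * ls.absorbance + 0.5 * hs.absorbance)
        assert highspin_fraction(mix, ls, hs) == pytest.approx(0.5, abs=1e-9)

    def test_noisy_mixture_recovery(self, rng):
        ls = _gaussian_spectrum(420.0)
        hs = _gaussian_spectrum(390.0)
        clean = 0.7 * ls.absorbance + 0.3 * hs.absorbance
        fractions = []
        for _ in range(100):
            noisy = clean + rng.normal(scale=0.01 * clean.max(),
                                       size=clean.shape)
            fractions.append(
                highspin_fraction(Spectrum(ls.wavelengths, noisy), ls, hs)
            )
        assert np.mean(fractions) == pytest.approx(0.30, abs=0.03)

    def test_degenerate_basis_rejected(self):
        ls = _gaussian_spectrum(420.0)
        with pytest.raises(DegenerateBasisError):
            highspin_fraction(ls, ls, Spectrum(ls.wavelengths,
                                               2.0 * ls.absorbance))
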