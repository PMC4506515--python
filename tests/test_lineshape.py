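"""Bloch-McConnell simulation, Lorentzian regression and k_ex estimation."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from confex.exceptions import InvalidInputError
from confex.lineshape import (
    LorentzianPair,
    Spectrum1D,
    TwoStateExchangeModel,
    coalescence_rate,
    estimate_kex_lineshape,
    fit_two_lorentzian,
    lorentzian_pair_signal,
    simulate_two_state_spectrum,
)
from confex.synthetic_data import gen_lineshape, paper_scenario
from confex.thermokinetics import eyring_fit


def symmetric_model(k_ex, dnu=172.0, R2=5.0):
    return TwoStateExchangeModel(0.5, 0.5, -dnu / 2, dnu / 2, R2, R2, k_ex)


class TestSimulator:
    def test_uncoupled_limit_is_two_lorentzians(self):
        R2 = 40.0
        m = TwoStateExchangeModel(0.6, 0.4, -100.0, 100.0, R2, R2, 0.0)
        axis = np.linspace(-400, 400, 8001)
        spec = simulate_two_state_spectrum(m, axis)
        w = 2 * np.pi * axis
        expected = (0.6 * R2 / ((w + 2 * np.pi * 100) ** 2 + R2**2)
                    + 0.4 * R2 / ((w - 2 * np.pi * 100) ** 2 + R2**2))
        np.testing.assert_allclose(spec.intensity, expected, rtol=1e-10)
        # FWHM of each component is R2/pi Hz
        pair = fit_two_lorentzian(spec)
        assert pair.w1 == pytest.approx(R2 / np.pi, rel=1e-4)
        # areas split as the populations
        assert pair.populations[0] == pytest.approx(0.6, abs=1e-4)

    def test_fast_exchange_collapses_to_population_average(self):
        m = TwoStateExchangeModel(0.7, 0.3, -100.0, 100.0, 10.0, 10.0, 1e6)
        spec = simulate_two_state_spectrum(m, np.linspace(-400, 400, 16001))
        center = spec.frequency[np.argmax(spec.intensity)]
        assert center == pytest.approx(0.7 * -100 + 0.3 * 100, abs=0.5)
        assert len(find_peaks(spec.intensity)[0]) == 1

    def test_area_conserved_across_kex(self):
        axis = np.linspace(-20000, 20000, 100001)
        areas = []
        for k in [0.0, 1.0, 10.0, 100.0, 1e3, 1e4]:
            spec = simulate_two_state_spectrum(symmetric_model(k, R2=40.0), axis)
            areas.append(np.trapezoid(spec.intensity, spec.frequency))
        assert max(areas) / min(areas) - 1 < 1e-3

    def test_coalescence_location_and_monotone_separation(self):
        # peak separation shrinks monotonically with k_ex and the doublet
        # merges near the analytic threshold
        axis = np.linspace(-300, 300, 12001)
        seps = []
        k_grid = np.linspace(10, 1200, 60)
        for k in k_grid:
            spec = simulate_two_state_spectrum(symmetric_model(k), axis)
            pk, _ = find_peaks(spec.intensity)
            seps.append(np.ptp(axis[pk]) if pk.size >= 2 else 0.0)
        seps = np.array(seps)
        assert np.all(np.diff(seps) <= 1e-9)
        merged = k_grid[seps == 0.0]
        assert merged.size > 0
        assert merged[0] == pytest.approx(coalescence_rate(172.0), rel=0.05)
        # k_ex ~ 20 s^-1 is deep slow exchange: well-resolved dual peaks
        spec = simulate_two_state_spectrum(symmetric_model(20.0), axis)
        assert len(find_peaks(spec.intensity)[0]) == 2

    def test_slow_exchange_broadening_grows_as_kij_over_pi(self):
        axis = np.linspace(-300, 300, 24001)
        widths = []
        for k in (0.0, 10.0, 20.0):
            pair = fit_two_lorentzian(
                simulate_two_state_spectrum(symmetric_model(k, R2=40.0), axis))
            widths.append(pair.w1)
        # dFWHM ~ k12/pi = (k/2)/pi in the slow regime
        assert widths[1] - widths[0] == pytest.approx(5.0 / np.pi, rel=0.05)
        assert widths[2] - widths[1] == pytest.approx(5.0 / np.pi, rel=0.05)

    def test_matches_fourier_transform_of_time_domain_oracle(self, rng):
        """Resolvent line shape == FT of the propagated magnetization."""
        for _ in range(5):
            p1 = rng.uniform(0.2, 0.8)
            m = TwoStateExchangeModel(
                p1, 1 - p1, rng.uniform(-150, -20), rng.uniform(20, 150),
                rng.uniform(10, 60), rng.uniform(10, 60), rng.uniform(0, 300))
            axis = np.linspace(-500, 500, 401)
            spec = simulate_two_state_spectrum(m, axis)
            A = np.array([
                [1j * 2 * np.pi * m.delta1 - m.R2_1 - m.k12, m.k21],
                [m.k12, 1j * 2 * np.pi * m.delta2 - m.R2_2 - m.k21]])
            evals, evecs = np.linalg.eig(A)
            coef = np.linalg.solve(evecs, np.array([m.p1, m.p2]))
            t = np.linspace(0, 2.0, 100001)
            fid = (evecs.sum(axis=0) * coef * np.exp(np.outer(t, evals))).sum(axis=1)
            oracle = np.empty(axis.size)
            for lo in range(0, axis.size, 50):
                blk = axis[lo:lo + 50, None]
                oracle[lo:lo + 50] = np.trapezoid(
                    np.real(fid[None, :] * np.exp(-1j * 2 * np.pi * blk * t)),
                    t, axis=1)
            np.testing.assert_allclose(spec.intensity, oracle,
                                       atol=2e-5 * spec.intensity.max(), rtol=5e-3)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_two_state_spectrum(symmetric_model(10.0), np.array([1.0, 1.0, 2.0]))


class TestLorentzianRegression:
    axis = np.linspace(103.0, 108.2, 4096)

    def test_noise_free_parameter_recovery(self):
        truth = dict(y0=0.01, d1=105.0, d2=106.2, A1=1.0, A2=1.0,
                     w1=0.15, w2=0.15)
        y = lorentzian_pair_signal(self.axis, *truth.values())
        pair = fit_two_lorentzian(Spectrum1D(self.axis, y, unit="ppm"))
        assert pair.delta1 == pytest.approx(105.0, abs=1e-6)
        assert pair.delta2 == pytest.approx(106.2, abs=1e-6)
        assert pair.w1 == pytest.approx(0.15, rel=1e-6)
        assert pair.A1 == pytest.approx(1.0, rel=1e-6)
        assert not pair.degenerate

    def test_single_peak_flagged_degenerate(self):
        y = lorentzian_pair_signal(self.axis, 0.0, 105.6, 105.6, 0.7, 0.7,
                                   0.2, 0.2)
        pair = fit_two_lorentzian(Spectrum1D(self.axis, y, unit="ppm"))
        assert pair.degenerate

    def test_mirror_symmetric_spectrum_gives_equal_amplitudes(self):
        y = lorentzian_pair_signal(self.axis, 0.0, 105.0, 106.2, 0.8, 0.8,
                                   0.15, 0.15)
        pair = fit_two_lorentzian(Spectrum1D(self.axis, y, unit="ppm"))
        assert abs(pair.A1 - pair.A2) / (pair.A1 + pair.A2) < 1e-6

    def test_simulate_fit_simulate_round_trip(self):
        """Slow-exchange spectra survive the Lorentzian round trip to <1% RMS."""
        m = TwoStateExchangeModel(0.5, 0.5, 105.0 * 86.2, 106.2 * 86.2,
                                  40.0, 40.0, 15.0)
        spec = simulate_two_state_spectrum(m, self.axis, unit="ppm")
        pair = fit_two_lorentzian(spec)
        rebuilt = lorentzian_pair_signal(
            self.axis, pair.y1 + pair.y2, pair.delta1, pair.delta2,
            pair.A1, pair.A2, pair.w1, pair.w2)
        rms = np.sqrt(np.mean((rebuilt - spec.intensity) ** 2))
        assert rms < 0.01 * spec.intensity.max()


class TestKexEstimation:
    def test_recovers_20_per_s_at_20C_noise_free(self, noise_free_scenario):
        spectra = gen_lineshape(noise_free_scenario)
        T20 = 293.15
        pair = fit_two_lorentzian(spectra[T20])
        rates = estimate_kex_lineshape({T20: spectra[T20]}, {T20: pair})
        assert rates.rates[0] == pytest.approx(20.0, rel=0.05)

    def test_zero_exchange_slice_yields_negligible_rate(self):
        cfg = paper_scenario(seed=0, ls_noise=0.0,
                             ls_kex_by_temp={10.0: 0.0}, ls_temps_C=(10.0,))
        spectra = gen_lineshape(cfg)
        T = 283.15
        rates = estimate_kex_lineshape(spectra, {T: fit_two_lorentzian(spectra[T])})
        assert rates.rates[0] < 0.5

    def test_temperature_series_feeds_eyring_recovery(self):
        # rates generated from the line-shape activation truth across
        # 283-323 K; the fitted rates must reproduce those parameters
        cfg = paper_scenario(seed=0, ls_noise=0.0, ls_kex_by_temp={})
        spectra = gen_lineshape(cfg)
        seeds = {T: fit_two_lorentzian(s) for T, s in spectra.items()}
        rates = estimate_kex_lineshape(spectra, seeds)
        fit = eyring_fit(rates)
        assert fit.dH == pytest.approx(68.6e3, rel=0.01)
        assert fit.dS == pytest.approx(15.3, abs=1.0)
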