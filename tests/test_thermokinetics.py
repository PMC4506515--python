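"""Eyring, Gibbs-Helmholtz, Michaelis-Menten, van't Hoff and barrier tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confex.constants import H_PLANCK, K_B, R_GAS
from confex.exceptions import DomainError, FitFailureError, InvalidInputError
from confex.thermokinetics import (
    Barrier,
    EyringParameters,
    RateSeries,
    binding_free_energy,
    compare_barriers,
    eyring_fit,
    eyring_rate,
    gibbs_activation,
    melt_signal,
    michaelis_menten_fit,
    vant_hoff_melt_fit,
)

SF_PARAMS = EyringParameters(62.1e3, -4.7)          # stopped-flow activation truth
LS_PARAMS = EyringParameters(68.6e3, 15.3)          # line-shape activation truth
CAT_PARAMS = EyringParameters(26.6e3, -120.0)       # catalytic activation truth


class TestEyring:
    def test_noise_free_round_trip_recovers_parameters(self):
        T = np.linspace(278.15, 298.15, 7)
        series = RateSeries(T, eyring_rate(SF_PARAMS, T))
        fit = eyring_fit(series)
        assert fit.dH == pytest.approx(62.1e3, rel=1e-10)
        assert fit.dS == pytest.approx(-4.7, rel=1e-10)
        # and the inverse reproduces every rate
        np.testing.assert_allclose(eyring_rate(fit, T), series.rates, rtol=1e-8)

    def test_zero_enthalpy_entropy_gives_prefactor(self):
        p = EyringParameters(0.0, 0.0)
        assert eyring_rate(p, 298.15) == pytest.approx(K_B * 298.15 / H_PLANCK)
        T = np.array([278.15, 288.15, 298.15])
        fit = eyring_fit(RateSeries(T, K_B * T / H_PLANCK))
        assert abs(fit.dH) < 1e-6
        assert abs(fit.dS) < 1e-9

    def test_rate_at_17C_consistent_with_measured_kapp(self):
        # closed-form evaluation; the measured value is 24 +/- 3 s^-1
        k = eyring_rate(SF_PARAMS, 290.15)
        assert k == pytest.approx(22.73, abs=0.01)
        assert abs(k - 24.0) < 3.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(dH=st.floats(10e3, 120e3), dS=st.floats(-150.0, 150.0))
    def test_round_trip_property(self, dH, dS):
        T = np.linspace(278.15, 323.15, 5)
        truth = EyringParameters(dH, dS)
        k = eyring_rate(truth, T)
        if np.any(k < 1e-30) or np.any(k > 1e30):
            return
        fit = eyring_fit(RateSeries(T, k))
        assert fit.dH == pytest.approx(dH, rel=1e-8, abs=1e-4)
        assert fit.dS == pytest.approx(dS, rel=1e-8, abs=1e-6)

    def test_monte_carlo_recovery_of_activation_enthalpy(self):
        # 5% lognormal noise on rates over the stopped-flow temperatures
        T = 273.15 + np.array([5.0, 8.0, 11.0, 14.0, 17.0, 20.0, 25.0])
        truth_k = eyring_rate(SF_PARAMS, T)
        dHs, dH_ses = [], []
        for seed in range(100):
            g = np.random.default_rng(seed)
            k = truth_k * np.exp(0.05 * g.standard_normal(T.size))
            fit = eyring_fit(RateSeries(T, k, 0.05 * k))
            dHs.append(fit.dH)
            dH_ses.append(fit.dH_se)
        assert abs(np.mean(dHs) - 62.1e3) < np.mean(dH_ses)

    def test_rejects_degenerate_or_unphysical_input(self):
        with pytest.raises(InvalidInputError):
            eyring_fit(RateSeries(np.array([290.0, 290.0]), np.array([1.0, 2.0])))
        with pytest.raises(DomainError):
            RateSeries(np.array([280.0, 290.0]), np.array([1.0, -2.0]))
        with pytest.raises(DomainError):
            eyring_rate(SF_PARAMS, -10.0)


class TestGibbsActivation:
    def test_catalytic_barrier_at_25C(self):
        b = gibbs_activation(CAT_PARAMS, 298.15)
        assert b.value / 1e3 == pytest.approx(62.378, abs=1e-3)

    def test_zero_entropy_barrier_equals_enthalpy(self):
        assert gibbs_activation(EyringParameters(50e3, 0.0), 310.0).value == 50e3

    def test_mean_dynamics_barrier(self):
        b1 = gibbs_activation(SF_PARAMS, 298.15).value
        b2 = gibbs_activation(LS_PARAMS, 298.15).value
        assert (b1 + b2) / 2e3 == pytest.approx(63.77, abs=0.01)

    def test_consistency_with_eyring_rate(self):
        # dG = -R T ln(k h / (k_B T)) for any parameters and T
        for T in (278.15, 298.15, 323.15):
            k = eyring_rate(SF_PARAMS, T)
            dG = -R_GAS * T * np.log(k * H_PLANCK / (K_B * T))
            assert gibbs_activation(SF_PARAMS, T).value == pytest.approx(dG)

    def test_covariance_propagation_reduces_se(self):
        p = EyringParameters(62.1e3, -4.7, dH_se=2.8e3, dS_se=9.7,
                             cov_HS=2.8e3 * 9.7 * 0.999)
        cov = gibbs_activation(p, 298.15).se
        marg = gibbs_activation(p, 298.15, propagate="marginal").se
        assert cov < marg


class TestBindingFreeEnergy:
    def test_ap5a_affinity_stabilization(self):
        assert binding_free_energy(250e-9, 298.15) / 1e3 == pytest.approx(37.69, abs=0.01)

    def test_reference_state_and_log_law(self):
        assert binding_free_energy(1.0, 310.0) == 0.0
        diff = binding_free_energy(125e-9, 298.15) - binding_free_energy(250e-9, 298.15)
        assert diff == pytest.approx(R_GAS * 298.15 * np.log(2), rel=1e-12)

    def test_non_positive_kd_rejected(self):
        with pytest.raises(DomainError):
            binding_free_energy(0.0, 298.15)


class TestMichaelisMenten:
    def test_noise_free_exact_recovery_and_zero_residuals(self):
        c = np.array([5, 10, 25, 50, 100, 200, 400, 800], dtype=float) * 1e-6
        v = 10.0 * c / (50e-6 + c)
        fit = michaelis_menten_fit(c, v)
        assert fit.Vmax == pytest.approx(10.0, rel=1e-9)
        assert fit.Km == pytest.approx(50e-6, rel=1e-9)
        resid = v - fit.Vmax * c / (fit.Km + c)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_half_saturation_at_km(self):
        c = np.array([5, 10, 25, 50, 100, 200, 400, 800], dtype=float) * 1e-6
        fit = michaelis_menten_fit(c, 10.0 * c / (50e-6 + c))
        v_at_km = fit.Vmax * fit.Km / (fit.Km + fit.Km)
        assert v_at_km == pytest.approx(fit.Vmax / 2)

    def test_low_concentration_regime_warns(self):
        c = np.array([1, 2, 3, 4, 5], dtype=float) * 1e-6  # far below Km
        v = 10.0 * c / (50e-6 + c)
        with pytest.warns(UserWarning, match="below the fitted Km"):
            michaelis_menten_fit(c, v)


class TestVantHoffMelt:
    T = np.linspace(295.0, 355.0, 121)

    def _clean_melt(self, Tm=325.0, dHvH=300e3):
        return melt_signal(self.T, Tm, dHvH, -20.0, -5.0, -12000.0, -2000.0)

    def test_noise_free_exact_recovery(self):
        fit = vant_hoff_melt_fit(self.T, self._clean_melt())
        assert fit.Tm == pytest.approx(325.0, abs=1e-6)
        assert fit.dHvH == pytest.approx(300e3, rel=1e-6)

    def test_signal_at_midpoint_is_baseline_mean(self):
        fit = vant_hoff_melt_fit(self.T, self._clean_melt())
        at_tm = melt_signal(fit.Tm, fit.Tm, fit.dHvH, fit.m_f, fit.m_u,
                            fit.Xi_f, fit.Xi_u)
        folded = fit.Xi_f + fit.m_f * fit.Tm
        unfolded = fit.Xi_u + fit.m_u * fit.Tm
        assert at_tm == pytest.approx((folded + unfolded) / 2)
        assert fit.unfolded_fraction(fit.Tm) == pytest.approx(0.5)

    def test_unfolded_fraction_monotone_and_slope_at_tm(self):
        fit = vant_hoff_melt_fit(self.T, self._clean_melt())
        frac = fit.unfolded_fraction(self.T)
        assert np.all(np.diff(frac) > 0)
        eps = 1e-4
        slope = (fit.unfolded_fraction(fit.Tm + eps)
                 - fit.unfolded_fraction(fit.Tm - eps)) / (2 * eps)
        assert slope == pytest.approx(fit.dHvH / (4 * R_GAS * fit.Tm**2), rel=1e-5)

    def test_steepness_increases_with_enthalpy(self):
        steep = vant_hoff_melt_fit(self.T, self._clean_melt(dHvH=500e3))
        shallow = vant_hoff_melt_fit(self.T, self._clean_melt(dHvH=200e3))
        assert steep.dHvH > shallow.dHvH

    def test_flat_signal_raises(self):
        with pytest.raises(FitFailureError):
            vant_hoff_melt_fit(self.T, np.full_like(self.T, -7000.0))


class TestCompareBarriers:
    def test_published_barriers_agree(self):
        c = compare_barriers(Barrier(63.8e3, 0.2e3, 298.15),
                             Barrier(62.4e3, 3.3e3, 298.15))
        assert c.agree
        assert c.z == pytest.approx(0.42, abs=0.01)

    def test_identical_inputs_agree_trivially(self):
        b = Barrier(60e3, 1e3, 298.15)
        c = compare_barriers(b, b)
        assert c.difference == 0.0 and c.agree

    def test_separated_barriers_flagged(self):
        c = compare_barriers(Barrier(60e3, 0.1e3, 298.15),
                             Barrier(70e3, 0.1e3, 298.15))
        assert not c.agree

    def test_mismatched_temperatures_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_barriers(Barrier(60e3, 1e3, 288.15),
                             Barrier(60e3, 1e3, 298.15))
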