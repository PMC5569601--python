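"""Algebraic laws: rheology, secretion, emptying-rate hypotheses, brake."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gastrosim import (
    EmptyingHypothesis,
    FeedbackParams,
    GastricState,
    HypothesisForm,
    RheologyParams,
    SecretionParams,
    SwitchMode,
    concentration_from_state,
    effective_gamma,
    gamma0,
    secretion_rate,
    viscosity_from_concentration,
)
from gastrosim.errors import (
    ConfigurationError,
    DegenerateStateError,
    DomainError,
)

RHEO = RheologyParams(a_L=2.0, b_L=4.21)
SEC = SecretionParams(lambda_s=0.018, b=1.5, S_b=0.018)


class TestViscosity:
    @pytest.mark.parametrize(
        "c, expected",
        [
            (0.0, 0.0),
            (1.0, 2.0),                   # 1 g/100 ml anchor
            (1.5, 2.0 * 1.5 ** 4.21),     # ~11 Pa s anchor
        ],
    )
    def test_power_law_values(self, c, expected):
        assert viscosity_from_concentration(c, RHEO) == pytest.approx(expected)

    def test_high_anchor_is_about_11_pa_s(self):
        assert viscosity_from_concentration(1.5, RHEO) == pytest.approx(
            11.0, rel=0.01
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            viscosity_from_concentration(-0.1, RHEO)

    def test_monotone_on_grid(self):
        c = np.linspace(0, 3, 100)
        mu = viscosity_from_concentration(c, RHEO)
        assert np.all(np.diff(mu) > 0)


class TestConcentration:
    @pytest.mark.parametrize(
        "thickener, liquid, expected",
        [(1.5, 100.0, 1.5), (0.0, 100.0, 0.0), (1.5, 200.0, 0.75)],
    )
    def test_dilution(self, thickener, liquid, expected):
        s = GastricState(nutrient_mass=0, liquid_mass=liquid,
                         thickener_mass=thickener)
        assert concentration_from_state(s, rho_w=1.0) == pytest.approx(expected)

    def test_zero_liquid_degenerate(self):
        s = GastricState(nutrient_mass=0, liquid_mass=0.0, thickener_mass=0.0)
        with pytest.raises(DegenerateStateError):
            concentration_from_state(s)


class TestSecretionRate:
    @pytest.mark.parametrize(
        "mu, expected",
        [(0.0, 0.018), (1.0, 0.036), (4.0, 0.018 * 8 + 0.018)],
    )
    def test_values_at_optimum_parameters(self, mu, expected):
        assert secretion_rate(mu, SEC) == pytest.approx(expected)

    def test_negative_viscosity_rejected(self):
        with pytest.raises(DomainError):
            secretion_rate(-1.0, SEC)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(lam=st.floats(0, 1), b=st.floats(0.1, 3), sb=st.floats(0, 0.1))
    def test_monotone_non_decreasing(self, lam, b, sb):
        p = SecretionParams(lambda_s=lam, b=b, S_b=sb)
        mu = np.linspace(0, 12, 100)
        k = secretion_rate(mu, p)
        assert np.all(np.diff(k) >= 0)
        assert k[0] == pytest.approx(sb)


class TestGamma0:
    def test_sec_plus_c_at_reported_optimum(self):
        h = EmptyingHypothesis(HypothesisForm.SEC_PLUS_C, m_sec=0.0025,
                               C1=6.58e-4)
        assert gamma0(h, K_sec=0.018) == pytest.approx(7.03e-4, rel=1e-3)

    def test_intercept_only_limits(self):
        h = EmptyingHypothesis(HypothesisForm.SEC_PLUS_C, m_sec=0.0025,
                               C1=6.58e-4)
        assert gamma0(h, K_sec=0.0) == pytest.approx(6.58e-4)
        h2 = EmptyingHypothesis(HypothesisForm.VISC_PLUS_C, m_mu=0.0, C1=1e-3)
        assert gamma0(h2, mu=5.0) == pytest.approx(1e-3)
        assert gamma0(h2, mu=50.0) == pytest.approx(1e-3)

    def test_linear_in_each_constant(self):
        mu, v, k = 3.0, 5e-4, 0.05
        h1 = EmptyingHypothesis(HypothesisForm.VISC_PLUS_VOL, m_mu=1e-4,
                                m_s=0.5)
        h2 = EmptyingHypothesis(HypothesisForm.VISC_PLUS_VOL, m_mu=2e-4,
                                m_s=0.5)
        base = gamma0(h1, mu=mu, V_tot=v)
        doubled = gamma0(h2, mu=mu, V_tot=v)
        assert doubled - base == pytest.approx(1e-4 * mu)

    def test_form_constant_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            EmptyingHypothesis(HypothesisForm.SEC_PLUS_C, m_mu=1e-4, C1=1e-3)
        with pytest.raises(ConfigurationError):
            EmptyingHypothesis(HypothesisForm.SEC_PLUS_C, m_sec=1e-3)


class TestBrakeSwitch:
    FB = dict(A_max=7e-3, tau_A=5e6)

    def test_smooth_is_half_gamma0_at_threshold(self):
        fb = FeedbackParams(mode=SwitchMode.SMOOTH, **self.FB)
        assert effective_gamma(7e-3, 1e-3, fb) == 0.5e-3

    def test_logical_brake_off_below_threshold(self):
        fb = FeedbackParams(mode=SwitchMode.LOGICAL, **self.FB)
        assert effective_gamma(0.0, 1e-3, fb) == 1e-3
        assert effective_gamma(7e-3, 1e-3, fb) == 1e-3  # at, not above
        assert effective_gamma(7.1e-3, 1e-3, fb) == 0.0

    def test_smooth_saturates_to_zero(self):
        fb = FeedbackParams(mode=SwitchMode.SMOOTH, **self.FB)
        g = effective_gamma(self.FB["A_max"] + 100 / self.FB["tau_A"],
                            1e-3, fb)
        assert g < 1e-4 * 1e-3

    def test_overflow_guarded(self):
        fb = FeedbackParams(mode=SwitchMode.SMOOTH, A_max=7e-3, tau_A=5e6)
        assert effective_gamma(1.0, 1e-3, fb) == 0.0
        assert effective_gamma(0.0, 1e-3, fb) == 1e-3

    def test_monotone_non_increasing_in_absorption(self):
        fb = FeedbackParams(mode=SwitchMode.SMOOTH, **self.FB)
        a = np.linspace(0, 2e-2, 200)
        g = effective_gamma(a, 1e-3, fb)
        assert np.all(np.diff(g) <= 0)
        assert np.all((g >= 0) & (g <= 1e-3))

    def test_smooth_converges_to_logical(self):
        # at tau_A = 5e6 the two differ only within |A - A_max| < 1e-5 g/s
        fb_s = FeedbackParams(mode=SwitchMode.SMOOTH, **self.FB)
        fb_l = FeedbackParams(mode=SwitchMode.LOGICAL, **self.FB)
        a = np.linspace(0, 2e-2, 5001)
        outside = np.abs(a - self.FB["A_max"]) >= 1e-5
        gs = effective_gamma(a[outside], 1e-3, fb_s)
        gl = effective_gamma(a[outside], 1e-3, fb_l)
        assert np.abs(gs - gl).max() < 1e-3 * 1e-9
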