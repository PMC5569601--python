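"""Algebraic laws of the gastric model.

Pure functions relating state to the quantities that drive the dynamics:

* thickener concentration -> viscosity (power law),
* viscosity -> gastric secretion rate,
* the five candidate laws for the base emptying rate ``gamma0``,
* the duodenal-brake switch gating ``gamma0`` by the intestinal
  absorption rate (logical on/off and its smooth sigmoid approximation).

All functions accept scalars or NumPy arrays and are vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateStateError, DomainError
from .params import (
    ML_PER_M3,
    EmptyingHypothesis,
    FeedbackParams,
    HypothesisForm,
    RheologyParams,
    SecretionParams,
    SwitchMode,
)

#: Exponent clip bound before np.exp, so the smooth switch saturates to its
#: exact limits instead of overflowing.
_EXP_CLIP = 700.0


@dataclass
class GastricState:
    """Instantaneous stomach composition [g] at a time [s].

    Total mass, concentration, viscosity and volume are derived, never
    stored.
    """

    nutrient_mass: float
    liquid_mass: float
    thickener_mass: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if min(self.nutrient_mass, self.liquid_mass, self.thickener_mass) < 0:
            raise ValueError("gastric masses must be >= 0")

    @property
    def total_mass(self) -> float:
        """Stom_tot = Stom_N + Stom_liq + Stom_LBG [g]."""
        return self.nutrient_mass + self.liquid_mass + self.thickener_mass

    def volume_m3(self, rho_w: float = 1.0) -> float:
        """Total gastric volume [m^3], taking all content at density
        ``rho_w`` [g/ml]."""
        return self.total_mass / rho_w / ML_PER_M3


def viscosity_from_concentration(c, p: RheologyParams):
    """Chyme viscosity [Pa s] from thickener concentration [g/100 ml].

    Power law ``mu = a_L * c**b_L``; strictly increasing, zero at c=0.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise DomainError("thickener concentration must be >= 0")
    mu = p.a_L * np.power(c, p.b_L)
    return float(mu) if mu.ndim == 0 else mu


def concentration_from_viscosity(mu, p: RheologyParams):
    """Invert the power law: concentration [g/100 ml] giving viscosity
    ``mu`` [Pa s]."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise DomainError("viscosity must be >= 0")
    c = np.power(mu / p.a_L, 1.0 / p.b_L)
    return float(c) if c.ndim == 0 else c


def concentration_from_state(state: GastricState, rho_w: float = 1.0) -> float:
    """Thickener concentration [g/100 ml] of a gastric state.

    ``C = Stom_LBG / (Stom_liq / rho_w)`` with the liquid volume expressed
    in units of 100 ml (``rho_w`` in g/ml).
    """
    if state.liquid_mass <= 0:
        raise DegenerateStateError(
            "thickener concentration undefined with zero liquid mass"
        )
    volume_100ml = state.liquid_mass / rho_w / 100.0
    return state.thickener_mass / volume_100ml


def secretion_rate(mu, p: SecretionParams):
    """Gastric secretion rate [g/s] at chyme viscosity ``mu`` [Pa s].

    ``K_sec = lambda_s * mu**b + S_b``; equals the basal rate S_b at mu=0
    and is non-decreasing in mu.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise DomainError("viscosity must be >= 0")
    k = p.lambda_s * np.power(mu, p.b) + p.S_b
    return float(k) if k.ndim == 0 else k


def gamma0(h: EmptyingHypothesis, mu=0.0, V_tot=0.0, K_sec=0.0):
    """Base gastric emptying rate [1/s] under hypothesis ``h``.

    Parameters
    ----------
    mu:
        Chyme viscosity [Pa s].
    V_tot:
        Total gastric volume [m^3].
    K_sec:
        Gastric secretion rate [g/s].

    Only the inputs used by ``h.form`` are read.
    """
    mu = np.asarray(mu, dtype=float)
    V_tot = np.asarray(V_tot, dtype=float)
    K_sec = np.asarray(K_sec, dtype=float)
    if np.any(mu < 0) or np.any(V_tot < 0) or np.any(K_sec < 0):
        raise DomainError("gamma0 inputs must be non-negative")
    form = h.form
    if form is HypothesisForm.VISC_PLUS_VOL:
        g = h.m_mu * mu + h.m_s * V_tot
    elif form is HypothesisForm.VOL_PLUS_C:
        g = h.m_s * V_tot + h.C1 + 0.0 * mu
    elif form is HypothesisForm.VISC_PLUS_C:
        g = h.m_mu * mu + h.C1
    elif form is HypothesisForm.SEC_PLUS_C:
        g = h.m_sec * K_sec + h.C1 + 0.0 * mu
    else:  # SEC_PLUS_VOL
        g = h.m_sec * K_sec + h.m_s * V_tot + 0.0 * mu
    g = np.asarray(g, dtype=float)
    return float(g) if g.ndim == 0 else g


def effective_gamma(A, gamma_0, fb: FeedbackParams):
    """Emptying rate [1/s] after the duodenal brake gates ``gamma_0``.

    LOGICAL mode: 0 where the absorption rate A [g/s] exceeds A_max, else
    gamma_0.  SMOOTH mode: the sigmoid ``gamma_0 / (1 + exp(tau_A*(A -
    A_max)))``, which equals gamma_0/2 exactly at A = A_max, is monotone
    non-increasing in A, and converges to the logical switch as tau_A ->
    inf.  The exponent is clipped so saturation returns the exact limits
    0 and gamma_0.
    """
    A = np.asarray(A, dtype=float)
    gamma_0 = np.asarray(gamma_0, dtype=float)
    if np.any(A < 0) or np.any(gamma_0 < 0):
        raise DomainError("A and gamma_0 must be >= 0")
    if fb.disabled:
        out = gamma_0 + 0.0 * A
    elif fb.mode is SwitchMode.LOGICAL:
        out = np.where(A > fb.A_max, 0.0, gamma_0)
    else:
        x = fb.tau_A * (A - fb.A_max)
        mid = gamma_0 / (1.0 + np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP)))
        # exact limits outside the clip window
        out = np.where(x >= _EXP_CLIP, 0.0,
                       np.where(x <= -_EXP_CLIP, gamma_0, mid))
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out
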