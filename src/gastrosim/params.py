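"""Domain types: meal composition, rheology, secretion, emptying-rate
hypotheses and the duodenal-brake feedback switch.

Internal units are SI throughout: seconds, grams, metres, Pa s.  The one
deliberate exception is thickener concentration, expressed in g/100 ml
(the unit in which the power-law rheology ``mu = a_L * c**b_L`` with
``a_L = 2`` and ``b_L = 4.21`` reproduces the anchor viscosities of the
source data: 1 g/100 ml <-> 2 Pa s, 1.5 g/100 ml <-> 11 Pa s).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import ConfigurationError

#: Density of water in g/ml, the assumed density of the non-nutrient liquid.
RHO_W_G_PER_ML = 1.0

#: Millilitres per cubic metre, for converting gastric volume to SI.
ML_PER_M3 = 1.0e6


@dataclass(frozen=True)
class MealSpec:
    """Initial composition of a liquid meal.

    Attributes
    ----------
    nutrient_mass_0:
        Glucose (or generic nutrient) mass at t=0 [g].
    liquid_mass_0:
        Non-nutrient liquid mass at t=0 [g].
    thickener_mass_0:
        Thickener (locust bean gum) mass at t=0 [g].
    label:
        Free-text description.
    """

    nutrient_mass_0: float
    liquid_mass_0: float = 0.0
    thickener_mass_0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("nutrient_mass_0", "liquid_mass_0", "thickener_mass_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.thickener_mass_0 > 0 and self.liquid_mass_0 <= 0:
            raise ValueError(
                "a thickened meal needs liquid_mass_0 > 0 so that the "
                "thickener concentration is defined"
            )


@dataclass(frozen=True)
class RheologyParams:
    """Power-law viscosity-concentration relation mu = a_L * c**b_L.

    ``a_L`` carries the units Pa s per (g/100 ml)**b_L; ``rho_w`` is the
    liquid density in g/ml used to convert liquid mass to volume.
    """

    a_L: float = 2.0
    b_L: float = 4.21
    rho_w: float = RHO_W_G_PER_ML

    def __post_init__(self) -> None:
        if self.a_L <= 0 or self.b_L <= 0 or self.rho_w <= 0:
            raise ValueError("a_L, b_L and rho_w must all be > 0")


@dataclass(frozen=True)
class SecretionParams:
    """Viscosity-driven gastric secretion K_sec = lambda_s * mu**b + S_b.

    ``S_b`` is the basal secretion rate [g/s] with no viscous stimulation;
    ``lambda_s`` [g/s per (Pa s)**b] scales the viscous response.
    """

    lambda_s: float
    b: float
    S_b: float

    def __post_init__(self) -> None:
        if self.lambda_s < 0 or self.S_b < 0:
            raise ValueError("lambda_s and S_b must be >= 0")


class HypothesisForm(enum.Enum):
    """The five candidate laws for the base emptying rate gamma0."""

    VISC_PLUS_VOL = "visc_plus_vol"   # m_mu*mu + m_s*V
    VOL_PLUS_C = "vol_plus_c"         # m_s*V + C1
    VISC_PLUS_C = "visc_plus_c"       # m_mu*mu + C1
    SEC_PLUS_C = "sec_plus_c"         # m_sec*K_sec + C1
    SEC_PLUS_VOL = "sec_plus_vol"     # m_sec*K_sec + m_s*V


#: Which constants each hypothesis form reads.
_FORM_CONSTANTS: dict[HypothesisForm, tuple[str, ...]] = {
    HypothesisForm.VISC_PLUS_VOL: ("m_mu", "m_s"),
    HypothesisForm.VOL_PLUS_C: ("m_s", "C1"),
    HypothesisForm.VISC_PLUS_C: ("m_mu", "C1"),
    HypothesisForm.SEC_PLUS_C: ("m_sec", "C1"),
    HypothesisForm.SEC_PLUS_VOL: ("m_sec", "m_s"),
}


@dataclass(frozen=True)
class EmptyingHypothesis:
    """A candidate gamma0 law: a two-term linear combination of viscosity
    [Pa s], gastric volume [m^3] and secretion rate [g/s].

    Units: m_mu [1/(Pa s^2)], m_s [1/(m^3 s)], m_sec [1/g], C1 [1/s].
    Exactly the constants used by ``form`` may be supplied.
    """

    form: HypothesisForm
    m_mu: float | None = None
    m_s: float | None = None
    m_sec: float | None = None
    C1: float | None = None

    def __post_init__(self) -> None:
        required = _FORM_CONSTANTS[self.form]
        for name in ("m_mu", "m_s", "m_sec", "C1"):
            value = getattr(self, name)
            if name in required:
                if value is None:
                    raise ConfigurationError(
                        f"{self.form.name} requires constant {name}"
                    )
                if value < 0:
                    raise ConfigurationError(f"{name} must be >= 0")
            elif value is not None:
                raise ConfigurationError(
                    f"{self.form.name} does not use constant {name}"
                )

    @property
    def constant_names(self) -> tuple[str, ...]:
        return _FORM_CONSTANTS[self.form]

    def constants(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.constant_names}


class SwitchMode(enum.Enum):
    """Duodenal-brake switch flavour: hard on/off or sigmoid approximation."""

    LOGICAL = "logical"
    SMOOTH = "smooth"


@dataclass(frozen=True)
class FeedbackParams:
    """Duodenal-brake parameters.

    ``A_max`` [g/s] is the absorption-rate ceiling above which emptying is
    suppressed; ``tau_A`` [s/g] sets the sharpness of the smooth switch
    (default 5e6, at which the sigmoid is indistinguishable from the hard
    switch outside |A - A_max| < ~1e-5 g/s).  ``A_max = inf`` disables the
    brake entirely.
    """

    A_max: float
    tau_A: float = 5.0e6
    mode: SwitchMode = SwitchMode.LOGICAL

    def __post_init__(self) -> None:
        if not (self.A_max > 0):
            raise ValueError("A_max must be > 0 (use math.inf to disable)")
        if not (self.tau_A > 0):
            raise ValueError("tau_A must be > 0")

    @property
    def disabled(self) -> bool:
        return math.isinf(self.A_max)


BRAKE_DISABLED = FeedbackParams(A_max=math.inf)
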