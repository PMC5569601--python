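"""Normalised finite-difference sensitivity of the gastric content curve.

For a parameter theta and model output f(t) (gastric nutrient mass), the
sensitivity is the one-sided finite difference

    df/dtheta ~= [f(theta*(1+eps)) - f(theta)] / (theta*eps)

normalised by the nominal parameter value and the meal input mass f0:

    S*(t) = df/dtheta * theta / f0 = [f_pert(t) - f_nom(t)] / (eps * f0)

Both runs share the exact same grid, so S* is zero wherever the
perturbation leaves the trajectory untouched — the signature used to
read off whether the duodenal brake ever engages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import SimulationConfig, Trajectory, simulate

#: Parameter name -> (getter, setter) on a SimulationConfig.
_PARAM_ACCESSORS = {
    "gamma_0": (
        lambda c: c.gamma_0,
        lambda c, v: replace(c, gamma_0=v),
    ),
    "A_max": (
        lambda c: c.feedback.A_max,
        lambda c, v: replace(c, feedback=replace(c.feedback, A_max=v)),
    ),
    "tau_A": (
        lambda c: c.feedback.tau_A,
        lambda c, v: replace(c, feedback=replace(c.feedback, tau_A=v)),
    ),
    "K_a": (
        lambda c: c.K_a,
        lambda c, v: replace(c, K_a=v),
    ),
    "StomN0": (
        lambda c: c.meal.nutrient_mass_0,
        lambda c, v: replace(c, meal=replace(c.meal, nutrient_mass_0=v)),
    ),
    "liq0": (
        lambda c: c.meal.liquid_mass_0,
        lambda c, v: replace(c, meal=replace(c.meal, liquid_mass_0=v)),
    ),
    "LBG0": (
        lambda c: c.meal.thickener_mass_0,
        lambda c, v: replace(c, meal=replace(c.meal, thickener_mass_0=v)),
    ),
    "a_L": (
        lambda c: c.rheology.a_L,
        lambda c, v: replace(c, rheology=replace(c.rheology, a_L=v)),
    ),
    "b_L": (
        lambda c: c.rheology.b_L,
        lambda c, v: replace(c, rheology=replace(c.rheology, b_L=v)),
    ),
    "lambda_s": (
        lambda c: c.secretion.lambda_s,
        lambda c, v: replace(c, secretion=replace(c.secretion, lambda_s=v)),
    ),
    "b": (
        lambda c: c.secretion.b,
        lambda c, v: replace(c, secretion=replace(c.secretion, b=v)),
    ),
    "S_b": (
        lambda c: c.secretion.S_b,
        lambda c, v: replace(c, secretion=replace(c.secretion, S_b=v)),
    ),
    "m_mu": (
        lambda c: c.hypothesis.m_mu,
        lambda c, v: replace(c, hypothesis=replace(c.hypothesis, m_mu=v)),
    ),
    "m_s": (
        lambda c: c.hypothesis.m_s,
        lambda c, v: replace(c, hypothesis=replace(c.hypothesis, m_s=v)),
    ),
    "m_sec": (
        lambda c: c.hypothesis.m_sec,
        lambda c, v: replace(c, hypothesis=replace(c.hypothesis, m_sec=v)),
    ),
    "C1": (
        lambda c: c.hypothesis.C1,
        lambda c, v: replace(c, hypothesis=replace(c.hypothesis, C1=v)),
    ),
    "u_bar": (
        lambda c: c.u_bar,
        lambda c, v: replace(c, u_bar=v),
    ),
}


def valid_parameters(cfg: SimulationConfig) -> list[str]:
    """Parameter names applicable to this configuration."""
    names = []
    for name, (get, _) in _PARAM_ACCESSORS.items():
        try:
            value = get(cfg)
        except AttributeError:
            continue
        if value is not None and np.isfinite(value):
            names.append(name)
    return names


@dataclass
class SensitivityResult:
    """Time series of the normalised sensitivity S*(t) for one parameter."""

    parameter: str
    eps: float
    times: np.ndarray
    s_star: np.ndarray
    f0: float
    nominal_value: float
    nominal: Trajectory = field(repr=False, default=None)
    perturbed: Trajectory = field(repr=False, default=None)


def sensitivity_series(
    cfg: SimulationConfig,
    param: str,
    eps: float = 0.01,
    f0: float | None = None,
) -> SensitivityResult:
    """Normalised sensitivity of gastric nutrient mass to ``param``.

    ``eps`` is the fractional perturbation (default 1%); ``f0`` defaults
    to the meal input mass.  Nominal and perturbed runs share the grid,
    step size and switch mode of ``cfg``.
    """
    if not (0 < eps <= 0.1):
        raise ValueError("eps must lie in (0, 0.1]")
    valid = valid_parameters(cfg)
    if param not in valid:
        raise ValueError(
            f"unknown or inapplicable parameter '{param}'; valid for this "
            f"configuration: {sorted(valid)}"
        )
    get, set_ = _PARAM_ACCESSORS[param]
    theta = float(get(cfg))
    cfg = replace(cfg, auto_refine_dt=False)
    nominal = simulate(cfg)
    perturbed = simulate(set_(cfg, theta * (1.0 + eps)))
    norm = f0 if f0 is not None else cfg.meal.nutrient_mass_0
    if norm <= 0:
        raise ValueError("normalisation f0 must be > 0")
    s_star = (perturbed.gastric_nutrient - nominal.gastric_nutrient) / (eps * norm)
    return SensitivityResult(
        parameter=param,
        eps=eps,
        times=nominal.times,
        s_star=s_star,
        f0=norm,
        nominal_value=theta,
        nominal=nominal,
        perturbed=perturbed,
    )
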