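"""Synthetic-data generator.

The emptying data the estimation workflows target live only in published
figures, so fitting and Monte-Carlo tests run on synthetic curves with
the same statistical structure: simulated trajectories from the packaged
parameter presets, sampled at 10-min intervals out to 60 min, with
additive noise whose per-time scales follow the printed replicate
standard deviations (interpreted as percent of the initial content).

Presets mirror the packaged parameter tables: eight glucose-meal
feedback-model conditions ("a".."h"), the non-nutrient secretion optimum
(``secretion_optimum``), and four combined-model meals (LVN, HVN, LVC,
HVC).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .core import concentration_from_viscosity
from .errors import ConfigurationError, DomainError
from .observations import GASTRIC_MASS, VISCOSITY, ObservationSet
from .params import (
    BRAKE_DISABLED,
    EmptyingHypothesis,
    FeedbackParams,
    HypothesisForm,
    MealSpec,
    RheologyParams,
    SecretionParams,
    SwitchMode,
)
from .simulate import (
    GridSpec,
    SimulationConfig,
    simulate,
    simulate_secretion_batch,
)

import pandas as pd

#: Lowest meaningful initial viscosity [Pa s]; below this the power-law
#: inversion gives thickener amounts indistinguishable from pure water.
VISCOSITY_FLOOR = 1e-3

#: Default non-nutrient liquid load [g] (500 ml test meals).
DEFAULT_LIQ0 = 500.0


def _load_yaml(name: str) -> dict:
    ref = resources.files("gastrosim").joinpath("presets", name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def feedback_table() -> dict[str, dict]:
    """The eight packaged feedback-model conditions (a..h)."""
    return _load_yaml("table1.yaml")


def noise_table() -> dict:
    """Replicate standard deviations (percent of initial) at 10-60 min."""
    return _load_yaml("table2.yaml")


def secretion_table() -> dict[str, dict]:
    """Non-nutrient secretion optimum with mean +/- 2 sigma bounds."""
    return _load_yaml("table3.yaml")


def combined_table() -> dict[str, dict]:
    """Combined-model parameters for the LVN/HVN/LVC/HVC meals."""
    return _load_yaml("table4.yaml")


@dataclass(frozen=True)
class ScenarioPreset:
    """A named, fully specified simulation scenario plus its sampling
    design: times [min] and additive noise scales (percent of the initial
    gastric content) at those times."""

    name: str
    config: SimulationConfig
    sample_times_min: tuple[float, ...] = (10, 20, 30, 40, 50, 60)
    noise_pct: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.noise_pct and len(self.noise_pct) != len(self.sample_times_min):
            raise ConfigurationError(
                "noise_pct must match sample_times_min in length"
            )


_T1_TFINAL_MIN = {"a": 120, "b": 120, "c": 180, "d": 240,
                  "e": 120, "f": 240, "g": 120, "h": 240}


def table1_preset(
    label: str,
    mode: SwitchMode = SwitchMode.LOGICAL,
    dt: float = 1.0,
    t_final_min: float | None = None,
    transport: str = "pde",
    n_cells: int = 150,
    fill_brake_from: str | None = None,
) -> ScenarioPreset:
    """Feedback-only scenario for condition ``label`` in "a".."h".

    Condition (a) reports no brake parameters; its preset runs with the
    brake disabled unless ``fill_brake_from`` names another condition
    whose Amax/Ka should stand in (useful for sensitivity probing, where
    a finite-but-never-engaged brake is needed).  Noise scales default to
    the printed condition-f percentages except for condition h, which has
    its own row.
    """
    table = feedback_table()
    if label not in table:
        raise KeyError(f"unknown condition '{label}'; choose from {sorted(table)}")
    row = table[label]
    amax = row["Amax_g_per_s"]
    ka = row["Ka_per_s"]
    if fill_brake_from is not None:
        donor = table[fill_brake_from]
        amax = amax if amax is not None else donor["Amax_g_per_s"]
        ka = ka if ka is not None else donor["Ka_per_s"]
    fb = (
        BRAKE_DISABLED
        if amax is None
        else FeedbackParams(A_max=amax, mode=mode)
    )
    t_final = 60.0 * (t_final_min if t_final_min is not None
                      else _T1_TFINAL_MIN[label])
    cfg = SimulationConfig(
        meal=MealSpec(nutrient_mass_0=row["StomN0_g"],
                      label=f"glucose condition {label}"),
        feedback=fb,
        K_a=0.0 if ka is None else ka,
        gamma_0=row["gamma0_per_s"],
        grid=GridSpec(dt=dt, t_final=t_final, n_cells=n_cells),
        transport=transport,
    )
    noise = noise_table()
    pct = noise["h"] if label == "h" else noise["f"]
    return ScenarioPreset(
        name=f"T1{label}", config=cfg,
        sample_times_min=tuple(noise["time_min"]), noise_pct=tuple(pct),
    )


def secretion_optimum() -> tuple[EmptyingHypothesis, SecretionParams]:
    """The packaged non-nutrient optimum: gamma0 = m_sec*K_sec + C1 with
    its secretion law."""
    row = secretion_table()["mean"]
    hyp = EmptyingHypothesis(
        form=HypothesisForm.SEC_PLUS_C, m_sec=row["msec"], C1=row["C1_per_s"]
    )
    sec = SecretionParams(
        lambda_s=row["lambdaS"], b=row["b"], S_b=row["Sb_g_per_s"]
    )
    return hyp, sec


def table4_preset(
    name: str,
    glucose_g: float | None = None,
    mode: SwitchMode = SwitchMode.LOGICAL,
    dt: float = 1.0,
    t_final_min: float = 240.0,
    transport: str = "pde",
    n_cells: int = 150,
) -> ScenarioPreset:
    """Combined secretion + brake scenario for LVN / HVN / LVC / HVC.

    ``glucose_g`` overrides the preset nutrient load (used for the
    half-time-versus-load predictions).
    """
    table = combined_table()
    if name not in table:
        raise KeyError(f"unknown meal '{name}'; choose from {sorted(table)}")
    row = table[name]
    rheo = RheologyParams()
    liq0 = row["liq0_g"]
    lbg0 = lbg_for_viscosity(row["mu0_Pa_s"], liq0, rheo)
    cfg = SimulationConfig(
        meal=MealSpec(
            nutrient_mass_0=glucose_g if glucose_g is not None
            else row["glucose_g"],
            liquid_mass_0=liq0,
            thickener_mass_0=lbg0,
            label=name,
        ),
        feedback=FeedbackParams(A_max=row["Amax_g_per_s"], mode=mode),
        K_a=row["Ka_per_s"],
        hypothesis=EmptyingHypothesis(
            form=HypothesisForm.SEC_PLUS_C,
            m_sec=row["msec"], C1=row["C1_per_s"],
        ),
        secretion=SecretionParams(
            lambda_s=row["lambdaS"], b=row["b"], S_b=row["Sb_g_per_s"]
        ),
        rheology=rheo,
        grid=GridSpec(dt=dt, t_final=60.0 * t_final_min, n_cells=n_cells),
        transport=transport,
    )
    return ScenarioPreset(name=name, config=cfg)


def lbg_for_viscosity(mu0: float, liq0: float,
                      rheology: RheologyParams | None = None) -> float:
    """Thickener mass [g] giving initial viscosity ``mu0`` [Pa s] in
    ``liq0`` g of liquid, by inverting the power law."""
    rheo = rheology or RheologyParams()
    if mu0 < VISCOSITY_FLOOR:
        raise DomainError(
            f"initial viscosity {mu0:g} Pa s below the detectable floor "
            f"{VISCOSITY_FLOOR:g}"
        )
    c = concentration_from_viscosity(mu0, rheo)  # g/100 ml
    return c * (liq0 / rheo.rho_w / 100.0)


def generate_dataset(
    preset: ScenarioPreset,
    seed: int | None = None,
    noise: bool = True,
) -> ObservationSet:
    """Simulate a preset and sample its gastric nutrient curve.

    Additive Gaussian noise with per-time standard deviation
    ``noise_pct/100 * StomN0`` is applied when ``noise`` is set (seeded);
    values are floored at zero.  The noiseless backbone is identical
    across seeds.
    """
    tr = simulate(preset.config)
    t_obs = 60.0 * np.asarray(preset.sample_times_min, dtype=float)
    values = np.interp(t_obs, tr.times, tr.gastric_nutrient)
    n0 = preset.config.meal.nutrient_mass_0
    if preset.noise_pct:
        sd = np.asarray(preset.noise_pct, dtype=float) / 100.0 * n0
    else:
        sd = np.zeros_like(t_obs)
    if noise and np.any(sd > 0):
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, sd), 0.0, None)
    frame = pd.DataFrame(
        {
            "experiment": preset.name,
            "time_s": t_obs,
            "value": values,
            "kind": GASTRIC_MASS,
            "sd": sd,
        }
    )
    meta = {
        preset.name: {
            "StomN0": n0,
            "liq0": preset.config.meal.liquid_mass_0,
            "label": preset.config.meal.label,
            "source": "synthetic",
        }
    }
    return ObservationSet(frame, meta)


def nonnutrient_viscosity_set(
    initial_viscosities: list[float],
    seed: int | None = None,
    hypothesis: EmptyingHypothesis | None = None,
    secretion: SecretionParams | None = None,
    rheology: RheologyParams | None = None,
    liq0: float = DEFAULT_LIQ0,
    sample_times_min: tuple[float, ...] = (0, 10, 20, 30, 40, 50, 60),
    noise_sigma: float = 0.0,
    dt: float = 5.0,
    t_final: float = 5400.0,
) -> ObservationSet:
    """Viscosity/half-time dataset for a panel of non-nutrient meals.

    Each meal is defined by its initial viscosity; the thickener load is
    found by inverting the power law.  The set carries per-meal viscosity
    samples, the total-content half-time, and the ``mu0``/``liq0``
    metadata the composite secretion objective requires.  Optional
    multiplicative log-normal noise (sigma in log-space) perturbs the
    viscosity samples.
    """
    if not initial_viscosities:
        raise ValueError("need at least one initial viscosity")
    for mu0 in initial_viscosities:
        if mu0 < VISCOSITY_FLOOR:
            raise DomainError(
                f"initial viscosity {mu0:g} Pa s below the detectable "
                f"floor {VISCOSITY_FLOOR:g}"
            )
    hyp, sec = secretion_optimum()
    hypothesis = hypothesis or hyp
    secretion = secretion or sec
    rheo = rheology or RheologyParams()
    mu0s = np.asarray(initial_viscosities, dtype=float)
    lbg0 = np.array([lbg_for_viscosity(m, liq0, rheo) for m in mu0s])
    liqs = np.full_like(mu0s, liq0)
    res = simulate_secretion_batch(
        liqs, lbg0, secretion, hypothesis, rheo, dt=dt, t_final=t_final
    )
    t_obs = 60.0 * np.asarray(sample_times_min, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    meta: dict[str, dict] = {}
    from .simulate import crossing_time

    for i, mu0 in enumerate(mu0s):
        exp = f"NN_{mu0:g}"
        mu_sim = np.interp(t_obs, res["times"], res["viscosity"][:, i])
        if noise_sigma > 0:
            mu_sim = mu_sim * rng.lognormal(0.0, noise_sigma, mu_sim.shape)
        for t, v in zip(t_obs, mu_sim):
            rows.append(
                {"experiment": exp, "time_s": t, "value": v,
                 "kind": VISCOSITY, "sd": np.nan}
            )
        # the composite objective normalises Stomtot by the initial liquid
        # load, so the synthetic "measured" half-time is the crossing of
        # liq0/2 (within ~1% of half the true initial total)
        tot = res["stomtot"][:, i]
        t_half = crossing_time(res["times"], tot, 0.5 * liq0)
        meta[exp] = {
            "mu0": float(mu0),
            "liq0": float(liq0),
            "lbg0": float(lbg0[i]),
            "half_time_s": float(t_half),
            "source": "synthetic",
        }
    return ObservationSet(pd.DataFrame(rows), meta)
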