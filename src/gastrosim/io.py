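"""Readers/writers for observation and trajectory tables, flat config
files with unit-suffixed keys, and run manifests.

Internal units are strictly SI (s, m, g, Pa s); minutes appear only at
the I/O boundary (``time_min`` columns, ``t_final_min`` keys).  The CSV
dialect is comma-separated, '.' decimal, UTF-8, with a mandatory header.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError
from .observations import ObservationSet
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
from .simulate import GridSpec, SimulationConfig, Trajectory

_FLOAT_FMT = "%.12g"


# -- observations ----------------------------------------------------------

def read_observations(path) -> ObservationSet:
    """Read a delimited observation table.

    Requires columns ``value`` and ``kind`` plus either ``time_min`` or
    ``time_s``; optional ``sd``, ``experiment`` and per-experiment
    metadata columns ``mu0``, ``liq0``, ``half_time_s``, ``StomN0``
    (constant within an experiment).
    """
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ParseError(f"cannot read '{path}': {err}") from err
    if "time_s" in df.columns:
        if "time_min" in df.columns:
            raise ParseError("give either time_s or time_min, not both")
        df["time_s"] = df["time_s"].astype(float)
    elif "time_min" in df.columns:
        df["time_s"] = 60.0 * df["time_min"].astype(float)
        df = df.drop(columns=["time_min"])
    else:
        raise ParseError("missing time column (time_min or time_s)")
    for col in ("value", "kind"):
        if col not in df.columns:
            raise ParseError(f"missing required column '{col}'")
    meta: dict[str, dict] = {}
    meta_cols = [c for c in ("mu0", "liq0", "half_time_s", "StomN0")
                 if c in df.columns]
    if meta_cols:
        exp_col = df["experiment"] if "experiment" in df.columns else "exp0"
        df["experiment"] = exp_col
        for exp, grp in df.groupby("experiment"):
            meta[exp] = {
                c: float(grp[c].iloc[0]) for c in meta_cols
                if np.isfinite(grp[c].iloc[0])
            }
        df = df.drop(columns=meta_cols)
    keep = [c for c in ("experiment", "time_s", "value", "kind", "sd")
            if c in df.columns]
    return ObservationSet(df[keep], meta)


def write_observations(data: ObservationSet, path) -> None:
    """Write an observation table with times in minutes (the I/O-boundary
    unit) and per-experiment metadata as repeated columns."""
    df = data.frame.copy()
    df.insert(df.columns.get_loc("time_s"), "time_min", df["time_s"] / 60.0)
    df = df.drop(columns=["time_s"])
    for exp, meta in data.meta.items():
        for key in ("mu0", "liq0", "half_time_s", "StomN0"):
            if key in meta:
                df.loc[df["experiment"] == exp, key] = meta[key]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- trajectories ----------------------------------------------------------

def write_trajectory(tr: Trajectory, path) -> None:
    """Write a trajectory as CSV at 12 significant digits; NaN anywhere is
    refused with a diagnostic."""
    df = tr.to_frame()
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"trajectory contains NaN in columns {bad}; refusing")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    required = [
        "time_s", "gastric_nutrient_g", "gastric_liquid_g",
        "gastric_thickener_g", "viscosity_Pa_s", "secretion_rate_g_per_s",
        "emptying_rate_per_s", "absorption_rate_g_per_s",
        "intestinal_mass_g", "cumulative_absorbed_g",
        "cumulative_outflow_g", "cumulative_secreted_g",
    ]
    for col in required:
        if col not in df.columns:
            raise ParseError(f"missing trajectory column '{col}'")
    return Trajectory(
        times=df["time_s"].to_numpy(float),
        gastric_nutrient=df["gastric_nutrient_g"].to_numpy(float),
        gastric_liquid=df["gastric_liquid_g"].to_numpy(float),
        gastric_thickener=df["gastric_thickener_g"].to_numpy(float),
        viscosity=df["viscosity_Pa_s"].to_numpy(float),
        secretion_rate=df["secretion_rate_g_per_s"].to_numpy(float),
        emptying_rate=df["emptying_rate_per_s"].to_numpy(float),
        absorption_rate=df["absorption_rate_g_per_s"].to_numpy(float),
        intestinal_mass=df["intestinal_mass_g"].to_numpy(float),
        cumulative_absorbed=df["cumulative_absorbed_g"].to_numpy(float),
        cumulative_outflow=df["cumulative_outflow_g"].to_numpy(float),
        cumulative_secreted=df["cumulative_secreted_g"].to_numpy(float),
        meta={"source": str(path)},
    )


def write_field_snapshot(field, path) -> None:
    """Export an intestinal field as (z_m, density_g_per_m) CSV."""
    pd.DataFrame(
        {"z_m": field.z_nodes, "density_g_per_m": field.densities}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- flat config files -----------------------------------------------------

_CONFIG_KEYS = {
    "label", "StomN0_g", "liq0_g", "LBG0_g",
    "gamma0_per_s", "hypothesis",
    "m_mu", "m_s", "m_sec", "C1_per_s",
    "Amax_g_per_s", "tauA_s_per_g", "switch",
    "Ka_per_s", "lambdaS", "b", "Sb_g_per_s",
    "aL", "bL", "rho_w_g_per_ml",
    "dt_s", "t_final_s", "t_final_min", "n_cells", "transport",
    "L_m", "u_bar_m_per_s", "l0_m", "seed",
}


def config_to_dict(cfg: SimulationConfig) -> dict:
    out: dict = {
        "label": cfg.meal.label,
        "StomN0_g": cfg.meal.nutrient_mass_0,
        "liq0_g": cfg.meal.liquid_mass_0,
        "LBG0_g": cfg.meal.thickener_mass_0,
        "Ka_per_s": cfg.K_a,
        "aL": cfg.rheology.a_L,
        "bL": cfg.rheology.b_L,
        "rho_w_g_per_ml": cfg.rheology.rho_w,
        "dt_s": cfg.grid.dt,
        "t_final_s": cfg.grid.t_final,
        "n_cells": cfg.grid.n_cells,
        "transport": cfg.transport,
        "L_m": cfg.L,
        "u_bar_m_per_s": cfg.u_bar,
        "l0_m": cfg.l_0,
    }
    if cfg.gamma_0 is not None:
        out["gamma0_per_s"] = cfg.gamma_0
    if cfg.hypothesis is not None:
        out["hypothesis"] = cfg.hypothesis.form.value
        consts = cfg.hypothesis.constants()
        if "C1" in consts:
            consts["C1_per_s"] = consts.pop("C1")
        out.update(consts)
    if not cfg.feedback.disabled:
        out["Amax_g_per_s"] = cfg.feedback.A_max
        out["tauA_s_per_g"] = cfg.feedback.tau_A
    out["switch"] = cfg.feedback.mode.value
    if cfg.secretion is not None:
        out["lambdaS"] = cfg.secretion.lambda_s
        out["b"] = cfg.secretion.b
        out["Sb_g_per_s"] = cfg.secretion.S_b
    if cfg.seed is not None:
        out["seed"] = cfg.seed
    return out


def config_from_dict(raw: dict) -> SimulationConfig:
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown config keys {sorted(unknown)}; allowed: "
            f"{sorted(_CONFIG_KEYS)}"
        )
    meal = MealSpec(
        nutrient_mass_0=float(raw.get("StomN0_g", 0.0)),
        liquid_mass_0=float(raw.get("liq0_g", 0.0)),
        thickener_mass_0=float(raw.get("LBG0_g", 0.0)),
        label=str(raw.get("label", "")),
    )
    rheology = RheologyParams(
        a_L=float(raw.get("aL", 2.0)),
        b_L=float(raw.get("bL", 4.21)),
        rho_w=float(raw.get("rho_w_g_per_ml", 1.0)),
    )
    secretion = None
    if "lambdaS" in raw or "Sb_g_per_s" in raw:
        secretion = SecretionParams(
            lambda_s=float(raw.get("lambdaS", 0.0)),
            b=float(raw.get("b", 1.0)),
            S_b=float(raw.get("Sb_g_per_s", 0.0)),
        )
    hypothesis = None
    if "hypothesis" in raw:
        form = HypothesisForm(raw["hypothesis"])
        kwargs = {}
        for key, cfg_key in (("m_mu", "m_mu"), ("m_s", "m_s"),
                             ("m_sec", "m_sec"), ("C1", "C1_per_s")):
            if cfg_key in raw:
                kwargs[key] = float(raw[cfg_key])
        hypothesis = EmptyingHypothesis(form=form, **kwargs)
    if "Amax_g_per_s" in raw and raw["Amax_g_per_s"] is not None:
        feedback = FeedbackParams(
            A_max=float(raw["Amax_g_per_s"]),
            tau_A=float(raw.get("tauA_s_per_g", 5.0e6)),
            mode=SwitchMode(raw.get("switch", "logical")),
        )
    else:
        feedback = BRAKE_DISABLED
    if "t_final_s" in raw:
        t_final = float(raw["t_final_s"])
    elif "t_final_min" in raw:
        t_final = 60.0 * float(raw["t_final_min"])
    else:
        t_final = 7200.0
    grid = GridSpec(
        dt=float(raw.get("dt_s", 1.0)),
        t_final=t_final,
        n_cells=int(raw.get("n_cells", 150)),
    )
    return SimulationConfig(
        meal=meal,
        feedback=feedback,
        K_a=float(raw.get("Ka_per_s", 0.0)),
        gamma_0=float(raw["gamma0_per_s"]) if "gamma0_per_s" in raw else None,
        hypothesis=hypothesis,
        secretion=secretion,
        rheology=rheology,
        grid=grid,
        transport=str(raw.get("transport", "pde")),
        L=float(raw.get("L_m", 2.85)),
        u_bar=float(raw.get("u_bar_m_per_s", 1.7e-4)),
        l_0=float(raw.get("l0_m", 0.025)),
        seed=int(raw["seed"]) if "seed" in raw else None,
    )


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


# -- run manifests ---------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record emitted alongside every CLI output."""

    command: str
    config: dict
    seed: int | None
    grid_used: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(manifest), fh, sort_keys=False)
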