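"""Forward-Euler time march coupling the stirred gastric compartment, the
viscosity-driven secretion law, the 1-D intestinal transport and the
duodenal-brake feedback.

Each step, in order: (i) the gastric state gives concentration ->
viscosity -> secretion rate -> base emptying rate gamma0; (ii) the
absorption rate A is read from the intestinal field of the previous step
(explicit coupling) and gated through the brake to give gamma; (iii) the
stomach masses advance by forward Euler; (iv) the emptied nutrient
gamma*StomN*dt is injected as a point bolus and the transport field takes
one upwind step.  Global nutrient bookkeeping (stomach + lumen + absorbed
+ outflow = input) is exact to round-off by construction.

Two transport back-ends are available: the full upwind PDE (``"pde"``)
and an exact lumped reduction (``"lumped"``) valid before any material
reaches the distal end: until then the total luminal mass M obeys
dM/dt = inflow - K_a*M identically to the discrete PDE, so the reduction
is not an approximation.  Fitting paths use it for speed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, SimulationInstabilityError
from .intestine import (
    DEFAULT_L,
    DEFAULT_L0,
    DEFAULT_U_BAR,
    IntestineField,
    absorption_rate,
    inject_bolus,
    step_transport,
)
from .params import (
    ML_PER_M3,
    EmptyingHypothesis,
    FeedbackParams,
    MealSpec,
    RheologyParams,
    SecretionParams,
    SwitchMode,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Numerical grid: time step dt [s], horizon t_final [s], number of
    intestinal cells, and the stride (in steps) between saved samples."""

    dt: float = 1.0
    t_final: float = 7200.0
    n_cells: int = 150
    save_stride: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_final <= 0:
            raise ValueError("dt and t_final must be > 0")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")

    @property
    def n_steps(self) -> int:
        return max(1, int(math.ceil(self.t_final / self.dt - 1e-12)))

    @property
    def stride(self) -> int:
        if self.save_stride is not None:
            return max(1, self.save_stride)
        # aim for ~10 s output resolution, at most ~2000 samples
        return max(1, int(round(10.0 / self.dt)), self.n_steps // 2000)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to run one forward simulation."""

    meal: MealSpec
    feedback: FeedbackParams
    K_a: float = 0.0
    gamma_0: float | None = None
    hypothesis: EmptyingHypothesis | None = None
    secretion: SecretionParams | None = None
    rheology: RheologyParams = field(default_factory=RheologyParams)
    grid: GridSpec = field(default_factory=GridSpec)
    transport: str = "pde"
    L: float = DEFAULT_L
    u_bar: float = DEFAULT_U_BAR
    l_0: float = DEFAULT_L0
    auto_refine_dt: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.gamma_0 is None) == (self.hypothesis is None):
            raise ConfigurationError(
                "supply exactly one of gamma_0 (fixed) or hypothesis"
            )
        if self.gamma_0 is not None and self.gamma_0 < 0:
            raise ConfigurationError("gamma_0 must be >= 0")
        if self.K_a < 0:
            raise ConfigurationError("K_a must be >= 0")
        if self.transport not in ("pde", "lumped"):
            raise ConfigurationError("transport must be 'pde' or 'lumped'")
        if self.hypothesis is not None:
            needs = self.hypothesis.constant_names
            if ("m_mu" in needs or "m_sec" in needs) and self.secretion is None:
                if "m_sec" in needs:
                    raise ConfigurationError(
                        "secretion-rate hypotheses need SecretionParams"
                    )
        if self.transport == "lumped":
            transit = (self.L - self.l_0) / self.u_bar if self.u_bar > 0 else math.inf
            if self.grid.t_final > transit:
                raise ConfigurationError(
                    f"lumped transport valid only for t_final <= axial "
                    f"transit time {transit:g} s"
                )


@dataclass
class Trajectory:
    """Sampled output of one simulation.  All series share ``times`` [s]."""

    times: np.ndarray
    gastric_nutrient: np.ndarray
    gastric_liquid: np.ndarray
    gastric_thickener: np.ndarray
    viscosity: np.ndarray
    secretion_rate: np.ndarray
    emptying_rate: np.ndarray
    absorption_rate: np.ndarray
    intestinal_mass: np.ndarray
    cumulative_absorbed: np.ndarray
    cumulative_outflow: np.ndarray
    cumulative_secreted: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def gastric_total(self) -> np.ndarray:
        """Total gastric content Stom_tot [g]."""
        return self.gastric_nutrient + self.gastric_liquid + self.gastric_thickener

    def nutrient_balance_error(self) -> np.ndarray:
        """Relative error of the global nutrient budget at each sample."""
        n0 = self.meta.get("nutrient_mass_0", self.gastric_nutrient[0])
        if n0 == 0:
            return np.zeros_like(self.times)
        total = (
            self.gastric_nutrient
            + self.intestinal_mass
            + self.cumulative_absorbed
            + self.cumulative_outflow
        )
        return (total - n0) / n0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "gastric_nutrient_g": self.gastric_nutrient,
                "gastric_liquid_g": self.gastric_liquid,
                "gastric_thickener_g": self.gastric_thickener,
                "viscosity_Pa_s": self.viscosity,
                "secretion_rate_g_per_s": self.secretion_rate,
                "emptying_rate_per_s": self.emptying_rate,
                "absorption_rate_g_per_s": self.absorption_rate,
                "intestinal_mass_g": self.intestinal_mass,
                "cumulative_absorbed_g": self.cumulative_absorbed,
                "cumulative_outflow_g": self.cumulative_outflow,
                "cumulative_secreted_g": self.cumulative_secreted,
            }
        )


def _gamma0_coefficients(cfg: SimulationConfig) -> tuple[float, float, float, float]:
    """Every candidate law is a linear combination; return scalar
    coefficients (c_mu, c_V, c_sec, c_1) so that
    gamma0 = c_mu*mu + c_V*V_tot + c_sec*K_sec + c_1."""
    h = cfg.hypothesis
    return (
        h.m_mu or 0.0,
        h.m_s or 0.0,
        h.m_sec or 0.0,
        h.C1 or 0.0,
    )


def _run(cfg: SimulationConfig, dt: float) -> Trajectory:
    grid = replace(cfg.grid, dt=dt)
    n_steps, stride = grid.n_steps, grid.stride
    rho_w = cfg.rheology.rho_w

    stom_n = float(cfg.meal.nutrient_mass_0)
    stom_liq = float(cfg.meal.liquid_mass_0)
    stom_lbg = float(cfg.meal.thickener_mass_0)
    n0 = stom_n

    evolve_liquid = stom_liq > 0 or stom_lbg > 0 or cfg.secretion is not None
    use_intestine = stom_n > 0 and (cfg.K_a > 0 or cfg.u_bar > 0)
    lumped = cfg.transport == "lumped"

    # hoisted scalar constants for the inner loop
    a_L, b_L = cfg.rheology.a_L, cfg.rheology.b_L
    sec = cfg.secretion
    lam_s, b_exp, s_b = (sec.lambda_s, sec.b, sec.S_b) if sec else (0.0, 0.0, 0.0)
    fixed_g0 = cfg.gamma_0
    if fixed_g0 is None:
        c_mu, c_v, c_sec, c_1 = _gamma0_coefficients(cfg)
    fb = cfg.feedback
    brake_off = fb.disabled
    brake_logical = fb.mode is SwitchMode.LOGICAL
    a_max, tau_a = fb.A_max, fb.tau_A
    k_a = cfg.K_a
    exp, isfinite = math.exp, math.isfinite

    fld = None
    if use_intestine and not lumped:
        fld = IntestineField.empty(
            n_cells=grid.n_cells, L=cfg.L, u_bar=cfg.u_bar,
            K_a=cfg.K_a, l_0=cfg.l_0,
        )
        if dt > fld.max_stable_dt():
            raise SimulationInstabilityError(
                f"dt={dt:g} s violates transport stability "
                f"(max {fld.max_stable_dt():g} s)"
            )
    m_lumen = 0.0
    cum_abs = cum_out = cum_sec = 0.0

    n_saved = n_steps // stride + (1 if n_steps % stride else 0) + 1
    out = {
        k: np.empty(n_saved)
        for k in (
            "times", "gastric_nutrient", "gastric_liquid",
            "gastric_thickener", "viscosity", "secretion_rate",
            "emptying_rate", "absorption_rate", "intestinal_mass",
            "cumulative_absorbed", "cumulative_outflow",
            "cumulative_secreted",
        )
    }
    i_save = 0

    def instant():
        """Rates at the current state (start of a step); scalar math only,
        this runs every step."""
        if stom_liq > 0:
            c = 100.0 * rho_w * stom_lbg / stom_liq
            mu = a_L * c ** b_L
        else:
            mu = 0.0
        k_sec = lam_s * mu ** b_exp + s_b if sec is not None else 0.0
        if fixed_g0 is not None:
            g0 = fixed_g0
        else:
            v_tot = (stom_n + stom_liq + stom_lbg) / rho_w / ML_PER_M3
            g0 = c_mu * mu + c_v * v_tot + c_sec * k_sec + c_1
        if lumped or fld is None:
            a_rate = k_a * m_lumen
        else:
            a_rate = absorption_rate(fld)
        if brake_off:
            g = g0
        elif brake_logical:
            g = 0.0 if a_rate > a_max else g0
        else:
            x = tau_a * (a_rate - a_max)
            if x > 700.0:
                g = 0.0
            elif x < -700.0:
                g = g0
            else:
                g = g0 / (1.0 + exp(x))
        return mu, k_sec, g0, a_rate, g

    def save(t, mu, k_sec, a_rate, g):
        nonlocal i_save
        out["times"][i_save] = t
        out["gastric_nutrient"][i_save] = stom_n
        out["gastric_liquid"][i_save] = stom_liq
        out["gastric_thickener"][i_save] = stom_lbg
        out["viscosity"][i_save] = mu
        out["secretion_rate"][i_save] = k_sec
        out["emptying_rate"][i_save] = g
        out["absorption_rate"][i_save] = a_rate
        out["intestinal_mass"][i_save] = (
            m_lumen if (lumped or fld is None) else fld.total_mass()
        )
        out["cumulative_absorbed"][i_save] = cum_abs
        out["cumulative_outflow"][i_save] = cum_out
        out["cumulative_secreted"][i_save] = cum_sec
        i_save += 1

    t = 0.0
    for k in range(n_steps):
        mu, k_sec, g0, a_rate, g = instant()
        if k % stride == 0:
            save(t, mu, k_sec, a_rate, g)
        emptied = g * stom_n * dt
        stom_n -= emptied
        if evolve_liquid:
            stom_liq += dt * k_sec - g * stom_liq * dt
            stom_lbg -= g * stom_lbg * dt
            cum_sec += dt * k_sec
        if use_intestine:
            if lumped:
                m_post = m_lumen + emptied
                absorbed = dt * k_a * m_post
                m_lumen = m_post - absorbed
                cum_abs += absorbed
            else:
                inject_bolus(fld, emptied, inplace=True)
                fld, absorbed, outflow = step_transport(fld, dt, inplace=True)
                cum_abs += absorbed
                cum_out += outflow
        t += dt
        bad = (
            stom_n < 0 or stom_liq < 0 or stom_lbg < 0
            or not isfinite(stom_n + stom_liq + stom_lbg)
            or (lumped and (m_lumen < 0 or not isfinite(m_lumen)))
            or (fld is not None and k % 64 == 0
                and (np.any(fld.densities < 0)
                     or not np.all(np.isfinite(fld.densities))))
        )
        if bad:
            raise SimulationInstabilityError(
                f"negative mass or NaN at t={t:g} s with dt={dt:g} s; "
                f"reduce the time step"
            )
    if fld is not None and (
        np.any(fld.densities < 0) or not np.all(np.isfinite(fld.densities))
    ):
        raise SimulationInstabilityError(
            f"negative density or NaN in the intestinal field with "
            f"dt={dt:g} s; reduce the time step"
        )
    mu, k_sec, g0, a_rate, g = instant()
    save(t, mu, k_sec, a_rate, g)

    meta = {
        "dt": dt, "n_steps": n_steps, "nutrient_mass_0": n0,
        "liquid_mass_0": cfg.meal.liquid_mass_0,
        "thickener_mass_0": cfg.meal.thickener_mass_0,
        "transport": cfg.transport if use_intestine else "none",
    }
    return Trajectory(meta=meta, **out)


def simulate(cfg: SimulationConfig) -> Trajectory:
    """Run the coupled model and return the sampled :class:`Trajectory`.

    On numerical instability (negative mass / NaN) the step is halved and
    the run retried, up to 8 refinements, when ``auto_refine_dt`` is set;
    otherwise :class:`SimulationInstabilityError` propagates.
    """
    dt = cfg.grid.dt
    attempts = 9 if cfg.auto_refine_dt else 1
    last_err: Exception | None = None
    for _ in range(attempts):
        try:
            return _run(cfg, dt)
        except SimulationInstabilityError as err:
            last_err = err
            dt /= 2.0
            logger.info("refining time step to dt=%g s after instability", dt)
    raise last_err  # type: ignore[misc]


def simulate_secretion_batch(
    liq0: np.ndarray,
    lbg0: np.ndarray,
    secretion: SecretionParams,
    hypothesis: EmptyingHypothesis,
    rheology: RheologyParams | None = None,
    dt: float = 5.0,
    t_final: float = 5400.0,
    save_stride: int = 1,
) -> dict[str, np.ndarray]:
    """Vectorised non-nutrient gastric simulation for several meals at once.

    With no nutrient there is no brake and no intestinal coupling; only
    the liquid/thickener pair evolves, with gamma = gamma0 from the
    hypothesis.  Returns arrays of shape (n_samples, n_meals) for
    ``stomtot``, ``viscosity``, ``secretion``, ``cumulative_secreted``
    plus the 1-D ``times``.  This is the inner loop of the secretion-model
    objective, so it stays allocation-light.
    """
    rheo = rheology or RheologyParams()
    liq = np.array(liq0, dtype=float)
    lbg = np.array(lbg0, dtype=float)
    if liq.shape != lbg.shape:
        raise ValueError("liq0 and lbg0 must have matching shapes")
    a_L, b_L, rho_w = rheo.a_L, rheo.b_L, rheo.rho_w
    lam_s, b_exp, s_b = secretion.lambda_s, secretion.b, secretion.S_b
    c_mu = hypothesis.m_mu or 0.0
    c_v = hypothesis.m_s or 0.0
    c_sec = hypothesis.m_sec or 0.0
    c_1 = hypothesis.C1 or 0.0
    c_v_mass = c_v / (rho_w * ML_PER_M3)
    conc_fac = 100.0 * rho_w
    n_steps = max(1, int(math.ceil(t_final / dt - 1e-12)))
    save_idx = list(range(0, n_steps, save_stride)) + [n_steps]
    n_saved = len(save_idx)
    n_meals = liq.size
    shape = (n_saved, n_meals)
    times = dt * np.asarray(save_idx, dtype=float)
    stomtot = np.empty(shape)
    visc = np.empty(shape)
    sec = np.empty(shape)
    cum = np.empty(shape)
    liq_flat, lbg_flat = liq.ravel(), lbg.ravel()
    isfinite = math.isfinite
    for i in range(n_meals):
        lq, lb, cs = liq_flat[i], lbg_flat[i], 0.0
        i_save = 0
        nxt = save_idx[i_save]
        for k in range(n_steps + 1):
            c = conc_fac * lb / lq
            mu = a_L * c ** b_L
            k_sec = lam_s * mu ** b_exp + s_b
            if k == nxt:
                stomtot[i_save, i] = lq + lb
                visc[i_save, i] = mu
                sec[i_save, i] = k_sec
                cum[i_save, i] = cs
                i_save += 1
                nxt = save_idx[i_save] if i_save < n_saved else -1
            if k == n_steps:
                break
            g = c_mu * mu + c_v_mass * (lq + lb) + c_sec * k_sec + c_1
            lq = lq + dt * (k_sec - g * lq)
            lb = lb - dt * g * lb
            cs = cs + dt * k_sec
            if lq < 0 or lb < 0 or not isfinite(lq + lb):
                raise SimulationInstabilityError(
                    f"negative mass or NaN at t={k * dt:g} s with dt={dt:g} s"
                )
    return {
        "times": times, "stomtot": stomtot, "viscosity": visc,
        "secretion": sec, "cumulative_secreted": cum,
    }


# -- summary statistics ----------------------------------------------------

TOTAL_CONTENT = "total"
NUTRIENT_ONLY = "nutrient"


def half_time(tr: Trajectory, which: str = TOTAL_CONTENT) -> float:
    """First time [s] the chosen gastric series falls to half its initial
    value, linearly interpolated; NaN when the series never crosses."""
    if which == TOTAL_CONTENT:
        series = tr.gastric_total
    elif which == NUTRIENT_ONLY:
        series = tr.gastric_nutrient
    else:
        raise ValueError("which must be 'total' or 'nutrient'")
    return crossing_time(tr.times, series, 0.5 * series[0])


def crossing_time(times: np.ndarray, series: np.ndarray,
                  target: float) -> float:
    """First downward crossing of ``series`` through ``target``,
    interpolated; NaN if the crossing never happens."""
    below = series <= target
    if series[0] <= target:
        return float(times[0])
    idx = np.argmax(below)
    if not below[idx]:
        return math.nan
    t0, t1 = times[idx - 1], times[idx]
    y0, y1 = series[idx - 1], series[idx]
    if y0 == y1:
        return float(t1)
    return float(t0 + (y0 - target) / (y0 - y1) * (t1 - t0))


def caloric_delivery_rate(tr: Trajectory, window: tuple[float, float]) -> float:
    """Time-averaged absorption rate A(t) [g/s] over ``window`` [s]."""
    t1, t2 = window
    if not (t1 < t2):
        raise ValueError("window must satisfy t1 < t2")
    mask = (tr.times >= t1) & (tr.times <= t2)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than two samples")
    t = tr.times[mask]
    a = tr.absorption_rate[mask]
    return float(np.trapezoid(a, t) / (t[-1] - t[0]))
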