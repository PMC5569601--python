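"""Parameter estimation and model selection.

Two fitting problems are supported:

* the duodenal-brake model against gastric nutrient curves — bounded
  nonlinear least squares over (gamma0, A_max, K_a, StomN0) or any
  subset, minimising the unweighted sum of squared mass residuals;
* the secretion model against panels of non-nutrient meals — a composite
  objective summing squared viscosity residuals normalised by each
  meal's initial viscosity plus twice the squared mismatch between half
  the initial liquid load and the simulated total content at the
  measured half-time:

      Obj = sum_ij ((mu_exp - mu_sim)/mu0_i)^2
          + sum_i 2*(0.5 - Stomtot(t_half_i)/liq0_i)^2

Model ranking across the five candidate emptying-rate laws uses the
Akaike information criterion AIC = n*ln(SSE/n) + 2p and relative
likelihoods exp((AIC_min - AIC_i)/2).

Fits run in log10 parameter space (all parameters are positive physical
rates) with a bounded trust-region least-squares solver and seeded
multi-start, because the brake makes the objective piecewise smooth.
The smooth sigmoid switch is used during fitting; simulation defaults to
the logical switch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, SimulationInstabilityError
from .observations import (
    GASTRIC_FRACTION,
    GASTRIC_MASS,
    VISCOSITY,
    ObservationSet,
)
from .params import (
    EmptyingHypothesis,
    HypothesisForm,
    RheologyParams,
    SecretionParams,
    SwitchMode,
    _FORM_CONSTANTS,
)
from .simulate import (
    GridSpec,
    SimulationConfig,
    simulate,
    simulate_secretion_batch,
)

__all__ = [
    "FitResult",
    "aic",
    "relative_likelihood",
    "fit_feedback_model",
    "composite_secretion_objective",
    "fit_secretion_model",
    "select_emptying_hypothesis",
]


# -- information criteria --------------------------------------------------

def aic(sse: float, n: int, p: int) -> float:
    """Akaike information criterion n*ln(SSE/n) + 2p.

    A perfect fit (SSE = 0) returns -inf with a warning, as the
    log-likelihood term is unbounded below.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if p < 0:
        raise ValueError("p must be >= 0")
    if sse < 0:
        raise ValueError("sse must be >= 0")
    if sse == 0:
        warnings.warn("SSE is zero; AIC is -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    return n * math.log(sse / n) + 2 * p


def relative_likelihood(aic_i: float, aic_min: float) -> float:
    """exp((AIC_min - AIC_i)/2), the likelihood of model i relative to the
    best model; 1 for the best model itself."""
    return math.exp((aic_min - aic_i) / 2.0)


# -- results ---------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of one bounded least-squares fit."""

    params: dict[str, float]
    sse: float
    n: int
    p: int
    residuals: np.ndarray
    bounds: dict[str, tuple[float, float]]
    success: bool = True
    message: str = ""
    flags: list[str] = field(default_factory=list)
    seed: int | None = None
    n_starts: int = 1
    provenance: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return aic(self.sse, self.n, self.p)

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "sse": self.sse,
            "n": self.n,
            "p": self.p,
            "aic": self.aic,
            "success": self.success,
            "message": self.message,
            "flags": list(self.flags),
            "seed": self.seed,
            "n_starts": self.n_starts,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "provenance": dict(self.provenance),
        }


# -- shared multistart machinery ------------------------------------------

def _multistart(residual_fn, names, bounds, starts, max_nfev=200,
                diff_step=0.02, ftol=1e-8, xtol=1e-8):
    """Bounded least squares in log10 space from several starts; returns
    (best_x_linear, best_residuals, success, message)."""
    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])

    def res_log(x):
        return residual_fn(10.0 ** x)

    best = None
    any_success = False
    message = ""
    for x0 in starts:
        x0 = np.clip(np.log10(x0), lo, hi)
        try:
            sol = least_squares(
                res_log, x0, bounds=(lo, hi), method="trf",
                diff_step=diff_step, max_nfev=max_nfev,
                ftol=ftol, xtol=xtol,
            )
        except (SimulationInstabilityError, FloatingPointError) as err:
            message = str(err)
            continue
        sse = float(sol.cost * 2.0)
        if best is None or sse < best[0]:
            best = (sse, 10.0 ** sol.x, sol.fun, sol.status > 0, sol.message)
        any_success = any_success or sol.status > 0
    if best is None:
        raise RuntimeError(f"all starts failed: {message}")
    return best[1], best[2], best[3] and any_success, best[4]


def _log_uniform_starts(rng, names, bounds, n_random):
    starts = []
    for _ in range(n_random):
        starts.append(
            np.array(
                [
                    10.0 ** rng.uniform(math.log10(bounds[n][0]),
                                        math.log10(bounds[n][1]))
                    for n in names
                ]
            )
        )
    return starts


# -- duodenal-brake model fitting -----------------------------------------

FEEDBACK_FREE_DEFAULT = ("gamma_0", "A_max", "K_a", "StomN0")


def _feedback_config(template: SimulationConfig, values: dict[str, float],
                     dt: float, t_final: float,
                     tau_A: float | None = None) -> SimulationConfig:
    meal = template.meal
    if "StomN0" in values:
        meal = replace(meal, nutrient_mass_0=max(values["StomN0"], 0.0))
    fb = template.feedback
    if "A_max" in values:
        fb = replace(fb, A_max=max(values["A_max"], 1e-30))
    fb = replace(fb, mode=SwitchMode.SMOOTH,
                 tau_A=tau_A if tau_A is not None else fb.tau_A)
    return replace(
        template,
        meal=meal,
        feedback=fb,
        gamma_0=max(values.get("gamma_0", template.gamma_0), 0.0)
        if template.gamma_0 is not None else None,
        K_a=max(values.get("K_a", template.K_a), 0.0),
        transport="lumped",
        grid=GridSpec(dt=dt, t_final=t_final, save_stride=1),
        auto_refine_dt=True,
    )


def _template_value(template: SimulationConfig, name: str) -> float:
    if name == "gamma_0":
        if template.gamma_0 is None:
            raise ConfigurationError(
                "fitting gamma_0 requires a fixed-gamma_0 template"
            )
        return template.gamma_0
    if name == "A_max":
        if template.feedback.disabled:
            raise ConfigurationError(
                "fitting A_max requires a finite A_max in the template"
            )
        return template.feedback.A_max
    if name == "K_a":
        return template.K_a
    if name == "StomN0":
        return template.meal.nutrient_mass_0
    raise ConfigurationError(
        f"unknown free parameter '{name}'; valid: {FEEDBACK_FREE_DEFAULT}"
    )


def fit_feedback_model(
    data: ObservationSet,
    template: SimulationConfig,
    free: tuple[str, ...] = FEEDBACK_FREE_DEFAULT,
    bounds: dict[str, tuple[float, float]] | None = None,
    x0: dict[str, float] | None = None,
    n_starts: int = 10,
    seed: int | None = 0,
    experiment: str | None = None,
    dt: float = 1.0,
) -> FitResult:
    """Fit the brake model to a gastric nutrient (or fraction) series.

    ``template`` supplies every fixed quantity; the parameters named in
    ``free`` are released.  The first start is ``x0`` (or the template
    values); the rest are log-uniform draws inside the bounds, seeded.

    Because the hard switch makes the objective piecewise flat in
    (A_max, K_a) whenever the brake never engages, every start is taken
    through a continuation ladder in the switch sharpness: the sigmoid is
    first fitted soft (tau_A = 5e2 s/g), then progressively sharpened to
    the template's tau_A, warm-starting each stage.  Optimizer
    non-convergence is reported in the result flags, never raised.
    """
    free = tuple(free)
    t_obs, obs, _ = data.series(GASTRIC_MASS, experiment)
    kind = GASTRIC_MASS
    if t_obs.size == 0:
        t_obs, obs, _ = data.series(GASTRIC_FRACTION, experiment)
        kind = GASTRIC_FRACTION
    if t_obs.size == 0:
        raise ConfigurationError("no gastric mass/fraction observations")
    if t_obs.size < len(free):
        raise ConfigurationError(
            f"{t_obs.size} data points cannot constrain {len(free)} "
            f"free parameters"
        )

    template_vals = {name: _template_value(template, name) for name in free}
    default_bounds = {}
    for name, v in template_vals.items():
        if name == "StomN0":
            default_bounds[name] = (0.3 * v, 3.0 * v)
        else:
            default_bounds[name] = (v / 10.0, v * 10.0)
    if bounds:
        default_bounds.update(bounds)
    bnds = default_bounds
    t_final = float(t_obs.max())

    def residual_fn(tau_A):
        def residual(theta: np.ndarray) -> np.ndarray:
            values = dict(zip(free, theta))
            cfg = _feedback_config(template, values, dt, t_final, tau_A)
            tr = simulate(cfg)
            sim = np.interp(t_obs, tr.times, tr.gastric_nutrient)
            if kind == GASTRIC_FRACTION:
                sim = sim / cfg.meal.nutrient_mass_0
            return sim - obs
        return residual

    tau_final = template.feedback.tau_A
    ladder = [(t, s) for t, s in ((5e2, 0.05), (5e3, 0.02), (5e4, 0.02))
              if t < tau_final] + [(tau_final, 0.01)]

    rng = np.random.default_rng(seed)
    first = np.array([(x0 or template_vals)[n] for n in free])
    starts = [first] + _log_uniform_starts(rng, free, bnds,
                                           max(0, n_starts - 1))
    lo = np.log10([bnds[n][0] for n in free])
    hi = np.log10([bnds[n][1] for n in free])
    best = None
    any_success = False
    for start in starts:
        x = np.clip(np.log10(start), lo, hi)
        sol = None
        try:
            for tau_A, diff_step in ladder:
                res = residual_fn(tau_A)
                sol = least_squares(
                    lambda z: res(10.0 ** z), x, bounds=(lo, hi),
                    method="trf", diff_step=diff_step, max_nfev=100,
                )
                x = sol.x
        except SimulationInstabilityError:
            continue
        sse_i = float(sol.cost * 2.0)
        any_success = any_success or sol.status > 0
        if best is None or sse_i < best[0]:
            best = (sse_i, 10.0 ** sol.x, sol.fun, sol.status > 0, sol.message)
    if best is None:
        raise RuntimeError("all fit starts failed with instabilities")
    sse, theta, resid, success, message = best
    success = success and any_success
    params = dict(zip(free, theta))

    flags = []
    if not success:
        flags.append("optimizer did not converge; best-so-far returned")
    # identifiability check: does the brake ever engage at the optimum?
    cfg_best = _feedback_config(template, params, dt, t_final)
    tr_best = simulate(cfg_best)
    if (
        "A_max" in params
        and float(tr_best.absorption_rate.max()) < 0.95 * cfg_best.feedback.A_max
    ):
        flags.append("A_max unidentifiable: brake never engages at optimum")

    return FitResult(
        params=params,
        sse=sse,
        n=int(t_obs.size),
        p=len(free),
        residuals=resid,
        bounds=bnds,
        success=success,
        message=str(message),
        flags=flags,
        seed=seed,
        n_starts=len(starts),
        provenance={
            "experiment": experiment or data.experiments[0],
            "kind": kind,
            "objective": "unweighted SSE of gastric content",
        },
    )


# -- secretion model fitting ----------------------------------------------

_SECRETION_BOUNDS: dict[str, tuple[float, float]] = {
    "m_mu": (1e-6, 1e-1),
    "m_s": (1e-3, 1e3),
    "m_sec": (1e-5, 1e-1),
    "C1": (1e-6, 1e-2),
    "lambda_s": (1e-4, 1.0),
    "b": (0.05, 4.0),
    "S_b": (1e-4, 0.1),
}


def _require_meta(data: ObservationSet, exp: str, key: str) -> float:
    meta = data.meta.get(exp, {})
    if key not in meta or meta[key] is None:
        raise ConfigurationError(
            f"experiment '{exp}' is missing required metadata '{key}'"
        )
    return float(meta[key])


def secretion_residuals(
    hypothesis: EmptyingHypothesis,
    secretion: SecretionParams,
    data: ObservationSet,
    rheology: RheologyParams | None = None,
    dt: float = 5.0,
) -> np.ndarray:
    """Residual vector whose squared sum is the composite objective.

    Components: normalised viscosity residuals (mu_sim - mu_exp)/mu0_i at
    every sampling point, then sqrt(2)*(0.5 - Stomtot(t_half_i)/liq0_i)
    per experiment.
    """
    from .synthetic import lbg_for_viscosity

    rheo = rheology or RheologyParams()
    exps = data.experiments
    exps += [e for e in data.meta if e not in exps]
    mu0 = np.array([_require_meta(data, e, "mu0") for e in exps])
    liq0 = np.array([_require_meta(data, e, "liq0") for e in exps])
    t_half = np.array([_require_meta(data, e, "half_time_s") for e in exps])
    lbg0 = np.array(
        [
            data.meta[e].get("lbg0") or lbg_for_viscosity(m, l, rheo)
            for e, m, l in zip(exps, mu0, liq0)
        ]
    )
    t_obs_max = data.frame["time_s"].max() if len(data.frame) else 0.0
    t_max = float(max(t_half.max(), t_obs_max) * 1.05)
    res = simulate_secretion_batch(
        liq0, lbg0, secretion, hypothesis, rheo, dt=dt, t_final=t_max
    )
    parts = []
    half_terms = []
    for i, exp in enumerate(exps):
        t_obs, mu_exp, _ = data.series(VISCOSITY, exp)
        if t_obs.size:
            mu_sim = np.interp(t_obs, res["times"], res["viscosity"][:, i])
            parts.append((mu_sim - mu_exp) / mu0[i])
        tot_at_half = np.interp(t_half[i], res["times"], res["stomtot"][:, i])
        half_terms.append(math.sqrt(2.0) * (0.5 - tot_at_half / liq0[i]))
    parts.append(np.asarray(half_terms))
    return np.concatenate(parts)


def composite_secretion_objective(
    hypothesis: EmptyingHypothesis,
    secretion: SecretionParams,
    data: ObservationSet,
    rheology: RheologyParams | None = None,
    dt: float = 5.0,
) -> float:
    """The scalar composite objective (see module docstring); zero iff the
    model reproduces every normalised viscosity sample and passes exactly
    through half content at each measured half-time."""
    r = secretion_residuals(hypothesis, secretion, data, rheology, dt)
    return float(np.dot(r, r))


def _secretion_param_names(form: HypothesisForm) -> tuple[str, ...]:
    return _FORM_CONSTANTS[form] + ("lambda_s", "b", "S_b")


def _informed_secretion_start(form, names, bnds, data, rheology):
    """Data-driven start: the observed half-times imply an overall
    gamma0 ~ ln2/t_half; split it evenly between the two terms of the
    candidate law, with secretion parameters at the bound centres."""
    exps = data.experiments
    t_half = np.array([_require_meta(data, e, "half_time_s") for e in exps])
    mu0 = np.array([_require_meta(data, e, "mu0") for e in exps])
    liq0 = np.array([_require_meta(data, e, "liq0") for e in exps])
    g_target = math.log(2.0) / float(np.mean(t_half))
    mu_ref = float(np.mean(mu0))
    rho_w = (rheology or RheologyParams()).rho_w
    v_ref = float(np.mean(liq0)) / rho_w / 1e6  # m^3
    lam = math.sqrt(bnds["lambda_s"][0] * bnds["lambda_s"][1])
    b_c = math.sqrt(bnds["b"][0] * bnds["b"][1])
    s_b = math.sqrt(bnds["S_b"][0] * bnds["S_b"][1])
    k_ref = lam * mu_ref ** b_c + s_b
    half = 0.5 * g_target
    guess = {
        "m_mu": half / max(mu_ref, 1e-12),
        "m_s": half / max(v_ref, 1e-12),
        "m_sec": half / max(k_ref, 1e-12),
        "C1": half,
        "lambda_s": lam,
        "b": b_c,
        "S_b": s_b,
    }
    return np.array([guess[n] for n in names])


def fit_secretion_model(
    data: ObservationSet,
    form: HypothesisForm,
    bounds: dict[str, tuple[float, float]] | None = None,
    x0: dict[str, float] | None = None,
    n_starts: int = 8,
    seed: int | None = 0,
    rheology: RheologyParams | None = None,
    dt: float = 5.0,
    max_nfev: int = 120,
) -> FitResult:
    """Fit one emptying-rate hypothesis (plus the secretion law) to a
    non-nutrient viscosity/half-time panel with the composite objective.

    Starts: the user's ``x0`` if given, a data-informed start (the two
    gamma0 constants sized so each contributes half of ln2/t_half), the
    geometric centre of the bounds, then seeded log-uniform draws.
    """
    names = _secretion_param_names(form)
    bnds = dict(_SECRETION_BOUNDS)
    if bounds:
        bnds.update(bounds)
    bnds = {n: bnds[n] for n in names}

    def residual(theta: np.ndarray) -> np.ndarray:
        values = dict(zip(names, theta))
        hyp = EmptyingHypothesis(
            form=form,
            **{k: values[k] for k in _FORM_CONSTANTS[form]},
        )
        sec = SecretionParams(
            lambda_s=values["lambda_s"], b=values["b"], S_b=values["S_b"]
        )
        try:
            return secretion_residuals(hyp, sec, data, rheology, dt)
        except SimulationInstabilityError:
            return np.full(_residual_size(data), 1e3)

    rng = np.random.default_rng(seed)
    starts = []
    if x0 is not None:
        starts.append(np.array([x0[n] for n in names]))
    starts.append(_informed_secretion_start(form, names, bnds, data, rheology))
    geo = np.array([math.sqrt(bnds[n][0] * bnds[n][1]) for n in names])
    starts.append(geo)
    starts += _log_uniform_starts(rng, names, bnds,
                                  max(0, n_starts - len(starts)))
    theta, resid, success, message = _multistart(
        residual, names, bnds, starts, max_nfev=max_nfev
    )
    params = dict(zip(names, theta))
    sse = float(np.dot(resid, resid))
    return FitResult(
        params=params,
        sse=sse,
        n=int(resid.size),
        p=len(names),
        residuals=resid,
        bounds=bnds,
        success=success,
        message=str(message),
        flags=[] if success else ["optimizer did not converge"],
        seed=seed,
        n_starts=len(starts),
        provenance={"form": form.name, "objective": "composite (viscosity + half-time)"},
    )


def _residual_size(data: ObservationSet) -> int:
    n_visc = data.n_points(VISCOSITY)
    return n_visc + len(data.experiments)


def select_emptying_hypothesis(
    data: ObservationSet,
    forms: tuple[HypothesisForm, ...] = tuple(HypothesisForm),
    n_starts: int = 8,
    seed: int | None = 0,
    **kwargs,
) -> list[tuple[HypothesisForm, FitResult | None, float]]:
    """Fit every candidate emptying law on the same panel and rank by AIC.

    Returns (form, FitResult, relative_likelihood) triples sorted by AIC
    ascending.  A failed fit is kept at the end of the list with a None
    result and zero likelihood.
    """
    if len(forms) < 1:
        raise ValueError("need at least one hypothesis form")
    fits: list[tuple[HypothesisForm, FitResult | None]] = []
    for i, form in enumerate(forms):
        sub_seed = None if seed is None else seed + 1000 * i
        try:
            fits.append(
                (form, fit_secretion_model(data, form, n_starts=n_starts,
                                           seed=sub_seed, **kwargs))
            )
        except Exception as err:  # individual failure recorded, not fatal
            warnings.warn(f"fit failed for {form.name}: {err}", RuntimeWarning)
            fits.append((form, None))
    ok = [(f, r) for f, r in fits if r is not None]
    ok.sort(key=lambda fr: fr[1].aic)
    aic_min = ok[0][1].aic if ok else math.nan
    ranked = [
        (f, r, relative_likelihood(r.aic, aic_min)) for f, r in ok
    ] + [(f, None, 0.0) for f, r in fits if r is None]
    return ranked
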