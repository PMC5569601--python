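"""Noise-injection Monte-Carlo assessment of parameter estimates.

The observations are perturbed with seeded random noise whose per-point
scale comes from the replicate standard deviations, the model is re-fit
on each perturbed set, and the spread of the re-fitted parameters gives
empirical means, standard deviations and mean +/- 2*sd bounds for
downstream estimation.

Noise law: uniform on [-sd, +sd] by default (the scales are quoted as
maximum deviations from the mean), Gaussian with standard deviation sd
as an option.  Perturbed values are floored at zero since all observed
quantities are masses or viscosities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .estimation import FitResult
from .observations import ObservationSet

NOISE_UNIFORM = "uniform"
NOISE_GAUSSIAN = "gaussian"


@dataclass
class MonteCarloResult:
    """Per-parameter samples over iterations plus summary statistics."""

    samples: pd.DataFrame
    means: dict[str, float]
    sds: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    n_iter: int
    n_failed: int
    seed: int | None
    baseline: FitResult | None = field(default=None, repr=False)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.samples.columns)


def bounds_from_samples(
    samples: pd.DataFrame | dict[str, np.ndarray],
    floor_at_zero: bool = False,
) -> dict[str, tuple[float, float]]:
    """mean +/- 2*sample-sd per parameter (sd with ddof=1).

    ``floor_at_zero`` clips the lower bound at 0 for physical rates;
    off by default.  Requires at least two samples.
    """
    frame = pd.DataFrame(samples)
    if len(frame) < 2:
        raise ValueError("need at least 2 samples to form bounds")
    out = {}
    for name in frame.columns:
        x = frame[name].to_numpy(float)
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
        if floor_at_zero:
            lo = max(lo, 0.0)
        out[name] = (lo, hi)
    return out


def _perturb(data: ObservationSet, rng: np.random.Generator,
             noise_model: str, scale: float) -> ObservationSet:
    sd = data.frame["sd"].to_numpy(float)
    sd = np.where(np.isfinite(sd), sd, 0.0) * scale
    if noise_model == NOISE_UNIFORM:
        delta = rng.uniform(-sd, sd)
    elif noise_model == NOISE_GAUSSIAN:
        delta = rng.normal(0.0, 1.0, sd.shape) * sd
    else:
        raise ValueError(
            f"unknown noise model '{noise_model}'; use "
            f"'{NOISE_UNIFORM}' or '{NOISE_GAUSSIAN}'"
        )
    values = np.clip(data.frame["value"].to_numpy(float) + delta, 0.0, None)
    return data.with_values(values)


def run_monte_carlo(
    data: ObservationSet,
    fit_fn: Callable[[ObservationSet, dict | None], FitResult],
    noise_model: str = NOISE_UNIFORM,
    n_iter: int = 5000,
    seed: int | None = 0,
    warm_start: bool = True,
    noise_scale: float = 1.0,
) -> MonteCarloResult:
    """Perturb -> re-fit -> collect, ``n_iter`` times, deterministically
    for a given seed.

    ``fit_fn(data, x0)`` must fit the model to an observation set,
    optionally warm-starting from the parameter dict ``x0``.  The
    unperturbed optimum is computed first and used as the warm start of
    every iteration (cold starts with ``warm_start=False``).  Iterations
    whose fit raises are recorded in ``n_failed`` and excluded.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not np.isfinite(data.frame["sd"]).any():
        raise ValueError("observation set carries no noise scales (sd)")
    rng = np.random.default_rng(seed)
    baseline = fit_fn(data, None)
    records = []
    n_failed = 0
    for _ in range(n_iter):
        perturbed = _perturb(data, rng, noise_model, noise_scale)
        try:
            fit = fit_fn(perturbed, dict(baseline.params) if warm_start else None)
        except Exception:
            n_failed += 1
            continue
        records.append(dict(fit.params))
    samples = pd.DataFrame(records)
    means = {k: float(samples[k].mean()) for k in samples.columns}
    if len(samples) >= 2:
        sds = {k: float(samples[k].std(ddof=1)) for k in samples.columns}
        bounds = bounds_from_samples(samples)
    else:
        sds = {k: 0.0 for k in samples.columns}
        bounds = {k: (means[k], means[k]) for k in samples.columns}
    return MonteCarloResult(
        samples=samples,
        means=means,
        sds=sds,
        bounds=bounds,
        n_iter=n_iter,
        n_failed=n_failed,
        seed=seed,
        baseline=baseline,
    )
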