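"""Fitting, composite objective, information criteria, model ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from gastrosim import (
    HypothesisForm,
    aic,
    composite_secretion_objective,
    fit_feedback_model,
    relative_likelihood,
)
from gastrosim.errors import ConfigurationError
from gastrosim.estimation import secretion_residuals
from gastrosim.observations import GASTRIC_MASS, ObservationSet
from gastrosim.synthetic import (
    generate_dataset,
    nonnutrient_viscosity_set,
    secretion_optimum,
    table1_preset,
)


class TestAic:
    def test_unit_sse_per_point(self):
        assert aic(sse=10.0, n=10, p=1) == 2.0

    def test_log_term(self):
        assert aic(sse=10 * math.e, n=10, p=0) == pytest.approx(10.0)

    def test_parameter_penalty_is_two_per_parameter(self):
        base = aic(3.7, 25, 2)
        assert aic(3.7, 25, 3) == pytest.approx(base + 2.0)

    def test_zero_sse_sentinel(self):
        with pytest.warns(RuntimeWarning):
            assert aic(0.0, 5, 1) == -math.inf

    @pytest.mark.parametrize("bad", [dict(sse=1, n=0, p=1),
                                     dict(sse=-1, n=5, p=1),
                                     dict(sse=1, n=5, p=-1)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            aic(**bad)


class TestRelativeLikelihood:
    def test_equal_models(self):
        assert relative_likelihood(12.3, 12.3) == 1.0

    def test_delta_two_is_inverse_e(self):
        assert relative_likelihood(2.0, 0.0) == pytest.approx(math.exp(-1))

    def test_delta_for_ninety_percent(self):
        # delta AIC ~ 0.211 corresponds to a 0.9 likelihood ratio
        assert relative_likelihood(0.2107, 0.0) == pytest.approx(0.9, abs=1e-3)


class TestCompositeObjective:
    def test_self_score_is_zero(self):
        hyp, sec = secretion_optimum()
        data = nonnutrient_viscosity_set([2.0, 11.0], noise_sigma=0.0, dt=10)
        assert composite_secretion_objective(hyp, sec, data, dt=10) == 0.0

    def test_half_time_term_value(self):
        """With no viscosity rows and a 'measured' half-time where the
        simulated content is 60% of liq0, the objective is 2*(0.1)^2."""
        from gastrosim.simulate import simulate_secretion_batch
        from gastrosim.synthetic import lbg_for_viscosity

        hyp, sec = secretion_optimum()
        liq0, mu0 = 500.0, 2.0
        lbg0 = lbg_for_viscosity(mu0, liq0)
        res = simulate_secretion_batch(np.array([liq0]), np.array([lbg0]),
                                       sec, hyp, dt=5.0, t_final=3600.0)
        t_60pct = float(np.interp(-0.6 * liq0, -res["stomtot"][:, 0],
                                  res["times"]))
        frame = pd.DataFrame(
            {"experiment": ["m1"], "time_s": [0.0], "value": [mu0],
             "kind": ["viscosity"]}
        )
        data = ObservationSet(
            frame.iloc[:0],  # no viscosity rows
            {"m1": {"mu0": mu0, "liq0": liq0, "lbg0": lbg0,
                    "half_time_s": t_60pct}},
        )
        obj = composite_secretion_objective(hyp, sec, data, dt=5.0)
        assert obj == pytest.approx(2 * 0.1 ** 2, rel=1e-3)

    def test_quadratic_in_viscosity_residuals(self):
        hyp, sec = secretion_optimum()
        data = nonnutrient_viscosity_set([2.0, 11.0], seed=5,
                                         noise_sigma=0.15, dt=10)
        r = secretion_residuals(hyp, sec, data, dt=10)
        n_visc = data.n_points("viscosity")
        visc_term = float(r[:n_visc] @ r[:n_visc])
        # doubling every viscosity residual quadruples that term
        assert 4 * visc_term == pytest.approx((2 * r[:n_visc]) @ (2 * r[:n_visc]))
        assert visc_term > 0

    def test_missing_metadata_rejected(self):
        hyp, sec = secretion_optimum()
        data = nonnutrient_viscosity_set([2.0], noise_sigma=0.0, dt=10)
        del data.meta["NN_2"]["liq0"]
        with pytest.raises(ConfigurationError, match="liq0"):
            composite_secretion_objective(hyp, sec, data, dt=10)


class TestFeedbackFit:
    def test_too_few_points_rejected(self):
        p = table1_preset("e")
        frame = pd.DataFrame(
            {"experiment": "x", "time_s": [600.0], "value": [20.0],
             "kind": GASTRIC_MASS}
        )
        with pytest.raises(ConfigurationError, match="points"):
            fit_feedback_model(ObservationSet(frame), p.config,
                               free=("gamma_0", "A_max", "K_a", "StomN0"))

    def test_pure_exponential_recovers_rate_and_flags_amax(self):
        """Brake-free data: gamma_0 converges to the decay rate and A_max
        is flagged unidentifiable."""
        r = 1.1e-3
        t = 60.0 * np.arange(5, 65, 5, dtype=float)
        frame = pd.DataFrame(
            {"experiment": "exp", "time_s": t,
             "value": 24.74 * np.exp(-r * t), "kind": GASTRIC_MASS}
        )
        p = table1_preset("e")
        fit = fit_feedback_model(
            ObservationSet(frame), p.config, free=("gamma_0", "A_max"),
            bounds={"A_max": (0.5, 50.0)},  # far above any simulated A
            n_starts=1, seed=0, dt=2.0,
        )
        assert fit.params["gamma_0"] == pytest.approx(r, rel=0.01)
        assert any("unidentifiable" in f for f in fit.flags)

    def test_noise_free_recovery_within_one_percent(self):
        """Inverse-crime check on the low-glucose/low-polymer condition:
        a 2x-perturbed start recovers all three rates to <1%."""
        from dataclasses import replace

        p = table1_preset("e")
        dense = replace(p, sample_times_min=tuple(range(5, 125, 5)),
                        noise_pct=())
        data = generate_dataset(dense, noise=False)
        truth = {"gamma_0": 9.22e-4, "A_max": 1e-2, "K_a": 1.7e-3}
        fit = fit_feedback_model(
            data, p.config, free=tuple(truth),
            x0={k: 2 * v for k, v in truth.items()},
            n_starts=1, seed=1, dt=2.0,
        )
        for name, value in truth.items():
            assert fit.params[name] == pytest.approx(value, rel=0.01)
        assert fit.n == 24 and fit.p == 3
        assert fit.aic == pytest.approx(
            fit.n * math.log(fit.sse / fit.n) + 2 * fit.p
        )
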