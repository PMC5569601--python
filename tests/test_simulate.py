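"""Coupled simulator: analytic limits, bookkeeping, summary statistics."""

import math
from dataclasses import replace

import numpy as np
import pytest

from gastrosim import (
    BRAKE_DISABLED,
    FeedbackParams,
    GridSpec,
    MealSpec,
    NUTRIENT_ONLY,
    SimulationConfig,
    TOTAL_CONTENT,
    caloric_delivery_rate,
    half_time,
    simulate,
    simulate_secretion_batch,
)
from gastrosim.errors import ConfigurationError
from gastrosim.simulate import crossing_time
from gastrosim.synthetic import (
    lbg_for_viscosity,
    secretion_optimum,
    table1_preset,
)


class TestAnalyticLimits:
    def test_exponential_solution(self, exponential_config):
        tr = simulate(exponential_config)
        g0 = exponential_config.gamma_0
        expected = 20.0 * np.exp(-g0 * tr.times)
        assert np.abs(tr.gastric_nutrient - expected).max() < 0.01 * 20.0
        t_half = math.log(2) / g0
        sim_half = np.interp(t_half, tr.times, tr.gastric_nutrient)
        assert sim_half == pytest.approx(10.0, rel=0.01)

    def test_zero_mass_meal_stays_zero(self):
        cfg = SimulationConfig(
            meal=MealSpec(0.0), feedback=BRAKE_DISABLED, gamma_0=1e-3,
            grid=GridSpec(dt=1.0, t_final=600.0),
        )
        tr = simulate(cfg)
        assert not tr.gastric_nutrient.any()
        assert not tr.absorption_rate.any()

    def test_time_rescaling_invariance(self):
        """Scaling gamma0 by k and time spans by 1/k leaves the sampled
        curve unchanged (minutes-vs-seconds round trip)."""
        k = 60.0
        cfg_s = SimulationConfig(
            meal=MealSpec(10.0), feedback=BRAKE_DISABLED, gamma_0=1e-3,
            grid=GridSpec(dt=0.6, t_final=1200.0, save_stride=100),
        )
        cfg_m = replace(
            cfg_s, gamma_0=1e-3 * k,
            grid=GridSpec(dt=0.6 / k, t_final=1200.0 / k, save_stride=100),
        )
        a, b = simulate(cfg_s), simulate(cfg_m)
        assert np.allclose(a.gastric_nutrient, b.gastric_nutrient,
                           rtol=1e-12)


class TestCoupledRuns:
    def test_lumped_reduction_equals_pde_before_transit(self):
        p_pde = table1_preset("e", transport="pde")
        p_lmp = table1_preset("e", transport="lumped")
        a, b = simulate(p_pde.config), simulate(p_lmp.config)
        assert np.abs(a.gastric_nutrient - b.gastric_nutrient).max() < 1e-10
        assert np.abs(a.cumulative_absorbed - b.cumulative_absorbed).max() < 1e-9

    def test_lumped_rejected_beyond_transit_time(self):
        with pytest.raises(ConfigurationError, match="transit"):
            SimulationConfig(
                meal=MealSpec(10.0), feedback=BRAKE_DISABLED, gamma_0=1e-3,
                K_a=1e-3, transport="lumped",
                grid=GridSpec(dt=1.0, t_final=30_000.0),
            )

    def test_nutrient_conservation_with_brake(self):
        tr = simulate(table1_preset("d").config)
        assert np.abs(tr.nutrient_balance_error()).max() < 1e-3

    def test_cumulative_series_non_decreasing(self):
        tr = simulate(table1_preset("f").config)
        assert np.all(np.diff(tr.cumulative_absorbed) >= 0)
        assert np.all(np.diff(tr.cumulative_outflow) >= 0)
        assert np.all(tr.gastric_nutrient >= 0)

    def test_batch_secretion_matches_full_simulator(self):
        """The vectorised non-nutrient path and the general simulator
        agree on a thickened meal."""
        hyp, sec = secretion_optimum()
        liq0, mu0 = 500.0, 2.0
        lbg0 = lbg_for_viscosity(mu0, liq0)
        res = simulate_secretion_batch(
            np.array([liq0]), np.array([lbg0]), sec, hyp,
            dt=1.0, t_final=1800.0,
        )
        cfg = SimulationConfig(
            meal=MealSpec(0.0, liquid_mass_0=liq0, thickener_mass_0=lbg0),
            feedback=BRAKE_DISABLED, hypothesis=hyp, secretion=sec,
            grid=GridSpec(dt=1.0, t_final=1800.0, save_stride=1),
        )
        tr = simulate(cfg)
        assert np.allclose(tr.gastric_total, res["stomtot"][:, 0],
                           rtol=1e-10)
        assert np.allclose(tr.viscosity, res["viscosity"][:, 0], rtol=1e-10)

    def test_higher_viscosity_secretes_more_and_thins_faster(self):
        """Across initial viscosities, cumulative secretion rises and the
        relative viscosity drop at 30 min deepens."""
        hyp, sec = secretion_optimum()
        mu0 = np.array([0.06, 2.0, 5.6, 11.0])
        lbg0 = np.array([lbg_for_viscosity(m, 500.0) for m in mu0])
        res = simulate_secretion_batch(
            np.full(4, 500.0), lbg0, sec, hyp, dt=5.0, t_final=3600.0
        )
        i30 = np.searchsorted(res["times"], 1800.0)
        cum = res["cumulative_secreted"][i30]
        drop = res["viscosity"][i30] / mu0
        assert np.all(np.diff(cum) > 0)
        assert np.all(np.diff(drop) < 0)


class TestSummaries:
    def test_half_time_exponential_closed_form(self, exponential_config):
        tr = simulate(exponential_config)
        g0 = exponential_config.gamma_0
        assert half_time(tr, NUTRIENT_ONLY) == pytest.approx(
            math.log(2) / g0, abs=2 * exponential_config.grid.dt + 1.0
        )

    def test_half_time_not_reached_is_nan(self):
        cfg = SimulationConfig(
            meal=MealSpec(10.0), feedback=BRAKE_DISABLED, gamma_0=1e-6,
            K_a=0.0, grid=GridSpec(dt=1.0, t_final=600.0),
        )
        tr = simulate(cfg)
        assert math.isnan(half_time(tr, NUTRIENT_ONLY))

    def test_constant_series_crossing_nan(self):
        t = np.arange(10.0)
        assert math.isnan(crossing_time(t, np.full(10, 4.0), 2.0))

    def test_nutrient_half_time_precedes_total_when_secreting(self):
        """Secretions add volume, so the labelled-nutrient half-time leads
        the total-content one (the scintigraphy-vs-MRI gap)."""
        from gastrosim.synthetic import table4_preset

        tr = simulate(table4_preset("HVN", t_final_min=240).config)
        assert half_time(tr, NUTRIENT_ONLY) < half_time(tr, TOTAL_CONTENT)

    def test_delivery_rate_consistent_with_cumulative(self, exponential_config):
        cfg = replace(exponential_config, K_a=9e-4,
                      grid=GridSpec(dt=0.5, t_final=3600.0))
        tr = simulate(cfg)
        window = (float(tr.times[0]), float(tr.times[-1]))
        mean_a = caloric_delivery_rate(tr, window)
        approx = tr.cumulative_absorbed[-1] / (window[1] - window[0])
        assert mean_a == pytest.approx(approx, rel=0.05)

    def test_empty_window_rejected(self, exponential_config):
        tr = simulate(exponential_config)
        with pytest.raises(ValueError):
            caloric_delivery_rate(tr, (100.0, 100.0))
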