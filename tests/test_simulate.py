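"""Integration under protocols and the in-silico experiment battery."""

import numpy as np
import pytest

from nkhif import (
    Agent,
    TreatmentEvent,
    TreatmentProtocol,
    condition_protocol,
    dose_response,
    integrate,
    monte_carlo_robustness,
    parameter_sweep,
    steady_state_value,
    timing_experiment,
    total_hif,
    untreated,
)


def _protocol(*events, horizon=30.0):
    return TreatmentProtocol(events=events, horizon_h=horizon)


class TestIntegrate:
    def test_null_system_constant_trajectory(self, zero_params, rng):
        y0 = rng.uniform(0.0, 2.0, 10)
        traj = integrate(zero_params, y0, untreated(10.0))
        assert np.allclose(traj.states, y0, atol=1e-12)

    def test_grid_contains_event_times(self, eq):
        proto = _protocol(TreatmentEvent(6.0, Agent.DMOG),
                          TreatmentEvent(13.7, Agent.IL15))
        traj = integrate(eq.params, eq.state, proto)
        assert 6.0 in traj.times and 13.7 in traj.times

    def test_il15_event_is_state_jump(self, eq):
        proto = _protocol(TreatmentEvent(6.0, Agent.IL15, 1.0))
        traj = integrate(eq.params, eq.state, proto,
                         t_eval=np.array([0.0, 6.0, 30.0]))
        i = int(np.flatnonzero(traj.times == 6.0)[0])
        # unprimed before the event; the grid keeps the post-impulse value
        assert traj.states[i, 0] == pytest.approx(1.0, abs=1e-9)
        # and the dose decays exponentially afterwards
        assert traj.states[-1, 0] == pytest.approx(
            np.exp(-eq.params["d1"] * 24.0), rel=1e-6)

    def test_states_remain_nonnegative(self, eq):
        proto = _protocol(TreatmentEvent(0.0, Agent.IL15),
                          TreatmentEvent(0.0, Agent.DMOG),
                          TreatmentEvent(0.0, Agent.S3I201))
        traj = integrate(eq.params, eq.state, proto)
        assert np.all(traj.states >= 0.0)

    def test_simultaneous_event_order_irrelevant(self, eq):
        e1 = (TreatmentEvent(6.0, Agent.DMOG),
              TreatmentEvent(6.0, Agent.IL15),
              TreatmentEvent(6.0, Agent.RAPAMYCIN))
        grid = np.linspace(0.0, 30.0, 31)
        a = integrate(eq.params, eq.state, _protocol(*e1), t_eval=grid)
        b = integrate(eq.params, eq.state, _protocol(*reversed(e1)),
                      t_eval=grid)
        assert np.array_equal(a.states, b.states)

    def test_integrator_families_agree(self, eq):
        proto = _protocol(TreatmentEvent(0.0, Agent.IL15),
                          TreatmentEvent(0.0, Agent.DMOG))
        grid = np.linspace(0.0, 30.0, 31)
        a = integrate(eq.params, eq.state, proto, t_eval=grid,
                      method="LSODA")
        b = integrate(eq.params, eq.state, proto, t_eval=grid,
                      method="RK45")
        rel = np.abs(a.observables - b.observables) / \
            np.maximum(np.abs(a.observables), 1e-9)
        assert np.max(rel) <= 1e-5

    def test_span_outside_horizon_rejected(self, eq):
        with pytest.raises(ValueError, match="horizon"):
            integrate(eq.params, eq.state, untreated(10.0),
                      t_span=(0.0, 20.0))


class TestSteadyStateValue:
    def test_untreated_endpoint_stays_at_equilibrium(self, eq):
        y_end, diag = steady_state_value(eq.params,
                                         condition_protocol("normoxia"))
        assert diag["converged"]
        rel = np.abs(y_end - eq.state) / np.maximum(eq.state, 1e-12)
        assert np.max(rel) < 0.01

    def test_il15_priming_effect_vanishes_at_steady_state(self, eq):
        # the pulse decays at rate d1; by 100 h its residual imprint on
        # total HIF-1a is below 1% of the (large) DMOG steady state and
        # below 10% of the normoxic baseline
        primed = eq.state.copy()
        primed[0] = 1.0
        for condition, tol in (("dmog", 0.01), ("normoxia", 0.10)):
            proto = condition_protocol(condition)
            y_p, _ = steady_state_value(eq.params, proto, y0=primed)
            y_u, _ = steady_state_value(eq.params, proto, y0=eq.state)
            assert total_hif(y_p) == pytest.approx(total_hif(y_u), rel=tol)

    def test_dmog_at_least_doubles_total_hif(self, eq):
        y_d, _ = steady_state_value(eq.params, condition_protocol("dmog"))
        y_n, _ = steady_state_value(eq.params, condition_protocol("normoxia"))
        assert total_hif(y_d) / total_hif(y_n) >= 2.0


class TestParameterSweep:
    def test_degenerate_grid_reduces_to_baseline(self, params, eq):
        res = parameter_sweep(params, ["a1"], [[0.0]], condition="normoxia")
        assert res.values["TOTAL_HIF"].shape == (1,)
        assert res.values["TOTAL_HIF"][0] == pytest.approx(1.0, rel=0.01)

    def test_il15_supply_monotone_under_dmog(self, params):
        grid = np.array([0.0, 2.0, 10.0])
        res = parameter_sweep(params, ["a1"], [grid], condition="dmog")
        hif = res.values["TOTAL_HIF"]
        assert np.all(np.diff(hif) > 0.0)

    def test_stat3_supply_dmog_dominates_normoxia(self, params):
        grid = np.array([0.0, 5.0, 10.0])
        hif = {}
        for cond in ("normoxia", "dmog"):
            res = parameter_sweep(params, ["a8"], [grid], condition=cond)
            hif[cond] = res.values["TOTAL_HIF"]
        assert np.all(hif["dmog"] >= hif["normoxia"])

    def test_two_dimensional_sweep_shape(self, params):
        res = parameter_sweep(params, ["a3", "a8"],
                              [[0.0, 5.0], [0.0, 5.0, 10.0]],
                              condition="normoxia")
        assert res.values["TOTAL_HIF"].shape == (2, 3)
        assert np.all(np.isfinite(res.values["TOTAL_HIF"]))

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(KeyError):
            parameter_sweep(params, ["bogus"], [[0.0]])


@pytest.fixture(scope="module")
def dose_table(params):
    return dose_response(params, np.array([0.0, 0.25, 0.5, 1.0]))


@pytest.fixture(scope="module")
def timing_folds(params):
    df = timing_experiment(params)
    return df.set_index("protocol")["fold_change_vs_untreated"]


class TestDoseResponse:
    def test_zero_dose_normalized_to_one(self, dose_table):
        assert dose_table["fold_change"].iloc[0] == 1.0

    def test_fold_change_strictly_increasing(self, dose_table):
        assert np.all(np.diff(dose_table["fold_change"]) > 0.0)

    def test_doubling_dose_is_sub_or_super_proportional(self, dose_table):
        # the dose-response is nonlinear: doubling the dose does not
        # double the response
        f = dose_table.set_index("dose")["fold_change"]
        ratio = f[1.0] / f[0.5]
        assert abs(ratio - 2.0) > 0.2


class TestTimingExperiment:
    def test_untreated_fold_is_one(self, timing_folds):
        assert timing_folds["gray: untreated"] == pytest.approx(1.0)

    def test_maximum_by_il15_first_then_dmog(self, timing_folds):
        assert timing_folds.idxmax() == \
            "black: IL-15 at 0 h + DMOG from 6 h"

    def test_treatment_order_matters(self, timing_folds):
        black = timing_folds["black: IL-15 at 0 h + DMOG from 6 h"]
        light_blue = timing_folds["light blue: DMOG from 0 h + IL-15 at 6 h"]
        assert black != pytest.approx(light_blue, rel=1e-3)

    def test_battery_has_nine_protocols(self, timing_folds):
        assert len(timing_folds) == 9


class TestQualitativeOrderings:
    def test_combined_treatment_dominates_singles_after_4h(self, eq):
        grid = np.linspace(4.0, 30.0, 27)
        A, E = Agent, TreatmentEvent
        both = integrate(eq.params, eq.state,
                         _protocol(E(0.0, A.IL15), E(0.0, A.DMOG)),
                         t_eval=grid)
        il15 = integrate(eq.params, eq.state, _protocol(E(0.0, A.IL15)),
                         t_eval=grid)
        dmog = integrate(eq.params, eq.state, _protocol(E(0.0, A.DMOG)),
                         t_eval=grid)
        sel = both.times >= 4.0
        hif = lambda tr: total_hif(tr.states[sel])
        assert np.all(hif(both) >= hif(il15))
        assert np.all(hif(both) >= hif(dmog))

    def test_double_tf_inhibition_abolishes_il15_enrichment(self, eq):
        A, E = Agent, TreatmentEvent
        grid = np.linspace(0.0, 30.0, 61)
        base = integrate(eq.params, eq.state, untreated(30.0), t_eval=grid)
        il15 = integrate(eq.params, eq.state, _protocol(E(0.0, A.IL15)),
                         t_eval=grid)
        blocked = integrate(
            eq.params, eq.state,
            _protocol(E(0.0, A.IL15), E(0.0, A.S3I201),
                      E(0.0, A.NFKB_INHIBITOR)), t_eval=grid)
        uninhibited = np.max(total_hif(il15.states) - total_hif(base.states))
        inhibited = np.max(total_hif(blocked.states)
                           - total_hif(base.states))
        assert inhibited <= 0.05 * uninhibited

    def test_rapamycin_reduces_but_does_not_eliminate(self, eq):
        A, E = Agent, TreatmentEvent
        grid = np.linspace(0.0, 30.0, 61)
        full = integrate(eq.params, eq.state,
                         _protocol(E(0.0, A.IL15), E(0.0, A.DMOG)),
                         t_eval=grid)
        rapa = integrate(eq.params, eq.state,
                         _protocol(E(0.0, A.IL15), E(0.0, A.DMOG),
                                   E(0.0, A.RAPAMYCIN)), t_eval=grid)
        base = integrate(eq.params, eq.state, untreated(30.0), t_eval=grid)
        assert np.max(total_hif(rapa.states)) < np.max(total_hif(full.states))
        assert np.max(total_hif(rapa.states)) > np.max(total_hif(base.states))


class TestMonteCarloRobustness:
    def test_zero_width_zero_spread(self, params):
        s = monte_carlo_robustness(params, "a2", width=0.0, n=3, seed=7)
        assert s.relative_spread == 0.0

    def test_seed_determinism(self, params):
        a = monte_carlo_robustness(params, "a3", n=5, seed=11)
        b = monte_carlo_robustness(params, "a3", n=5, seed=11)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.multipliers, b.multipliers)

    def test_small_sample_spread_below_ten_percent(self, params):
        s = monte_carlo_robustness(params, "a2", n=20, seed=3)
        assert s.relative_spread < 0.10
        lo, hi = s.percentile_band
        assert lo <= s.baseline <= hi

    def test_unknown_element_rejected(self, params):
        with pytest.raises(ValueError, match="element"):
            monte_carlo_robustness(params, "k4", n=2, seed=0)
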