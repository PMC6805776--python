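"""Measurement model, weighted least squares, Gauss-Newton fitting,
sensitivities and the collinearity screen."""

import numpy as np
import pandas as pd
import pytest

from nkhif import (
    Agent,
    ExperimentDataset,
    IdentifiabilityError,
    PEPConfig,
    TreatmentEvent,
    TreatmentProtocol,
    fit_pep,
    identifiability_screen,
    integrate,
    objective,
    observe,
    read_datasets,
    sensitivity_matrix,
    untreated,
    write_datasets,
)
from nkhif.calibrate import fd_jacobian
from nkhif.synthetic import default_design, generate_calibration_suite


@pytest.fixture(scope="module")
def design():
    return default_design(seed=5)


@pytest.fixture(scope="module")
def noise_free_suite():
    d = default_design(seed=5, sd=0.0)
    cal, val = generate_calibration_suite(d)
    return d, cal, val


@pytest.fixture(scope="module")
def noisy_suite(design):
    cal, val = generate_calibration_suite(design)
    return design, cal, val


def _small_config(**kw):
    base = dict(free_names=["d1", "k6", "k3"], use_priors=False,
                rtol=1e-7, atol=1e-9, max_iter=25)
    base.update(kw)
    return PEPConfig(**base)


class TestObserve:
    def test_canonical_start_is_unit_vector(self, eq):
        traj = integrate(eq.params, eq.state, untreated(10.0))
        assert observe(traj, [0.0])[0] == pytest.approx([1.0, 1.0, 1.0],
                                                        rel=1e-6)

    def test_total_hif_column_matches_state_sum(self, eq):
        proto = TreatmentProtocol(
            events=(TreatmentEvent(0.0, Agent.DMOG),), horizon_h=20.0)
        traj = integrate(eq.params, eq.state, proto)
        times = np.array([1.0, 5.0, 18.0])
        g = observe(traj, times)
        states = traj.eval_states(times)
        assert np.allclose(g[:, 0],
                           states[:, 3] + states[:, 5] + states[:, 9])

    def test_interpolation_matches_fine_reintegration(self, eq):
        proto = TreatmentProtocol(
            events=(TreatmentEvent(0.0, Agent.IL15),
                    TreatmentEvent(0.0, Agent.DMOG)), horizon_h=27.0)
        coarse = integrate(eq.params, eq.state, proto,
                           t_eval=np.array([0.0, 27.0]))
        times = np.array([3.3, 7.7, 19.1])
        fine = integrate(eq.params, eq.state, proto, t_eval=times)
        a = observe(coarse, times)
        b = fine.observables[np.isin(fine.times, times)]
        assert np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-9)) <= 1e-5

    def test_extrapolation_rejected(self, eq):
        traj = integrate(eq.params, eq.state, untreated(10.0))
        with pytest.raises(ValueError, match="span"):
            observe(traj, [11.0])


class TestObjective:
    def test_zero_at_truth_on_noise_free_data(self, noise_free_suite):
        d, cal, _ = noise_free_suite
        f, r = objective(d.params_true, cal, PEPConfig(use_priors=False))
        assert f <= 1e-10
        assert r.shape == (39,)

    def test_doubling_sigma_quarters_data_term(self, noisy_suite):
        d, cal, _ = noisy_suite
        f1, _ = objective(d.params_true, cal, PEPConfig(use_priors=False))
        wide = [
            ExperimentDataset(ds.label, ds.protocol,
                              ds.table.assign(sd=2.0 * ds.table["sd"]))
            for ds in cal
        ]
        f2, _ = objective(d.params_true, wide, PEPConfig(use_priors=False))
        assert f2 == pytest.approx(f1 / 4.0, rel=1e-6)

    def test_single_point_residual_hand_computed(self, eq):
        proto = untreated(10.0)
        table = pd.DataFrame({"time_h": [0.0], "observable": ["STAT3"],
                              "value": [1.3], "sd": [0.2]})
        ds = ExperimentDataset("one", proto, table)
        f, r = objective(eq.params, [ds], PEPConfig(use_priors=False),
                         y0=eq.state)
        # model STAT3(0) = 1, so residual = (1 - 1.3)/0.2 = -1.5
        assert r[0] == pytest.approx(-1.5, abs=1e-9)
        assert f == pytest.approx(0.5 * 1.5 ** 2, rel=1e-9)

    def test_infinite_lambda_switches_prior_off(self, noisy_suite):
        d, cal, _ = noisy_suite
        p = d.params_true.copy()
        p.lambdas = {n: np.inf for n in p.lambdas}
        f_off, r_off = objective(p, cal, PEPConfig(use_priors=True))
        f_no, r_no = objective(p, cal, PEPConfig(use_priors=False))
        assert f_off == f_no
        assert r_off.shape == r_no.shape


class TestSensitivity:
    def test_fd_matches_richardson_on_three_parameter_toy(self):
        def toy(p):
            return np.array([p[0] ** 2 + p[1], np.sin(p[2]), p[0] * p[2]])

        x = np.array([1.3, 0.7, 0.4])
        J = fd_jacobian(toy, x, rel=1e-6, floor=1e-8)
        # Richardson refinement with two central steps
        J_ref = np.empty_like(J)
        for i in range(3):
            h = 1e-4 * abs(x[i])
            for (sign, w) in ((1, 1.0),):
                e = np.zeros(3)
                e[i] = 1.0
                d1 = (toy(x + h * e) - toy(x - h * e)) / (2 * h)
                d2 = (toy(x + h / 2 * e) - toy(x - h / 2 * e)) / h
                J_ref[:, i] = (4 * d2 - d1) / 3
        assert np.allclose(J, J_ref, rtol=1e-4, atol=1e-8)

    def test_insensitive_parameter_gives_zero_column(self, noise_free_suite):
        # rho_rapa cannot influence experiments without rapamycin
        d, cal, _ = noise_free_suite
        no_rapa = [ds for ds in cal if "RAPA" not in ds.label]
        cfg = PEPConfig(free_names=["d1", "rho_rapa"], use_priors=False)
        rep = sensitivity_matrix(d.params_true, no_rapa, cfg)
        j = rep.free_names.index("rho_rapa")
        assert np.all(rep.jacobian[:, j] == 0.0)
        assert np.any(rep.jacobian[:, rep.free_names.index("d1")] != 0.0)

    def test_row_count_is_points_plus_active_priors(self, noisy_suite):
        d, cal, _ = noisy_suite
        cfg = PEPConfig(free_names=["d1", "k6", "k3"], use_priors=True)
        rep = sensitivity_matrix(d.params_true, cal, cfg)
        n_points = sum(ds.n_points for ds in cal)
        assert rep.jacobian.shape == (n_points + 3, 3)


class TestIdentifiabilityScreen:
    def test_orthonormal_columns_pass(self):
        J = np.eye(6)[:, :4]
        rep = identifiability_screen(J, threshold=0.1)
        assert rep.collinearity_index == pytest.approx(1.0)
        assert rep.rejected == []
        assert len(rep.estimable) == 4

    def test_duplicate_column_rejected(self):
        col = np.array([1.0, 2.0, 3.0])
        J = np.column_stack([col, col, np.array([0.0, 1.0, -1.0])])
        rep = identifiability_screen(J, threshold=0.1,
                                     free_names=["a", "b", "c"])
        assert len(rep.rejected) == 1
        assert rep.rejected[0] in ("a", "b")
        assert "c" in rep.estimable

    def test_near_collinear_pair_against_closed_form_svd(self):
        eps = 1e-3
        J = np.array([[1.0, 1.0], [1.0, 1.0 + eps]])
        # closed-form singular values of the column-scaled matrix
        Js = J / np.linalg.norm(J, axis=0, keepdims=True)
        s = np.linalg.svd(Js, compute_uv=False)
        assert s[-1] < 0.1  # so the threshold rule must reject one
        rep = identifiability_screen(J, threshold=0.1)
        assert len(rep.rejected) == 1
        assert rep.collinearity_index == pytest.approx(1.0 / s[-1], rel=1e-9)


class TestFitPep:
    def test_truth_is_fixed_point(self, noise_free_suite):
        d, cal, _ = noise_free_suite
        # generation and fit must share integration tolerances, else the
        # residual floor is the tolerance gap rather than zero
        cfg = _small_config(rtol=1e-8, atol=1e-10, step_tol=1e-7)
        fit = fit_pep(cal, d.params_true, cfg)
        assert fit.n_iter <= 2
        for n in cfg.free_names:
            assert fit.estimates[n] == pytest.approx(d.params_true[n],
                                                     rel=1e-6)

    def test_objective_decreases_monotonically(self, noisy_suite):
        d, cal, _ = noisy_suite
        cfg = _small_config()
        start = {"d1": 1.4 * d.params_true["d1"],
                 "k6": 0.7 * d.params_true["k6"],
                 "k3": 1.4 * d.params_true["k3"]}
        fit = fit_pep(cal, d.params_true, cfg, start=start)
        objs = [h["objective"] for h in fit.history]
        assert len(objs) >= 2
        assert all(b < a for a, b in zip(objs, objs[1:]))

    def test_noisy_subset_recovery_within_sd(self, noisy_suite):
        d, cal, _ = noisy_suite
        cfg = _small_config()
        start = {n: 1.5 * d.params_true[n] for n in cfg.free_names}
        fit = fit_pep(cal, d.params_true, cfg, start=start)
        for n in cfg.free_names:
            err = abs(fit.estimates[n] - d.params_true[n])
            assert err <= 4.0 * fit.sd[n]

    def test_dataset_order_does_not_change_sd(self, noisy_suite):
        d, cal, _ = noisy_suite
        cfg = _small_config(max_iter=2)
        a = fit_pep(cal, d.params_true, cfg)
        b = fit_pep(list(reversed(cal)), d.params_true, cfg)
        for n in cfg.free_names:
            assert a.sd[n] == pytest.approx(b.sd[n], rel=1e-6)

    def test_rank_deficient_system_raises(self, noise_free_suite):
        d, cal, _ = noise_free_suite
        no_rapa = [ds for ds in cal if "RAPA" not in ds.label]
        cfg = PEPConfig(free_names=["d1", "rho_rapa"], use_priors=False,
                        rtol=1e-7, atol=1e-9)
        with pytest.raises(IdentifiabilityError, match="screen"):
            fit_pep(no_rapa, d.params_true, cfg)

    def test_multiple_shooting_matches_single_shooting(self, noisy_suite):
        d, cal, _ = noisy_suite
        two = cal[:2]
        nodes = {ds.label: np.array([0.0, 4.0, 12.0, 27.0]) for ds in two}
        # the continuity-constraint Jacobian needs an FD step well above
        # the integration error, hence the 1e-4 relative step here
        kw = dict(free_names=["d1", "k6"], use_priors=False,
                  rtol=1e-8, atol=1e-10, max_iter=30, fd_rel_step=1e-4)
        start = {"d1": 1.3 * d.params_true["d1"],
                 "k6": 0.8 * d.params_true["k6"]}
        single = fit_pep(two, d.params_true, PEPConfig(**kw), start=start)
        multi = fit_pep(two, d.params_true,
                        PEPConfig(shooting="multiple",
                                  shooting_nodes=nodes, **kw),
                        start=start)
        assert multi.constraint_norm <= 1e-5
        assert multi.objective == pytest.approx(single.objective, rel=1e-4)


class TestDatasetIO:
    def test_csv_round_trip(self, noisy_suite, tmp_path):
        _, cal, _ = noisy_suite
        path = tmp_path / "suite.csv"
        write_datasets(cal, path)
        back = read_datasets(path, {ds.label: ds.protocol for ds in cal})
        assert [ds.label for ds in back] == [ds.label for ds in cal]
        for a, b in zip(back, cal):
            pd.testing.assert_frame_equal(a.table, b.table,
                                          check_dtype=False)

    def test_sigma_must_be_positive(self, eq):
        table = pd.DataFrame({"time_h": [1.0], "observable": ["AKT"],
                              "value": [1.0], "sd": [0.0]})
        with pytest.raises(ValueError, match="sd > 0"):
            ExperimentDataset("bad", untreated(10.0), table)
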