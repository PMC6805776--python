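"""Multi-experiment calibration of the network.

The estimation problem is a weighted least-squares fit of the model
observables (total HIF-1a, phospho-STAT3, phospho-AKT) to time-series
measurements from several perturbation experiments simultaneously,
optionally with a Tikhonov prior pulling each free parameter toward its
published value:

    min_p  1/2 sum_{i,j,ex} [(eta_ij - g_i(t_j))/sigma_ij]^2
         + 1/2 sum_m [(p_m - p0_m)/lambda_m]^2

subject to the steady-state ties (a1 = 0, d8 = k8) and the untreated
equilibrium.  The problem is solved by a generalized Gauss-Newton
iteration with damped steps t_k in (0, 1] (Armijo backtracking on the
full objective).  Two shooting parameterizations are available:

* ``single`` -- each experiment is one initial value problem;
* ``multiple`` -- the horizon is split at a node grid, the node states
  become extra unknowns and continuity at the nodes becomes equality
  constraints, handled by a null-space step.

Non-negativity of rate constants is enforced by log-reparameterization;
efficacies are optimized on their natural [0, 1] box with projection.

Parameter uncertainty comes from the linearized covariance at the
solution (generalized inverse of the weighted sensitivity matrix), and
identifiability is screened with the collinearity index: the reciprocal
of the smallest singular value of the column-scaled sensitivity matrix,
with singular values below 0.1 flagging a poorly identifiable subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import IdentifiabilityError, NkhifError
from .model import (
    rhs_core,
    pack_constants,
    solve_consistent_equilibrium,
    steady_state_residual,
    canonical_initial_state,
)
from .params import EFFICACY_NAMES, ParameterSet
from .protocols import TreatmentProtocol
from .simulate import OBSERVABLE_NAMES, Trajectory, integrate

__all__ = [
    "ExperimentDataset",
    "read_datasets",
    "write_datasets",
    "PEPConfig",
    "FitResult",
    "SensitivityReport",
    "observe",
    "objective",
    "fit_pep",
    "sensitivity_matrix",
    "identifiability_screen",
]


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class ExperimentDataset:
    """One perturbation experiment: protocol + noisy measurements.

    ``table`` columns: ``time_h``, ``observable`` (one of TOTAL_HIF,
    STAT3, AKT), ``value``, ``sd``.
    """

    label: str
    protocol: TreatmentProtocol
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_h", "observable", "value", "sd"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset table missing columns {sorted(missing)}")
        t = self.table
        if (t["sd"] <= 0).any():
            raise ValueError("every measurement must have sd > 0")
        if not np.isfinite(t["value"]).all():
            raise ValueError("measurement values must be finite")
        if (t["time_h"] < 0).any() or (t["time_h"] > self.protocol.horizon_h).any():
            raise ValueError("measurement times outside protocol horizon")
        bad = set(t["observable"]) - set(OBSERVABLE_NAMES)
        if bad:
            raise ValueError(f"unknown observables {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def n_points(self) -> int:
        return len(self.table)


def write_datasets(datasets, path) -> None:
    """Serialize datasets to the long CSV dialect
    (experiment,label,time_h,observable,value,sd)."""
    frames = []
    for i, ds in enumerate(datasets):
        df = ds.table.copy()
        df.insert(0, "label", ds.label)
        df.insert(0, "experiment", i)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_datasets(path, protocols) -> list[ExperimentDataset]:
    """Read datasets written by :func:`write_datasets`.

    ``protocols`` maps each label to its :class:`TreatmentProtocol`
    (protocols are not stored in the CSV).
    """
    df = pd.read_csv(path)
    out = []
    for label, grp in df.groupby("label", sort=False):
        if label not in protocols:
            raise KeyError(f"no protocol supplied for experiment {label!r}")
        out.append(ExperimentDataset(
            label=str(label), protocol=protocols[label],
            table=grp[["time_h", "observable", "value", "sd"]].copy(),
        ))
    return out


# ---------------------------------------------------------------------------
# Observation
# ---------------------------------------------------------------------------

_OBS_INDEX = {name: i for i, name in enumerate(OBSERVABLE_NAMES)}


def observe(trajectory: Trajectory, times) -> np.ndarray:
    """(len(times), 3) matrix of (total HIF-1a, STAT3, AKT).

    Uses the trajectory's dense output; requesting times outside the
    integrated span raises ``ValueError``.
    """
    states = trajectory.eval_states(times)
    return np.column_stack([
        states[:, 3] + states[:, 5] + states[:, 9],
        states[:, 7],
        states[:, 1],
    ])


# ---------------------------------------------------------------------------
# Configuration / results
# ---------------------------------------------------------------------------

@dataclass
class PEPConfig:
    """Controls for the multi-experiment estimation problem."""

    free_names: list[str] | None = None   # None -> ParameterSet free set
    use_priors: bool = True
    steady_state: str = "presolved"       # 'presolved' | 'penalty'
    ss_weight: float = 1e3                # weight on Eq.-residual rows ('penalty')
    shooting: str = "single"              # 'single' | 'multiple'
    shooting_nodes: dict | None = None    # label -> node grid (default: data times)
    max_iter: int = 50
    step_tol: float = 1e-8
    # FD step for the Gauss-Newton Jacobian: large enough that the
    # integration error (rtol) does not drown the difference quotient
    fd_rel_step: float = 1e-4
    fd_abs_step: float = 1e-8
    obj_stall_tol: float = 1e-6           # relative objective stall stop
    rtol: float = 1e-8
    atol: float = 1e-10
    armijo_c: float = 1e-4
    constraint_weight: float = 1e4        # merit weight on continuity defects

    def __post_init__(self) -> None:
        if self.steady_state not in ("presolved", "penalty"):
            raise ValueError(f"unknown steady_state mode {self.steady_state!r}")
        if self.shooting not in ("single", "multiple"):
            raise ValueError(f"unknown shooting mode {self.shooting!r}")


@dataclass
class FitResult:
    estimates: dict[str, float]
    sd: dict[str, float]
    objective: float
    data_term: float
    prior_term: float
    history: list[dict]
    converged: bool
    n_iter: int
    constraint_norm: float
    free_names: list[str]

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates, "sd": self.sd,
            "objective": self.objective, "data_term": self.data_term,
            "prior_term": self.prior_term, "converged": self.converged,
            "n_iter": self.n_iter, "constraint_norm": self.constraint_norm,
            "free_names": self.free_names, "history": self.history,
        }


@dataclass
class SensitivityReport:
    jacobian: np.ndarray
    free_names: list[str]
    singular_values: np.ndarray = field(default=None)
    collinearity_index: float = np.nan
    estimable: list[str] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)
    threshold: float = np.nan


# ---------------------------------------------------------------------------
# Residual assembly
# ---------------------------------------------------------------------------

def _transform(values: np.ndarray, names) -> np.ndarray:
    """Natural -> optimizer scale (log for rates, identity for efficacies)."""
    out = np.empty_like(values)
    for i, n in enumerate(names):
        out[i] = values[i] if n in EFFICACY_NAMES else np.log(max(values[i], 1e-12))
    return out


def _untransform(theta: np.ndarray, names) -> np.ndarray:
    out = np.empty_like(theta)
    for i, n in enumerate(names):
        out[i] = min(max(theta[i], 0.0), 1.0) if n in EFFICACY_NAMES \
            else np.exp(theta[i])
    return out


class _Problem:
    """Weighted residuals of the PEP as a function of free parameters."""

    def __init__(self, base_params: ParameterSet, datasets, config: PEPConfig,
                 y0=None):
        self.base = base_params.copy()
        self.datasets = list(datasets)
        if not self.datasets:
            raise ValueError("at least one dataset is required")
        self.config = config
        self.free_names = list(config.free_names) if config.free_names \
            else self.base.free_names
        for n in self.free_names:
            if n not in self.base.values:
                raise KeyError(f"unknown free parameter {n!r}")
        if y0 is not None:
            self.y0 = np.asarray(y0, dtype=float)
        elif config.steady_state == "presolved":
            self.y0 = solve_consistent_equilibrium(self.base).state
        else:
            self.y0 = canonical_initial_state(il15_primed=False)
        # penalty mode optimizes the HIF split alongside the parameters
        self.n_split = 2 if config.steady_state == "penalty" else 0

    # -- parameter bookkeeping ------------------------------------------

    @property
    def n_theta(self) -> int:
        return len(self.free_names) + self.n_split

    def theta0(self, start: dict[str, float] | None = None) -> np.ndarray:
        vals = np.array([
            (start or {}).get(n, self.base[n]) for n in self.free_names
        ])
        theta = _transform(vals, self.free_names)
        if self.n_split:
            theta = np.concatenate([theta, [self.y0[3], self.y0[5]]])
        return theta

    def natural(self, theta: np.ndarray) -> np.ndarray:
        return _untransform(theta[:len(self.free_names)], self.free_names)

    def params_at(self, theta: np.ndarray) -> ParameterSet:
        p = self.natural(theta)
        return self.base.with_updates(dict(zip(self.free_names, p)))

    def initial_state(self, theta: np.ndarray) -> np.ndarray:
        y0 = self.y0.copy()
        if self.n_split:
            s4, s6 = theta[-2], theta[-1]
            y0[3], y0[5] = s4, s6
            y0[9] = max(1.0 - s4 - s6, 0.0)
        return y0

    def project(self, theta: np.ndarray) -> np.ndarray:
        """Clip efficacies into [0, 1] and splits into the simplex."""
        theta = theta.copy()
        for i, n in enumerate(self.free_names):
            if n in EFFICACY_NAMES:
                theta[i] = min(max(theta[i], 0.0), 1.0)
        if self.n_split:
            theta[-2:] = np.clip(theta[-2:], 0.0, 1.0)
        return theta

    def theta_upper(self) -> np.ndarray:
        up = np.full(self.n_theta, np.inf)
        for i, n in enumerate(self.free_names):
            if n in EFFICACY_NAMES:
                up[i] = 1.0
        if self.n_split:
            up[-2:] = 1.0
        return up

    def natural_upper(self) -> np.ndarray:
        return np.array([
            1.0 if n in EFFICACY_NAMES else np.inf for n in self.free_names
        ])

    # -- residuals --------------------------------------------------------

    def data_residuals(self, theta: np.ndarray) -> np.ndarray:
        params = self.params_at(theta)
        y0 = self.initial_state(theta)
        cfg = self.config
        rows = []
        for ds in self.datasets:
            t_max = max(float(ds.table["time_h"].max()), 1e-6)
            try:
                traj = integrate(params, y0, ds.protocol,
                                 t_span=(0.0, t_max),
                                 t_eval=np.array([0.0, t_max]),
                                 rtol=cfg.rtol, atol=cfg.atol)
            except Exception as exc:
                raise NkhifError(
                    f"simulation failed for dataset {ds.label!r}: {exc}"
                ) from exc
            g = observe(traj, ds.table["time_h"].to_numpy())
            model = g[np.arange(len(ds.table)),
                      [_OBS_INDEX[o] for o in ds.table["observable"]]]
            rows.append((model - ds.table["value"].to_numpy())
                        / ds.table["sd"].to_numpy())
        return np.concatenate(rows)

    def prior_residuals(self, theta: np.ndarray) -> np.ndarray:
        if not self.config.use_priors:
            return np.empty(0)
        p = self.natural(theta)
        rows = []
        for val, n in zip(p, self.free_names):
            lam = self.base.lambdas.get(n, np.inf)
            p0 = self.base.priors.get(n, self.base[n])
            if np.isfinite(lam) and lam > 0:
                rows.append((val - p0) / lam)
        return np.asarray(rows)

    def ss_residuals(self, theta: np.ndarray) -> np.ndarray:
        if self.config.steady_state != "penalty":
            return np.empty(0)
        params = self.params_at(theta)
        y0 = self.initial_state(theta)
        return self.config.ss_weight * steady_state_residual(y0, params)

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        return np.concatenate([
            self.data_residuals(theta),
            self.prior_residuals(theta),
            self.ss_residuals(theta),
        ])

    def objective_terms(self, theta: np.ndarray) -> tuple[float, float, float]:
        r_d = self.data_residuals(theta)
        r_p = self.prior_residuals(theta)
        r_s = self.ss_residuals(theta)
        data = 0.5 * float(r_d @ r_d)
        prior = 0.5 * float(r_p @ r_p) if r_p.size else 0.0
        ss = 0.5 * float(r_s @ r_s) if r_s.size else 0.0
        return data, prior, ss


def fd_jacobian(fun, x: np.ndarray, rel: float = 1e-6,
                floor: float = 1e-8, upper=None) -> np.ndarray:
    """Forward finite-difference Jacobian of ``fun`` at ``x``.

    Components sitting against an ``upper`` bound are differenced
    backward so box-constrained directions (inhibitor efficacies at
    100%) still yield a usable column.
    """
    f0 = np.asarray(fun(x))
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        h = rel * abs(x[i]) + floor
        if upper is not None and x[i] + h > upper[i]:
            h = -h
        xp = x.copy()
        xp[i] += h
        J[:, i] = (np.asarray(fun(xp)) - f0) / h
    return J


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def objective(params: ParameterSet, datasets, config: PEPConfig | None = None,
              y0=None) -> tuple[float, np.ndarray]:
    """Value and stacked weighted residual vector of the PEP objective
    at the given parameters (data residuals first, then prior rows)."""
    config = config or PEPConfig()
    prob = _Problem(params, datasets, config, y0=y0)
    theta = prob.theta0()
    r = prob.residuals(theta)
    return 0.5 * float(r @ r), r


def sensitivity_matrix(params: ParameterSet, datasets,
                       config: PEPConfig | None = None,
                       y0=None, rel_step: float = 1e-6,
                       abs_step: float = 1e-8) -> SensitivityReport:
    """Jacobian of the weighted residuals w.r.t. the free parameters.

    Forward finite differences on the natural parameter scale (relative
    step 1e-6, absolute floor 1e-8); one row per measurement plus one
    per active prior; columns in canonical free-parameter order.
    """
    config = config or PEPConfig()
    prob = _Problem(params, datasets, config, y0=y0)
    names = prob.free_names
    p0 = np.array([params[n] for n in names])

    def res_nat(p):
        trial = params.with_updates(dict(zip(names, np.maximum(p, 0.0))))
        sub = _Problem(trial, datasets, config, y0=prob.y0)
        th = sub.theta0()
        return np.concatenate([sub.data_residuals(th),
                               sub.prior_residuals(th)])

    J = fd_jacobian(res_nat, p0, rel=rel_step,
                    floor=abs_step, upper=prob.natural_upper())
    return SensitivityReport(jacobian=J, free_names=list(names))


def identifiability_screen(report_or_J, threshold: float = 0.1,
                           free_names=None) -> SensitivityReport:
    """Partition free parameters into an estimable and a rejected set.

    The sensitivity matrix is column-scaled to unit norm and its SVD
    computed; while the smallest singular value lies below ``threshold``
    the parameter carrying the largest weight in the corresponding
    singular vector is removed (fixed at its prior).  The collinearity
    index is the reciprocal of the smallest singular value.
    """
    if isinstance(report_or_J, SensitivityReport):
        J = report_or_J.jacobian
        names = list(report_or_J.free_names)
    else:
        J = np.asarray(report_or_J, dtype=float)
        names = list(free_names) if free_names is not None \
            else [f"p{i}" for i in range(J.shape[1])]
    if J.size == 0:
        raise ValueError("empty sensitivity matrix")

    active = list(range(len(names)))
    rejected: list[int] = []
    # zero columns carry no information at all
    for i in list(active):
        if np.linalg.norm(J[:, i]) == 0.0:
            active.remove(i)
            rejected.append(i)
    if not active:
        raise IdentifiabilityError("all sensitivity columns are zero")

    def scaled(cols):
        sub = J[:, cols]
        return sub / np.linalg.norm(sub, axis=0, keepdims=True)

    sv0 = linalg.svdvals(scaled(active))
    index_before = 1.0 / sv0[-1]
    while True:
        A = scaled(active)
        U, s, Vt = linalg.svd(A, full_matrices=False)
        if s[-1] >= threshold or len(active) == 1:
            break
        worst_dir = Vt[-1]
        drop = active[int(np.argmax(np.abs(worst_dir)))]
        active.remove(drop)
        rejected.append(drop)
        if not active:
            raise IdentifiabilityError("all parameters rejected by the screen")
    s_final = linalg.svdvals(scaled(active))
    return SensitivityReport(
        jacobian=J, free_names=names,
        singular_values=sv0,
        collinearity_index=index_before,
        estimable=[names[i] for i in sorted(active)],
        rejected=[names[i] for i in sorted(rejected)],
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Gauss-Newton driver
# ---------------------------------------------------------------------------

def _armijo(prob: _Problem, theta, r, f, delta, g, c1, min_step=2.0 ** -10):
    """Backtracking line search; returns (accepted, theta, r, f, step)."""
    descent = max(-float(g @ delta), 0.0)
    step = 1.0
    while step >= min_step:
        cand = prob.project(theta + step * delta)
        rc = prob.residuals(cand)
        fc = 0.5 * float(rc @ rc)
        if fc <= f - c1 * step * descent and fc < f:
            return True, cand, rc, fc, step
        step *= 0.5
    return False, theta, r, f, 0.0


def _gn_single(prob: _Problem, theta: np.ndarray):
    """Damped Gauss-Newton on the unconstrained (single-shooting) problem.

    The plain Gauss-Newton step is tried first with Armijo backtracking;
    if no damped step decreases the objective (the normal matrix of this
    network is severely ill-conditioned away from the solution) the step
    is re-solved on a Levenberg ridge ladder before giving up.
    """
    cfg = prob.config
    history = []
    r = prob.residuals(theta)
    f = 0.5 * float(r @ r)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        J = fd_jacobian(prob.residuals, theta,
                        rel=cfg.fd_rel_step, floor=cfg.fd_abs_step,
                        upper=prob.theta_upper())
        sv = linalg.svdvals(J)
        if sv[0] == 0 or sv[-1] / sv[0] < 1e-13:
            raise IdentifiabilityError(
                "rank-deficient Gauss-Newton system; run "
                "identifiability_screen to select an estimable subset"
            )
        g = J.T @ r
        JTJ = J.T @ J
        smax2 = sv[0] ** 2
        accepted = False
        delta, *_ = linalg.lstsq(J, -r, lapack_driver="gelsd")
        accepted, theta_n, r_n, f_n, step = _armijo(
            prob, theta, r, f, delta, g, cfg.armijo_c)
        if not accepted:
            # ridge ladder: growing mu already shortens the step, so
            # each attempt only tries a couple of damping factors
            for mu in 10.0 ** np.arange(-10, 3):
                delta = linalg.solve(
                    JTJ + mu * smax2 * np.eye(JTJ.shape[0]), -g,
                    assume_a="pos")
                accepted, theta_n, r_n, f_n, step = _armijo(
                    prob, theta, r, f, delta, g, cfg.armijo_c,
                    min_step=0.25)
                if accepted:
                    break
        if not accepted:
            break
        p_old = prob.natural(theta)
        f_old = f
        theta, r, f = theta_n, r_n, f_n
        p_new = prob.natural(theta)
        rel_step = np.linalg.norm(p_new - p_old) / (1.0 + np.linalg.norm(p_new))
        history.append({"iter": it, "objective": f, "step": step,
                        "rel_step": float(rel_step)})
        if rel_step < cfg.step_tol:
            converged = True
            break
        if f_old - f < cfg.obj_stall_tol * max(f, 1e-30) and step == 1.0:
            converged = True
            break
    return theta, f, history, converged, it


def _fit_covariance(prob: _Problem, theta: np.ndarray) -> dict[str, float]:
    """Linearized parameter standard deviations at the solution.

    The weighted residual Jacobian is taken w.r.t. the natural-scale
    free parameters; the covariance is the generalized inverse of its
    normal matrix (measurement weighting is already inside the
    residuals).
    """
    names = prob.free_names
    p_hat = prob.natural(theta)

    def res_nat(p):
        th = theta.copy()
        th[:len(names)] = _transform(np.maximum(p, 1e-300), names)
        return prob.residuals(th)

    J = fd_jacobian(res_nat, p_hat, rel=prob.config.fd_rel_step,
                    floor=prob.config.fd_abs_step,
                    upper=prob.natural_upper())
    cov = linalg.pinv(J.T @ J)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return dict(zip(names, sd))


def fit_pep(datasets, base_params: ParameterSet,
            config: PEPConfig | None = None,
            start: dict[str, float] | None = None,
            y0=None) -> FitResult:
    """Solve the multi-experiment estimation problem.

    ``base_params`` supplies fixed values, ties, priors and the
    pre-solved untreated equilibrium; ``start`` optionally overrides the
    starting values of free parameters.  Returns estimates with
    linearized standard deviations, the objective split into data and
    prior terms, and the iteration history.
    """
    config = config or PEPConfig()
    prob = _Problem(base_params, datasets, config, y0=y0)
    theta = prob.theta0(start)

    if config.shooting == "single":
        theta, f, history, converged, n_iter = _gn_single(prob, theta)
        constraint_norm = 0.0
    else:
        theta, f, history, converged, n_iter, constraint_norm = \
            _gn_multiple(prob, theta)

    data, prior, _ = prob.objective_terms(theta)
    estimates = dict(zip(prob.free_names, prob.natural(theta)))
    sd = _fit_covariance(prob, theta)
    return FitResult(
        estimates=estimates, sd=sd, objective=f,
        data_term=data, prior_term=prior, history=history,
        converged=converged, n_iter=n_iter,
        constraint_norm=constraint_norm, free_names=list(prob.free_names),
    )


# ---------------------------------------------------------------------------
# Multiple shooting
# ---------------------------------------------------------------------------

class _ShootingProblem:
    """Multiple-shooting parameterization of one PEP.

    Unknowns: the transformed free parameters followed by the interior
    node states of every dataset.  Residuals F1: data + prior rows;
    constraints F2: continuity defects at the interior nodes.
    """

    def __init__(self, prob: _Problem):
        self.prob = prob
        cfg = prob.config
        self.grids = []
        for ds in prob.datasets:
            if cfg.shooting_nodes and ds.label in cfg.shooting_nodes:
                grid = np.asarray(cfg.shooting_nodes[ds.label], float)
            else:
                times = set(ds.table["time_h"])
                times |= {t for t in ds.protocol.event_times()}
                times |= {0.0, float(ds.table["time_h"].max())}
                grid = np.array(sorted(times))
            self.grids.append(grid)
        self.n_theta = prob.n_theta
        self.node_slices = []
        off = self.n_theta
        for grid in self.grids:
            n_int = max(len(grid) - 2, 0)
            self.node_slices.append((off, off + 10 * n_int))
            off += 10 * n_int
        self.n_unknowns = off

    def init_vector(self, theta: np.ndarray) -> np.ndarray:
        """Seed node states from a single-shooting forward simulation."""
        x = np.zeros(self.n_unknowns)
        x[:self.n_theta] = theta
        params = self.prob.params_at(theta)
        y0 = self.prob.initial_state(theta)
        for ds, grid, (lo, hi) in zip(self.prob.datasets, self.grids,
                                      self.node_slices):
            if hi == lo:
                continue
            traj = integrate(params, y0, ds.protocol,
                             t_span=(0.0, grid[-1]), t_eval=grid,
                             rtol=self.prob.config.rtol,
                             atol=self.prob.config.atol)
            nodes = traj.eval_states(grid[1:-1])
            x[lo:hi] = nodes.ravel()
        return x

    def _segment(self, params, ds, grid, m, y_start):
        """Integrate subinterval m; return (end state, data residual rows)."""
        t0, t1 = grid[m], grid[m + 1]
        y_start = np.clip(y_start, 0.0, None)  # node unknowns are unbounded
        traj = integrate(params, y_start, ds.protocol, t_span=(t0, t1),
                         t_eval=np.array([t0, t1]),
                         rtol=self.prob.config.rtol,
                         atol=self.prob.config.atol)
        sel = (ds.table["time_h"] > t0 + 1e-12) & (ds.table["time_h"] <= t1) \
            if m > 0 else (ds.table["time_h"] <= t1)
        sub = ds.table[sel]
        rows = np.empty(0)
        if len(sub):
            g = observe(traj, sub["time_h"].to_numpy())
            model = g[np.arange(len(sub)),
                      [_OBS_INDEX[o] for o in sub["observable"]]]
            rows = (model - sub["value"].to_numpy()) / sub["sd"].to_numpy()
        return traj.states[-1], rows

    def evaluate(self, x: np.ndarray):
        """(F1, F2) at the current unknowns."""
        theta = x[:self.n_theta]
        params = self.prob.params_at(theta)
        y0 = self.prob.initial_state(theta)
        F1_rows, F2_rows = [], []
        for ds, grid, (lo, hi) in zip(self.prob.datasets, self.grids,
                                      self.node_slices):
            n_int = (hi - lo) // 10
            nodes = x[lo:hi].reshape(n_int, 10)
            starts = [y0] + [nodes[m] for m in range(n_int)]
            for m in range(len(grid) - 1):
                y_end, rows = self._segment(params, ds, grid, m, starts[m])
                F1_rows.append(rows)
                if m < n_int:
                    # impulses at the node time belong to the next segment's
                    # start; integrate() applies them, so the defect compares
                    # the raw endpoint with the pre-impulse node state
                    F2_rows.append(y_end - nodes[m])
        F1 = np.concatenate(
            F1_rows + [self.prob.prior_residuals(theta),
                       self.prob.ss_residuals(theta)])
        F2 = np.concatenate(F2_rows) if F2_rows else np.empty(0)
        return F1, F2


def _gn_multiple(prob: _Problem, theta: np.ndarray):
    """Generalized Gauss-Newton with continuity constraints (null-space
    step) for the multiple-shooting parameterization."""
    cfg = prob.config
    sp = _ShootingProblem(prob)
    x = sp.init_vector(theta)

    def F1_fun(v):
        return sp.evaluate(v)[0]

    def F2_fun(v):
        return sp.evaluate(v)[1]

    def merit(v):
        F1, F2 = sp.evaluate(v)
        return (0.5 * float(F1 @ F1)
                + 0.5 * cfg.constraint_weight * float(F2 @ F2))

    def project(v):
        v = v.copy()
        v[:sp.n_theta] = prob.project(v[:sp.n_theta])
        v[sp.n_theta:] = np.clip(v[sp.n_theta:], 0.0, None)
        return v

    history = []
    f = merit(x)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        F1, F2 = sp.evaluate(x)
        upper = np.full(sp.n_unknowns, np.inf)
        upper[:sp.n_theta] = prob.theta_upper()
        Jfull = fd_jacobian(lambda v: np.concatenate(sp.evaluate(v)), x,
                            rel=cfg.fd_rel_step, floor=cfg.fd_abs_step,
                            upper=upper)
        J1, J2 = Jfull[:F1.size], Jfull[F1.size:]
        if F2.size:
            d_p, *_ = linalg.lstsq(J2, -F2, lapack_driver="gelsd")
            Z = linalg.null_space(J2)
            if Z.size == 0:
                delta = d_p
            else:
                q, *_ = linalg.lstsq(J1 @ Z, -(F1 + J1 @ d_p),
                                     lapack_driver="gelsd")
                delta = d_p + Z @ q
        else:
            delta, *_ = linalg.lstsq(J1, -F1, lapack_driver="gelsd")
        step = 1.0
        accepted = False
        while step >= 2.0 ** -10:
            cand = project(x + step * delta)
            fc = merit(cand)
            # the null-space step may trade a little objective for a large
            # constraint correction, so accept any non-increase of the merit
            if fc <= f * (1.0 + 1e-12):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        p_old = prob.natural(x[:sp.n_theta])
        x, f = cand, fc
        p_new = prob.natural(x[:sp.n_theta])
        rel_step = np.linalg.norm(p_new - p_old) / (1.0 + np.linalg.norm(p_new))
        history.append({"iter": it, "objective": f, "step": step,
                        "rel_step": float(rel_step)})
        if rel_step < cfg.step_tol:
            converged = True
            break
    F1, F2 = sp.evaluate(x)
    constraint_norm = float(np.max(np.abs(F2))) if F2.size else 0.0
    theta_out = x[:sp.n_theta]
    f_obj = 0.5 * float(F1 @ F1)
    return theta_out, f_obj, history, converged, it, constraint_norm
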