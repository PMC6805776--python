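"""Integration of the network and the in-silico experiment battery.

Protocols are handled by piecewise integration: the solver is restarted
at every event time, applying IL-15 impulses as state jumps and holding
the sustained controls (DMOG, inhibitors) constant on each segment.
Restarting keeps event times exact with any stiff solver.

Steady states are operationalized as the t = 100 h endpoint together
with a convergence check (no component moving more than 0.1% over the
final 10 h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import StiffnessError
from .model import (
    canonical_initial_state,
    pack_constants,
    rhs_core,
    solve_consistent_equilibrium,
    total_hif,
    N_STATES,
    STATE_NAMES,
)
from .params import ParameterSet
from .protocols import (
    Agent,
    TreatmentEvent,
    TreatmentProtocol,
    effective_inputs,
    untreated,
)

__all__ = [
    "Trajectory",
    "integrate",
    "steady_state_value",
    "SweepResult",
    "parameter_sweep",
    "dose_response",
    "timing_protocols",
    "timing_experiment",
    "RobustnessSummary",
    "monte_carlo_robustness",
    "condition_protocol",
]

#: Default integration tolerances.
RTOL = 1e-8
ATOL = 1e-10

#: Observable panel: total HIF-1a, phospho-STAT3, phospho-AKT.
OBSERVABLE_NAMES = ("TOTAL_HIF", "STAT3", "AKT")

_NEG_CLIP_TOL = 1e-9


@dataclass
class Trajectory:
    """Solution of the network over one protocol.

    ``states`` has one row per time point, columns in state order.  The
    per-segment dense outputs are retained so observables can be
    evaluated at arbitrary times within the span.
    """

    times: np.ndarray
    states: np.ndarray
    protocol: TreatmentProtocol
    _segments: list = field(default_factory=list, repr=False)

    @property
    def observables(self) -> np.ndarray:
        """(n_times, 3) array of (total HIF-1a, STAT3, AKT)."""
        return np.column_stack([
            total_hif(self.states), self.states[:, 7], self.states[:, 1],
        ])

    def eval_states(self, times) -> np.ndarray:
        """Interpolate states at arbitrary times via the dense outputs."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        lo, hi = self.times[0], self.times[-1]
        if np.any(times < lo - 1e-12) or np.any(times > hi + 1e-12):
            raise ValueError(
                f"requested times outside trajectory span [{lo}, {hi}]"
            )
        out = np.empty((times.size, N_STATES))
        for i, t in enumerate(times):
            for (t0, t1, sol, y_start) in self._segments:
                if t0 <= t <= t1:
                    out[i] = y_start if t == t0 else sol(t)
                    break
            else:  # pragma: no cover - guarded above
                raise ValueError(f"time {t} not covered by any segment")
        return np.clip(out, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_h, variable, value)."""
        recs = []
        for name, col in zip(STATE_NAMES, self.states.T):
            recs.append(pd.DataFrame(
                {"time_h": self.times, "variable": name, "value": col}))
        for name, col in zip(OBSERVABLE_NAMES, self.observables.T):
            recs.append(pd.DataFrame(
                {"time_h": self.times, "variable": name, "value": col}))
        return pd.concat(recs, ignore_index=True)


def _clip_states(y: np.ndarray) -> np.ndarray:
    worst = y.min(initial=0.0)
    if worst < -_NEG_CLIP_TOL:
        warnings.warn(
            f"state undershoot {worst:.3e} beyond tolerance; clipping to 0",
            RuntimeWarning, stacklevel=3,
        )
    return np.clip(y, 0.0, None)


def integrate(params: ParameterSet, y0, protocol: TreatmentProtocol,
              t_span=None, rtol: float = RTOL, atol: float = ATOL,
              t_eval=None, method: str = "LSODA") -> Trajectory:
    """Integrate the network under a protocol.

    ``t_span`` defaults to ``(0, protocol.horizon_h)`` and must lie
    within the horizon.  The returned grid is the union of ``t_eval``
    (default: 241 evenly spaced points) and all event times in the span.
    """
    if t_span is None:
        t_span = (0.0, protocol.horizon_h)
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (0.0 <= t0 < t1 <= protocol.horizon_h):
        raise ValueError(f"t_span {t_span} outside protocol horizon")
    y = np.asarray(y0, dtype=float).copy()
    if y.shape != (N_STATES,) or np.any(y < 0):
        raise ValueError("y0 must be a non-negative 10-state vector")

    events = [t for t in protocol.event_times() if t0 <= t <= t1]
    breaks = sorted({t0, t1, *events})
    if t_eval is None:
        t_eval = np.linspace(t0, t1, 241)
    grid = np.unique(np.concatenate([np.asarray(t_eval, float), breaks]))

    c = pack_constants(params)
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    segments = []
    for seg_start, seg_end in zip(breaks[:-1], breaks[1:]):
        for agent, dose in protocol.impulses_at(seg_start).items():
            if agent is Agent.IL15:
                y[0] += dose
        e = effective_inputs(params, protocol, seg_start).as_tuple()
        seg_times = grid[(grid >= seg_start) & (grid <= seg_end)]
        sol = solve_ivp(
            rhs_core, (seg_start, seg_end), y, method=method,
            t_eval=seg_times, args=(c, e), rtol=rtol, atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise StiffnessError(
                f"solver failed on [{seg_start}, {seg_end}] h: {sol.message}"
            )
        segments.append((seg_start, seg_end, sol.sol, y.copy()))
        y = _clip_states(sol.y[:, -1].copy())
        states_out.append(_clip_states(sol.y.T))
        times_out.append(sol.t)

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    keep = np.concatenate([[True], np.diff(times) > 0])
    # keep the post-impulse row at event times (later duplicate wins)
    dup_starts = np.flatnonzero(~keep) - 1
    states[dup_starts] = states[dup_starts + 1]
    return Trajectory(times=times[keep], states=states[keep],
                      protocol=protocol, _segments=segments)


def condition_protocol(condition: str, horizon_h: float = 100.0,
                       il15_primed: bool = False,
                       dmog_dose: float = 1.0) -> TreatmentProtocol:
    """Constant-condition protocol: 'normoxia' or 'dmog' (from t = 0),
    optionally with an IL-15 priming impulse at t = 0."""
    events: list[TreatmentEvent] = []
    if condition not in ("normoxia", "dmog"):
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "dmog":
        events.append(TreatmentEvent(0.0, Agent.DMOG, dmog_dose))
    if il15_primed:
        events.append(TreatmentEvent(0.0, Agent.IL15, 1.0))
    return TreatmentProtocol(events=tuple(events), horizon_h=horizon_h,
                             label=condition)


def steady_state_value(params: ParameterSet, protocol: TreatmentProtocol,
                       y0=None, t_end: float = 100.0,
                       rtol: float = RTOL, atol: float = ATOL):
    """Steady state as the t = 100 h endpoint of a constant condition.

    Returns ``(y_end, diagnostic)`` where the diagnostic reports the
    endpoint derivative max-norm and flags non-convergence if any
    component moves by more than 0.1% (relative) over the final 10 h.
    """
    if y0 is None:
        y0 = solve_consistent_equilibrium(params).state
    traj = integrate(params, y0, protocol, t_span=(0.0, t_end),
                     rtol=rtol, atol=atol,
                     t_eval=np.array([0.0, t_end - 10.0, t_end]))
    y_end = traj.states[-1]
    y_prev = traj.eval_states(t_end - 10.0)[0]
    # Convergence is judged on the internal states: the IL-15 input has
    # no feedback and decays exponentially, so its *relative* change
    # never settles; its residual is reported separately.  States are
    # normalized, hence the floor of one normalized unit.
    scale = np.maximum(np.abs(y_end[1:]), 1.0)
    drift = float(np.max(np.abs(y_end[1:] - y_prev[1:]) / scale))
    c = pack_constants(params)
    e = effective_inputs(params, protocol, t_end).as_tuple()
    dy = rhs_core(t_end, y_end, c, e)
    diagnostic = {
        "max_abs_derivative": float(np.max(np.abs(dy))),
        "final_10h_max_rel_change": drift,
        "il15_residual": float(y_end[0]),
        "converged": drift <= 1e-3,
    }
    return y_end, diagnostic


# ---------------------------------------------------------------------------
# Parameter sweeps (external-regulation experiments)
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Steady-state summaries over a 1-D or 2-D parameter grid."""

    names: list[str]
    grids: list[np.ndarray]
    condition: str
    values: dict[str, np.ndarray]     # summary -> array with grid shape
    missing: list[tuple] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        mesh = np.meshgrid(*self.grids, indexing="ij")
        recs = {n: m.ravel() for n, m in zip(self.names, mesh)}
        for k, v in self.values.items():
            recs[k] = v.ravel()
        df = pd.DataFrame(recs)
        df.insert(0, "condition", self.condition)
        return df


_SWEEP_SUMMARIES = {
    "TOTAL_HIF": lambda y: float(total_hif(y)),
    "STAT3": lambda y: float(y[7]),
    "MTOR": lambda y: float(y[2]),
    "NFKB": lambda y: float(y[6]),
}


def parameter_sweep(params: ParameterSet, names, grids,
                    condition: str = "normoxia",
                    il15_primed: bool = False,
                    rtol: float = 1e-7, atol: float = 1e-9) -> SweepResult:
    """Steady-state response to external-regulation rates.

    Sweeping a basal rate IS the perturbation: the untreated equilibrium
    is not re-solved per grid point; the initial state stays canonical
    (solved once from the base parameters).
    """
    names = list(names)
    grids = [np.asarray(g, dtype=float) for g in grids]
    if len(names) not in (1, 2) or len(names) != len(grids):
        raise ValueError("sweeps support 1 or 2 parameters with one grid each")
    for n in names:
        if n not in params.values:
            raise KeyError(n)
    base_eq = solve_consistent_equilibrium(params)
    base = base_eq.params.copy()
    # swept rates must behave as plain constants even where the default
    # role ties them to the untreated steady state (a1 is tied to 0)
    for n in names:
        base.roles[n] = "fixed"
    y0 = base_eq.state.copy()
    if il15_primed:
        y0[0] += 1.0
    proto = condition_protocol(condition, horizon_h=100.0)
    shape = tuple(g.size for g in grids)
    values = {k: np.full(shape, np.nan) for k in _SWEEP_SUMMARIES}
    missing = []
    for idx in product(*(range(s) for s in shape)):
        point = {n: g[i] for n, g, i in zip(names, grids, idx)}
        try:
            trial = base.with_updates(point)
            y_end, _ = steady_state_value(trial, proto, y0=y0,
                                          rtol=rtol, atol=atol)
        except Exception as exc:  # record and continue
            missing.append((idx, str(exc)))
            continue
        for k, fn in _SWEEP_SUMMARIES.items():
            values[k][idx] = fn(y_end)
    return SweepResult(names=names, grids=grids, condition=condition,
                       values=values, missing=missing)


# ---------------------------------------------------------------------------
# DMOG dose-response
# ---------------------------------------------------------------------------

def dose_response(params: ParameterSet, dose_grid=None,
                  with_il15_priming: bool = True,
                  rtol: float = 1e-7, atol: float = 1e-9) -> pd.DataFrame:
    """Fold change of steady-state total HIF-1a vs DMOG dose.

    Dose 1.0 corresponds to 20 uM DMOG; hydroxylase inhibition scales
    linearly with dose.  Fold changes are normalized to the dose-0
    steady state.
    """
    if dose_grid is None:
        dose_grid = np.linspace(0.0, 1.0, 11)
    dose_grid = np.asarray(dose_grid, dtype=float)
    if np.any((dose_grid < 0) | (dose_grid > 1)):
        raise ValueError("DMOG doses must lie in [0, 1]")
    eq = solve_consistent_equilibrium(params)
    y0 = eq.state.copy()
    if with_il15_priming:
        y0[0] += 1.0
    levels = []
    for dose in dose_grid:
        proto = condition_protocol("dmog", dmog_dose=dose) if dose > 0 \
            else condition_protocol("normoxia")
        y_end, _ = steady_state_value(eq.params, proto, y0=y0,
                                      rtol=rtol, atol=atol)
        levels.append(float(total_hif(y_end)))
    levels = np.asarray(levels)
    ref = levels[np.flatnonzero(dose_grid == 0.0)[0]] \
        if np.any(dose_grid == 0.0) else levels[0]
    return pd.DataFrame({
        "dose": dose_grid,
        "total_hif_steady_state": levels,
        "fold_change": levels / ref,
    })


# ---------------------------------------------------------------------------
# Treatment-timing experiments
# ---------------------------------------------------------------------------

def timing_protocols(horizon_h: float = 30.0) -> dict[str, TreatmentProtocol]:
    """The nine treatment-timing protocols (keys follow the published
    color code)."""
    E = TreatmentEvent
    A = Agent

    def proto(label, *events):
        return TreatmentProtocol(events=events, horizon_h=horizon_h,
                                 label=label)

    return {
        "gray: untreated": proto("gray: untreated"),
        "dark blue: IL-15 at 0 h": proto(
            "dark blue: IL-15 at 0 h", E(0.0, A.IL15)),
        "magenta: DMOG from 0 h": proto(
            "magenta: DMOG from 0 h", E(0.0, A.DMOG)),
        "green: IL-15 at 0 h + DMOG from 0 h": proto(
            "green: IL-15 at 0 h + DMOG from 0 h",
            E(0.0, A.IL15), E(0.0, A.DMOG)),
        "yellow: IL-15 at 6 h": proto(
            "yellow: IL-15 at 6 h", E(6.0, A.IL15)),
        "orange: DMOG from 6 h": proto(
            "orange: DMOG from 6 h", E(6.0, A.DMOG)),
        "red: IL-15 + DMOG at 6 h": proto(
            "red: IL-15 + DMOG at 6 h", E(6.0, A.IL15), E(6.0, A.DMOG)),
        "light blue: DMOG from 0 h + IL-15 at 6 h": proto(
            "light blue: DMOG from 0 h + IL-15 at 6 h",
            E(0.0, A.DMOG), E(6.0, A.IL15)),
        "black: IL-15 at 0 h + DMOG from 6 h": proto(
            "black: IL-15 at 0 h + DMOG from 6 h",
            E(0.0, A.IL15), E(6.0, A.DMOG)),
    }


def timing_experiment(params: ParameterSet, protocol_library=None,
                      readout_h: float = 12.0,
                      rtol: float = RTOL, atol: float = ATOL) -> pd.DataFrame:
    """Total HIF-1a at 12 h per protocol, normalized to untreated cells.

    Protocols must extend to at least 30 h so the full treatment-timing
    battery is well defined.
    """
    if protocol_library is None:
        protocol_library = timing_protocols()
    for label, proto in protocol_library.items():
        if proto.horizon_h < 30.0:
            raise ValueError(f"protocol {label!r} shorter than 30 h")
    eq = solve_consistent_equilibrium(params)
    ref_traj = integrate(eq.params, eq.state, untreated(30.0),
                         t_span=(0.0, 30.0), rtol=rtol, atol=atol)
    ref = float(total_hif(ref_traj.eval_states(readout_h)[0]))
    rows = []
    for label, proto in protocol_library.items():
        traj = integrate(eq.params, eq.state, proto, t_span=(0.0, 30.0),
                         rtol=rtol, atol=atol)
        level = float(total_hif(traj.eval_states(readout_h)[0]))
        rows.append({"protocol": label,
                     "total_hif_at_readout": level,
                     "fold_change_vs_untreated": level / ref})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte Carlo robustness
# ---------------------------------------------------------------------------

ROBUSTNESS_ELEMENTS = ("IL15_input", "a2", "a3")


@dataclass
class RobustnessSummary:
    """Distribution of steady-state total HIF-1a under uniform +/-width
    perturbation of one element."""

    element: str
    width: float
    n: int
    seed: int
    baseline: float
    samples: np.ndarray
    multipliers: np.ndarray

    @property
    def relative_spread(self) -> float:
        """max over samples of |value - baseline| / baseline."""
        if self.baseline == 0:
            return 0.0
        return float(np.max(np.abs(self.samples - self.baseline))
                     / self.baseline)

    @property
    def percentile_band(self) -> tuple[float, float]:
        return (float(np.percentile(self.samples, 2.5)),
                float(np.percentile(self.samples, 97.5)))


def monte_carlo_robustness(params: ParameterSet, element: str,
                           width: float = 0.25, n: int = 1000,
                           seed: int = 0, t_end: float = 100.0,
                           rtol: float = 1e-6, atol: float = 1e-9,
                           ) -> RobustnessSummary:
    """Robustness of steady-state total HIF-1a to stochastic perturbation.

    Baseline condition: IL-15 priming (impulse 1 at t = 0) plus DMOG at
    full dose from t = 0; readout at t = 100 h.  ``element`` is either
    the extrinsic IL-15 input (the priming level ``y1(0)``) or one of
    the intrinsic basal activation rates ``a2`` (AKT) / ``a3`` (mTOR),
    sampled uniformly in ``base * [1 - width, 1 + width]`` with a seeded
    generator.
    """
    if element not in ROBUSTNESS_ELEMENTS:
        raise ValueError(
            f"element must be one of {ROBUSTNESS_ELEMENTS}, got {element!r}")
    if width < 0 or n < 1:
        raise ValueError("width must be >= 0 and n >= 1")
    eq = solve_consistent_equilibrium(params)
    proto = condition_protocol("dmog", horizon_h=t_end)
    y_base = eq.state.copy()
    y_base[0] = 1.0  # IL-15 priming

    def evaluate(mult: float) -> float:
        p, y0 = eq.params, y_base
        if element == "IL15_input":
            y0 = y_base.copy()
            y0[0] = mult
        else:
            p = p.with_updates({element: eq.params[element] * mult})
        y_end, _ = steady_state_value(p, proto, y0=y0, t_end=t_end,
                                      rtol=rtol, atol=atol)
        return float(total_hif(y_end))

    baseline = evaluate(1.0)
    rng = np.random.default_rng(seed)
    mults = rng.uniform(1.0 - width, 1.0 + width, size=n)
    samples = np.array([evaluate(m) for m in mults])
    return RobustnessSummary(element=element, width=width, n=n, seed=seed,
                             baseline=baseline, samples=samples,
                             multipliers=mults)
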