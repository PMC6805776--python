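"""Synthetic measurement data with the statistical structure the
calibration assumes.

Real calibration data for this network are densitometric and multiplex
time series that are not publicly deposited; this module generates
datasets with exactly the structure the estimation problem expects:
normalized observables (total HIF-1a, phospho-STAT3, phospho-AKT) under
the five study protocols, corrupted by independent additive zero-mean
Gaussian noise with a known per-point standard deviation.  Negative
noisy values are allowed, as in real densitometry ratios.

The default design emulates the study conditions: four calibration
experiments — (i) IL-15, (ii) DMOG, (iii) IL-15 + DMOG + rapamycin,
(iv) IL-15 + DMOG + S3I-201 — totalling 39 data points in the 0-27 h
observation window, plus a held-out IL-15 + DMOG validation experiment.
The exact measurement times and noise levels of the original study are
not published; the defaults here (times drawn from
{1, 2, 4, 8, 12, 27} h, sd 0.1 on the normalized scale) are documented
stand-ins and fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import ExperimentDataset, PEPConfig, fit_pep, observe
from .errors import NkhifError
from .model import solve_consistent_equilibrium
from .params import ParameterSet, build_default_parameters
from .protocols import Agent, TreatmentEvent, TreatmentProtocol
from .simulate import integrate

__all__ = [
    "SyntheticDesign",
    "default_design",
    "generate_dataset",
    "generate_calibration_suite",
    "RecoveryReport",
    "recovery_study",
]


def _proto(label: str, *agents: Agent, horizon_h: float = 30.0
           ) -> TreatmentProtocol:
    events = tuple(TreatmentEvent(0.0, a, 1.0) for a in agents)
    return TreatmentProtocol(events=events, horizon_h=horizon_h, label=label)


def _plan(times_by_obs: dict[str, list[float]], sd: float) -> pd.DataFrame:
    rows = [
        {"time_h": t, "observable": obs, "sd": sd}
        for obs, times in times_by_obs.items() for t in times
    ]
    return pd.DataFrame(rows)


@dataclass
class SyntheticDesign:
    """Ground truth, protocols and measurement plan of a synthetic study.

    ``plans`` maps each experiment label to a table of (time_h,
    observable, sd) rows; the experiment listed in ``validation_label``
    is excluded from fitting.
    """

    params_true: ParameterSet
    protocols: dict[str, TreatmentProtocol]
    plans: dict[str, pd.DataFrame]
    validation_label: str
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.plans) != set(self.protocols):
            raise ValueError("plans and protocols must cover the same labels")
        for label, plan in self.plans.items():
            if (plan["sd"] < 0).any():
                raise ValueError(f"negative sd in plan for {label!r}")
        if self.validation_label not in self.protocols:
            raise ValueError("validation experiment missing from protocols")

    @property
    def calibration_labels(self) -> list[str]:
        return [l for l in self.protocols if l != self.validation_label]

    @property
    def n_calibration_points(self) -> int:
        return sum(len(self.plans[l]) for l in self.calibration_labels)


def default_design(seed: int = 0, sd: float = 0.1,
                   params_true: ParameterSet | None = None) -> SyntheticDesign:
    """The study-sized design: 4 calibration experiments, 39 points,
    one validation experiment; noise sd 0.1 on the normalized scale.

    Ground truth defaults to the published parameterization made exactly
    consistent with the untreated equilibrium.
    """
    if params_true is None:
        params_true = solve_consistent_equilibrium(
            build_default_parameters()).params
    A = Agent
    protocols = {
        "IL15": _proto("IL15", A.IL15),
        "DMOG": _proto("DMOG", A.DMOG),
        "IL15+DMOG+RAPA": _proto("IL15+DMOG+RAPA", A.IL15, A.DMOG,
                                 A.RAPAMYCIN),
        "IL15+DMOG+S3I": _proto("IL15+DMOG+S3I", A.IL15, A.DMOG, A.S3I201),
        "IL15+DMOG": _proto("IL15+DMOG", A.IL15, A.DMOG),
    }
    base = {
        "TOTAL_HIF": [2.0, 4.0, 8.0, 12.0, 27.0],
        "STAT3": [1.0, 4.0, 12.0],
        "AKT": [1.0, 8.0],
    }
    plans = {
        "IL15": _plan(base, sd),
        "DMOG": _plan(base, sd),
        "IL15+DMOG+RAPA": _plan(base, sd),
        # drop one AKT point so the four calibration experiments carry
        # 39 points in total
        "IL15+DMOG+S3I": _plan({**base, "AKT": [1.0]}, sd),
        "IL15+DMOG": _plan({
            "TOTAL_HIF": [1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 27.0],
            "STAT3": [1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 27.0],
            "AKT": [1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 27.0],
        }, sd),
    }
    return SyntheticDesign(params_true=params_true, protocols=protocols,
                           plans=plans, validation_label="IL15+DMOG",
                           seed=seed)


def generate_dataset(protocol: TreatmentProtocol, params_true: ParameterSet,
                     plan: pd.DataFrame, seed, label: str = "",
                     y0=None, rtol: float = 1e-8, atol: float = 1e-10,
                     ) -> ExperimentDataset:
    """Simulate the true trajectory and add per-point Gaussian noise.

    ``plan`` columns: ``time_h``, ``observable``, ``sd``.  Noise is
    independent, zero-mean, with the given sd; noisy values are not
    clipped.  Rows with ``sd == 0`` receive no noise and are recorded
    with unit weight (sd 1.0), keeping the dataset usable for weighted
    fitting.  ``seed`` may be an int or a ``numpy`` Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if y0 is None:
        y0 = solve_consistent_equilibrium(params_true).state
    t_max = max(float(plan["time_h"].max()), 1e-6)
    traj = integrate(params_true, y0, protocol, t_span=(0.0, t_max),
                     t_eval=np.array([0.0, t_max]), rtol=rtol, atol=atol)
    g = observe(traj, plan["time_h"].to_numpy())
    obs_idx = {"TOTAL_HIF": 0, "STAT3": 1, "AKT": 2}
    model = g[np.arange(len(plan)),
              [obs_idx[o] for o in plan["observable"]]]
    sds = plan["sd"].to_numpy(dtype=float)
    noise = rng.standard_normal(len(plan)) * sds
    table = pd.DataFrame({
        "time_h": plan["time_h"].to_numpy(dtype=float),
        "observable": plan["observable"].to_numpy(),
        "value": model + noise,
        "sd": np.where(sds > 0, sds, 1.0),
    })
    return ExperimentDataset(label=label or protocol.label,
                             protocol=protocol, table=table)


def generate_calibration_suite(design: SyntheticDesign, seed=None
                               ) -> tuple[list[ExperimentDataset],
                                          ExperimentDataset]:
    """Generate the calibration datasets and the held-out validation set.

    One seeded generator drives all experiments so a design seed fully
    determines the suite.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    y0 = solve_consistent_equilibrium(design.params_true).state
    calibration = [
        generate_dataset(design.protocols[label], design.params_true,
                         design.plans[label], rng, label=label, y0=y0)
        for label in design.calibration_labels
    ]
    validation = generate_dataset(
        design.protocols[design.validation_label], design.params_true,
        design.plans[design.validation_label], rng,
        label=design.validation_label, y0=y0)
    return calibration, validation


# ---------------------------------------------------------------------------
# Parameter-recovery studies
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Per-parameter recovery statistics over seeded replicates."""

    summary: pd.DataFrame          # one row per free parameter
    estimates: pd.DataFrame        # one row per (replicate, parameter)
    n_replicates: int
    n_failures: int
    free_names: list[str] = field(default_factory=list)


def recovery_study(design: SyntheticDesign, free_names, n_replicates: int,
                   seed: int = 0, start_scale: float = 1.5,
                   config: PEPConfig | None = None) -> RecoveryReport:
    """Repeatedly regenerate noise, refit, and score the estimates.

    Each replicate draws a fresh noisy suite from the design, starts the
    fit at ``start_scale`` times the true free-parameter values, and
    records estimate, linearized sd and whether the +/-2 sd interval
    covers the truth.  Individual fit failures are recorded; more than
    50% failures raise an error.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    free_names = list(free_names)
    truth = {n: design.params_true[n] for n in free_names}
    config = config or PEPConfig(free_names=free_names, use_priors=False,
                                 rtol=1e-7, atol=1e-9, step_tol=1e-6,
                                 max_iter=30)
    config = PEPConfig(**{**config.__dict__, "free_names": free_names})
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    n_failures = 0
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        calibration, _ = generate_calibration_suite(design, seed=rng)
        start = {n: start_scale * truth[n] for n in free_names}
        for n in start:  # efficacies live in [0, 1]
            if n in ("rho3", "rho4", "rho6", "rho_rapa", "rho_nfkb"):
                start[n] = min(start[n], 1.0)
        try:
            fit = fit_pep(calibration, design.params_true, config,
                          start=start)
        except NkhifError as exc:
            n_failures += 1
            rows.append({"replicate": rep, "error": str(exc)})
            continue
        for n in free_names:
            est, sd = fit.estimates[n], fit.sd[n]
            rows.append({
                "replicate": rep, "parameter": n, "truth": truth[n],
                "estimate": est, "sd": sd,
                "covered": abs(est - truth[n]) <= 2.0 * sd,
                "converged": fit.converged,
            })
    if n_failures > 0.5 * n_replicates:
        raise NkhifError(
            f"{n_failures}/{n_replicates} recovery fits failed")
    est = pd.DataFrame([r for r in rows if "parameter" in r])
    summary = (
        est.groupby("parameter", sort=False)
        .apply(lambda g: pd.Series({
            "truth": g["truth"].iloc[0],
            "mean_estimate": g["estimate"].mean(),
            "bias": (g["estimate"] - g["truth"]).mean(),
            "rmse": np.sqrt(((g["estimate"] - g["truth"]) ** 2).mean()),
            "coverage": g["covered"].mean(),
        }), include_groups=False)
        .reset_index()
    )
    return RecoveryReport(summary=summary, estimates=est,
                          n_replicates=n_replicates, n_failures=n_failures,
                          free_names=free_names)
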