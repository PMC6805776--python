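"""Scenario presets reproducing each in-silico experiment end to end.

Each scenario builds its inputs, runs the corresponding operation and
writes tidy CSV results plus a JSON metadata sidecar (seed, tolerances,
protocols, package version) sufficient to reconstruct the run.  Scenario
ids follow the experiment battery:

========== ==========================================================
id          experiment
========== ==========================================================
fit         calibrate a free-parameter subset on a synthetic suite
validate    simulate the held-out IL-15+DMOG experiment vs its data
figure4_5   treatment/inhibitor trajectory panels (normoxia and DMOG)
figure6     IL-15 external-regulation sweep (a1 in [0, 10] nM/h)
figure7     mTOR (a3) and STAT3 (a8) external-regulation sweeps
figure8     2-D sweeps: (a3, a8) and (a7, a8)
figure9     2-D sweep: (a1, a8)
figure10    Monte Carlo robustness (IL-15 input, a2, a3; n = 1000)
figure11    DMOG dose-response (0-100% of 20 uM)
figure12    treatment-timing battery, 12 h fold changes
recovery    parameter-recovery study on synthetic replicates
========== ==========================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import PEPConfig, fit_pep, observe
from .model import solve_consistent_equilibrium, total_hif
from .params import ParameterSet, build_default_parameters, load_parameters
from .protocols import Agent, TreatmentEvent, TreatmentProtocol
from .simulate import (
    condition_protocol,
    dose_response,
    integrate,
    monte_carlo_robustness,
    parameter_sweep,
    timing_experiment,
)
from .synthetic import default_design, generate_calibration_suite, recovery_study

__all__ = [
    "ScenarioSpec",
    "run_scenario",
    "validate_inputs",
    "load_protocol",
    "save_protocol",
    "SCENARIOS",
]


def load_protocol(path) -> TreatmentProtocol:
    """Read a protocol YAML: {horizon_h, label, events: [{time_h, agent,
    dose_fraction}, ...]}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    events = tuple(
        TreatmentEvent(float(e["time_h"]), Agent(e["agent"]),
                       float(e.get("dose_fraction", 1.0)))
        for e in doc.get("events", [])
    )
    return TreatmentProtocol(events=events,
                             horizon_h=float(doc.get("horizon_h", 100.0)),
                             label=str(doc.get("label", "")))


def save_protocol(protocol: TreatmentProtocol, path) -> None:
    doc = {
        "label": protocol.label,
        "horizon_h": protocol.horizon_h,
        "events": [
            {"time_h": e.time_h, "agent": e.agent.value,
             "dose_fraction": e.dose_fraction}
            for e in protocol.events
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class ScenarioSpec:
    scenario: str
    out_dir: str | Path = "results"
    seed: int = 0
    params_file: str | None = None
    overrides: dict = field(default_factory=dict)
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; "
                f"choose from {sorted(SCENARIOS)}"
            )

    def to_dict(self) -> dict:
        return {"scenario": self.scenario, "out_dir": str(self.out_dir),
                "seed": self.seed, "params_file": self.params_file,
                "overrides": self.overrides, "rtol": self.rtol,
                "atol": self.atol}


def _params(spec: ScenarioSpec) -> ParameterSet:
    if spec.params_file:
        return load_parameters(spec.params_file)
    return build_default_parameters()


def _treatment_settings():
    A = Agent
    E = TreatmentEvent
    return {
        "untreated": (),
        "IL15": (E(0.0, A.IL15),),
        "IL15+S3I": (E(0.0, A.IL15), E(0.0, A.S3I201)),
        "IL15+RAPA": (E(0.0, A.IL15), E(0.0, A.RAPAMYCIN)),
        "IL15+NFKBi": (E(0.0, A.IL15), E(0.0, A.NFKB_INHIBITOR)),
        "IL15+S3I+RAPA": (E(0.0, A.IL15), E(0.0, A.S3I201),
                          E(0.0, A.RAPAMYCIN)),
        "IL15+NFKBi+RAPA": (E(0.0, A.IL15), E(0.0, A.NFKB_INHIBITOR),
                            E(0.0, A.RAPAMYCIN)),
        "IL15+NFKBi+S3I": (E(0.0, A.IL15), E(0.0, A.NFKB_INHIBITOR),
                           E(0.0, A.S3I201)),
    }


def _run_figure4_5(spec, params, out):
    eq = solve_consistent_equilibrium(params)
    frames = []
    for condition in ("normoxia", "dmog"):
        dmog = (TreatmentEvent(0.0, Agent.DMOG),) if condition == "dmog" else ()
        for setting, events in _treatment_settings().items():
            proto = TreatmentProtocol(events=events + dmog, horizon_h=30.0,
                                      label=setting)
            traj = integrate(eq.params, eq.state, proto, t_span=(0.0, 30.0),
                             rtol=spec.rtol, atol=spec.atol)
            df = traj.to_frame()
            df.insert(0, "setting", setting)
            df.insert(0, "condition", condition)
            frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        out / "trajectories.csv", index=False)
    return {"settings": len(_treatment_settings()), "conditions": 2}


def _run_sweep(spec, params, out, names, grids):
    frames = []
    for condition in ("normoxia", "dmog"):
        res = parameter_sweep(params, names, grids, condition=condition)
        frames.append(res.to_frame())
    pd.concat(frames, ignore_index=True).to_csv(out / "sweep.csv", index=False)
    return {"parameters": names, "grid_sizes": [len(g) for g in grids]}


def _run_figure10(spec, params, out):
    n = int(spec.overrides.get("n_samples", 1000))
    rows = []
    for i, element in enumerate(("IL15_input", "a2", "a3")):
        summ = monte_carlo_robustness(params, element, width=0.25, n=n,
                                      seed=spec.seed + i)
        lo, hi = summ.percentile_band
        rows.append({
            "element": element, "n": summ.n, "width": summ.width,
            "seed": summ.seed, "baseline_total_hif": summ.baseline,
            "relative_spread": summ.relative_spread,
            "p2.5": lo, "p97.5": hi,
        })
        pd.DataFrame({"multiplier": summ.multipliers,
                      "total_hif": summ.samples}).to_csv(
            out / f"samples_{element}.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "robustness.csv", index=False)
    return {"n_samples": n, "elements": 3}


def _run_fit(spec, params, out):
    free = spec.overrides.get("free_names",
                              ["d1", "k6", "k3", "d3", "k4"])
    n_max = int(spec.overrides.get("max_iter", 30))
    design = default_design(seed=spec.seed)
    calibration, _ = generate_calibration_suite(design)
    cfg = PEPConfig(free_names=list(free), use_priors=False,
                    max_iter=n_max, rtol=1e-7, atol=1e-9)
    start = {n: 1.3 * design.params_true[n] for n in free}
    fit = fit_pep(calibration, design.params_true, cfg, start=start)
    with open(out / "fit.json", "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2, default=float)
    return {"free_names": list(free), "objective": fit.objective,
            "converged": fit.converged}


def _run_validate(spec, params, out):
    design = default_design(seed=spec.seed)
    _, validation = generate_calibration_suite(design)
    eq = solve_consistent_equilibrium(params)
    t_max = float(validation.table["time_h"].max())
    traj = integrate(eq.params, eq.state, validation.protocol,
                     t_span=(0.0, t_max), rtol=spec.rtol, atol=spec.atol)
    g = observe(traj, validation.table["time_h"].to_numpy())
    obs_idx = {"TOTAL_HIF": 0, "STAT3": 1, "AKT": 2}
    pred = g[np.arange(len(validation.table)),
             [obs_idx[o] for o in validation.table["observable"]]]
    df = validation.table.copy()
    df["prediction"] = pred
    df["weighted_residual"] = (pred - df["value"]) / df["sd"]
    df.to_csv(out / "validation.csv", index=False)
    return {"n_points": len(df),
            "rms_weighted_residual":
                float(np.sqrt(np.mean(df["weighted_residual"] ** 2)))}


def _run_recovery(spec, params, out):
    free = spec.overrides.get("free_names",
                              ["d1", "k6", "k3", "d3", "k4"])
    n_rep = int(spec.overrides.get("n_replicates", 5))
    design = default_design(seed=spec.seed)
    report = recovery_study(design, free, n_rep, seed=spec.seed)
    report.summary.to_csv(out / "recovery_summary.csv", index=False)
    report.estimates.to_csv(out / "recovery_estimates.csv", index=False)
    return {"free_names": list(free), "n_replicates": n_rep,
            "n_failures": report.n_failures}


SCENARIOS = {
    "fit": _run_fit,
    "validate": _run_validate,
    "figure4_5": _run_figure4_5,
    "figure6": lambda s, p, o: _run_sweep(
        s, p, o, ["a1"], [np.linspace(0.0, 10.0, 11)]),
    "figure7": lambda s, p, o: {
        "a3": _run_sweep(s, p, o / "a3", ["a3"], [np.linspace(0, 10, 11)]),
        "a8": _run_sweep(s, p, o / "a8", ["a8"], [np.linspace(0, 10, 11)]),
    },
    "figure8": lambda s, p, o: {
        "a3_a8": _run_sweep(s, p, o / "a3_a8", ["a3", "a8"],
                            [np.linspace(0, 10, 6)] * 2),
        "a7_a8": _run_sweep(s, p, o / "a7_a8", ["a7", "a8"],
                            [np.linspace(0, 10, 6)] * 2),
    },
    "figure9": lambda s, p, o: _run_sweep(
        s, p, o, ["a1", "a8"],
        [np.linspace(0, 5, 6), np.linspace(0, 10, 6)]),
    "figure10": _run_figure10,
    "figure11": lambda s, p, o: (
        dose_response(p, np.linspace(0.0, 1.0, 11)).to_csv(
            o / "dose_response.csv", index=False),
        {"doses": 11})[1],
    "figure12": lambda s, p, o: (
        timing_experiment(p).to_csv(o / "timing.csv", index=False),
        {"protocols": 9})[1],
    "recovery": _run_recovery,
}


def run_scenario(spec: ScenarioSpec) -> Path:
    """Run a scenario preset and write its result bundle.

    Returns the output directory.  A ``metadata.json`` sidecar records
    the full spec, seed and package version so the run can be
    reproduced bit-for-bit.
    """
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in ("a3", "a8", "a3_a8", "a7_a8"):
        if spec.scenario in ("figure7", "figure8"):
            (out / sub).mkdir(exist_ok=True)
    params = _params(spec)
    summary = SCENARIOS[spec.scenario](spec, params, out)
    from . import __version__
    meta = {"spec": spec.to_dict(), "package_version": __version__,
            "summary": summary}
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
    return out


def validate_inputs(parameter_file=None, protocol_file=None,
                    dataset_file=None) -> dict:
    """Schema and invariant checks with line-level diagnostics.

    Returns ``{"valid": bool, "diagnostics": [str, ...]}``; the loaders'
    own invariants (non-negativity, efficacy ranges, sd > 0, monotone
    times) supply the messages.
    """
    diagnostics: list[str] = []

    if parameter_file is not None:
        try:
            load_parameters(parameter_file)
        except Exception as exc:
            diagnostics.append(f"parameters: {exc}")

    if protocol_file is not None:
        try:
            load_protocol(protocol_file)
        except Exception as exc:
            diagnostics.append(f"protocol: {exc}")

    if dataset_file is not None:
        try:
            df = pd.read_csv(dataset_file)
            for col in ("time_h", "observable", "value", "sd"):
                if col not in df.columns:
                    diagnostics.append(f"dataset: missing column {col!r}")
            if "sd" in df.columns:
                for idx in df.index[df["sd"] <= 0]:
                    diagnostics.append(
                        f"dataset row {idx}: sd must be > 0, got "
                        f"{df.loc[idx, 'sd']}")
            if "time_h" in df.columns:
                for idx in df.index[df["time_h"] < 0]:
                    diagnostics.append(
                        f"dataset row {idx}: negative time "
                        f"{df.loc[idx, 'time_h']}")
        except Exception as exc:
            diagnostics.append(f"dataset: {exc}")

    return {"valid": not diagnostics, "diagnostics": diagnostics}
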