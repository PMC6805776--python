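"""Parameters of the NK-cell HIF-1a regulatory network.

The model is parameterized by ~50 non-negative constants: basal
production rates (``a*``), first-order decay rates (``d*``), activation
and catalytic rates (``k*``), Michaelis/Hill thresholds (``xi*``),
hydroxylase equilibrium levels (``a11``, ``phi``, ``Delta``), inhibitor
efficacies (``rho*``) and the HIF-1 feedback constants ``alpha1``,
``alpha2``.  Each parameter carries a role flag:

* ``fixed`` -- held constant during calibration,
* ``free``  -- estimated (the default free set has 25 members),
* ``tied``  -- resolved algebraically from the untreated steady state
  (``a1 = 0`` and ``d8 = k8``) and never exposed as a degree of freedom.

States are normalized to their untreated t=0 values, so all parameter
values act on dimensionless states even where the nominal unit is nM.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "PARAMETER_NAMES",
    "ParameterSet",
    "build_default_parameters",
    "load_parameters",
    "save_parameters",
]

#: Canonical parameter ordering used everywhere (arrays, Jacobian columns).
PARAMETER_NAMES: tuple[str, ...] = (
    "a1", "a2", "a3", "a5", "a7", "a8", "a9", "a11",
    "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "d9", "d10",
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10",
    "k11", "k12", "k13", "k14", "k15", "kS", "k_alpha",
    "n2", "xi28", "xi4", "xi44", "xi10",
    "Delta", "phi", "K_O2",
    "rho3", "rho4", "rho6", "rho_rapa", "rho_nfkb",
    "alpha1", "alpha2",
)

#: Parameters constrained to [0, 1] (inhibitor efficacies).
EFFICACY_NAMES: frozenset[str] = frozenset(
    {"rho3", "rho4", "rho6", "rho_rapa", "rho_nfkb"}
)

_VALID_ROLES = ("fixed", "free", "tied")


@dataclass
class ParameterSet:
    """All rate constants of the network plus calibration metadata.

    Parameters are accessed by name (``p["k4"]``).  ``priors`` holds the
    regularization anchors p0 and ``lambdas`` the per-parameter Tikhonov
    scales; ``lam = inf`` (the default for parameters without an explicit
    scale) switches the prior off.
    """

    values: dict[str, float]
    roles: dict[str, str]
    priors: dict[str, float] = field(default_factory=dict)
    lambdas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        missing = set(PARAMETER_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing parameter values: {sorted(missing)}")
        for name, role in self.roles.items():
            if role not in _VALID_ROLES:
                raise ValueError(f"invalid role {role!r} for {name!r}")
        self.resolve_ties()
        self.validate()

    # -- access ------------------------------------------------------------

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __setitem__(self, name: str, value: float) -> None:
        if name not in self.values:
            raise KeyError(name)
        self.values[name] = float(value)
        self.resolve_ties()

    def role(self, name: str) -> str:
        return self.roles.get(name, "fixed")

    @property
    def free_names(self) -> list[str]:
        """Free parameters, in canonical order."""
        return [n for n in PARAMETER_NAMES if self.role(n) == "free"]

    # -- manipulation --------------------------------------------------------

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            values=dict(self.values),
            roles=dict(self.roles),
            priors=dict(self.priors),
            lambdas=dict(self.lambdas),
        )

    def with_updates(self, updates: Mapping[str, float]) -> "ParameterSet":
        new = self.copy()
        for name, value in updates.items():
            if name not in new.values:
                raise KeyError(name)
            new.values[name] = float(value)
        new.resolve_ties()
        new.validate()
        return new

    def resolve_ties(self) -> None:
        """Apply the steady-state ties (a1 := 0, d8 := k8) in place."""
        if self.role("a1") == "tied":
            self.values["a1"] = 0.0
        if self.role("d8") == "tied":
            self.values["d8"] = self.values["k8"]

    def validate(self) -> None:
        for name, value in self.values.items():
            if not (value == value) or value in (float("inf"), float("-inf")):
                raise ValueError(f"parameter {name!r} is not finite: {value}")
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")
            if name in EFFICACY_NAMES and value > 1.0:
                raise ValueError(
                    f"efficacy {name!r} must lie in [0, 1], got {value}"
                )

    def free_values(self, names: Iterable[str] | None = None) -> list[float]:
        names = list(names) if names is not None else self.free_names
        return [self.values[n] for n in names]


def _published() -> dict:
    text = (
        importlib.resources.files("nkhif.data")
        .joinpath("published_parameters.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def build_default_parameters() -> ParameterSet:
    """The published parameterization of the network.

    Role flags mark the 25-parameter default free set; priors default to
    the published values with weak Tikhonov scales lambda = 10*|p0|.
    """
    doc = _published()
    values = {k: float(v) for k, v in doc["values"].items()}
    roles = {n: "tied" for n in doc["roles"]["tied"]}
    roles.update({n: "free" for n in doc["roles"]["free"]})
    for n in PARAMETER_NAMES:
        roles.setdefault(n, "fixed")
    priors = {n: values[n] for n in doc["roles"]["free"]}
    lambdas = {n: 10.0 * abs(values[n]) if values[n] != 0 else 10.0
               for n in doc["roles"]["free"]}
    return ParameterSet(values=values, roles=roles, priors=priors,
                        lambdas=lambdas)


def load_parameters(path) -> ParameterSet:
    """Read a ParameterSet from a YAML document (same layout as the
    packaged ``published_parameters.yaml``; ``priors``/``lambdas`` blocks
    optional)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    values = {k: float(v) for k, v in doc["values"].items()}
    roles_doc = doc.get("roles", {})
    roles = {n: "tied" for n in roles_doc.get("tied", [])}
    roles.update({n: "free" for n in roles_doc.get("free", [])})
    for n in PARAMETER_NAMES:
        roles.setdefault(n, "fixed")
    priors = {k: float(v) for k, v in doc.get("priors", {}).items()}
    lambdas = {k: float(v) for k, v in doc.get("lambdas", {}).items()}
    return ParameterSet(values=values, roles=roles, priors=priors,
                        lambdas=lambdas)


def save_parameters(params: ParameterSet, path) -> None:
    doc = {
        "values": {n: params.values[n] for n in PARAMETER_NAMES},
        "roles": {
            "tied": [n for n in PARAMETER_NAMES if params.role(n) == "tied"],
            "free": [n for n in PARAMETER_NAMES if params.role(n) == "free"],
        },
        "priors": dict(params.priors),
        "lambdas": dict(params.lambdas),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
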