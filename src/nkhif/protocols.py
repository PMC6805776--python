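"""Treatment protocols and their effect on the model equations.

A protocol is an ordered list of treatment events.  Agents act in two
ways:

* ``IL15`` events are impulses: the event adds ``dose_fraction`` to the
  IL-15 state at the event time (priming a culture with cytokine).
* ``DMOG``, ``RAPAMYCIN``, ``S3I201`` and ``NFKB_INHIBITOR`` events are
  sustained: the dose applies from the event time to the end of the
  horizon.  A later event for the same agent replaces the earlier dose,
  so a dose of 0 switches the agent off.

At any time the active doses reduce to five multiplicative scales on the
right-hand side (the :class:`EffectiveInputs`):

* DMOG inhibits the oxygen-dependent hydroxylases, scaling the three
  ``K_O2``-bearing hydroxylation terms by ``1 - rho6 * dose`` (dose 1.0
  corresponds to 20 uM DMOG, the inhibition scaling linearly with dose),
  and blunts IL-15-mediated STAT3 activation by ``1 - rho4`` whenever it
  is active (all-or-nothing by default).
* S3I-201 scales the whole STAT3 activation input by ``1 - rho3 * dose``.
* Rapamycin scales the mTOR activation input by ``1 - rho_rapa * dose``.
* The NF-kB inhibitor scales all NF-kB activation inputs by
  ``1 - rho_nfkb * dose``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Agent",
    "TreatmentEvent",
    "TreatmentProtocol",
    "EffectiveInputs",
    "effective_inputs",
    "untreated",
]


class Agent(str, Enum):
    IL15 = "IL15"
    DMOG = "DMOG"
    RAPAMYCIN = "RAPAMYCIN"
    S3I201 = "S3I201"
    NFKB_INHIBITOR = "NFKB_INHIBITOR"


#: Agents whose dose persists from onset to the end of the horizon.
SUSTAINED_AGENTS = (
    Agent.DMOG,
    Agent.RAPAMYCIN,
    Agent.S3I201,
    Agent.NFKB_INHIBITOR,
)


@dataclass(frozen=True)
class TreatmentEvent:
    time_h: float
    agent: Agent
    dose_fraction: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "agent", Agent(self.agent))
        if self.time_h < 0:
            raise ValueError(f"event time must be >= 0, got {self.time_h}")
        if not 0.0 <= self.dose_fraction <= 1.0:
            raise ValueError(
                f"dose_fraction must lie in [0, 1], got {self.dose_fraction}"
            )


@dataclass(frozen=True)
class TreatmentProtocol:
    """Ordered treatment events over a finite observation horizon."""

    events: tuple[TreatmentEvent, ...] = ()
    horizon_h: float = 100.0
    label: str = ""

    def __post_init__(self) -> None:
        evs = tuple(
            e if isinstance(e, TreatmentEvent) else TreatmentEvent(*e)
            for e in self.events
        )
        evs = tuple(sorted(evs, key=lambda e: e.time_h))
        object.__setattr__(self, "events", evs)
        if self.horizon_h <= 0:
            raise ValueError("horizon must be positive")
        for e in evs:
            if e.time_h > self.horizon_h:
                raise ValueError(
                    f"event at t={e.time_h} h outside horizon {self.horizon_h} h"
                )

    def event_times(self) -> list[float]:
        return sorted({e.time_h for e in self.events})

    def impulses_at(self, t: float) -> dict[Agent, float]:
        """Impulse doses (IL-15) scheduled exactly at time t."""
        out: dict[Agent, float] = {}
        for e in self.events:
            if e.agent is Agent.IL15 and e.time_h == t:
                out[Agent.IL15] = e.dose_fraction
        return out

    def dose(self, agent: Agent, t: float) -> float:
        """Active dose of a sustained agent at time t (last event wins)."""
        agent = Agent(agent)
        if agent is Agent.IL15:
            raise ValueError("IL15 is an impulse agent; it has no sustained dose")
        dose = 0.0
        for e in self.events:
            if e.agent is agent and e.time_h <= t:
                dose = e.dose_fraction
        return dose


def untreated(horizon_h: float = 100.0) -> TreatmentProtocol:
    return TreatmentProtocol(events=(), horizon_h=horizon_h, label="untreated")


@dataclass(frozen=True)
class EffectiveInputs:
    """Multiplicative scales the active treatments impose on the RHS."""

    hydroxylation_scale: float = 1.0   # on the three K_O2-bearing terms
    stat3_il15_scale: float = 1.0      # on the k6*y1 term
    stat3_block_scale: float = 1.0     # on the whole STAT3 activation input
    mtor_block_scale: float = 1.0      # on the mTOR activation input
    nfkb_block_scale: float = 1.0      # on the NF-kB activation inputs

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.hydroxylation_scale,
            self.stat3_il15_scale,
            self.stat3_block_scale,
            self.mtor_block_scale,
            self.nfkb_block_scale,
        )


IDENTITY_INPUTS = EffectiveInputs()


def effective_inputs(params, protocol: TreatmentProtocol | None,
                     t: float) -> EffectiveInputs:
    """Evaluate the treatment scales at time t.

    With no protocol (or no events) every scale is 1.  Raises
    ``ValueError`` if t lies outside the protocol horizon.
    """
    if protocol is None:
        return IDENTITY_INPUTS
    if not 0.0 <= t <= protocol.horizon_h:
        raise ValueError(
            f"t={t} h outside protocol horizon [0, {protocol.horizon_h}] h"
        )
    if not protocol.events:
        return IDENTITY_INPUTS
    dmog = protocol.dose(Agent.DMOG, t)
    s3i = protocol.dose(Agent.S3I201, t)
    rapa = protocol.dose(Agent.RAPAMYCIN, t)
    nfkbi = protocol.dose(Agent.NFKB_INHIBITOR, t)
    return EffectiveInputs(
        hydroxylation_scale=1.0 - params["rho6"] * dmog,
        stat3_il15_scale=1.0 - params["rho4"] * (1.0 if dmog > 0 else 0.0),
        stat3_block_scale=1.0 - params["rho3"] * s3i,
        mtor_block_scale=1.0 - params["rho_rapa"] * rapa,
        nfkb_block_scale=1.0 - params["rho_nfkb"] * nfkbi,
    )
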