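"""State, right-hand side and steady-state structure of the network.

The model tracks ten normalized concentrations:

====  ============  =====================================================
idx   name          species
====  ============  =====================================================
0     IL15          interleukin-15 (y1)
1     AKT           activated AKT (y2)
2     mTOR          activated mTOR (y3)
3     HIF1a         free HIF-1a protein (y4)
4     HIF1b         HIF-1b (y5)
5     HIF1          HIF-1 complex (y6)
6     NFkB          activated NF-kB (y7)
7     STAT3         phosphorylated STAT3 (y8)
8     HIF1a_mRNA    HIF-1a mRNA (y9)
9     HIF1a_aOH     asparaginyl-hydroxylated HIF-1a (y10)
====  ============  =====================================================

Untreated cells are normalized so that AKT, mTOR, HIF-1b, NF-kB, STAT3
and mRNA start at 1, while total HIF-1a (protein + complex + aOH form)
starts at 1 with split (0.05, 0.05, 0.9): in normoxia most HIF-1a is
hydroxylated.  IL-15 starts at 1 in primed cells and 0 otherwise.

The dynamics couple an IL-15 -> AKT -> mTOR -> STAT3/NF-kB signaling
cascade to HIF-1a transcription (via NF-kB and STAT3), translation,
FIH/PHD hydroxylation (PHD level modeled at quasi-steady state as
``Delta*y6 + a11``, FIH fixed at ``phi``), HIF-1 complex formation, a
negative HIF-1 feedback on mTOR and a positive one on NF-kB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import InfeasibleEquilibriumError, ModelDomainError, NumericError
from .params import ParameterSet
from .protocols import (
    EffectiveInputs,
    IDENTITY_INPUTS,
    TreatmentProtocol,
    effective_inputs,
)

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "canonical_initial_state",
    "rhs",
    "total_hif",
    "steady_state_residual",
    "solve_consistent_equilibrium",
    "EquilibriumResult",
]

STATE_NAMES: tuple[str, ...] = (
    "IL15", "AKT", "mTOR", "HIF1a", "HIF1b",
    "HIF1", "NFkB", "STAT3", "HIF1a_mRNA", "HIF1a_aOH",
)
N_STATES = len(STATE_NAMES)

#: Canonical split of total HIF-1a between protein, complex and aOH form.
DEFAULT_HIF_SPLIT = (0.05, 0.05, 0.9)


def canonical_initial_state(il15_primed: bool = False,
                            hif_split=DEFAULT_HIF_SPLIT) -> np.ndarray:
    """The normalized t=0 state of (un)primed cells in normoxia."""
    y4, y6, y10 = hif_split
    y = np.ones(N_STATES)
    y[0] = 1.0 if il15_primed else 0.0
    y[3], y[5], y[9] = y4, y6, y10
    return y


# Order in which parameters are packed for the fast RHS core.
_PACK_ORDER = (
    "a1", "a2", "a3", "a5", "a7", "a8", "a9", "a11",
    "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "d9", "d10",
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10",
    "k11", "k12", "k13", "k14", "k15", "kS", "k_alpha",
    "n2", "xi28", "xi4", "xi44", "xi10", "Delta", "phi", "K_O2",
    "alpha1", "alpha2",
)


def pack_constants(params: ParameterSet) -> tuple[float, ...]:
    """Flatten the rate constants into the tuple the RHS core consumes."""
    v = params.values
    return tuple(v[name] for name in _PACK_ORDER)


def _rhs_core_py(t: float, y, c: tuple, e: tuple) -> np.ndarray:
    """Time derivatives of the ten states (no validation; hot path).

    ``c`` is ``pack_constants(params)``; ``e`` the five treatment scales
    ``(hydroxylation, stat3_il15, stat3_block, mtor_block, nfkb_block)``.
    """
    (a1, a2, a3, a5, a7, a8, a9, a11,
     d1, d2, d3, d4, d5, d6, d7, d8, d9, d10,
     k1, k2, k3, k4, k5, k6, k7, k8, k9, k10,
     k11, k12, k13, k14, k15, kS, k_alpha,
     n2, xi28, xi4, xi44, xi10, Delta, phi, K_O2,
     alpha1, alpha2) = c
    h, s_il15, s_stat3, s_mtor, s_nfkb = e
    y1, y2, y3, y4, y5, y6, y7, y8, y9, y10 = y

    # Hill-type STAT3 -> AKT drive; defined as 0 on the degenerate input.
    y8n = y8 ** n2
    denom = xi28 ** n2 + y8n
    hill = kS * y8n / denom if denom != 0.0 else 0.0

    mtor_denom = alpha2 + y6
    mtor_drive = (s_mtor * (a3 + k2 * y2) * alpha1 / mtor_denom
                  if mtor_denom != 0.0 else 0.0)

    phd = Delta * y6 + a11           # quasi-steady-state PHD level
    den4 = xi4 + y4
    fih_term = h * k10 * K_O2 * phi * y4 / den4 if den4 != 0.0 else 0.0
    den44 = xi44 + y4
    phd_term4 = h * k13 * K_O2 * phd * y4 / den44 if den44 != 0.0 else 0.0
    den10 = xi10 + y10
    phd_term10 = h * k12 * K_O2 * phd * y10 / den10 if den10 != 0.0 else 0.0

    assoc = k4 * y4 * y5

    return np.array([
        a1 - d1 * y1,
        a2 + k1 * y1 + hill - d2 * y2,
        mtor_drive - d3 * y3,
        (k_alpha * y9 - d4 * y4 - assoc + k5 * y6
         - phd_term4 - fih_term + k11 * y10),
        a5 - assoc + k5 * y6 - d5 * y5,
        assoc - k5 * y6 - d6 * y6,
        s_nfkb * (a7 + k7 * y1 + k14 * y6 + k15 * y3) - d7 * y7,
        s_stat3 * (a8 + k8 * y3 + s_il15 * k6 * y1) - d8 * y8,
        a9 + k9 * y7 + k3 * y8 - d9 * y9,
        fih_term - phd_term10 - k11 * y10 - d10 * y10,
    ])


# The right-hand side dominates integration cost (thousands of solver
# callbacks per trajectory); compile it when numba is available.
try:  # pragma: no cover - exercised indirectly everywhere
    from numba import njit as _njit

    rhs_core = _njit(cache=True)(_rhs_core_py)
    rhs_core(0.0, np.ones(N_STATES), tuple(float(i + 1) for i in range(45)),
             (1.0, 1.0, 1.0, 1.0, 1.0))
except Exception:  # pragma: no cover
    rhs_core = _rhs_core_py


def rhs(t: float, y, params: ParameterSet,
        protocol: TreatmentProtocol | None = None,
        inputs: EffectiveInputs | None = None) -> np.ndarray:
    """Validated right-hand side under a treatment protocol.

    Treatment scales are taken from ``inputs`` when given, otherwise
    evaluated from ``protocol`` at time ``t`` (identity when both are
    absent).  Raises :class:`ModelDomainError` on negative states and
    :class:`NumericError` (naming the offending equation) on
    non-finite derivatives.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATES,):
        raise ModelDomainError(f"state must have {N_STATES} components")
    if np.any(y < 0):
        bad = int(np.argmin(y))
        raise ModelDomainError(
            f"negative state component {STATE_NAMES[bad]} = {y[bad]}"
        )
    if inputs is None:
        inputs = effective_inputs(params, protocol, t)
    dy = rhs_core(t, y, pack_constants(params), inputs.as_tuple())
    if not np.all(np.isfinite(dy)):
        bad = int(np.flatnonzero(~np.isfinite(dy))[0])
        raise NumericError(
            f"non-finite derivative in equation {bad + 1} ({STATE_NAMES[bad]})"
        )
    return dy


def total_hif(y) -> np.ndarray | float:
    """Total HIF-1a: free protein + HIF-1 complex + aOH form.

    Accepts a single state (shape ``(10,)``) or a trajectory array with
    states along the last axis.
    """
    y = np.asarray(y, dtype=float)
    return y[..., 3] + y[..., 5] + y[..., 9]


def steady_state_residual(y0, params: ParameterSet) -> np.ndarray:
    """The ten steady-state equations of untreated cells.

    Returns the right-hand side evaluated at ``y0`` under the untreated
    control; a consistent equilibrium makes every component vanish.
    """
    return rhs(0.0, y0, params, protocol=None)


# ---------------------------------------------------------------------------
# Consistent equilibrium
# ---------------------------------------------------------------------------

#: Parameters adjusted (with the HIF split) to make the printed values
#: consistent with the untreated steady state.  The printed tables are
#: rounded to three decimals, so exact equilibrium requires small slack.
SLACK_PARAMETERS = ("a2", "a3", "a5", "k_alpha", "d9", "d10")

# Residual rows with algebraic content once the ties hold
# (IL-15 row vanishes via a1 = 0, STAT3 row via d8 = k8 at the
# canonical normalization).
_ACTIVE_ROWS = np.array([1, 2, 3, 4, 5, 6, 8, 9])


@dataclass
class EquilibriumResult:
    """Consistent untreated equilibrium and the adjusted parameters."""

    state: np.ndarray
    params: ParameterSet
    adjustments: dict[str, tuple[float, float]] = field(default_factory=dict)
    max_residual: float = np.nan

    @property
    def max_relative_adjustment(self) -> float:
        rel = 0.0
        for old, new in self.adjustments.values():
            scale = abs(old) if old != 0 else 1.0
            rel = max(rel, abs(new - old) / scale)
        return rel

    def __iter__(self):
        return iter((self.state, self.params))


def solve_consistent_equilibrium(params: ParameterSet,
                                 tol: float = 1e-8,
                                 hif_split=DEFAULT_HIF_SPLIT,
                                 ) -> EquilibriumResult:
    """Adjust slack quantities so untreated cells sit exactly at rest.

    The canonical normalization is held fixed (unit AKT, mTOR, HIF-1b,
    NF-kB, STAT3 and mRNA; total HIF-1a = 1) while the basal rates
    ``a2, a3, a5``, the synthesis/decay rates ``k_alpha, d9, d10`` and
    the HIF split ``(y4, y6, y10)`` within the simplex are solved so the
    steady-state residual's max-norm falls below ``tol``.  The ties
    ``a1 = 0`` and ``d8 = k8`` are enforced throughout.  Adjustments are
    reported per quantity as ``(old, new)`` pairs.
    """
    params = params.copy()
    params.resolve_ties()

    base = [params[n] for n in SLACK_PARAMETERS]
    split0 = list(hif_split[:2])

    def unpack(q):
        trial = params.with_updates(
            {n: max(v, 0.0) for n, v in zip(SLACK_PARAMETERS, q[:6])}
        )
        y4, y6 = q[6], q[7]
        y0 = canonical_initial_state(il15_primed=False,
                                     hif_split=(y4, y6, 1.0 - y4 - y6))
        return trial, y0

    def system(q):
        trial, y0 = unpack(q)
        res = rhs_core(0.0, y0, pack_constants(trial),
                       IDENTITY_INPUTS.as_tuple())
        return res[_ACTIVE_ROWS]

    q0 = np.array(base + split0)
    sol = optimize.root(system, q0, method="hybr", tol=1e-12)
    trial, y0 = unpack(sol.x)
    residual = steady_state_residual(y0, trial)
    max_res = float(np.max(np.abs(residual)))
    if (not sol.success and max_res > tol) or max_res > tol:
        raise InfeasibleEquilibriumError(
            f"no consistent equilibrium found (max residual {max_res:.3e})"
        )
    if np.any(y0 < 0) or np.any(sol.x[:6] < 0):
        raise InfeasibleEquilibriumError(
            "consistent equilibrium violates non-negativity bounds"
        )

    adjustments = {
        n: (params[n], trial[n])
        for n in SLACK_PARAMETERS if params[n] != trial[n]
    }
    for name, old, new in (
        ("y4(0)", hif_split[0], y0[3]),
        ("y6(0)", hif_split[1], y0[5]),
        ("y10(0)", hif_split[2], y0[9]),
    ):
        if old != new:
            adjustments[name] = (old, new)
    return EquilibriumResult(state=y0, params=trial,
                             adjustments=adjustments, max_residual=max_res)
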