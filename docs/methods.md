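# Methods

## The regulatory network

The model is a deterministic, well-mixed, single-compartment description
of HIF-1α regulation in an NK-cell population. Ten species are tracked
(IL-15, activated AKT, activated mTOR, HIF-1α protein, HIF-1β, HIF-1
complex, activated NF-κB, phospho-STAT3, HIF-1α mRNA, HIF-1α-aOH), all
normalized to their untreated t = 0 values, so the state is
dimensionless while thresholds and basal rates keep their nominal nM /
nM h⁻¹ values from the published tables. The structural assumptions:

- IL-15 enters at a constant supply rate a₁ (zero for primed-only
  cultures) and decays first-order; it activates AKT, STAT3 and NF-κB
  through linear terms.
- AKT additionally receives a Hill-type STAT3 drive (coefficient n₂ = 2,
  threshold ξ₂₈) and feeds mTOR; mTOR activation is inhibited by the
  HIF-1 complex through the factor α₁/(α₂ + y₆) — the hypoxia→mTOR
  negative feedback.
- HIF-1α mRNA is produced by NF-κB (k₉) and STAT3 (k₃); the protein is
  translated at k_α, degraded basally at d₄, and hydroxylated by FIH
  (fixed level φ, Michaelis constant ξ₄) and by PHD, whose level is a
  quasi-steady-state function Δ·y₆ + a₁₁ of the HIF-1 complex (the
  PHD-mediated negative feedback). Prolyl-hydroxylated protein is
  treated as instantly degraded and not tracked; the asparaginyl form
  (aOH) can be further hydroxylated by PHD, dehydroxylated at k₁₁, or
  degraded.
- HIF-1β is constitutive; the α/β association (k₄) and dissociation
  (k₅) close the complex balance, and the complex activates NF-κB
  (k₁₄), the positive feedback that amplifies chemical hypoxia.

k₁₁ is printed with units nM h⁻¹ but acts first-order (k₁₁·y₁₀) in the
equations; the equations are implemented literally. Likewise the FIH
term uses k₁₀ even though the published description labels k₁₀
"PHD-mediated" — the equations, not the table prose, are authoritative
here.

## Treatments as controls

Events are of two kinds. IL-15 events are impulses: the dose is added
to y₁ at the event time (priming). DMOG, rapamycin, S3I-201 and the
NF-κB inhibitor are sustained: a dose holds from its onset until
replaced. At any instant the active doses reduce to five multiplicative
scales: DMOG multiplies the three K_O₂-bearing hydroxylation terms by
(1 − ρ₆·dose) — dose 1.0 ≡ 20 µM, inhibition linear in dose — and
multiplies the IL-15→STAT3 term by (1 − ρ₄) whenever it is active
(all-or-nothing; a dose-scaled variant would need data that do not
exist). S3I-201 scales the whole STAT3 activation input by (1 − ρ₃),
rapamycin the mTOR activation input by (1 − ρ_rapa), the NF-κB
inhibitor all NF-κB activation inputs by (1 − ρ_nfkb). ρ_rapa and
ρ_nfkb are never published; the defaults of 1.0 (complete block) are
assumptions and configurable.

## Consistent equilibrium

Untreated cells are assumed to rest: the initial state must solve the
ten steady-state equations. With the canonical normalization (unit
internal states, total HIF-1α = 1 split 0.05/0.05/0.9) and the ties
a₁ = 0, d₈ = k₈, eight equations retain content. The published values
are printed to three decimals, so they cannot satisfy equilibrium
exactly; `solve_consistent_equilibrium` adjusts a small slack set —
the basal rates a₂, a₃, a₅, the synthesis/decay rates k_α, d₉, d₁₀,
and the HIF split within its simplex — by root finding until the
residual max-norm is ≤ 1e−8. Six slack parameters plus two split
degrees of freedom are the minimal square system: fewer slacks leave
the eight equations over-determined (the basal rates alone absorb only
three of them). For the published tables every adjustment is below
1.4% (most below 0.25%), consistent with pure rounding; notably the
printed values satisfy k₉ + k₃ = d₉ and k₄ = k₅ + d₆ exactly, which is
how the remaining rows close.

## Integration and steady states

`integrate` restarts the stiff solver (LSODA by default; RK45 available
as an independent cross-check) at every event time, applying IL-15
jumps and switching the control scales between segments; this keeps
events exact under adaptive stepping. Default tolerances rtol 1e−8 /
atol 1e−10; per-segment dense output supports observation at arbitrary
times. States are clipped to zero below an undershoot tolerance of
1e−9 (a warning is raised beyond it).

Steady states are operationalized as the t = 100 h endpoint, with a
convergence diagnostic: no internal state may move more than 0.1%
(relative, floored at one normalized unit) over the final 10 h. The
IL-15 input itself is excluded from this check — it decays exponentially
toward zero with no feedback, so its *relative* change never settles;
its residual level is reported separately. A consequence worth knowing:
because d₁ = 0.062 h⁻¹ is slow and k₆/d₈ ≈ 43 amplifies IL-15 into
STAT3, a priming pulse still leaves a ≈8% imprint on the *normoxic*
total-HIF-1α level at 100 h (it is <0.1% of the much larger DMOG-treated
level). "Priming does not affect the steady state" therefore holds
tightly under DMOG and only approximately in normoxia at the 100 h
snapshot.

External-regulation sweeps do **not** re-solve the equilibrium per grid
point: sweeping a basal rate *is* the perturbation, and the initial
state stays canonical. Swept parameters are temporarily stripped of
steady-state ties (otherwise a₁ would be silently reset to zero).

## Measurement model and calibration

Measurements are the normalized observables (total HIF-1α = y₄+y₆+y₁₀,
STAT3, AKT) plus independent additive zero-mean Gaussian noise with
per-point standard deviation σ. The estimation problem is the
multi-experiment weighted least squares

  ½ Σ [(η − g)/σ]² + ½ Σ [(p − p₀)/λ]²

over all perturbation experiments simultaneously, with optional
Tikhonov priors p₀ (defaults: the published values, λ = 10·|p₀| — weak
enough to be dominated by data, strong enough to stabilize sloppy
directions; λ = ∞ switches a prior off). Equality information enters in
two modes: `presolved` (default) fixes the initial state at the
equilibrium solved once from the prior parameters and enforces the
a₁/d₈ ties; `penalty` adds the weighted steady-state residuals as extra
rows with the HIF split as extra unknowns.

The solver is a generalized Gauss–Newton iteration: linearize the
weighted residuals, solve the linear least-squares step, damp with
Armijo backtracking t_k ∈ {1, ½, …, 2⁻¹⁰} on the full objective.
Because the network's normal matrix is severely ill-conditioned away
from the optimum (scaled singular values of the 39-point design span
3.4 down to 1.3e−3), a plain damped step can fail to descend; in that
case the step is re-solved on a Levenberg ridge ladder
(µ·σ_max²·I, µ = 1e−10 … 1e2) and the first descending candidate is
taken. Iterations stop on relative step norm (default 1e−8), an
objective stall (relative decrease < 1e−6 at a full step), or the
iteration cap. Rate constants are optimized in log space; efficacies on
their natural [0, 1] box with projection — a logit map would be
degenerate at the published ρ₃ = 100% boundary.

Jacobians are forward finite differences. The step must dominate the
integration error: the driver defaults to a relative step of 1e−4
(slope noise ~1e−3 at rtol 1e−7), while `sensitivity_matrix` uses the
tighter 1e−6/1e−8 steps appropriate for its tight-tolerance use; at an
upper bound (efficacy at 100%) the difference is taken backward.
Variational (forward-sensitivity) equations are not implemented; the
finite differences are validated against Richardson refinement on an
analytic problem.

In multiple-shooting mode each experiment's horizon is split at a node
grid (default: the measurement times), interior node states become
unknowns, and continuity defects become equality constraints solved by
a null-space step within the same damped iteration; node states are
kept non-negative by projection. Multiple and single shooting agree to
~1e−6 relative in objective on the synthetic suite.

Standard deviations come from the generalized inverse of the normal
matrix of the weighted residual Jacobian at the solution, on the
natural parameter scale. Covariances in multiple-shooting mode are
computed on the full unknown vector and reduced to the parameter block.

## Identifiability screening

The collinearity index is 1/σ_min of the column-scaled (unit-norm)
sensitivity matrix. The screen rejects greedily: while σ_min < 0.1, the
parameter with the largest weight in the smallest singular vector is
fixed at its prior; exactly-zero columns are rejected outright. The
greedy one-at-a-time rule is this package's concretization of subset
selection — the choice is not unique, but it reproduces the expected
behaviour on orthonormal, duplicated and ε-collinear columns.

On the default 39-point design the full 25-parameter free set has a
collinearity index of order 10²–10³ (the exact value depends on the
weighting) and the screen retains 15–17 parameters.
One rejected direction deserves a name: HIF-1α mRNA is unobserved and
its dynamics is linear, so (c·k₉, c·k₃, k_α/c) changes the observables
only through the fast e^(−d₉t) decay of the initial mRNA level — a
near-gauge. Noise-free data still pin it (the residual is exactly zero
only at the generating values), but with realistic noise any subset
containing it is unrecoverable; recovery studies should use
screen-passing subsets (e.g. {d₁, k₆, k₃, d₃, k₄}, index 2.2).

## Synthetic data

The generator emulates the study's calibration structure: four
perturbation experiments — IL-15; DMOG; IL-15+DMOG+rapamycin;
IL-15+DMOG+S3I-201 — with 39 points total in the 0–27 h observation
window, plus a held-out IL-15+DMOG validation experiment. The true
measurement times and per-point σ of the original study are not
published; the defaults (total HIF-1α at {2,4,8,12,27} h, STAT3 at
{1,4,12} h, AKT at {1,8} h per experiment, minus one AKT point in the
S3I arm; σ = 0.1 on the normalized scale, the order of the published
error bars) are documented stand-ins and fully configurable. Noise is
independent per point and values are not clipped, as in densitometry
ratios. Rows generated with σ = 0 receive unit weight so the dataset
remains usable for weighted fitting.

What passing recovery tests on these data do show: the estimation
machinery is correct (noise-free recovery of all 25 free parameters to
~1e−6 relative), and the linearized uncertainties are calibrated for
well-conditioned subsets (±2 sd coverage ≳90% at σ = 0.1). What they do
not show: that real densitometric/multiplex data — with correlated
errors, normalization artifacts and model misspecification — would
identify the same set, nor that the published point estimates would be
reproduced; the original raw time series are not publicly deposited.

## Problem sizes and determinism

The shipped analyses use: 1000 Monte Carlo samples per robustness
element (±25%, uniform, seeded; spread statistic max|Δ|/baseline plus a
2.5–97.5 percentile band); 5-point IL-15-supply sweep per condition for
the fold-change curve; 11-point dose grids; 20 seeded replicates for
the noisy recovery study; tolerances rtol 1e−6–1e−10 chosen per task as
noted above. Every stochastic step flows through a `numpy` Generator
seeded from a single run seed, so reruns are bit-identical.

## Known limitations

- Single compartment: no nucleus/cytoplasm distinction, no VHL species,
  no receptor trafficking; JAK/STAT5 and Ras-Raf-MEK cascades are
  outside the network boundary.
- Quantities without measurements (NF-κB, mTOR, mRNA) are meaningful
  only on a relative scale.
- The optimizer is local; multi-start from perturbed initial guesses is
  supported through `recovery_study`-style loops but no global search
  is attempted.
- Confidence statements are first-order (linearized covariance); no
  profile likelihood or second-order regions.
- The inhibitor placement (which term each efficacy scales) follows the
  network diagram and table descriptions; the original supplementary
  specification is unavailable, so placements are configuration-level
  choices validated against the qualitative fit behaviour.
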