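# Methods

## Scope and assumptions

The package predicts condition-specific steady-state fluxes by fitting an
FBA-constrained flux vector to expression-derived targets. The central
modelling assumption is that the flux through a reaction scales *linearly*
with the (log2) expression of its coding genes within the reaction's
attainable flux range; no kinetic, thermodynamic (ΔG) or proteomic
information is used. GPR boolean structure (AND/OR) is deliberately
ignored: a reaction's expression summary is the plain arithmetic mean over
its mapped genes (a hook for min/sum rules exists in
`summarize_expression`'s design but is off by default). Genes missing from
the expression matrix are dropped per reaction; a reaction losing all its
genes leaves the fitted set with a logged warning.

## The fit problem

Per condition, the LP minimises
`Σ_ri w_ri·|v_ri − v_ri^fit| + α·Σ_ro |v_ro|` subject to `S·v = 0`,
`lb ≤ v ≤ ub`, the optional per-condition growth floor, and the optional
uptake cap. Absolute values are linearised by split non-negative
auxiliaries (`v − p + n = v^fit`, residual `p + n`) and epigraph variables
(`a ≥ ±v`). Conditions share no variables, so per-condition solves are
exactly equivalent to the summed objective. The penalty is applied to the
*absolute* flux of non-fitted reactions: the signed sum is meaningless for
reversible reactions, and the quantity monitored when choosing α is the
absolute flux mass.

Parameters that matter:

- **α** (dimensionless, default 0.01): trade-off between mapping fidelity
  and total flux mass on non-fitted reactions. The scalarization property
  (fit term non-decreasing, penalty term non-increasing in α) is asserted
  in the test suite over α ∈ {0, 0.01, 0.1, 1, 10}.
- **weights** `1/V^weight` (core) and `1/(V^weight+100)` (associated),
  `V^weight = max(|V^max|,|V^min|)` from FVA: equalises the leverage of
  high- and low-range reactions; the +100 offset (flux units) down-weights
  associated reactions. Fitted reactions with `V^min = V^max = 0` are
  discarded up front — they cannot carry flux.
- **uptake cap** (mmol·gDW⁻¹·h⁻¹): bounds the summed uptake magnitude of
  all non-designated exchange reactions, linearised with one auxiliary
  `u_e ≥ max(0, −v_e)` per exchange. Designated carbon-source exchanges
  are exempt and instead have their lower bounds opened simultaneously in
  every condition, so the constraints never encode the true source.

Degenerate cases: a flat expression profile (`g^max = g^min`) leaves the
linear map undefined; the target falls back to the midpoint of the flux
range, which collapses to the single attainable value when that range is
degenerate too, and is logged per reaction. FVA is run once on the
globally-bounded network — condition-specific floors are *not* applied —
because the mapping uses a single per-reaction range across all conditions.

## Iterative bound reduction (IFFPR)

FVA ranges inflated by internal cycles produce absurd mapping targets.
IFFPR ranks fitted reactions by `max(|V^max|,|V^min|)` (descending, ties
broken lexicographically for determinism) and, per reaction, repeatedly
halves the mapping range — both bounds when the range straddles zero,
otherwise only the bound further from zero, clamping so the range never
inverts — re-derives targets, re-solves, and keeps the halving only when
the unweighted total discrepancy `d` strictly decreases; a rejected halving
restores the previous bounds before moving on, so the accepted-step `d`
sequence is non-increasing by construction. Termination: list exhausted,
an optional iteration cap, or `d` stable to a relative 1e-4 over a window
of 10 processed reactions (the observed behaviour is a long plateau once
the wide-range reactions are handled). Residual weights stay at their
initial FVA-derived values throughout. The procedure is a training-phase
step with no randomness; its narrowed bounds are reused at prediction time.

## Loop removal (RED-TIL)

The loop law forbids internal cycles with nonzero net flux. Detection
works on the *oriented support*: internal reactions with `|v| ≥ threshold`
(default 0.01, a CPU/strictness trade-off), stoichiometric columns
sign-flipped for negative fluxes so cycle fluxes λ are non-negative in the
solution's direction. The MILP minimises `Σλ` subject to `Σ S_r λ_r = 0`,
`inFC_r ≤ λ_r ≤ 1000·inFC_r`, `Σ inFC_r ≥ 2`, `inFC` binary. The upper
link between λ and its indicator is a deliberate addition: without it the
optimiser may mark only two members of a longer cycle, with it the
returned membership is exactly the flux-carrying cycle, and any positive
cap yields the same membership up to scaling. Infeasibility certifies a
circulation-free support. Minimising total cycle flux makes the detector
prefer the shortest cycle (a 2-cycle beats a 3-cycle).

Each detected loop of length k adds a cut: per oriented member a binary
`y`, with `y = 0` forcing the member's loop-direction flux to zero, and
`Σ y ≤ k − 1`. Forcing the excluded member to zero (rather than to just
below the threshold) keeps the re-optimised objective identical to the
exact loopless solver whenever the loop is worthless at the optimum, at
the cost of being marginally stricter than the detection threshold; the
threshold still governs which loops are considered at all. Cuts are
condition-specific, never repeat (asserted), and each shrinks the feasible
set, so the objective sequence is non-decreasing and termination is
guaranteed — zero circulation is always feasible. Loops are re-detected
against the support of each *fresh* solution.

Two independent oracles validate looplessness and must agree on every
instance: (a) infeasibility of the detection MILP, (b) exhaustive
enumeration of balanced directed cycles on the support graph. The
enumeration treats the support as a gain graph and is exact for reactions
consuming and producing one metabolite each (all bundled fixtures and the
random test networks, which use unit coefficients); other topologies raise
rather than silently degrade. `full_loopless_reference` implements the
classical single-MILP construction — direction binaries, potential-like
variables `G` forced to the sign opposite the flux, and `G` orthogonal to
the nullspace of the internal stoichiometric columns — guarded to ≤ 200
reactions, as validation only.

## Carbon-source calling

Per transporter, uptake magnitudes `max(0, −v)` across conditions are
standardised with the sample (n−1) SD; transporters with zero variance are
excluded with a warning, and within each condition transporters are ranked
by z (ties broken lexicographically and flagged). Scoring uptake magnitude
rather than signed flux makes "most negative exchange flux" rank first
under the uptake-is-negative convention; a flag exposes signed scoring.
Evaluation metrics: the normalized error `‖pred − ref‖₂/‖ref‖₂` and
Pearson r, with zero-variance series reported as undefined, never as r = 0.

## Synthetic scenarios

The generators produce the structure the method assumes, with ground
truth: planted flux vectors satisfying steady state and bounds, and
expression `g = a + b·v + ε`, `ε ~ N(0, σ)` on the log2 scale with
per-reaction `a ~ U(5,7)`, `b ~ U(0.4,0.8)` and σ = 0.1 by default (the
linearity is an assumption of the method; the noise model and its scale
are generator parameters, not a claim about real data). All entry points
require a seed and are bit-reproducible.

- *path*: irreversible uptake→chain→secretion line with a biomass sink.
- *loop*: a directed internal cycle, detached (irreversible, a pure TIL)
  or grafted onto the path with reversible ±1000 members, whose FVA ranges
  inflate to the full bound — the regime motivating IFFPR.
- *loop scenario*: path+cycle with eight conditions (mirroring an
  eight-condition study design) at path flux levels 2…8 and zero planted
  cycle flux. With very few conditions each reaction's expression extremes
  coincide with single conditions and single-reaction halvings cannot
  lower `d`; eight conditions avoid that degenerate regime.
- *multicarbon*: one exchange+transporter pair per carbon source feeding a
  common sink; each condition's designated transporter carries 8.0 and the
  others 0.5 mmol·gDW⁻¹·h⁻¹ against identical open uptake bounds of 10.
- *random networks*: unimolecular backbone-plus-shortcuts graphs with
  random reversibility, used to stress loop removal against the oracles.

What passing on these scenarios does **not** show: performance under GPR
boolean logic, multi-substrate stoichiometry in the enumeration oracle,
measurement noise structure of real arrays (replicate correlation, batch
effects), or genome-scale runtimes.

## Numerical choices

HiGHS (via scipy) solves all LPs/MILPs single-threaded with primal/dual
tolerances 1e-9 and zero MIP gap, so repeated runs are bit-identical.
Solution validation enforces `|S·v|∞ ≤ 1e-6` and bound satisfaction on
every returned flux vector. Big-M constants are the largest bound
magnitude in the network (+threshold where relevant); the loopless
reference uses K = 1000 potential bounds. Alternate optima are accepted
throughout: correctness is asserted on constraints and objective values,
never on vertex identity — method-agreement correlations can therefore sit
below 1 even when objectives coincide exactly.

## Problem sizes used in the shipped checks

The test suite and acceptance script run on the toy fixtures above
(5–15 reactions), 100 random networks for the oracle-agreement property,
20 random networks for the reference-equivalence correlation, and 20
seeded noisy multicarbon scenarios for call accuracy; these sizes exercise
every code path while keeping the whole suite in the low minutes on one
CPU.

## Known limitations

- The expression→flux map is per-reaction affine; saturation and
  allosteric effects are out of scope (explored transformations showed no
  benefit under this framework's assumptions).
- IFFPR is greedy in ranking order; it finds a good, not provably optimal,
  set of ranges.
- The enumeration loop oracle requires 1-in/1-out support reactions;
  general stoichiometry is validated by the MILP route and the loopless
  reference only.
- Carbon calling needs ≥ 2 conditions (z-scores are undefined otherwise)
  and is non-statistical: it ranks, it does not test significance.
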