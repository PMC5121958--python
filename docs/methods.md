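# Methods

## Model and scope

`phaseflux` treats growth on a complex medium as a piecewise-constant
environment: the growth curve is divided into one-hour phases, each with a
fixed set of nutrient uptake bounds, and the metabolic network is assumed to
reach a steady state within each phase (`S·v = 0`, bounds `lb ≤ v ≤ ub`).
Dynamics enter only through the bounds; there is no kinetic or dynamic-FBA
forward simulation of concentrations, and no thermodynamic or loop-law
constraints. Phase `i` spans `[t_{i-1}, t_i]`; the growth rate `GR_i` and the
concentration vector used by the uptake formula are read at the phase start
`t_{i-1}`.

The in-memory model container is a `cobra.Model`. SBML L3/fbc is the
interchange format (pathway labels travel as SBML groups; legacy files whose
reversibility is encoded only in bounds are handled, since reversibility is
defined here solely as `lb < 0 < ub`). A flat JSON dialect with identical
content exists so fixtures are human-readable and diff-able. Exchange
reactions are detected structurally (exactly one metabolite), excluding the
biomass drain. Uptake is a negative exchange flux; an uptake rate `r` is
imposed as `lower_bound = −r`, i.e. the magnitude is the bound.

GPR rules are boolean expressions over whitespace-free gene ids with `and`
binding tighter than `or` and parentheses allowed; parsing is delegated to
cobrapy's GPR machinery, with malformed rules raising instead of silently
emptying.

## Uptake parameterization

* Biomass per OD: `dry_weight / (OD_ref × volume)`, default anchor
  (1.28 g, OD 3.8, 1.4 l) → 0.2406 g·l⁻¹ per OD unit.
* Consumption is computed on mass concentrations (g/l = mM × MW × 10⁻³) and
  clamped at zero when a concentration rises hour-to-hour (nutrient
  accumulation is not negative consumption).
* Yield `Y_i` is biomass increment over total mass consumed; a phase with
  biomass gain but zero consumption is flagged unparameterizable (NaN) and
  aborts uptake derivation with a clear error.
* The uptake formula multiplies the mass-concentration fraction (over all
  substrates with nonzero concentration at the phase start) by `GR_i / Y_i`
  and converts to molar units. Substrates with zero consumption in the phase
  are masked to UF = 0 even when their concentration is positive, so the
  invariant "no consumption ⇒ no uptake bound" holds alongside the
  concentration-ratio formula.
* Per-phase scale constants are underdetermined by the data; the default
  normalizes each phase's total carbon-mass uptake flux to a configurable
  reference (1 g·gDW⁻¹·h⁻¹), making phases comparable. Explicit constants or
  no scaling can be supplied. Absolute flux magnitudes therefore carry an
  arbitrary per-phase factor; ratios within a phase do not.
* Trailing phases with neither growth nor uptake are dropped (twelve-phase
  curves with a two-hour dead tail yield a ten-phase window); a dead phase in
  the middle is retained.

## Phase-wise FBA and FVA

FBA maximizes the biomass reaction per phase under GLPK; each solution is
checked against `‖S·v‖∞ < 10⁻⁶` and its bounds. Degenerate alternate optima
make individual flux vectors solver-dependent; the package records the plain
optimal basis for reproducibility on one solver stack and exposes the flux
matrix for any post-processing. |v| > 10⁻⁹ mmol·gDW⁻¹·h⁻¹ defines "carrying
flux" throughout (configurable); a change in flux requires
`|Δ|v|| > 10⁻⁶` (configurable).

FVA runs at a fraction of the phase optimum (default 1.0). The span
`v = f_max / f_min` classifies reactions as fixed (v = 1) or flexible; when
`f_min ≈ 0` the ratio is undefined, the span is reported as NaN, and the
class falls back to `f_max − f_min > tol`.

The minimal-media screen closes every substrate exchange and the inorganic
nitrogen exchange (secretion stays open), opens one substrate at
1 mmol·gDW⁻¹·h⁻¹, and records the optimum — the substrate is the sole carbon
and nitrogen source.

## Transition classification

For reactions active in either flanking phase: a sign flip with both
magnitudes above tolerance is *reversed*; otherwise the change in |v| decides
*increased*/*decreased*/*unchanged*. The three change classes are disjoint
(reversed reactions are not double-counted), and turned-on/off sets track
activity crossings (subsets of increased/decreased). Because uptake rates
derived from fed-batch data decline with the growth rate, some fluxes shrink
at every transition; the *adjusted* decreasing set removes reactions that
decrease at every transition in which they are active, isolating genuine
substrate-switching responses. Activity means exclude trailing all-off
phases. Growth-rate normalization divides each column by its predicted μ and
rescales the activity tolerance by 1/μ so active sets are preserved
(zero-growth columns are left untouched).

## Nutritional-MOMA

The minimal-adjustment step solves `min ‖v − v_ref‖₂²` subject to steady
state and the phase's bounds — the canonical quadratic-adjustment objective,
repurposed so that the "perturbation" is a nutrient shift rather than a gene
knockout. Design choices:

* **No biomass floor.** Growth emerges from the adjustment; the predicted
  biomass flux is provably ≤ the phase's FBA optimum.
* **Seed reference.** The chain needs a state for the first phase; the FBA
  solution of phase 1 is the only defined one and seeds the chain, so the
  minimal-adjustment matrix has one column fewer than FBA's (nine for ten
  phases). The first transition's distance partly reflects the change of
  optimization character, not only the nutrient shift.
* **Distance over all reactions**, not just shared active ones.
* **Solver.** OSQP on the sparse stoichiometric matrix with
  `eps_abs = eps_rel = 10⁻¹⁰` and polishing; solutions are clipped into the
  box to remove terminal tolerance violations. An L1 (least-absolute
  adjustment) variant via HiGHS linear programming is available behind a
  flag and is not the default.

Comparison with FBA counts active reactions per phase under each method and
their intersection, and per-subsystem fractions active under one method only
or both. Minimal adjustment characteristically keeps more reactions active:
it drags the previous phase's flux pattern along instead of re-optimizing
from scratch.

## Covariation clustering

Reactions with a constant |flux| trend (including all-zero) are removed;
the rest get difference vectors `d_z = |f_{j,z+1}| − |f_{j,z}|` over the
transitions of the modelled window. Pairwise Pearson correlation is computed
on these vectors (zero-variance vectors are excluded rather than producing
NaN rows); clusters are the connected components of the graph with edges at
`r > 0.7` — single linkage, the simplest construction consistent with a
pairwise threshold; a max-clique rule would be stricter but is not used.
The threshold and the strictness of the comparison are configurable.
Absolute values make the clustering invariant to global sign flips, and
component extraction is invariant to reaction order. Cluster gene sets are
GPR unions, exported as per-cluster text lists plus a combined GMT file for
downstream annotation tools (functional-association or motif analysis is out
of scope).

## Synthetic scenario

The generator emulates a fed-batch experiment on an amino-acid medium:

* **Structure.** Six amino acids, twelve one-hour phases. OD grows
  exponentially at a non-increasing per-phase μ (0.30 → 0.04, then two
  zero-growth phases with no uptake, exercising the dead-tail truncation).
  Total mass consumption per phase is `Δbiomass / yield` with a planted
  constant yield of 0.4 g/g, so the yield arithmetic inverts the generator
  exactly on noise-free data. Each substrate's starting concentration equals
  its cumulative consumption, so it reaches zero exactly at its scheduled
  depletion phase (defaults: aa1–aa3 after phase 3 — the planted major
  switch; aa4 after 6; aa5 after 8; aa6 persists to phase 10).
* **Diauxie design.** Preferred (early-depleted) substrates are consumed at
  three-fold the rate of the others, carry small molar weights (the light
  amino acids) and are minor biomass components (stoichiometric coefficient
  0.2 vs 1.2). Their molar supply while fed therefore exceeds biomass
  demand, keeping their biosynthetic routes off until the depletion
  transition — which makes the planted major switch the largest rewiring
  event, with shutdowns and activations on both sides.
* **Accumulation.** One substrate's concentration is bumped at a single time
  point (default aa5 at t = 3, coinciding with the switch, where transient
  release of a no-longer-consumed compound is plausible); downstream
  parameterization must clamp that phase's consumption to zero.
* **Toy network.** Per amino acid: exchange, transporter, one-step
  degradation into a 2-oxoglutarate hub (releasing NH4) and one-step
  biosynthesis back (costing ATP); a cyclic three-step TCA-like subsystem
  whose emitted CO2 is re-fixed by a carboxylation step, producing ATP from
  O2; open salt exchanges (NH4, O2, phosphate); a biomass reaction over all
  amino acids, ATP and phosphate. ATP has no sink besides biosynthesis and
  biomass, so fluxes stay bounded despite the energetically generous
  respiration abstraction. Every internal reaction carries a synthetic GPR
  (some multi-subunit, some isozymic) and a subsystem label. Construction is
  deterministic given the seed, which only varies gene-id tags.

What the synthetic data does **not** emulate: measurement noise is off by
default (a relative-noise knob exists), concentrations follow the planted
yield exactly rather than scattering around it, the network has none of the
redundancy, compartmentalization or cofactor bookkeeping of a genome-scale
reconstruction, and all substrates enter metabolism through a single hub.
Passing tests therefore demonstrate the correctness of the arithmetic,
optimization and classification machinery and the qualitative switching
phenomenology — not quantitative agreement with any real organism's flux
distribution, which additionally depends on the reconstruction, the solver
basis chosen among degenerate optima, and the unpublished per-phase scale
constants.

## Problem sizes and numerical defaults

The reference scenario (36-reaction toy model, ten modelled phases) runs the
full pipeline — 10 FBA solves, 10 FVA sweeps, 9 quadratic programs, ~400
correlations — in a few seconds on one CPU; the test-suite's property checks
(LP oracle via HiGHS, dense KKT projection, brute-force classification and
union-find clustering) use the same sizes. Tolerances: steady state 10⁻⁶,
activity 10⁻⁹, flux change 10⁻⁶, OSQP 10⁻¹⁰, all configurable where they are
scientific rather than numerical. Ties in cluster ordering are broken by
size then lexicographically; degenerate inputs (empty GPRs, zero-variance
vectors, zero-growth columns, infeasible phases) are reported explicitly
rather than guessed around.
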