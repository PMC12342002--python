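# Methods

## Model

A network is a pair of ordered lists — species with initial concentrations
`x₀ ≥ 0` (nM) and irreversible mass-action reactions with integer
stoichiometry and rate constants `k > 0` (units nM^(1−order)·s⁻¹) — from
which the stoichiometric matrix `S` and the dynamics `ẋ = S·v(x,k)`,
`v_j = k_j ∏ x_i^{a_ij}`, follow.  Reversible steps are always written as
two reactions, so the mapping from file to `S` and `k` is unambiguous.
Time is seconds everywhere inside the library; minutes appear only in
reporting.

Two modelling assumptions shape everything downstream:

1. **Closed moiety structure.**  The networks of interest are closed (no
   synthesis/degradation except where explicitly modelled), so each
   protein moiety contributes a semi-positive conservation law and the
   state is confined to the stoichiometric compatibility class of `x₀`.
2. **Global stability.**  Each class is assumed to carry a unique globally
   asymptotically stable equilibrium.  The package does not prove this; it
   checks it empirically by multi-start root finding and by comparing the
   root-finder with long-horizon integration.

## Conservation laws

The basis is computed exactly.  A rational null-space basis of `Sᵀ`
(sympy) defines the cone `{y ≥ 0 : Sᵀy = 0}` in kernel coordinates, whose
extreme rays are enumerated by the incremental double-description method
in `Fraction` arithmetic with the combinatorial adjacency test.  The rays
are scaled to primitive integer vectors, ordered by support, and checked
for weak elementality: for each law, the lowest-index species that occurs
in no other law becomes its elemental species and the row is rescaled so
that entry is 1, yielding an identity submatrix.  `N·S = 0` therefore
holds exactly, which the tests assert in rational arithmetic.  If the left
null space contains directions no semi-positive combination can represent,
a warning is attached (p < dim ker Sᵀ); this does not occur for the
package's closed fixtures.  Files may also pre-declare conservation rows,
which are verified and used as-is — useful when reproducing a published
network whose basis is fixed.

Extreme-ray enumeration is exponential in the worst case but the cone
dimension here equals the moiety count (≤ ~12 in the fixtures), where the
algorithm is instantaneous.  A brute-force support-enumeration oracle
(n ≤ 6) cross-validates the rays in the test suite.

## Equilibrium solver

The steady state solves the square system obtained by deleting the p
elemental-species rows of `S·v` (each is linearly dependent on the others
given `N·S = 0`) and appending `N·x − N·x₀`.  The solver is a damped
Newton iteration with projection onto the non-negative orthant:
`x⁺ = max(x + t·d, 0)` with backtracking on the merit `½‖F‖²` (Armijo-type
acceptance `f⁺ ≤ f·(1 − 10⁻⁴ t)`); on stagnation it falls back to a
gradient step on the same merit, and on full stagnation it restarts from a
randomized point of the class.  Restart points redistribute each conserved
total over its moiety's species by a seeded Dirichlet draw; species shared
between moieties receive the mean of their draws and the point is then
projected back onto `{N·x = N·x₀}` by affine least squares and clipped
(the exact class membership is not required at the start because the
conservation rows are part of `F`).  Defaults: tolerance
`‖F‖∞ < 10⁻¹⁰·(1 + ‖x‖∞)`, 200 iterations, 10 restarts.  Singular Newton
systems fall back to least-squares directions; a rank-deficient Jacobian
at the solution is reported as a possible non-isolated equilibrium.

ODE integration (`simulate_to_equilibrium`) doubles its horizon from 100 s
up to 10⁹ s and declares equilibrium only when
`‖S·v‖∞ < tol·(1 + ‖x‖∞)` at two successive checkpoints, so a plateau on a
slow transient (drug degradation operates on ~10⁵–10⁶ s) is not mistaken
for convergence.  Integrator: BDF with the analytic Jacobian,
rtol 10⁻⁸ / atol 10⁻¹² nM.  These tolerances are deliberately tight:
relative-difference profiles divide by small physiological concentrations
and amplify absolute error.  The root-finder is the default for every
pipeline stage; integration serves as verification and for time courses.

## Mutations and drugs

GoF is a data-driven operation: the network file tags the de-activation
reactions of a gene (`deactivation:<GENE>`), and the mutation scales their
rates by λ (removing them at λ = 0).  Which reactions count as
de-activation is biology and therefore lives in the data layer, not in
code.  LoF zeroes the protein and every species whose composition
multiset contains it; partial LoF is not offered.  Because GoF edits rates
and LoF edits the initial state, any set of mutations commutes; the
implementation still canonicalizes the application order and the tests
verify order-independence of the resulting equilibria.

A drug is pure structure: species `D` (x₀ = c₀, or 0 when scheduled) and
complexes `D_T` per target `T`, reactions `D + T → D_T` (k_on) and
`D_T → D + T` (k_off), all tagged `drug:<name>`.  Bound complexes take
part in no other reaction, so competitive inhibition (binding the active
kinase) and allosteric inhibition (binding all phosphoforms) both act by
sequestration — no invented modified rate laws.  Fixture binding constants
default to k_on = 10⁻³ nM⁻¹s⁻¹, k_off = 10⁻² s⁻¹ (Kd = 10 nM, a typical
potency scale for kinase inhibitors); no published constants were
available to adopt, so these are explicit and overridable.  Optional
degradation adds `D → ∅` at 5.79·10⁻⁶ s⁻¹ by default (a literature
dabrafenib value); with degradation the drug moiety is not conserved and
the drug washes out asymptotically, so dose scans use degradation-free
specs and degradation is a time-course device.  Scheduled administration
is an instantaneous bolus event during integration; the final equilibrium
depends only on the class, not on the administration time, which the
tests confirm.

## Metrics and dosage

δ- and d-profiles require a strictly positive reference equilibrium and
raise `ZERO_REFERENCE` otherwise.  `G` is evaluated in log space and uses
`|d_i|`: the product formula does not survive negative entries, and every
use reads G as a distance to health.  d-profiles feeding G are restricted
to the original species — drug species have no physiological reference.
Dose scans are grid arg-min searches (matching the figure-style scans the
method is used for) with smallest-dose (1-D) or lexicographic (2-D)
tie-breaking; a zero dose skips drug augmentation entirely, so the
zero-dose margins of a 2-D scan equal the 1-D scans bit-for-bit.
Per-dose solver failures are recorded and the scan continues.

## Synthetic fixtures

`build_mapk_toy` is the testbed: a GTPase cycle (GEF-catalysed activation;
GAP-catalysed hydrolysis tagged `deactivation:KRAS`), three kinase tiers
with explicit enzyme–substrate complexes (single phosphorylation for the
Raf analog, double for MEK/ERK analogs), one phosphatase per tier, and a
decoupled PTEN-analog branch so LoF has a target.  Michaelis–Menten
reduction is deliberately avoided — elementary steps keep the moiety
conservation structure exact.  Default totals (10–120 nM) and rates
(association 10⁻³ nM⁻¹s⁻¹, dissociation 0.1 s⁻¹, catalysis 0.1–5 s⁻¹)
are chosen once at typical signalling scales such that GAP and phosphatase
activity dominate at rest; this yields a strictly positive physiological
equilibrium with modest basal activation and a strong, sign-consistent
response to K-Ras GoF (active forms up, inactive pools down).

What the toy does *not* emulate: the published colorectal network's 419
species, its absolute concentrations, crosstalk between pathways, and
feedback loops.  Passing tests therefore demonstrate the correctness of
the machinery (conservation, solver equivalence, operator semantics,
scan logic) and the qualitative mutation/drug phenotype, not quantitative
agreement with any real cell.  The full published network can be supplied
in the interchange format via `load_crcrn` (a documented manual conversion
is required; the loader verifies the 419/850 counts and the presence of
K-Ras de-activation tags).

`random_mass_action_network` grows closed networks from a few monomers by
reversible isomerisation and complex formation, so per-monomer
conservation laws hold by construction; leftover reaction budget becomes
parallel copies of existing reactions.  It powers the solver-equivalence
and validation property tests.  `build_reversible_pair` supplies the
closed-form oracle `(total·k_r/(k_f+k_r), total·k_f/(k_f+k_r))`.

## Numerical choices and problem sizes

- Exact rational arithmetic for everything conservation-related; floats
  only in dynamics and root finding.
- Newton tie-breaks: elemental species = lowest feasible index; deleted
  kinetic rows = the elemental rows.
- Trajectory states are clipped at 0 on output (integrator undershoot
  ≤ 10⁻⁹ in practice).
- Test and acceptance workloads use the 31-species toy, 6–8-species random
  networks (20–25 seeds) and grids of ~20 doses; the full suite runs in
  well under a minute on one CPU.

## Known limitations

- Uniqueness/global stability is assumed, checked only empirically.
- No sensitivity analysis with respect to kinetic parameters.
- No pharmacokinetics beyond bolus + first-order decay; no partial LoF;
  no stochastic or spatial simulation.
- The semi-positive basis routine targets moiety-structured (closed)
  networks; cones with many extreme rays relative to their dimension
  would be slow and are reported, not silently truncated.
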