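# Methods

## Model and assumptions

`reintroplan` works with deterministic, density-independent, female-only
stage-structured projection: a nonnegative m×m matrix **L** (2 ≤ m ≤ 5)
whose top row holds fertilities and whose remaining nonzero entries are
per-time-unit transition probabilities, applied to a stage-abundance vector
by `n_{t+1} = L n_t`. The matrix is assumed static over the planning
horizon and the system closed (no immigration/emigration, no males, no
density dependence or stochasticity). These assumptions are reasonable near
time zero of a reintroduction into empty habitat — exponential and logistic
growth coincide near zero abundance — but degrade with Allee effects,
changing vital rates, or site-fidelity problems; the package makes no
attempt to model those.

Primitivity of **L** is required, not assumed: validation applies the
Wielandt criterion (L is primitive iff the zero pattern of
L^(m²−2m+2) is strictly positive, an exponent of at most 17 for m = 5),
computed on the boolean adjacency pattern with exact zero/nonzero
classification, since users enter literal zeros. Primitivity guarantees a
unique real positive dominant eigenvalue λ₁ with strictly positive right
eigenvector (Perron–Frobenius), so the stable stage proportions (SSP,
the eigenvector normalized to sum 1) are well defined and every
trajectory converges to that ray.

## Planning procedure

Given a goal (T time units, B breeding females at time T):

1. Breeding stages are those with strictly positive fertility — the only
   definition consistent with a juvenile stage that is counted outside the
   breeding target.
2. The target `n_T` is the SSP scaled so its breeding-stage entries sum to
   B exactly; non-breeding stages carry whatever the stable distribution
   requires alongside.
3. The release is `n_0 = n_T / λ₁^T`, and the schedule row at time t is
   `n_0 · λ₁^t`. The scalar form is used instead of repeated matrix
   multiplication because on the SSD ray the two are identical (this
   equivalence is property-tested at 1e−8 relative) and the scalar form
   accumulates no matrix round-off.
4. Scaling a plan to a different total release multiplies every vector by
   one scalar; proportions and λ₁ are untouched and the goal's B is
   recomputed, since the original B is no longer met.

Abundances are carried as continuous reals throughout. Integer displays
are obtained by truncation toward zero, never rounding, and only at the
display/serialization boundary; machine outputs carry 12 significant
digits plus separate `*_display` fields so the display convention can
never contaminate computation.

## Candidate search

Alternative matrices share the user matrix's exact zero pattern
("identical life-history structure") and draw each nonzero entry uniformly
from a ±0.5 box clamped to legal ranges (fertilities ≥ 0, transitions in
[0, 1]). Uniformity within the box is a declared choice — the box is the
constraint of interest, and no entry deserves a priori preference inside
it. Draws violating the per-column survival budget or primitivity are
rejected and redrawn, capped at 1000 attempts (a cap hit signals an
infeasible neighborhood and raises rather than silently degrading).
Candidates are scored by the total release their own plan requires for the
shared goal; the x−1 smallest totals are listed after the user's row in
ascending order, ties broken by larger λ₁ then generation order, so row 2
is always the pool's most efficient model. The "pre-saved library" the
workflow emulates is replaced by seeded on-the-fly generation
(default pool 2000), which is reproducible and equivalent in behavior. An
optional boolean freeze mask pins entries (e.g. fertilities, when biology
rules out manipulating them) to the user's values during sampling.

## Trajectory comparison

`compare_release` projects an arbitrary release vector for T steps next to
the planner's stable schedule. Each step is flagged by comparing the
transient total abundance with the launch total scaled by λ₁^t —
"attenuating" below, "amplifying" above, at 1e−9 relative tolerance. This
formalizes attenuation/amplification as departure from λ₁-scaled growth;
the package reports trajectories and flags only and encodes no decision
rule about which trajectory a manager should prefer. `time_to_goal` scans
a projected trajectory for the first time the breeding-stage total reaches
B within a horizon, returning none when it never does (for λ₁ < 1 and a
start below target, the breeding total decays geometrically and no horizon
helps).

## Synthetic life histories

The fixture generator emits Lefkovitch-pattern matrices: stage 1 never
breeds, stages 2..m draw fertilities uniform on [0, 2] (ungulate-like
magnitudes) bounded away from zero so the adult→newborn arc exists; each
column draws a survival uniform below the budget (default 1.0) and splits
it between growth (sub-diagonal) and stasis (diagonal), the last stage
keeping all survival as stasis so its self-loop makes the cycle aperiodic.
Draws are rejection-sampled until they validate *and* have damping ratio
|λ₂|/λ₁ ≤ 0.65 (default). The ceiling is a modeling choice: the tool
targets iteroparous species whose reproduction is spread across adult
stages, which mixes the life cycle quickly (the worked ungulate example
has damping ratio 0.12), and it guarantees transients decay to below 1e−6
within 50 steps (0.65⁵⁰ ≈ 4e−10 leaves ample margin) so convergence-based
checks are meaningful rather than flaky. What the generator does *not*
emulate: taxon-specific rate correlations, senescence patterns, trade-offs
between survival and fertility, or empirically calibrated magnitudes —
tests passing on these fixtures demonstrate the mathematics, not realism
for any particular species.

## Numerical choices

- Eigen-analysis uses `numpy.linalg.eig`; the dominant pair is the
  largest-modulus eigenvalue, required to be real positive within 1e−12
  relative imaginary tolerance, with the eigenvector sign-corrected and
  required strictly positive (violations raise a convergence error rather
  than returning garbage).
- An independent 200-iteration power iteration (L¹-normalized) serves as a
  cross-check oracle in tests, agreeing with the solver at 1e−8 relative
  on all generated fixtures.
- The per-column survival budget (sum of a column's transition entries
  ≤ 1) is enforced as a hard error with 1e−9 tolerance for entry
  round-off: it is a probability statement, and silently accepting a
  violating matrix would corrupt every downstream quantity.
- Validation accepts any transition pattern that is primitive, not only
  strict Lefkovitch sparsity; the Lefkovitch layout guides documentation
  and the generator, not the validator.
- Stage indices are 1-based in all user-facing output and 0-based
  internally.

## Problem sizes

Property suites run on 100 seeded random matrices per stage count
(m ∈ {2,3,4,5}; 400 total) for the eigen oracle and release round trip,
25 per stage count for trajectory-convergence and brute-force primitivity
cross-checks, 500 per stage count for the generator contract, and 10,000
draws for the candidate-sampling uniformity test; candidate-pool tests use
pools of 100–300 with the default 2000 reserved for interactive use. These
sizes make the whole suite run in seconds while each check still exercises
every stage count.

## Known limitations

- Deterministic only: no demographic/environmental stochasticity,
  confidence envelopes, or quasi-extinction probabilities.
- Female-only: two-sex extrapolation (e.g. doubling for a 1:1 ratio) is
  left to the user.
- No sensitivity/elasticity matrices, damping-ratio reporting, or
  standardized transient indices (reactivity, inertia); the
  attenuation/amplification flags are the only transient summary.
- The candidate search perturbs all nonzero entries including fertilities;
  biological immutability is available only through the freeze mask.
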