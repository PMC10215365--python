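# Methods

## Model

The simulator is a stochastic, asynchronous individual-based model on a
toroidal square lattice. Each site holds at most one bacterium; six cell
types are distinguished (recipient, donor, transconjugant, and the three
segregant classes that mark which lineage lost the plasmid). The model's
assumptions, in brief:

* **Space is the resource.** There is no explicit nutrient field; the
  nutrient proxy at a cell is `C`, the empty fraction of its 7×7
  neighbourhood (49 sites, focal site included, so `C ≤ 48/49` for an
  occupied cell). Division requires an empty site in the 3×3 Moore
  neighbourhood and succeeds with probability `ψ(C)` — saturating at
  `ψmax·(1 − cost)` above the threshold `θ` and linear below it.
  The plasmid cost enters multiplicatively: `cost` is `c` for donors and
  adapted transconjugants, `b` for non-adapted transconjugants, 0 for
  plasmid-free cells.
* **Conjugation is local and nutrient-gated.** A plasmid-bearing cell
  transfers to a uniformly chosen plasmid-free Moore neighbour with
  probability `γ(C)`: zero below `θ1`, saturating at `γmax` above `θ2`,
  and `γmax·(C − θ1)/(θ2 − θ1)` between — the linear ramp that is
  continuous at both thresholds.
* **Amelioration is a division counter.** A transconjugant's plasmid cost
  drops from `b` to `c` after `adaptation_time` divisions of the lineage
  carrying it. One division consumes one countdown unit *before* the
  daughter is created, so both products of the final division are adapted.
  The countdown is stored per cell; the mutation-locus switch only changes
  what a *transfer* does:
  - chromosome locus: the transferred plasmid is unmodified — targets pay
    `b` with a full countdown, except targets whose own chromosome already
    carries the compensation (adapted segregants re-acquire at cost `c`,
    countdown 0). Re-acquisition is decided by the target, not the source.
  - plasmid locus: the transferred copy carries the source plasmid's
    current cost and countdown. Donor plasmids always transfer at `b`
    with a full countdown: the donor's own adaptation is treated as a
    property of the donor genotype, not encoded on its plasmid.
  - in both modes, a donor-derived segregant that re-acquires a plasmid
    becomes a donor again at cost `c` (its chromosome is the donor
    chromosome). This is applied for any source; the alternative (only
    for donor sources) differs only in a doubly-rare event chain and was
    rejected for consistency of the lineage bookkeeping.
* **Segregation** happens at birth only: a plasmid-bearing parent's
  daughter loses the plasmid with probability 0.001 and becomes the
  segregant class matching the parent's current adaptation state.
* **Resource renewal by culling.** When occupancy reaches
  `floor(0.95·edge²)` the six type counts are recorded and occupied sites
  are emptied uniformly at random (type-blind) down to `floor(0.5·edge²)`.
  A run is `n_cull_events` such cycles (reference value 1073).

### Scheduling and randomness

Updating is serial-asynchronous: one occupied site is drawn uniformly
(with replacement) per step; it first attempts division, then — if
plasmid-bearing — conjugation, so a cell may do both in one step. If the
division fills the grid, the census/cull executes immediately and that
cell forfeits its conjugation opportunity for the step.

All randomness comes from numpy's legacy Mersenne-Twister stream, consumed
in a fixed documented order (site selection; growth acceptance; daughter
slot; segregation; conjugation acceptance; target choice; one draw per
culled cell). Uniform integers in `[0, n)` are taken as `floor(u·n)`. The
run seed feeds a `RandomState` that performs the initial placement
(without-replacement sampling of site indices, guaranteeing exact initial
counts) and then yields a derived loop seed.

Two engines execute the loop: a numba-compiled fused kernel (default) and
a pure-Python composition of the per-event reference kernels. Because
numba reproduces the legacy numpy stream bit-for-bit, the two engines are
trajectory-identical from the same seed; the test suite asserts this,
which cross-checks the production kernel against the readable reference
implementation event by event.

### Generation clock

"Generations" are population doublings: each culling cycle contributes
`log2(N_fill/N_start)`. Every steady cycle therefore contributes exactly
`log2(0.95/0.5) ≈ 0.926` regardless of grid size, and a 1073-cycle run
spans `log2(fill/N₀) + 1072·log2(1.9)` generations — 999.24 for a
100×100 grid seeded with 100 cells, deterministically, because census
occupancies are exact floor values. This is the denominator of the
selection rate.

### Fitness statistics

`S_AB = [ln(N_Af/N_Ai) − ln(N_Bf/N_Bi)]/t` with `t` the generation clock;
initial counts come from the seeding, final counts from the last census
record. Donor fitness counts donor-derived segregants with the donor
lineage (they are donor descendants) but plasmid fitness counts them as
plasmid-free — the only assignment consistent with both compartment
definitions at once. A zero count makes `S_AB` NaN (flagged, never
silently dropped); sweep summaries mark such conditions `extinct`,
mirroring how donor-extinct conditions are omitted from bar charts but
not from bookkeeping.

Mode comparisons pair replicates by index under matched seeds and test
ΔS = S_chromosome − S_plasmid against zero with a one-sample Student
t-test (α = 0.05; Δ > 0 means plasmid-locus mutations are detrimental to
the compared quantity). Zero-variance Δ is treated as an exact tie (p = 1
when all Δ = 0). The with/without-transfer contrast is a Welch two-sample
t-test against matched `γmax = 0` baseline runs. No multiple-testing
correction is applied across conditions, by design.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `edge` | 1000 | lattice side; all occupancy fractions scale with `edge²` |
| `psi_max` | 1 | maximum division probability per attempt |
| `theta` | 0.8 | nutrient threshold for saturated growth |
| `gamma_max` | 1 (swept: 1, 0.1, 0.01) | maximum conjugation probability |
| `theta1`, `theta2` | 0.2, 0.3 | conjugation ramp thresholds |
| `b` | 0.2 (swept: 0.2, 0.4, 0.6) | cost of the non-adapted plasmid |
| `c` | 0 (swept: 0, 0.1) | permanent cost after amelioration / in donors |
| `adaptation_time` | 70 (swept: 70, 400) | divisions until amelioration |
| `segregation_prob` | 0.001 | plasmid loss per daughter |
| fill / cull fractions | 0.95 / 0.5 | census trigger and post-cull occupancy |
| `n_cull_events` | 1073 | cycles per run (≈1000 generations) |
| donor frequency | swept: 0.1%, 1%, 50%, 99% | of the initial population |

The reference design seeds 10,000 cells (1% of sites) on the full grid;
scaled grids preserve the donor *fractions* against a total population of
1% of `edge²` (clipped so both compartments start non-empty). The full
factorial is 2×3×3×4×2 = 144 conditions × 2 modes × 3 replicates.

## What the tests show — and what they do not

All simulated data come from the model itself; there is no external data.
Desk-scale runs (edge 20–100, tens to a few hundred culling cycles) keep
the suite and the acceptance script to a couple of minutes on one CPU.
Sizes used: the generation-clock check runs the full 1073 cycles at
edge = 100; mode-equivalence uses edge = 50 × 30 cycles × 10 seeds; the
donor-advantage check edge = 100 × 15 cycles; extinction checks edge =
50–100 × 120–200 cycles.

Consequences of the scale-down, chosen deliberately:

* The donor-advantage check (γmax = 1, c = 0, b = 0.6, 50% donors) stops
  at 15 cycles because on a 10⁴-site grid this strong selection drives
  the non-donor compartment to extinction within ~30 cycles, after which
  the selection rate is undefined; the advantage is already decisive and
  positive in every replicate well before fixation. On the full 10⁶-site
  grid fixation takes far longer.
* The exact mode-equivalence oracle (b = c, shared seeds) is asserted on
  runs shorter than the adaptation time in divisions. In that regime the
  two modes are *mathematically* identical state-for-state, so the census
  series must match byte-for-byte — a sharp test of the shared draw
  order. On much longer runs the segregant *labels* (adapted vs
  non-adapted) could differ between modes even though the dynamics remain
  identical, because countdown bookkeeping differs while costs do not.
* Small grids have strong drift: single-lineage compartments (e.g. 1
  initial donor) can die out by chance, which full-scale runs with 10–
  9900 donors rarely show. Extinction flags, not exclusions, are the
  contract throughout.

Numerical/degenerate-input choices: thresholds are compared with `≥` so
both rate laws are right-continuous and exactly continuous at their knots;
`floor` is used for the fill threshold and cull target and exactness is
asserted; event draws use `u ≤ rate` so `rate = 0` never fires and
`rate = 1` always does; ties in daughter/target choice are resolved by a
uniform index into the fixed row-major neighbour scan order; degenerate
zero-variance t-tests are resolved as exact ties or exact displacements.

## Known limitations

* No cell death outside culling, no multi-plasmid cells or incompatibility,
  no explicit antibiotics, no off-lattice or continuous-space variant.
* The asynchronous scheme (uniform site selection with replacement) is the
  simplest consistent choice; sweep-based asynchrony would alter
  short-time correlations, though not the qualitative behaviour.
* "Generation" is defined operationally via log2 expansion; other clocks
  (e.g. counting cull cycles) would rescale selection rates by a constant
  close to 1.
* Whether a donor's own plasmid can acquire the compensatory mutation in
  plasmid-locus mode is unspecified in the underlying model description;
  donors here are permanently adapted hosts whose plasmids transfer
  non-adapted. An alternative (donor plasmids transferring pre-adapted)
  would collapse much of the mode contrast and contradicts the stated
  transfer rule.
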