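# Methods

## Model

The forest is a single species in a single stratum whose only state is the
area vector `A ∈ R²⁴` over five-year age classes (total 10,000 km² per
simulated forest). One five-year step applies the textbook age-class
management recipe — harvest the oldest class, regenerate the cut area into
the youngest class, age every uncut class by one — which on `A` is the
cyclic permutation `A'₁ = A₂₄`, `A'ᵢ₊₁ = Aᵢ`. Consequences used throughout:
total area is conserved exactly (steps permute the vector bitwise), 24
steps (120 years) are the identity, and backcasting is the inverse
permutation. An explicit 24×24 permutation matrix is exposed for
inspection and serves as an independent cross-check in the tests. There is
no growth *within* a class between steps, no thinning, and no stochastic
transition: volume changes only because area changes class.

Stand volume per km² at age `t` follows the Chapman-Richards curve
`V(t) = vmax·(1 − e^(rate·t))^shape` (defaults 1.0, −0.05, 5.0), and the
growing stock of a distribution is `Σᵢ Aᵢ·V(tᵢ)`. Two age-point
conventions are provided: `class_upper` (`tᵢ = 5i`, default) and
`class_midpoint` (`tᵢ = 5i − 2.5`). The default is anchored by the
mature-forest benchmark: 10,000 km² at `t = 120` gives a stock of 9,876.7 ≈
9,877, whereas midpoints give 9,860. Volumes are deliberately unitless
("arbitrary units"); biomass expansion factors are omitted, so biomass ≡
growing-stock volume everywhere.

HFM accounting: `HFM_RP = H_RP / TBA_RP` with `H` the harvested volume and
`TBA` the *period-start* (pre-harvest) stock, both summed over RP periods
1–2. TBA is taken pre-harvest because "total biomass available" must
include the biomass that is then cut; with that choice `HFM_RP ∈ [0, 1]`
always. The projected allowable harvest of period `p` is
`HFM_RP · stock_p` (per period, not a CP lump sum, so the projection can
be plotted against the realized line); CP totals are the sums over periods
5–6. A run is a computational **source** if its realized CP total exceeds
the projected one, else a **sink**.

## Period layout and initialization

Thirteen five-year periods starting 2000, 2005, …, 2060 (so the horizon is
2000–2065); RP = periods 1–2, CP = periods 5–6. Each sampled distribution
is used twice: as the year-2000 state directly (forecast) and as the
year-2020 state backcast four periods to 2000 (backcast). The backcast
variant therefore passes through the generated state exactly at period 5 —
the same forest observed 20 years apart — which is what isolates the
effect of age-peak *timing* on the accounting.

## Synthetic age structures

Stand ages are drawn on [0, 1] from a Beta distribution (or a two-component
Beta mixture), binned into 24 equal bins (half-open, last bin closed at 1)
and scaled to the total area, so class areas sum to the total by
construction. The shipped catalog:

| shape  | mixture                              | seed |
|--------|--------------------------------------|------|
| unif   | Beta(1, 1)                           | 1    |
| norm   | Beta(6, 6)                           | 2    |
| skwj   | Beta(8, 1)                           | 3    |
| revj   | Beta(1, 5)                           | 4    |
| bimod1 | 0.5·Beta(8, 2) + 0.5·Beta(2, 8)      | 5    |
| bimod2 | 0.35·Beta(10, 3) + 0.65·Beta(3, 10)  | 6    |

with `n_samples = 10,000` per shape. Mixtures are needed for the bimodal
shapes because a single Beta is only bimodal with both modes at the
boundary. The J-shape uses Beta(8, 1) rather than a gentler exponent
because the forecast-variant classification of a shallow J sits within a
few percent of the source/sink boundary in the infinite-sample limit; the
steeper J keeps the qualitative behaviour of every shape — each non-uniform
shape a source in one initialization variant and a sink in the other —
clear of sampling noise at `n_samples = 10,000`. All shapes, parameters,
sample counts and seeds are overridable through the YAML scenario config.

What the generator does *not* emulate: real national forest-inventory age
distributions (no fitting to any country), measurement error, multiple
strata or species, disturbances, or market-driven harvest behaviour.
Passing tests therefore demonstrate properties of the accounting *rule*
under idealized age dynamics, not predictions for any real forest estate.

## Numerical choices

- **Tie classification.** Source/sink uses strict inequality with a
  relative tie band of 1e-9: reconstructing the harvest as
  `(H/TBA)·stock` incurs last-bit rounding, so an exactly stationary
  (uniform) forest would otherwise be classified by floating-point noise.
  Ties are classified sink. All substantive margins are orders of
  magnitude larger than the band.
- **Conservation.** The step permutes the area vector bitwise; vector
  *sums* can differ in the last ulp under reordering, so conservation is
  asserted at 1e-9 relative (and as bitwise multiset equality in the
  property tests).
- **Seeding.** Per-shape seeds are fixed in the catalog; a global seed is
  mixed in as `(global·100003 + shape_seed) mod 2³¹`, so global seed 0
  reproduces the shipped experiment bit-identically and any other seed
  redraws all shapes reproducibly.
- **Degenerate inputs.** Zero total area, empty mixtures, non-summing
  weights, non-negative-age queries, RP/CP overlaps and too-short
  trajectories are rejected with explicit errors; an RP with zero stock
  (impossible for valid distributions) is rejected rather than returning
  NaN.

## Open design choices, as resolved here

- `HFM_RP` divides *summed* RP totals rather than averaging period-wise
  ratios (the two coincide for stationary forests).
- "Growing stock" reported per period is the period-start, pre-harvest
  stock, including the class about to be cut.
- Harvest is evaluated on the period-start state before any ageing.
- The uniform shape's own classification is knife-edge by construction
  (it depends on the sampling noise around exact uniformity); robust
  statements are made only about the exactly uniform state and about the
  ten non-uniform runs.

## Sensitivity

Re-running the whole experiment with Chapman-Richards `shape` exponents 1
and 10 (driver `04`, CLI `sensitivity`) preserves all structural
invariants — area conservation, `HFM ∈ [0, 1]`, stock bounds — while
individual source/sink signs may move, confirming the phenomenon is driven
by the age-class distribution rather than by the particular growth curve.

## Problem sizes

The shipped experiment is 12 runs × 13 periods on 24-dimensional states
with 10,000 Beta draws per shape; the full pipeline, test suite and
acceptance script each run in seconds on one CPU. Shape-fidelity tests use
100,000 draws, where sampled class shares match the bin-integrated mixture
density to < 0.01 absolute.

## Limitations

Only final felling of the oldest class is simulated — no thinnings, partial
harvests, age-dependent mortality, disturbance, or climate/market response.
Volume is a deterministic function of age, so the model cannot represent
density-dependent growth or the volume dimension of richer area-based
matrix models. Results are in arbitrary volume units and are not
convertible to carbon without expansion factors, which are intentionally
out of scope.
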