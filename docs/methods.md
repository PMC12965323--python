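# Methods

This note documents the model assumptions, parameters, numerical
choices and limitations of the `multicrop` pipeline in one place.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem and model

The pipeline estimates how much existing cropland could be harvested
more than once per year, how much extra production that would yield,
and how much of the irrigated part of that potential local freshwater
can actually support.  It operates on a 0.5°-style grid of cells, each
carrying monthly grass productivity (GPP) and evapotranspiration under
rainfed and irrigated conditions, per-crop main-season yields and ET
components under both regimes, physical and harvested crop areas,
fallow land, irrigation-system shares, a river network with annual
runoff, and non-agricultural water demand.

Grass is the year-round climate proxy: crops are simulated only in
their prescribed main season, while monthly grass GPP reflects growing
conditions in every month.  Suitability, off-season yields and
off-season water use are all derived from it.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `gpp_threshold` | 100 | g C m⁻² month⁻¹ | growing-period month cutoff (strictly "exceeds") |
| `min_growing_months` | 9 | months | months required for multiple-cropping suitability |
| `carbon_fraction` | 0.45 | g C / g DM | converts the threshold to ≈ 2.2 t DM ha⁻¹ |
| `offseason_dampening` | 0.25 | – | reduction of off-season yield *and* off-season water use below full potential (turnaround time, harvest losses) |
| `radius_km` | 100 | km | maximum water conveyance distance |
| field efficiency | 0.60 / 0.75 / 0.90 | – | surface / sprinkler / drip |
| conveyance efficiency | 0.70 / 0.95 / 0.95 | – | surface / sprinkler / drip |
| `consumptive_loss_share` | 0.5 | – | fraction of conveyance losses that evaporates |

The efficiency values are representative of standard global irrigation
accounting parameterizations; all are configurable through
`RunConfig` / YAML, with range validation and rejection of unknown keys.

## Design choices where the design was open

* **Strict threshold.** A month at exactly 100 g C m⁻² does not count;
  the cutoff is measure-zero in practice.
* **Non-consecutive months.** Suitability counts qualifying months, not
  runs.  A cyclic consecutive-run variant exists
  (`consecutive=True`) but is off by default.
* **Off-season ratio over sums.** The ratio uses GPP summed over months
  rather than monthly means, so it directly represents total off-season
  productivity relative to the main season; it is invariant under
  uniform GPP scaling either way.
* **One aggregate off-season.** No distinction between one or two extra
  cycles; correspondingly the multiple-cropped share from cropping
  intensity is capped at 1.
* **Multiplicative calibration.** Country-level yield calibration uses
  one multiplicative factor per country × crop (area-weighted mean of
  calibrated main-season yield equals the reported yield), preserving
  within-country spatial patterns; factors are uncapped by default with
  an optional configurable cap.  Calibration is idempotent.
* **Pooled regressions with fallback.** Off-season water regressions
  are fit per crop × irrigation system across cells that use the
  system, falling back to all cells when fewer than three do.  Negative
  predictions are clamped to zero.  ET components (transpiration,
  evaporation, interception) are summed uniformly across systems.
* **Same-basin, nearest-first sourcing.** The 100 km neighborhood is
  restricted to the requesting cell's basin (no cross-basin
  transfers — a conservative reading of basin-wise ranking) and sources
  are tapped nearest-first with ties broken by cell id.
* **Return flows and upstream constraints.** Withdrawing `w` with
  consumption ratio ρ at source `s` reduces availability by `w` at `s`
  and by `ρ·w` at every strictly-downstream cell (the return flow
  `(1−ρ)·w` re-enters at the downstream neighbor).  A request may take
  at most `min(avail[s], min_downstream avail / ρ)` from each source,
  which guarantees no availability ever goes negative and yields exact
  outlet mass balance.
* **Groundwater in withdrawal terms.** Unmet non-agricultural and
  committed withdrawal volumes are booked as non-renewable groundwater;
  expansion gets none and is scaled by its fulfilled fraction,
  proportionally across crops within the cell.
* **Consumptive conveyance losses count as consumption** in allocation
  (they do not return to the river).
* **Deterministic service order**: basin id, then priority class
  (non-agricultural → committed → expansion), then descending rank,
  then cell id.  Basins are independent, so this order is also
  parallel-safe.
* **NWL as POT's limit.** The no-water-limitation scenario runs the
  same area bookkeeping as POT with fulfilled fraction ≡ 1, so flooding
  the network with water reproduces NWL bit-for-bit — a designed-in
  limit equivalence rather than a numerical coincidence.
* **Irrigation-for-yield-only expansion is out of scope**: area
  conversion to irrigation happens only where irrigation enables a
  second season (rainfed-unsuitable, irrigated-suitable, currently
  rainfed).  Fallow land never participates in expansion.

## Synthetic worlds

The generator emulates the statistical structure of the real input
stack, not its climatology:

* Monthly GPP per cell is a warmth-ranked seasonal curve (warm months
  land in [120, peak], cold months below 80 g C m⁻², ±10% noise) with a
  dry-season suppression factor (default 0.2) outside the wet months
  for the rainfed regime.  Irrigated GPP is the unsuppressed curve, so
  irrigated ≥ rainfed holds month-wise and irrigation removes exactly
  the dry-season limitation.
* Cells are planted in three climatic strata with configurable
  fractions — rainfed-suitable (≥9 warm months, all wet),
  irrigated-only (≥9 warm, <9 wet) and unsuitable (<9 warm) — plus a
  water-scarce stratum realized by scaling runoff down (×0.01) in a
  random 20% of basins.  Stratum labels are kept as bookkeeping for
  tests.
* Basins are compact random-walk blobs on a 0.5° lattice in disjoint
  longitude windows; the walk's attachment edges form the river tree,
  rooted at the basin outlet.  Cell areas follow the cosine-of-latitude
  rule for 0.5° cells.
* Grass ET is proportional to GPP (0.35 mm per g C m⁻²).  Crop
  consumptive irrigation water requirement is a noisy linear function
  of grass consumptive IWR (slope 1.2, intercept 5 mm, σ = 5 mm) —
  exactly the relationship the off-season regression recovers.  Crop
  yields are proportional to mean main-season GPP with lognormal noise
  shared between regimes.
* Cropland fraction is clustered by basin (an arbitrary choice of
  spatial covariance, made explicit here); cropping intensity above 1
  is planted only in suitable cell-regimes, with CI ∈ [1, 1.8].
  Reported country yields are the modeled area-weighted means times
  hidden management factors in [0.6, 1.1], which the calibration
  recovers.
* Non-agricultural demand is a small fraction (≤5%) of local runoff
  with consumption at 30–70% of withdrawal.

What passing tests on these worlds shows: the *mechanics* — threshold
classification, scaling arithmetic, regression recovery, routing, the
priority/return-flow/groundwater rules, scenario orderings and
conservation — behave exactly as specified under controlled conditions.
What they do not show: realism of any global magnitude.  Real grids
have ~67k land cells, 12–17 crop types, observed seasonal covariance
between GPP, yields, areas and runoff, and real basin topology; the
synthetic worlds make no claim to reproduce those, so absolute areas,
productions and volumes from this package's runs are properties of the
generated world only.

## Numerical notes

* World serialization is tidy text (CSV/JSON) at 17 significant digits
  with round-trip float parsing, so save/load is bit-exact.
* Degenerate cells (zero main-season grass GPP with nonzero off-season
  GPP) get off-season yield 0 and are logged; such cells have no
  meaningful main crop.
* Negative irrigated-minus-rainfed ET differences are clamped to zero
  and logged.
* Allocation uses an absolute guard of ~1e-15 × demand for micro-takes
  and clips availability at zero after each request; an internal
  assertion fires if availability ever drops below −1e-9 of the scale.
* Shares with zero denominators (e.g. multiple-cropped share of zero
  irrigated area) are reported as NaN, never 0.
* Problem sizes in the shipped tests and acceptance script — worlds of
  25–500 cells, 100-seed sweeps, 100 random basins for the allocation
  oracle, a 300-cell world for the acceptance run — were chosen so the
  full suite completes in well under a minute of compute while still
  exercising every rule on nontrivial topologies.

## Known limitations

* Annual water budgets only: no intra-annual storage or timing, so
  water availability is optimistic where seasonal storage is binding.
* The off-season repeats the same crop; rotations and crop sequencing
  are not represented.
* Environmental flow requirements are not reserved before allocation.
* The committed-demand interleaving across basins is class-then-rank;
  other interleavings are defensible and would change results only in
  basins where committed demand competes across cells.
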