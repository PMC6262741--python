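# Methods

`allosim` is an individual-based, spatially explicit resource–consumer model
for studying how fine-grained habitat fragmentation and resource productivity
shape the body-size distribution of an actively moving consumer, together
with the downstream statistics (occupancy, biomass variability across scales,
and a redundancy-analysis variation partitioning of the outcomes).

## The model

**Landscape.** A square torus of cells of side SL = 0.25 m. A fixed number of
cells (2,500 by default, arranged as a 50 × 50 sub-lattice) are suitable
patches; isolation is set by the nearest-neighbour distance NND — the number
of unsuitable matrix cells between adjacent patches — so the grid side is
`sqrt(n_patches) · (1 + NND)` cells and habitat amount never changes with
isolation. Distances are Euclidean between cell centres on the torus, because
the daily searching area is circular.

**Resource.** Each suitable cell holds one energy pool R (J) updated once per
day by a discrete logistic map, `R' = min(K, R + r·R·(1 − R/K))`, with
K = 2,000 J and r ∈ {0.1, 0.5, 0.9} per day. A non-consumable floor
E_nc = 1 J (belowground tissue) survives any depletion and seeds regrowth.
The discrete map is used rather than the continuous-time solution because the
whole model advances in daily steps; for r ≤ 0.9 the map is monotone and
stable at K.

**Consumer.** Haploid, parthenogenetic, semelparous; the single heritable
gene is the asymptotic adult mass W_max ∈ [0.01 g, 3 g]. All rates are
allometric in the current mass W (kg):

| quantity | form | units |
|---|---|---|
| max daily ingestion | `2·W^0.80·t_f`, t_f = 54,000 s | J/day |
| basal metabolic rate | `0.14·W^0.751` (×86,400 s/day) | W |
| optimal walking speed | `0.3·W^0.29` | m/s |
| locomotion cost | `0.17·W^0.75 + 3.4·W` | J/s |
| perceptual range | `301·W + 0.097` | m |
| clutch mass | `0.158·W^0.92`, split over 15 eggs | kg |

The speed and perception laws evaluated at the mass bounds give the printed
endpoints 0.0106/0.0557 m/s and 0.10/1.0 m, which are also the daily
resampling ranges of the decoupled variant.

**Daily schedule.** Consumption → basal metabolism → movement → growth
(juveniles) or reproduction (adults), in strict energy-priority order.
Competition is scramble: a cell's consumable pool `R − E_nc` is granted in
full when it covers the pooled demand and shared proportionally to demand
otherwise, so equal demands always receive equal intakes. An individual whose
reserve plus intake cannot cover the day's basal cost starves. The moving
probability is cell-level and equal for all occupants,
`p = max(0, 1 − R/Σi_max)`, computed from the resources the cell held at the
start of the day against the summed daily ingestion capacity of its surviving
occupants: a cell that could have fed everyone sends no one away. Movers
search for `t_m = min(1 h, E_r/c_m)` at speed v, perceive d_per to both
sides, and prospect the equal-area circle of radius
`rad = sqrt((2·d_per·(v·t_m) + π·d_per²)/π)` (reducing to d_per for a
stationary searcher); they relocate to the richest suitable cell within
`rad`, ties broken uniformly at random, and pay `t_m·c_m` whether or not the
best cell is their origin — the cost is for the area searched. In the
*coupled* mode v and d_per follow the mass laws; in the *decoupled* mode both
are redrawn daily from the uniform endpoint ranges, severing the
size–movement link while leaving the cost law mass-based.

**Growth and reproduction.** Juveniles grow along the ontogenetic (West)
curve `dW/dt = a·W^{3/4}·(1 − (W/W_max)^{1/4})`, one explicit Euler step per
day, capped both by the asymptote and by what the reserve can pay at the
tissue energy density; they mature at 99 % of W_max. Adults accumulate
reserve until it covers the clutch (15 eggs of mass CS/15) plus each
hatchling's first-day endowment, then reproduce once and die. Offspring
genotypes copy the parent, mutating with probability 0.001 to a uniform draw
from [W_max/2, 3·W_max/2], rejection-sampled into the physiological bounds.

**Initialisation and immigration.** Runs start with all cells at K and 1,000
adults (100 at desk scale) whose genotype is `10^u`, u uniform on
[−5, −2.5229] — equal weight per order of magnitude, right-skewed on the
linear scale — each holding exactly a first-day reserve (one day's basal cost
plus one hour's movement). Immigrants arrive as a Bernoulli(q) event per day
(q = 0.1 by default; q = 0 disables rescue) drawn by the same rule.

## Parameters chosen here (not fixed by the published laws)

- **Tissue energy density, 7.0 × 10⁶ J/kg** — converts reserve energy into
  structural and clutch mass; a typical wet-biomass energy content.
- **Growth coefficient a = 0.06 kg^(1/4)/day** — calibrated so the smallest
  genotype matures in ≈ 20 days when food is unlimited; in practice growth of
  small genotypes is mostly energy-limited, giving maturation in ≈ 15–25
  days, a realistic arthropod development time.
- **Reproduction threshold** = clutch tissue energy + 15 first-day
  endowments. The threshold must rise with body size; including the
  endowments makes the population energy ledger close exactly — every joule
  entering a hatchling leaves its parent.
- **Searching radius** — the equal-area-circle form above; it is increasing
  in speed, time and perceptual range and degenerates to the perceptual
  range when no distance is covered.
- **Run length** defaults to 5,000 days with all observation windows anchored
  to the end of the run.

## Measurement protocol

- **Occupancy**: fraction of suitable patches occupied, sampled every 10 days
  over the final 100 days, averaged (11 samples).
- **Biomass panel**: total consumer biomass of 100 randomly chosen suitable
  patches at the same 11 sample times (exported both as mass and as tissue
  energy).
- **Variability**: with `w` the temporal covariance matrix between panel
  patches and `μ_m` the temporal means, `γ_CV = Σ_{mn} w_mn / (Σ μ_m)²` and
  `α_CV = (Σ_m √w_mm / Σ μ_m)²` (the biomass-weighted squared local CV of
  Wang & Loreau's framework), so `β₂ = α_CV − γ_CV ≥ 0` holds by
  Cauchy–Schwarz. A `plain` switch computes the unweighted
  `Σ w_mm / (Σ μ_m)²` variant instead; the weighted form is the default
  because it alone guarantees a non-negative asynchrony component.
- **Genotype snapshots**: every 500 days, at most 50,000 sampled W_max
  values; summary moments are the population-moment mean, CV, Fisher g1
  skewness and excess kurtosis g2 (normal = 0).
- **Egg cohort**: up to 1,000 eggs laid in the final 600 days are followed
  for life (move count, lifetime displacement, reproductive success).

## Variation partitioning

Run summaries are z-scored column-wise, extinct runs excluded. Redundancy
analysis on standardised responses reduces to multivariate least squares;
the canonical R² (trace of fitted over total sum of squares) is adjusted
with the Ezekiel formula, and the three blocks — coupling (binary),
isolation (NND, numeric) and growth speed (r, numeric) — are partitioned by
inclusion–exclusion over the seven subset models, exactly the procedure of
vegan's `varpart` (against which the implementation is tested). Adjusted
fractions may be negative and are reported as computed. A per-NND two-block
variant (coupling × growth) mirrors the within-isolation analysis. Note that
with orthogonal predictors the *raw* unique fractions equal the single-factor
R² exactly; the adjusted ones differ by an O((1−R²)/n) degrees-of-freedom
correction, which is why exact-equality checks are stated on the closure and
subset-recovery identities rather than on uniques.

## Numerical and implementation notes

- The population is held as a structure of NumPy arrays; all daily phases are
  vectorised. Destination choice for movers is batched: eligibility by a
  precomputed pairwise torus-distance matrix between suitable cells, and
  exact resource ties broken by adding per-(mover, cell) uniform jitter of
  amplitude 10⁻⁹ J — far below any meaningful resource difference — which a
  test verifies is distributionally equivalent to the exact uniform
  tie-break rule.
- With a fixed seed every output is bit-identical across runs; replicates
  derive independent seeds from a base seed via `SeedSequence`.
- Energy bookkeeping can be audited per day (`audit=True`): intake, basal
  cost, starvation removals, movement cost, growth investment, reproduction
  investment, endowments, immigration input, and death removals reconstruct
  the population reserve exactly (relative drift < 10⁻⁶).

## Desk-scale testing and what it shows

The stochastic tests run a reduced system — 100 suitable patches, 100
founders, 2,000 days, 5–10 replicates — chosen so the full suite completes on
one CPU. At this scale the qualitative selection gradients are reproducible:
mean evolved adult mass increases with isolation and decreases with resource
growth speed (coupled mode), and the variation-partitioning pipeline runs
end-to-end on simulator output. The desk-scale system is *not* a quantitative
miniature of the published experiment: populations are ~25× smaller, so
demographic stochasticity is far stronger, extinction at low growth speed
(r = 0.1) is near-universal rather than occasional, and the published
full-scale fractions of explained variation are not recovered numerically.
In particular, the contrast "decoupled populations go extinct more often than
coupled ones" holds in the full-scale system only beyond NND ≈ 5; at desk
scale with r = 0.1 both modes die in the initial resource crash, so that
contrast is not observable here (the relevant test documents this honestly).

## Known limitations

- No temperature dependence, no endotherm or flying/swimming cost laws.
- The resource does not diffuse between cells and has no seasonality.
- Only one evolving lineage; "community" interpretations read size classes
  as species.
- Movement is a daily teleport to the chosen cell; within-day paths are not
  modelled beyond their energetic and search-area consequences.
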