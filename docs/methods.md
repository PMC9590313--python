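# Methods

## Model

`greenreach` measures spatial accessibility to urban parks with a
supply-demand adjusted two-step floating catchment area (2SFCA) model and
derives equity statistics from the resulting surface.

**Supply (park attractiveness).** Each park `j` is scored on three
components: its area `S_ja` (m²), the mean street green-view index `S_jg`
of the sample points inside its network service area, and the
Shannon-Wiener diversity `S_jd = −Σ_c p_c ln p_c` (nats, at most `ln 13`)
of the 13 service-function POI categories inside that area. A green-view
sample's index is the mean vegetation fraction over four compass headings
(0°/90°/180°/270°). The service area is the set of road locations within
300 m (community and street parks, special parks under 5 000 m²) or 500 m
(comprehensive parks, larger special parks) of network distance from any
entrance, dilated by a 20 m off-road buffer so that points standing beside
a covered street count as inside. Components are divided by their maxima
over all parks and combined with weights `γ_A, γ_G, γ_D` (equal thirds by
default, sum constrained to 1), giving a dimensionless `S_j ∈ [0, 1]`. A
component whose maximum is zero contributes zero for every park.

**Demand and choice.** Travel time `t_ij` from cell centroid `i` to park
`j` is the network shortest path at constant mode speed (walking 5,
cycling 15, driving 40 km/h), taking the minimum over the park's
entrances; both endpoints snap to their nearest road node and the snap gap
is traversed at mode speed. Decay uses the normalized Gaussian
`G(t, t₀) = (e^{−(t/t₀)²/2} − e^{−1/2})/(1 − e^{−1/2})` on `[0, t₀]`, zero
beyond: `G(0)=1`, `G(t₀)=0`, continuous at the threshold. The
psychological threshold `t₀` defaults to 30/25/30 min for
walking/cycling/driving and can be re-derived from survey bins: per park
category and mode the willing travel time is the share-weighted mean of
bin midpoints (the open "over 60 min" bin contributes its fixed 60-min
midpoint), and `t₀` is the rounded maximum of the four category means, so
the threshold accommodates the park type people travel furthest for.
Each cell's demand is spread over the parks reachable within `t₀` by Huff
probabilities `Prob_ij ∝ S_j·G(t_ij, t₀)` (row-normalized); two
alternative weightings that keep an explicit travel-time factor
(`S_j/t_ij·G` and `S_j·t_ij·G`) are selectable for sensitivity analysis.

**Two steps.** Step 1: `R_j = S_j / Σ_i Prob_ij·P_i·G(t_ij, t₀)` over
cells within the threshold; a park with zero weighted demand gets
`R_j = 0`. Step 2: `A_i = Σ_j Prob_ij·R_j·G(t_ij, t₀)`. Because the same
`Prob·G` weights appear in both steps, the identity
`Σ_i P_i·A_i = Σ_{j: demand>0} S_j` holds exactly; the pipeline records
its relative error per mode and the tests require it at 1e-9.

**Equity.** The equality index `E_i = a_i·max(R_j)/max(a_i)` rescales the
accessibility surface so its maximum equals the best supply-demand ratio,
then bins into six classes (I: `E=0` no supply; II: `0<E<0.25`; III:
`0.25≤E<0.5`; IV: `0.5≤E<0.75`; V: `0.75≤E≤1`; VI: `E>1` oversupply —
kept with its "serious inequality" label as printed in the source
classification even though the wording is counterintuitive). Spatial
clustering of `E_i` (configurably `A_i`) uses the Anselin local Moran
`I_i = (x_i−x̄)/m₂ · Σ_j w_ij(x_j−x̄)` with `m₂ = Σ(x_k−x̄)²/n` on
row-standardized queen-contiguity weights, with conditional-permutation
pseudo p-values (999 draws, α = 0.05, seeded) and HH/HL/LH/LL labels for
significant cells. Inequality overall is the Gini coefficient of the
Lorenz curve of cumulative resource share against cumulative population
share, with units sorted ascending by resource per capita and the
trapezoid rule `G = 1 − Σ(P_k−P_{k−1})(Q_k+Q_{k−1})`; the resource
defaults to population-weighted accessibility `P_i·A_i` (raw `A_i`
selectable). Gini bands: <0.2 absolute equality, 0.2–0.3 equality,
0.3–0.4 relatively equality, 0.4–0.5 low inequality, >0.5 high
inequality, boundaries joining the lower-Gini band.

## Design choices where the design was open

- **Huff weight.** The default drops a bare travel-time factor from the
  Huff weight, using `S_j·G(t_ij, t₀)` — the form consistent with
  Gaussian-decay 2SFCA practice, where `G` already carries the impedance.
  The literal-product and inverse-time forms remain available as
  variants; every conservation and normalization property holds for all
  three.
- **Gini formula.** The rectangle form `1 − ΣΔP·ΔQ` yields `1 − 1/n` on a
  perfectly uniform allocation and therefore cannot measure inequality
  with 0 as perfect equality; the trapezoid form is the default and is
  oracle-tested against the O(n²) pairwise mean-absolute-difference
  formula. The rectangle form survives behind `literal_formula=True` for
  inspection only.
- **Supply scale.** `S_j` is dimensionless by default (Eq.-level
  normalization), with `supply_scale: area` multiplying it by park area so
  ratios and accessibility come out in m²/person. The scenario analyses
  and the acceptance script use the area scale, because the absolute
  equality-class cutoffs (0.25/0.5/0.75/1) are only meaningful when
  `max(R_j)` is of order 1: at the dimensionless scale with a realistic
  urban population, `max(R_j) ≈ 10⁻⁴` and every cell would land in the
  two lowest classes regardless of the spatial pattern.
- **Service-radius tie.** A special park of exactly 5 000 m² takes the
  500 m radius (the source rule states only strict inequalities).
- **Snapping.** Nearest node rather than nearest point on edge; at 100 m
  network spacing the induced error is below half a cell.
- **Zone assignment and partial cells.** Cells join the ring zone of
  their centroid; partial boundary cells are kept with their true clipped
  area, and population redistribution uses residential-POI counts only
  (never cell area).
- **Underserved share.** Defined as the percentage of populated cells
  with exactly zero accessibility under the mode; zonal statistics are
  population-unweighted over populated cells.
- **LISA inference.** Weight scheme (queen), permutation count (999) and
  α (0.05) are configurable defaults; the permutation shortcut reuses one
  block of without-replacement index draws across units, the standard
  conditional-randomization device.

## Synthetic cities

The generator emulates the structure the analysis assumes about a dense
monocentric city; its defaults are the study conditions used throughout
the tests and the acceptance script: a 50×50 grid of 100 m cells (a 5×5 km
core), ring zones at radii 800 and 1 600 m, 250 000 residents
(10 000 persons/km², an inner-city density) split over rings by an
exponentially decaying density surface and spread within rings by
residential-POI counts, 20 parks (2 comprehensive, 3 special, 7 community,
8 street; log-normal areas floored at 0.1 ha) with 1–4 entrances snapped
to road nodes, a 100 m lattice network (2 601 nodes) with 5% diagonal
shortcuts and an optional river gap with bridges, 1 200 service POIs (60%
clustered around parks) in the 13 categories, and a smooth random
green-view bump field in [0, 1]. All randomness flows from one master seed
through a named stream per layer, so a city is bit-reproducible and layers
can be regenerated independently.

Named scenarios encode qualitative expectations: `park_desert_quadrant`
keeps the NE quadrant park-free (the lowest equality classes should
concentrate there under walking); `uniform_everything` is an analytic
limit — identical parks on a symmetric lattice with uniform population —
whose accessibility surface is constant up to boundary effects and whose
Gini stays below 0.05; `riverside_greenway` adds a river gap and elevated
green view along the banks.

What the generator does *not* emulate: real street topologies and speed
limits, transit and multimodal travel, park quality differences beyond
area/green-view/diversity, temporal variation in population, or
behavioural heterogeneity in thresholds. Passing tests therefore
demonstrate the correctness and internal consistency of the method and
its qualitative behaviour on plausible urban structure — not calibrated
predictions for any real city.

## Numerical notes and problem sizes

Unreachable origin-park pairs carry an `inf` travel time and decay weight
0. A cell whose reachable parks all have zero attractiveness keeps an
all-zero Huff row (warned). The inverse-time Huff variant floors travel
times at 0.1 min. Lorenz units with zero population are dropped before
sorting; a zero total resource raises instead of returning a meaningless
Gini. The test suite runs the full three-mode pipeline on the 2 500-cell
baseline (seconds per run); the acceptance script uses the same baseline
with 199 LISA permutations and finishes in a few seconds.

## Known limitations

Driving times include no parking or access walking; roads are undirected
with uniform speed per mode; the Huff threshold equals the catchment
threshold; LISA p-values are pseudo p-values from conditional permutation
and inherit its multiple-testing caveats.
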