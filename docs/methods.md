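# Methods

`runsit` studies the relation between the *situation* at the start of a run —
calendar time, weather, surrounding landuse, neighborhood demographics — and
*running performance*, defined as the run distance normalized by the runner's
own statistics. Because the mobile-fitness datasets this kind of analysis is
performed on are proprietary, the package pairs the analysis pipeline with a
synthetic-world generator that plants known effects, so every stage can be
validated against ground truth.

## Situation vectors

Each run is described by exactly 29 categorical items:

| group | features | discretization |
|---|---|---|
| temporal (3) | hour, weekday, month | 8 three-hour bins `[0,3) … [21,24)`; 7 weekdays; 12 months |
| weather (4) | temperature, weather, wind, humidity | 5 width-8 °C bins over [−10, 30] (values outside clamp); fixed vocabularies of 9 / 5 / 3 types |
| topographical (18) | distance to nearest cell of each of 9 landuse classes; coverage % of each class in a 10×10-cell window | a dedicated `0` category plus decile bins (below) |
| demographical (4) | population density, % over 65, % one-person households, % households without children | `0` category plus decile bins |

Geographic features are computed on a 100 m analysis grid. Distances are
center-to-center Euclidean to the nearest cell of the class (exact Euclidean
distance transform), 0 on the class itself. The coverage window is the 10×10
block spanning rows `[r−5, r+4]` and columns `[c−5, c+4]` — a 10-cell window
has no center cell, so this fixed convention is used everywhere, clipped at
raster borders with the denominator reduced accordingly. Demographics come
from a point-in-polygon query of the start cell center against the
neighborhood table; boundary cells go to the first covering polygon in table
order.

Continuous geographic features are binned against the *reference
distribution* over all grid cells of the study landscape: a `0` category
(being *on* the class, or zero coverage/density carries distinct meaning)
plus 10 equal-probability bins over the strictly positive values. Quantiles
use the nearest-rank method and duplicate edges are merged, so discrete
distributions produce fewer, well-defined bins. Values above the reference
maximum clamp into the top bin. Whether zero cells should participate in the
quantiles is genuinely open; excluding them matches the separately listed
zero categories and keeps the positive bins informative.

## Cleaning and normalization

Runs are dropped when fields are missing or unparseable, categorical values
fall outside the fixed vocabularies, total distance is below 100 m, or the
start point has no geographic context (outside the raster or every
neighborhood polygon); drops are logged per reason and cleaning is
idempotent. Users with fewer than 10 retained runs are removed entirely.

Per-run weight: `w = (y − average) / (max − min)` over the user's retained
runs across the full horizon (the personal statistics are not restricted to
the active window). This lies in [−1, 1]; a run at the user's mean is exactly
0; `max = min` (all runs identical) yields 0 by convention, avoiding a 0/0
while preserving the at-the-mean semantics.

## Annual pattern and clustering

Per user, weekly run counts are aggregated on the user's own ISO-week axis
and the window of 52 consecutive weeks with the most runs is selected (ties:
earliest start; short histories zero-pad on the right). Pairwise similarity
between the 52-week sequences uses classic DTW (unit steps, |aᵢ−bⱼ| cost, no
window constraint), dynamic programming in a numba kernel.

The distance matrix is clustered with agglomerative Ward linkage via the
standard Lance–Williams recurrence

    d(Cx,Cy)² = [ (nᵢ+n_y)·d(Cᵢ,Cy)² + (nⱼ+n_y)·d(Cⱼ,Cy)² − n_y·d(Cᵢ,Cⱼ)² ]
                / (nᵢ+nⱼ+n_y)

with deterministic tie-breaking on the smallest index pair. A plus-term
variant of the recurrence with `n(Cx)+n(Cy)` denominators, which circulates
in some applied write-ups, is available as `variant="printed"` for
comparison; the standard form is the default because it is the established
Ward update and can be cross-checked against scipy. Two caveats are inherited
knowingly: Ward linkage presumes Euclidean distances and DTW is not
Euclidean, so the dendrogram is a heuristic grouping; and the flat-cut
threshold is in data-dependent DTW units, so it is a free parameter
(`cut_threshold`) with a `threshold_for_k` helper that reads the height gap
for a requested cluster count from the linkage.

## Weighted frequent item mining

A transaction is a run's 29 items plus its weight; the weighted support of an
itemset X is the sum of weights over transactions containing X, and itemsets
are reported when |w(X)| ≥ σ. Signs separate situations associated with
above-average (+) and below-average (−) distances.

Signed weights break the anti-monotonicity that classical FP-Growth pruning
relies on: a superset's |support| can exceed a subset's (negative and
positive transactions cancel differently). The miner therefore ships two
modes over the same weighted FP-tree (prefix tree with per-node accumulated
weight and count, header ordered by descending |w(item)| with name
tie-breaks):

* **exhaustive** (default): enumerates every itemset of surviving header
  items occurring in at least one transaction, up to `max_len` (default 4 in
  the API, 3 in the pipeline config, to bound combinatorics), and reports
  those passing σ. This has declarative semantics and is tested against
  brute-force subset enumeration.
* **pruned**: also prunes items inside conditional trees by |w| — the classic
  operational behavior, faster but possibly incomplete. Its output is always
  a subset of exhaustive output at equal σ.

σ is a free parameter. A principled default is provided by
`permutation_null`: permuting weights across transactions breaks any
situation–distance association while preserving both marginals, giving null
SDs of single-item supports; σ = 5× the largest null support SD admits
essentially no spurious itemsets.

Per-feature *variability* is the population standard deviation of the
single-item weighted supports over the feature's observed categories — the
Fig.-style screening statistic for which features matter. Note the raw
statistic scales like √n (supports are sums); `normalize=True` divides
supports by the number of transactions, which is the variant that vanishes
under a null of no effects and is used for null-calibration checks.

## Synthetic world

The generator emulates the structure of a 4-year national fitness dataset:

* **Landscape** — Voronoi patches of seeded points labeled from a class mix
  (default mix dominated by agriculture and residential), giving contiguous
  regions and hence spatially autocorrelated distance/coverage features.
  Neighborhoods are a jittered rectangular tiling; population density
  correlates with residential coverage, and purely non-residential polygons
  get density 0 so the zero demographic category is populated.
* **Runners** — two archetypes as study conditions: *sporadic* users
  averaging 34 runs/year inside a contiguous 10–30-week sub-period with
  situation sensitivity 2.0, and *regular* users averaging 94 runs/year
  across the whole year with sensitivity 0.5 (an 80/20 mixture by default).
  Per-user annual rates are Gamma with CV 0.25; baselines are Gaussian
  (6000 ± 1500 m, floored at 500 m).
* **Runs** — distance = baseline + Σ(matched effect deltas) × sensitivity +
  N(0, 300 m), clipped at 50 m; 2% of runs are "aborted" (50–150 m) and 1%
  carry a missing weather type, so the cleaning rules have work to do. Start
  cells favor residential areas (8:4:1 weights for residential : within 2
  cells : elsewhere). Weather is month-conditioned (temperate-maritime
  monthly temperature means, season-dependent weather-type probabilities).
  Start times follow 8-slot diurnal and 7-day weekday preference vectors
  aligned with the hour bins, with weekend and morning slots elevated.
* **Weekly placement** — each year spreads a user's runs evenly (stratified)
  over that user's active weeks, repeating the same yearly pattern. This is a
  deliberate convention: with Poisson-scattered weeks, the most-active-window
  statistic inflates the annual rate by max-selection (~20% at these rates),
  whereas the repeating pattern makes the window statistic identify the
  planted rate. The cost is less realistic week-to-week count dispersion;
  weekday, time-of-day, weather and distance noise remain stochastic.
* **Default planted effects** — +800 m on Sunday-morning runs
  (`{weekday=Sunday, hour=[09,12)}`) and +400 m at moderate temperatures
  (`{temperature=[6,14)}`), directions chosen to mimic the attraction of
  Sunday mornings and mild weather for less-active runners.

What passing tests on this world do **not** show: recovery under realistic
GPS noise, behavioral drift, seasonality of participation, churn,
heterogeneous effect structures, or real landuse class frequencies — the
generator makes no attempt at those (non-goals).

## Numerical and design choices

* Distances and coverages are precomputed per cell (exact EDT, integral
  image); extraction is a vectorized cell lookup.
* ISO-8601 weeks; most-active-window ties resolved to the earliest window.
* Hour bins are half-open; temperature bins half-open with the final bin
  closed at 30 °C; out-of-range temperatures clamp into the boundary bins.
* A landscape missing a landuse class makes that distance feature undefined;
  the pipeline raises at transaction building (the default landscapes always
  contain all 9 classes).
* Rasters are single-band GeoTIFF (tifffile with ModelPixelScale/ModelTiepoint
  tags, lower-left array convention); vectors are GeoJSON; all tables CSV;
  the binning scheme serializes to JSON.
* One global seed fans out to per-stage child seeds through `SeedSequence`,
  so stage re-runs and full runs are bit-reproducible.

## Problem sizes

The packaged studies use a 60×60-cell landscape (36 km²), 500 users over 4
years (~90k runs) for archetype/effect recovery, and 200 users over 2 years
for null calibration; oracle cross-checks run on 100 random mining instances
(≤12 items, ≤200 transactions), 200 random DTW pairs (length ≤52) and 50
random distance matrices (n ≤ 50). These sizes give stable statistics
(recovery ARI ≈ 0.97, cluster means within a few percent of 34/94) while the
whole suite runs in well under a minute after JIT warm-up.

## Known limitations

* Exhaustive mining is exponential in the surviving-header size; it is meant
  to be used with a calibrated σ and a `max_len` cap. The pruned mode scales
  further but inherits the incompleteness of |w|-pruning under signed
  weights.
* The variability statistic has no significance calibration built in beyond
  the permutation null; supports are not tested for significance
  (deliberately out of scope).
* A single planar metric CRS is assumed end to end; there is no reprojection
  and no vector-based distance computation.
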