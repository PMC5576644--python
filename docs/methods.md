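# Methods

## Observation model

The unit of observation is a *group sighting*: a set of individually
identifiable animals recorded moving together at one place on one date,
either resighted or captured together in a mist net (both are treated
identically as group observations). Analysis rests on the gambit of the
group: every member of a sighted group is taken to be associating with every
other member. Sightings are assembled into a binary group-by-individual
(GBI) matrix per scenario; individuals with fewer than `min_sightings = 2`
total appearances in that scenario are dropped, then rows left empty are
dropped, iterated to a fixed point (a row whose remaining membership is a
single retained individual is kept — singleton sightings still count toward
sighting totals and mean group size). The filter is applied per scenario
network, not per season; a flag on `build_gbi` does not exist for the
per-season variant because windowing happens upstream — callers who want a
season-level filter can pre-filter the observation list.

## Association index and metrics

Edge weights use the simple-ratio index, SRI(i,j) = x / (n_i + n_j − x)
with x the joint-group count: the proportion of groups containing either
individual in which both appeared. It is the natural estimator when joint
and single sightings are equally detectable, which holds for this kind of
walked-transect resighting. A half-weight variant is provided
(`half_weight_index`) for sensitivity analysis where joint sightings are
under-recorded; the index is pluggable in `node_metrics`.

Weighted degree is the row sum of the association matrix (bounded by the
number of possible partners); mean group size for an individual is the
arithmetic mean of the sizes (self included) of the groups it appeared in.
Centrality-style metrics are deliberately out of scope: in sparse,
low-density populations they are dominated by sampling noise.

## Spatial classification

Treatment is assigned from sighting geometry: *affected* if every sighting
of the individual lies on or within `affected_radius_m = 100` of the
disturbance polygons (distance 0 inside), *unaffected* if every sighting is
at least `unaffected_radius_m = 500` away, *excluded* otherwise — any
sighting inside the 100–500 m buffer band, or sightings straddling the two
zones, removes the bird from analysis. The all-sightings rule is strict by
design: with small home ranges and weak flight the zones are effectively
closed, and a straddling record more likely signals a mis-georeferenced
point than genuine commuting. Coordinates may arrive as lon/lat; they are
projected once at ingest to planar meters on a local tangent plane about the
site centroid (sub-meter error at site scale), so the buffer radii are
literal meters.

## Permutation inference

The statistic for a pre/post comparison is the OLS slope of the
per-individual metric on a 0/1 period indicator, computed in closed form as
mean(post) − mean(pre). Individuals present in both periods contribute one
value per period; no pairing is imposed, because the permutation scheme
carries the dependence structure.

The null model randomizes the data stream itself. One elementary move picks
two sightings of different individuals in different groups and swaps them —
a 2×2 checkerboard flip — preserving every group size and every individual's
sighting count, and never crossing a treatment block. Permutations form a
sequential chain from the observed matrix (`swaps_per_permutation = 1`,
`burn_in = 0` by default, both configurable); each period's matrix has its
own chain with its own child seed, the metric and slope are recomputed at
every step, and the one-tailed p-value uses the add-one estimator
(1 + k)/(1 + n). Degenerate matrices with no available checkerboard (e.g.
all-ones) pass through unchanged after a bounded search, so chains never
hang.

Seed handling: all child seeds derive from one master seed through numpy
`SeedSequence` spawn keys — generator streams use keys 1–3, the pre/post
permutation chains use keys 101/102, and replicate studies use
two-component keys — so no two components ever share a bit stream and every
result is exactly reproducible from the master seed.

### Calibration behaviour (important)

When the observed matrix is itself a uniform draw from the fixed-margin
ensemble, the test is exactly calibrated (measured rejection 0.035 at the
5% level over 200 replicates; see the oracle test). On realistic simulated
surveys, however, the degree test rejects effect-free data at roughly
8–10% at nominal 5%. The reason is structural, not a bug: the slope statistic
depends on each individual's sighting count and each group's size, and the
permutation holds those margins fixed, so between-dataset margin variability
(who happened to be surveyed how often in each period) is not propagated
into the null. This anticonservatism of data-stream permutation regression
tests is a recognized property of the method class; fully mixing the chain
makes it worse (rejection 0.135 with a 1000-swap burn-in), which is why the
chain-from-observed convention is the default. Users should treat p-values
near the threshold with caution and regard the control arm of a BACI design
as the more trustworthy guard against false positives.

## Habitat comparison

Grass cover lives on a 5% measurement grain in [0, 100], so the data are
tied and non-normal; comparisons use the Wilcoxon rank-sum test with
midranks. The exact enumeration p-value is used when the pooled sample is
tie-free and ≤ 25 observations; otherwise the normal approximation with tie
and continuity corrections. Both the rank-sum W of the first sample and the
Mann-Whitney U are reported, since W is only interpretable with the sample
sizes attached. Being rank-based, the analysis cannot test a period × use
interaction; the report keeps the three marginal contrasts (pre vs post
pooled; used vs random within each period) and states this limitation.
Off-grain cover values are a row-level error in strict mode; lenient mode
snaps to the grain with exact halves rounded down (37 → 35, 37.5 → 35,
38 → 40) and logs each snap.

## Synthetic generator

The generator emulates one field season. A square site of 700 ha carries a
rectangular fire scar covering 30% of its area. Home-range centers are
static: affected individuals inside the scar with a 60 m interior margin,
unaffected ones at least 600 m beyond it, none in the buffer band, so the
distance classifier recovers the arms exactly (sighting jitter is clipped at
50 m). Per observation day (32 per ~6-week period by default, dates drawn
without replacement from the 2013-style windows 15 May–28 Jun and
13 Jul–24 Aug) each arm's individuals are partitioned into groups: group
sizes follow a zero-truncated Poisson with mean 3.0, and membership is
filled by companion preference — each pair holds a fixed latent affinity,
and candidates join a forming group with probability ∝ exp(strength × mean
affinity to current members). Survey effort records at most `groups_per_day
= 3` randomly chosen groups per arm per day, so individuals are sighted on
random day subsets and a few can fail the two-sighting filter, as in real
resighting data. A tenth of observations are labelled mist-net captures.

The post-fire response in the affected arm has two channels: a group-size
multiplier (1.6), representing congregation in remaining habitat, and an
added companion-reuse concentration (2.0), representing tighter
associations. These defaults were calibrated once so that the affected
arm's mean weighted degree rises by ≈ 1.0 (measured +1.10 averaged over 100
replicates) — the magnitude of change the motivating field setting reports —
while the control arm stays flat. The concentration channel is what makes
the shift detectable by data-stream permutations; a pure group-size change
lives in the row margins and is largely absorbed by the null.
`SyntheticConfig.neutral()` switches off every effect *and* the baseline
companion preference, giving exchangeable group membership for null
calibration.

Vegetation plots draw grass cover from beta distributions (concentration
κ = 8) rescaled to percent and snapped to the 5% grain: pre-fire, used and
random plots share a mean of 60%; post-fire the random-plot mean falls to
30% and used plots sit 20 points above it (selection for remaining grass).
Default counts are 106 used and 152 random plots, split evenly across
periods.

What the generator does not emulate: observer-effort heterogeneity along
roads and trails, home-range drift or dispersal, demographic turnover,
between-arm contact, and spatial autocorrelation of vegetation. Passing
tests therefore demonstrate correctness of the machinery and sane behaviour
under a plausible observation process, not that any particular field system
meets the model's assumptions.

## Problem sizes and numerics

Replicate studies in the tests and the reproduction script use 200
effect-free datasets (single arm of 40 individuals, 30 days per period, 500
permutations) for calibration and 100 effect datasets (two arms of 30, 500
permutations) for power; the single-season demonstration uses the full 1000
permutations. These sizes give Monte-Carlo standard errors of 1–2 points on
the reported rates. Ties in the p-value count (`null ≥ observed`) are
counted in favour of the null, which together with the add-one rule makes
the test slightly conservative at tiny permutation counts and keeps p in
(0, 1]. The simple-ratio denominator guard (0/0 → 0) is unreachable for
retained individuals but kept for safety. Association-matrix symmetry is
validated on construction; the truncated-Poisson rate is solved by Brent's
method on λ/(1−e^(−λ)) = mean.

## Known limitations

- The type-I inflation of the degree test under realistic effort noise,
  discussed above — inherent to data-stream permutation regression, and the
  main reason the BACI control arm matters.
- A deposited season of real sightings is needed to reproduce any published
  per-cell degree table; the package ships only the generator, and the
  association-index choice (simple ratio vs half weight) shifts absolute
  degree values.
- The rank-based habitat analysis cannot estimate a period × use
  interaction effect size, only the marginal contrasts.
- Networks of different sizes are compared through per-individual metrics
  and within-arm permutations; no explicit network-size correction is
  applied beyond that.
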