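# firenet

Social-network analysis of how fire disturbance changes animal sociality,
built around a before-after-control-impact (BACI) design for group-sighting
data — the setting is a color-banded population of savanna songbirds whose
habitat partially burns midway through a field season, but the machinery
applies to any gambit-of-the-group observation stream.

It is written for behavioral ecologists who have (1) repeated sightings of
identifiable individuals in groups, (2) a mapped disturbance footprint, and
(3) optionally, used-vs-random habitat plots — and who want the standard
permutation-based inference for "did social connectivity change after the
disturbance, beyond what the sampling structure explains?"

## What it computes

**Networks.** Each observed group is a row of a binary group-by-individual
(GBI) matrix; individuals seen fewer than twice are filtered out (to a fixed
point, so no empty rows remain). Pairwise edge weights use the simple-ratio
index

&nbsp;&nbsp;&nbsp;&nbsp;SRI(i, j) = x_ij / (n_i + n_j − x_ij),

the number of groups containing both i and j over the number containing
either, so weights run from 0 (never together) to 1 (always together). Each
individual's **weighted degree** is the sum of its incident edge weights,
and its **mean group size** is the average size of the groups it was seen
in.

**Design.** Individuals are classified *affected* if every sighting lies on
or within 100 m of the disturbance footprint, *unaffected* if every sighting
is at least 500 m away, and excluded otherwise. One network is built per
(arm × period) cell: pre/post × affected/unaffected in a BACI year, pre/post
only when the whole site is affected.

**Inference.** The test statistic is the OLS slope of metric ~ period
(pre = 0, post = 1), i.e. mean(post) − mean(pre). The null model is a
**data-stream permutation**: checkerboard swaps ([[1,0],[0,1]] ↔
[[0,1],[1,0]]) exchange individuals between groups while preserving every
group size and every individual's sighting count; swaps never cross
treatment arms. Each period's matrix is permuted in its own sequential
chain, the metric and slope are recomputed per permutation, and the
one-tailed p-value is (1 + #{null ≥ observed}) / (1 + n) (add-one rule, so
p ≥ 1/(n+1)).

**Habitat.** Grass cover in used vs random 10 × 10 m plots (recorded to the
nearest 5%) is compared with Wilcoxon rank-sum tests: pre vs post (fire
effect), and used vs random within each period (habitat selection).

A synthetic-data generator (`firenet.synthetic_data`) simulates the whole
setting — home ranges, a fire scar covering 30% of a ~700 ha site, daily
group formation with preferred companions, survey effort, and vegetation
plots — with configurable post-fire effects, so the entire pipeline is
testable end to end without field data.

## Worked example

```
$ firenet simulate --seed 42 --out demo/sim
wrote 384 observations, 258 veg plots to demo/sim

$ firenet baci --sightings demo/sim/sightings.csv --scars demo/sim/scars.geojson \
               --seed 42 --n-perm 1000 --out demo/baci
classified 60 individuals: 30 affected, 30 unaffected, 0 excluded
affected     weighted_degree    coef=+0.918 p(greater)=0.00699
affected     mean_group_size    coef=+1.525 p(greater)=0.215
unaffected   weighted_degree    coef=+0.141 p(less)=0.825
unaffected   mean_group_size    coef=+0.190 p(less)=0.415
```

The affected arm's weighted degree rose by 0.92 after the fire, larger than
all but 6 of 1000 margin-preserving permutations (p ≈ 0.007): birds whose
habitat burned became more connected. The control arm shows no credible
decline (p = 0.83). The per-cell summary written to
`demo/baci/degree_summary.csv`:

```
scenario,period,n,mean_weighted_degree,sd_weighted_degree
affected,pre,30,1.54,0.41
affected,post,30,2.45,0.47
unaffected,pre,30,1.34,0.34
unaffected,post,30,1.49,0.29
```

```
$ firenet habitat --veg demo/sim/veg.csv --out demo/hab
pre_vs_post_all: W=21849.0 U=13464.0 p=7.687e-18 (n1=129, n2=129, normal_approx)
used_vs_random_pre: W=3835.5 U=2404.5 p=0.06057 (n1=53, n2=76, normal_approx)
used_vs_random_post: W=4575.0 U=3144.0 p=5.775e-08 (n1=53, n2=76, normal_approx)
```

Fire sharply reduced grass cover overall; used and random plots were similar
before the fire but used plots had far more grass afterwards — the birds
selected the remaining grass.

Each output directory also contains `pvalues.csv`, the full
`null_coefficients.csv` for audit, a `report.json` with every number at full
precision (stamped with the seed and a config hash), and — unless
`--no-figures` is passed — null-distribution histograms with the observed
coefficient overlaid plus network drawings and GraphML exports.

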