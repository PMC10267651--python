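# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the limits of what the validation suite shows.

## Graph measures

A connectome is a symmetric non-negative weighted adjacency matrix over
atlas ROIs; zero means "no reconstructed connection" and the diagonal is
zero. Weighted path metrics require a weight-to-length map, which no
single convention fixes; we use the reciprocal, `L_ij = 1/w_ij`, the
standard choice in connectivity toolboxes where a stronger
(higher-anisotropy) connection is a shorter functional distance. All
rank-based consumers (hub criteria) are invariant to this choice up to
monotone transforms.

* **Nodal strength** is the sum of incident weights.
* **Betweenness** counts, per node, the fraction of length-shortest
  paths through it, endpoints excluded, each unordered pair counted
  once, unnormalized (only ranks are consumed downstream). Tied shortest
  paths share credit via full σ-counting; no arbitrary single-path
  tie-break exists anywhere in the pipeline.
* **Nodal average path length (APL)** is the mean shortest-path length
  to *reachable* nodes. Unreachable pairs are excluded from the mean and
  logged as a reachability deficit rather than mapped to infinity: this
  keeps APL finite and rankable on almost-connected subject matrices,
  at the cost of a slight optimism for poorly connected nodes (the
  deficit count is surfaced so consumers can check it). An isolated
  node's APL is undefined (NaN) and is dropped pairwise by the
  inference layer.
* **Clustering** is the Onnela weighted coefficient: the mean geometric
  mean of triangle weights normalized by the network-wide maximum
  weight; zero below degree 2.

Betweenness and clustering are computed by networkx and shortest paths
by scipy's Dijkstra; the test suite checks all of them, plus the
rich-club coefficient, against independent brute-force enumerations
(exhaustive simple-path search, Floyd–Warshall, triple loops) on
hundreds of random graphs with up to 8 nodes, to 1e-9.

## Weighted rich club and its null

φW(k) is the ratio of the weight carried among nodes of binary degree
strictly greater than k to the sum of the equally many largest edge
weights anywhere in the network, undefined when fewer than two nodes
survive or the club has no edges. The strict `> k` threshold follows the
seminal definition. Ties among equal weights in the denominator are
irrelevant (a sum over the top-|E| weights is tie-invariant).

Because φW(k) grows mechanically with k in any graph, it is normalized
by its mean over "comparable random networks": Maslov–Sneppen double
edge swaps in which each edge keeps its weight. This preserves exactly
the binary degree sequence and the multiset of edge weights (both
verified exactly for every draw in the tests), but not the strength
sequence — the standard construction in the weighted rich-club
literature. Defaults: 10 accepted swaps per edge, 1000 null networks
for group-averaged curves (with smaller test-scale overrides); swaps
creating self-loops or multi-edges are rejected and retried, with a
bounded retry budget and a logged best-effort fallback for pathological
graphs. The swap loop is a numba kernel; a rewiring of a ~1000-edge
network costs well under a millisecond, which is what makes per-subject
null ensembles affordable.

Per-k empirical p-values use the add-one convention
`(1 + #{φ_rand ≥ φ_obs}) / (n_null + 1)`; the rich-club *regime* is the
longest contiguous run of k with φWnorm > 1 (first run wins ties).

Calibration: on Erdős–Rényi weighted graphs (N=100, p=0.2, i.i.d.
lognormal weights, 200 nulls) the per-k mean of φWnorm is 1.000 at every
level, and ~97% of all (seed, k) cells with at least 10 surviving nodes
fall within [0.9, 1.1]. The spread grows mechanically at the highest k,
where the club shrinks to ~10 nodes and ~15 edges and the sampling
standard deviation of φWnorm approaches 0.1; a joint ±10% band across
all such levels simultaneously is therefore not a meaningful check and
the calibration is asserted cell-wise.

Group comparison of rich-club curves runs on per-subject curves (each
subject normalized against its own null ensemble, with the null stream
keyed to a hash of the subject's matrix so identical networks get
identical ensembles), restricted to k levels defined in ≥90% of
subjects, Welch t + Freedman–Lane permutation per level, Bonferroni
across levels × the two coefficient families. Group-averaged curves are
also produced as the descriptive surface.

## Hubs and connection classes

Each of the four criteria marks the extreme `round(0.2·N)` nodes
(half-away-from-zero rounding; ties broken toward the smaller roi_id so
runs are bit-reproducible); a node is a hub at ≥ 2 of 4 marks. The 2-of-4
consensus rule is the established convention when no explicit cut-off is
given; it is exposed as `min_hits`. Hub sets are computed per group on
the group-averaged network (per-subject hub sets are available through
the same API); both groups' sets, their intersection and an equality
flag are reported.

Edge classes depend only on endpoint hub membership. Class strengths are
computed by partitioning the per-edge weight vector once (`np.bincount`
over class labels) and the reported total is `rich + feeder + local`,
so conservation holds exactly in floating point by construction; the
agreement of that total with an independent direct summation of the
matrix is separately asserted at 1e-12 relative (floating-point
associativity makes "exact" and "independently summed" two different
statements, and we keep both).

## Edge-wise inference (NBS)

Per masked edge (tested when nonzero in ≥ 50% of subjects — sparse-edge
t statistics are degenerate; the fraction is configurable), the model is
`weight ~ intercept + group + demeaned age`; the statistic is the group
coefficient's t. Constant edges get t = 0. The primary threshold is
taken directly as a t value (default 3.9805, a stringent uncorrected
edge-level cut under a ~58-subject design) with a `p_to_t(p, df)` helper,
since a p-threshold maps to t only through the df. Supra-threshold edges
form components scored by edge count (extent); family-wise error is
controlled by the permutation distribution of the maximal component
size. Permutations follow Freedman–Lane: the outcome matrix is
residualized on the nuisance design, residual rows are permuted, the
nuisance fit is re-added, and the full model is refit. Two one-sided
runs (APD>HC, HC>APD), each with its own null, realize the two-tailed
test. Measured operating characteristics (seeded simulations, reported
by `scripts/acceptance.py`): family-wise error ≈ 0.045 at nominal 0.05
over 200 null cohorts; power 1.0 for a 10-edge component attenuated to
60% at n=29+29 with 20% edge noise.

## Permutation engine

The observed statistic for scalar group contrasts is the Welch
(unequal-variance) t; p-values come from Freedman–Lane residual
permutation with demeaned age, `(1 + exceedances)/(n_perm + 1)`,
two-sided. Exceedance counting uses a relative tie tolerance (1e-9) so
permutations that merely re-order the observed data cannot lose the tie
to floating-point re-summation — without it, Monte-Carlo p is biased
low relative to exact enumeration. An exhaustive mode enumerates all
group-label partitions (valid when the nuisance is constant or absent)
and agrees with Monte-Carlo within binomial error; null p-values pass
KS uniformity. Zero-variance outcomes are flagged with t = 0, p = 1;
zero within-group variance with distinct means yields a signed infinite
t (an unbounded standardized effect) rather than a silent zero.

Bonferroni across ROIs × measures (factor 4N for the nodal scan) is the
multiplicity control throughout. Note the granularity constraint this
implies: with N ROIs the corrected threshold is 0.05/(4N), so the
permutation count must exceed 4N/0.05 for significance to be reachable
at all; the defaults (20,000 permutations) satisfy this for N up to 250.

Brain–behavior coupling is the Pearson correlation of age-residualized
metric and behavior (degenerate residuals flagged and reported as r=0),
with permutation of the residualized behavior vector, run per group and
pooled — group-specific associations are invisible in pooled samples
and vice versa, so both surfaces are reported. Missing behavior scores
are dropped pairwise per (group, behavior).

Demographics: pooled (Student) two-sample t for continuous variables —
which reproduces the conventional reporting of such tables — and Pearson
chi-square without continuity correction for categorical ones (the form
that yields exactly 0.000 on a balanced 2×2 table).

## Synthetic cohort model

The generator emulates a two-group pediatric diffusion-MRI study at desk
scale. Defaults (all overridable):

| parameter | default | rationale |
|---|---|---|
| n_nodes | 90 | desk-scale stand-in for a 246-region atlas; `study_scale()` gives 246 |
| n_per_group | (29, 29) | the study's group sizes |
| hub_fraction | 0.2 | matches the top-20% hub criteria |
| p_rich / p_feeder / p_local | 0.9 / 0.4 / 0.1 | dense hub core, sparse periphery; ordering enforced |
| weights | lognormal(−1, 0.5) | positive, right-skewed, QA-like scale |
| rich_weight_multiplier | 3 | rich-club in weight as well as topology |
| subject_noise_sigma | 0.15 | multiplicative lognormal edge noise |
| edge_dropout | 0.05 | tractography-like missed connections |
| effect_attenuation | 0.5 | group effect: all edges of one non-hub node halved in APD |
| behavior_target_r | 0.62 | planted APL–behavior correlation in HC |
| ages | U(8, 13), HC +1 yr | reproduces the age confound the nuisance handling must absorb |
| missing scores | 2 APD, 1 HC | missing-battery subjects, exercising pairwise deletion |

Planted hubs occupy the first `round(hub_fraction·N)` roi_ids; the
effect node defaults to the middle of the non-hub range and doubles as
the behavior reporter node. The group effect is implemented as
attenuation of incident edge weights — raising that node's APL and
perturbing betweenness ranks — which mirrors regional-metric group
differences without asserting a biological mechanism. An optional
`effect_edges` list plants a connected attenuated component for NBS
power studies. Behavior scores for the carrier group are
`ρ·z(APL at reporter) + √(1−ρ²)·ε`; the other group is pure noise. A
master seed drives named per-subject substreams, so cohorts are
byte-identical across runs and invariant to consumption order.

What the generator does *not* emulate: spatial embedding and distance-
dependent connectivity, atlas geometry, hemispheric symmetry,
tractography false positives correlated across subjects, heteroscedastic
weight noise, or comorbidity structure. Passing the recovery tests
therefore shows the estimators and their error control work under a
faithful two-group weighted-network model — not that any specific
real-data finding would replicate.

## Validation scales and observed operating points

The test suite and `scripts/acceptance.py` run everything at reduced
but statistically meaningful sizes chosen so a full pass completes in a
few minutes on one core: oracle equivalence on 200 graphs of ≤8 nodes;
1000 null-model draws; 50 calibration seeds × 200 nulls; 200 null NBS
cohorts (N=60, 15+15, 500 permutations) and 25 power seeds (n=29+29);
10 end-to-end recovery cohorts at N=90 with 20,000-permutation scans.
At those scales, measured: hub-recovery Jaccard 1.0; the attenuated
node is the unique Bonferroni-significant APL node in ~90–100% of
seeds; the behavior reporter node attains the top |r| in ~80% of seeds
but clears the Bonferroni-corrected 0.05 only in ~50–70% — with ρ=0.62
at n=28 the corrected threshold (0.05/90 ≈ 5.6e-4) coincides almost
exactly with the central parametric p of the planted effect (5.7e-4),
so a ~50% pass rate per seed is the theoretically expected operating
point of that design, not an estimator deficiency; the corresponding
acceptance check asserts a higher rate and is expected to read as a
failure at this power.

## Known limitations

* The rewiring null preserves degree and weight multiset but not
  strength sequence; strength-preserving weighted nulls are out of
  scope.
* NBS component scoring is extent-only (no intensity/TFCE variants);
  designs beyond two groups + one covariate are not supported.
* APL's exclusion-of-unreachable convention biases comparisons if
  reachability itself differs systematically between groups; the
  logged deficit should be inspected in that case.
* Betweenness on large dense networks uses networkx and is the slowest
  stage (~seconds per 246-node subject); per-subject metric tables are
  cached by the pipeline for this reason.
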