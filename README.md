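# connectomestats

Group analysis of structural brain connectomes, built for two-group
case–control studies of weighted (anisotropy-derived) connectivity
matrices — the setting of diffusion-MRI studies that ask whether a
clinical group (here: children with auditory processing disorder, APD,
versus healthy controls, HC) differs in whole-brain network organization,
in specific connections, or in regional network roles.

The package implements the full analysis chain on subject-level N×N
weighted adjacency matrices:

* **Nodal hub measures** — nodal strength (NS), weighted betweenness
  centrality (BC), nodal average path length (APL, with edge length
  `1/w`), and the Onnela weighted clustering coefficient (CC).
* **Weighted rich-club organization** — φ<sup>W</sup>(k) = W<sub>&gt;k</sub> / Σ of the
  |E<sub>&gt;k</sub>| largest weights, normalized as
  φ<sup>W</sup><sub>norm</sub>(k) = φ<sup>W</sup>(k) / ⟨φ<sup>W</sup><sub>rand</sub>(k)⟩ against an
  ensemble of degree-preserving Maslov–Sneppen rewirings in which each
  edge carries its weight through the swap. φ<sup>W</sup><sub>norm</sub>(k) &gt; 1 over a
  contiguous range of k indicates a rich club.
* **Consensus hubs and connection classes** — a node is a hub when it is
  extreme on ≥ 2 of the four criteria (top 20% NS, top 20% BC, bottom 20%
  APL, bottom 20% CC); edges are then *rich* (hub–hub), *feeder*
  (hub–non-hub) or *local*, and their summed strengths partition total
  network strength exactly.
* **Network-based statistic (NBS)** — edge-wise GLM t-tests
  (`weight ~ intercept + group + age`), supra-threshold component
  extraction, and family-wise error control by permuting the maximal
  component size under a Freedman–Lane scheme; both directional
  contrasts are tested, each against its own null.
* **Permutation inference** — Welch two-sample t with Freedman–Lane
  residual permutation (demeaned age as nuisance), Bonferroni correction
  across ROIs × measures, exact exhaustive enumeration for tiny samples,
  and age-controlled partial correlations between nodal metrics and
  behavioral (listening-task) z-scores.
* **Synthetic cohort generator** — two groups of subject matrices with a
  planted rich club, planted hubs, a localized group effect (attenuation
  of one node's edges), an optional planted edge component, and a
  one-group metric–behavior correlation, so every analysis can be
  validated against known ground truth.

## Worked example

```python
import numpy as np
from connectomestats import (SimulationConfig, generate_cohort, group_average,
                             normalized_curve, hubs_per_group, NBS,
                             cohort_nodal_metrics, NodalGroupTest)

cfg = SimulationConfig(n_nodes=60, n_per_group=(15, 15), seed=11)
cohort, truth = generate_cohort(cfg)

curve = normalized_curve(group_average(cohort, "HC"), n_null=200,
                         rng=np.random.default_rng(0))
print("HC rich-club regime:", curve.regime)

hubs = hubs_per_group(cohort)
res = NBS(cohort, t_threshold=3.0).fit(n_perm=500, rng=np.random.default_rng(1))
print(res["HC>APD"].summary())

metrics = cohort_nodal_metrics(cohort)
scan = NodalGroupTest(cohort, metrics).fit(n_perm=20000, rng=np.random.default_rng(2))
print(scan.summary())
```

prints

```
HC rich-club regime: (3, 34)
NBS HC>APD: t threshold 3.0000, 500 permutations, 2 component(s)
  size 8 edges, p_fwe = 0.0020
  size 1 edges, p_fwe = 0.3992
Nodal group differences (Welch t, Freedman-Lane permutation, 20000 permutations, Bonferroni x240)
 roi_id metric          t  p_perm   p_bonf direction
     36     ns -12.533671 0.00005 0.011999    HC>APD
     36     bc  -3.971916 0.00005 0.011999    HC>APD
     36    apl   4.537751 0.00005 0.011999    APD>HC
     36     cc  -5.842695 0.00005 0.011999    HC>APD
```

Reading the output: the normalized rich-club coefficient exceeds 1 for
degree levels 3–34, i.e. the planted hub block is more strongly
interconnected than degree-matched chance. The NBS finds one significant
8-edge component weaker in the APD group (p_fwe = 0.002) — the planted
attenuation around the effect node — and the nodal scan flags exactly
that node (roi 36) on all four hub measures after Bonferroni correction
across 60 ROIs × 4 measures. Hub detection recovers the 12 planted hub
regions exactly (`hubs["HC"].hub_ids`).

The same stages are available from the shell:

```bash
connectome-richclub simulate --seed 1 --out cohort/
connectome-richclub metrics --cohort cohort/ --out metrics.tsv
connectome-richclub richclub --cohort cohort/ --n-null 1000 --out richclub.tsv
connectome-richclub hubs --cohort cohort/ --out hubs.tsv strengths.tsv
connectome-richclub nbs --cohort cohort/ --t-thresh 3.9805 --n-perm 10000 --out nbs.json
connectome-richclub infer --cohort cohort/ --metrics metrics.tsv --out stats/
connectome-richclub run --ci-profile --seed 1 --out run/
```

Real cohorts are read from a manifest (`subject_id`, `group ∈ {APD, HC}`,
`age`, optional behavioral z-scores) plus one matrix file per subject
(headered TSV or bare CSV) and a parcellation lookup table; see
`connectomestats.io`.

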