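# l1mosaic

Downstream analysis of LINE-1 retrotransposition mosaicism in a mouse
TDP-43 proteinopathy model: temporal categorization of
retrotransposable-element (RTE) expression, spatial cluster calling of
L1-EGFP reporter-positive cells across serial brain sections, and
distance-binned quantification of programmed cell death around those
clusters.

## The problem

Transgenic mice carrying human TDP-43 (wild-type or the ALS-linked
Q331K variant) alongside an intron-interrupted antisense L1-EGFP
reporter develop focal groups of GFP-positive cells — cells in which a
LINE-1 retrotransposition event has completed — in motor cortex, and
show broad changes in RTE/ERV transcript levels with age and genotype.
Three quantitative questions follow, each served by one analysis stage
of this package:

1. **Which RTEs change with age, and how does that relate to
   neurodegeneration?** (`l1mosaic.rte_aging`) Each RTE's
   differential-expression results for the four aging comparisons
   (15 months vs 1.5, 3, 6, 10 months in non-transgenic animals;
   "UP" = higher at 15 months, called at adjusted p < α with the
   sign of log₂FC) form a 4-call significance pattern that maps onto
   five mutually exclusive temporal categories — strongly
   age-dependent, mildly age-dependent, 1.5-month peak, early
   expressors, strongly anti-age-dependent — evaluated
   most-specific-first. The "RTEs associated with neurodegeneration"
   set (significantly up-regulated RTEs in 15-month hTDP-43-WT vs
   non-transgenic) is tested for overlap with each category by
   Fisher's exact test, reporting the sample odds ratio
   *ad/bc* (+∞ when *bc* = 0 and *ad* > 0) with
   Benjamini–Hochberg adjustment across the batch.

2. **Are reporter-positive cells spatially clustered, and on which
   hemisphere?** (`l1mosaic.cluster_spatial`) GFP-positive cells are
   counted per animal over 14 sections at fixed bregma coordinates
   (50 µm sections, 150 µm apart) and per pseudo-hemisphere. An animal
   carries a cluster when its total count strictly exceeds the
   reporter-only control mean + 3 SD; sections are called
   LEFT/RIGHT/BILATERAL against per-bregma control thresholds, giving
   a lateralization map whose run-length statistics separate a single
   large unilateral cluster from scattered small bilateral foci.
   Group count comparisons use a Box-Cox transform (λ = 0.041,
   offset 1) followed by one-way ANOVA and post-hoc t-tests.

3. **Does cell death decay with distance from a cluster?**
   (`l1mosaic.imagequant`) From multi-channel confocal stacks
   (nuclei / GFP / empty red background / far-red / TUNEL), the
   pipeline max-projects, subtracts the background red channel from
   green (clamped at 0), segments cells by threshold + connected
   components, counts TUNEL puncta per nucleus (≥ 3 puncta ⇒
   TUNEL-positive), and bins the positive fraction in 100-µm bins
   over a 900 × 300 µm field from the cluster edge. The profile is
   summarized by a bounded fit of
   `p(d) = p_far + (p_near − p_far)·exp(−d/ℓ)`.

`l1mosaic.stats` holds the shared kernels (Box-Cox, ANOVA, t, exact
hypergeometric Fisher test, BH step-up), and `l1mosaic.synthetic`
generates every input with planted ground truth — planted temporal
categories and set overlaps with a target odds ratio, planted cluster
spans and hemispheres over Poisson baselines, and rendered tissue
stacks whose per-nucleus death probability follows a known distance
decay — so the whole pipeline is testable end to end without the
original data.

## Worked example

```python
import numpy as np
from l1mosaic import synthetic as syn, rte_aging as ra, cluster_spatial as cs, imagequant as iq

# 1. RTE categories and neurodegeneration-set enrichment
sim = syn.simulate_de_tables(syn.DeSimConfig(seed=42))
cats = ra.classify_features(sim.aging_tables())
table = sim.tables[sim.neuro_label]
neuro = ra.neurodegeneration_set(table[table["feature_class"] == "RTE"])
enr = ra.enrich_categories(neuro, cats)

# 2. cluster thresholds and the lateralization map
sp = syn.simulate_section_counts(syn.SpatialSimConfig(seed=42))
controls = sp.counts[sp.counts["genotype"] == "L1-EGFP"]
thr = cs.compute_thresholds(controls)
m = cs.build_map(sp.counts[sp.counts["genotype"] != "L1-EGFP"], thr)

# 3. TUNEL death-probability profile and decay fit
cfg = syn.StackSimConfig(seed=42)
prof = iq.distance_profile(syn.simulate_nuclei(cfg), cfg.gfp_cluster_edge_x_um)
fit = iq.fit_decay(prof)
```

Output (abridged):

```
neurodegeneration set: 304 RTEs
                   category  a  odds_ratio  padj
     strongly_age_dependent 69      10.232 0.000
       mildly_age_dependent 23       1.183 0.599
             peak_1p5_month 12       0.896 0.884
           early_expressors 11       1.268 0.599
strongly_anti_age_dependent  6       0.680 0.599

global cluster threshold: 44.0 (control mean 28.1 + 3 x SD 5.30)
animal_id  n_runs  max_run_length  unilateral_fraction  total_size
   aff_00       3               5             0.750000         102
   aff_01       2               5             0.833333         112

TUNEL fraction near cluster 0.55 -> far 0.05
fitted decay: p_near=0.62, p_far=0.05, length=200 um
```

The enrichment table recovers the planted overlap: the
neurodegeneration set is enriched only in the strongly-age-dependent
category (sample odds ratio ≈ 10, the generator's target), while the
other categories sit at odds ≈ 1. The cluster stage recovers the
planted 5-section unilateral spans (max run length 5), and the decay
fit recovers the planted 200-µm decay length.

The same stages run from the command line:

```bash
l1mosaic all --out run/ --seed 42          # simulate + analyze everything
l1mosaic clusters --counts counts.csv --control-genotype L1-EGFP --k-sd 3 --out out/
```

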