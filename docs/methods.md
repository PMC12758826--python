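# Methods

This note documents the models and conventions implemented in
`l1mosaic`, the parameters that matter, what the synthetic-data
generators emulate, and the design decisions taken where the
procedure was genuinely open.

## 1. Temporal categorization of RTE expression

### Inputs and direction convention

The classifier consumes per-comparison differential-expression tables
(`feature_id`, `feature_class` ∈ {gene, RTE}, `log2fc`, `pvalue`,
`padj`) for the four aging comparisons in non-transgenic animals.
Published descriptions of such rules often mix reference frames
("increase vs 15 months" in one rule, "decrease in 15-month vs
1.5-month" in another). We fix one convention throughout: **every
comparison is expressed as 15 months relative to the earlier age**, so
UP means higher expression in old animals. Under this convention the
"strongly age-dependent" rule indeed describes age-increasing
elements, which reconciles the rules with their names. A feature's
call for one comparison is UP if `padj < α` and `log2fc > 0`, DOWN if
`padj < α` and `log2fc < 0`, else NS (α = 0.05 by default).

### The five rules and their precedence

With the pattern indexed (t1.5, t3, t6, t10):

| category | rule |
|---|---|
| strongly age-dependent (i) | ≥ 3 of 4 UP, and t1.5 not DOWN |
| strongly anti-age-dependent (v) | DOWN at t1.5, t3 and t6 |
| early expressors (iv) | DOWN at t1.5 and t3; not DOWN at t6 and t10 |
| 1.5-month peak (iii) | DOWN at t1.5; not DOWN at t3 |
| mildly age-dependent (ii) | ≥ 1 UP and no DOWN anywhere |

As written the rules overlap (every pattern matching (i) with no DOWN
also matches (ii); (v) ⊂ "DOWN at t1.5"), so they are evaluated
most-specific-first — (i), (v), (iv), (iii), (ii), else NONE — which
makes the categories a partition: every feature receives exactly one
label. The scalar rule evaluator and the vectorized table classifier
are both tested against an independently written transcription of the
rules over all 3⁴ = 81 patterns.

### Neurodegeneration set and enrichment

The "RTEs associated with neurodegeneration" set is the set of RTEs
with `padj < α` and `log2fc > 0` in the 15-month hTDP-43-WT vs
non-transgenic comparison (a switch allows nominal-p selection
instead). Overlap between this set and each temporal category is
scored with Fisher's exact test on the 2×2 table (a, b, c, d) within a
universe that defaults to the RTEs classified (i.e. present in all
four aging tables). Conventions:

* the odds ratio is the **unconditioned sample odds ratio**
  (a·d)/(b·c), reported as +∞ when b·c = 0 with a·d > 0 and NaN when
  both products vanish — no Haldane correction, so nested sets report
  infinity rather than a finite smoothed value;
* the p-value is two-sided by default (one-sided tails are exposed),
  computed by summing hypergeometric point masses ≤ the observed mass
  (relative tolerance 1e−7 for float ties);
* one BH family per enrichment batch (the five category tests run in
  one call).

## 2. Spatial cluster calling

Counts of GFP-positive cells arrive per animal, per section (14
sections ordered anterior→posterior by descending bregma; 50-µm
sections at 150-µm intervals, so bregma labels step by 0.2 mm) and
per pseudo-hemisphere (hemisphere identity assigned from cryosection
asymmetry).

Thresholds come from reporter-only control littermates, with the
sample (n−1) SD since control cohorts are small, and k = 3 SD by
default:

* **global threshold** = mean + k·SD of control per-animal totals
  (all sections, both hemispheres); an animal carries a cluster iff
  its total **strictly exceeds** this (ties are non-clusters);
* **per-section thresholds** = mean + k·SD of control per-animal
  hemisphere-summed counts at that bregma.

Whether the published per-section calls compared hemispheres against
a full or a halved section threshold is not stated; we compare each
hemisphere against the section threshold scaled by the control
hemisphere share (default 0.5, configurable; `hemisphere_rule="full"`
uses the unscaled threshold). Exactly one qualifying hemisphere gives
a LEFT/RIGHT call, both give BILATERAL, neither NONE; the call's size
is the summed count of qualifying hemispheres.

The lateralization map assembles per-section calls for animals that
pass the animal-level call. Contiguity statistics (number of maximal
non-NONE runs, longest run, fraction of positive sections matching
the modal unilateral hemisphere, total size) operationalize the
qualitative contrast between one large unilateral cluster spanning
multiple sections and several small bilateral foci. When an animal
has only BILATERAL calls the modal hemisphere is undefined and the
unilateral fraction is reported as 0.

Incomplete section series are excluded from threshold estimation;
calling runs on whatever sections are present.

Group comparisons of per-animal counts Box-Cox-transform the counts
(λ = 0.041 — the value used for these reporter-count data — with
offset 1 because counts contain zeros), then run one-way ANOVA and
pairwise two-sample t-tests (pooled variance by default; Welch via a
flag, since the published post-hoc tests do not state the variance
treatment).

## 3. Image quantification and the death profile

Stacks are channels × z × y × x with declared roles (nuclei, GFP,
empty background-red, far-red, TUNEL). The reporter-cell count path
is: max-project green and red over z; subtract red from green
**clamped at zero** (intensities are nonnegative by convention);
threshold (Otsu by default — the published counting was manual, so a
reproducible automatic rule is required; fixed and percentile rules
are available); 8-connected components; area filter; one detection
per component.

TUNEL puncta are strict local maxima of the TUNEL image above an
intensity threshold (Otsu by default) **within each nucleus mask**,
merged within a 3-pixel radius (plateaus of equal maxima count once);
2-D projections and raw 3-D stacks are both supported since the
published counting could be read either way. A nucleus is
TUNEL-positive iff its puncta count ≥ 3.

The death profile bins nuclei by distance from the GFP-cluster edge
in half-open 100-µm bins over a 900-µm extent (the 9 × 3 tile field).
Distance is 1-D along the field's long axis from a supplied edge
coordinate (a Euclidean mode is offered); nuclei at negative distance
(inside the cluster) are assigned to bin 0 and flagged. Per bin the
profile reports n_nuclei, n_positive and the fraction; empty bins are
flagged and excluded from fitting.

### Decay fit

The profile is summarized by
`p(d) = p_far + (p_near − p_far)·exp(−d/ℓ)` with probabilities
bounded to [0, 1] and ℓ > 0. Numerical choices:

* the model is evaluated at each bin's **mean clamped distance**
  rather than the bin center; bin 0 typically mixes inside-cluster
  nuclei (d = 0) with nuclei up to 100 µm out, and using the center
  biases ℓ low by ~20%;
* the default estimator maximizes the **binomial likelihood** of the
  per-bin positive counts (L-BFGS-B, three ℓ starts, tight
  tolerances). A least-squares fit of the bin fractions weighted by
  n_nuclei is available (`method="wls"`); the ML fit is kept as the
  default because it is the efficient estimator for binned Bernoulli
  outcomes — in the recovery simulations below it attains ~95% versus
  ~88% coverage of the ±20% decay-length band;
* when the data carry no real distance dependence, ℓ is
  unidentifiable and the parameter difference p_near − p_far can
  drift along a likelihood ridge; the identifiable amplitude measure
  is `fitted_drop`, the drop of the fitted curve across the observed
  distance range, and that is what should be compared to zero for
  flat profiles;
* fitting requires ≥ 4 nonempty bins.

## 4. Synthetic data: what it emulates, and what it does not

All generators are bit-reproducible from (config, seed) and return
planted truth alongside the data.

**DE tables.** Summary statistics are simulated directly rather than
via counts and a negative-binomial fit: the classifier consumes only
(log2fc, padj), and upstream differential expression is out of scope.
An observed log2FC is the planted effect plus N(0, σ) noise with
σ = `null_sd` (default 0.4) treated as the known standard error; the
p-value is the two-sided normal tail of z = log2fc/σ, and padj is BH
within each table. The default planted effect (2.0, i.e. 5σ) makes
planted calls clearly detectable, which is the regime the recovery
criteria describe. Category patterns are planted as the canonical
sign vectors of the five rules (e.g. strongly-age-dependent = UP at
all four ages; mildly = UP at t6 only). The neurodegeneration set is
planted with **deterministic member counts** inside and outside the
designated category (default: strongly-age-dependent) at the rates
implied by the target odds ratio (default 10) over a 5% baseline —
this removes pure Bernoulli sampling noise from the planted odds so
that the measured estimate reflects classifier and set-recovery
error, not generator noise. Fractions default to 20% of RTEs spread
over the five categories; genes are simulated as nulls.

**Section counts.** Controls draw i.i.d. Poisson(`control_rate`,
default 1) per hemisphere per section; affected animals additionally
draw Poisson(`cluster_amplitude`, default 20) in the planted cluster
sections. The unilateral-contiguous layout plants one span of 5
consecutive sections on one random hemisphere; the bilateral-small
layout plants the same number of single-section foci at random
sections with independently random hemispheres. Cohort sizes default
to 10 controls + 10 affected.

**Tissue stacks.** Nuclei are placed by random sequential adsorption
on the pixel grid with a minimum center distance (defaults: 3000
nuclei of radius 3.5 µm at ≥ 7.5 µm separation in a 1000 × 300 µm
field with 5 optical planes; placement fails loudly if the requested
density is unreachable). The GFP cluster is the band x < 100 µm;
nuclei inside it are GFP-positive and sit at distance 0. Each nucleus
dies with probability p(d) (defaults p_near = 0.6, p_far = 0.05,
ℓ = 200 µm — an exponential is a generator convention; the profile
estimator itself is model-free). TUNEL-positive nuclei receive
3 + min(Poisson(1), 2) puncta and negative nuclei min(Poisson(0.5), 2),
so the ≥ 3-puncta rule holds exactly by construction. Puncta are
placed on integer-pixel ring templates (radius ≤ √10 px) whose
pairwise separations exceed the detector's 3-px merge radius, and
channels are rendered as additive Gaussian blobs plus background and
Gaussian noise — hence a noise-free, background-free stack is exactly
recoverable by the detectors, which is what the exactness checks use.

The field density (3000 nuclei) was set by a design power analysis:
the Fisher information of the binned design gives sd(ℓ̂) ≈ 25 µm at
2000 nuclei — too wide for a ±20% recovery band at 90% coverage even
for an ideal estimator — and ≈ 20 µm at 3000, where the ML fit
reaches ~95% coverage.

**What the generators do not emulate:** optics (no PSF, no
depth-dependent attenuation), segmentation-hostile histology (no
touching nuclei, debris or intensity gradients), read-level RNA-seq
(no count overdispersion, library-size or batch structure),
inter-animal variance components beyond Poisson counting noise, and
behavioral data. Passing recovery tests therefore demonstrates that
the pipeline's logic and estimators are correct under the stated
noise models, not that they are robust to every artifact of real
tissue and sequencing data.

## 5. Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the recovery studies
at: 100 (tests) / 20 (script) seeds for planted-enrichment and
cluster-caller recovery; 50 / 15 seeds for decay recovery; 50
animals per layout for the contiguity contrast; exhaustive
enumeration of 2×2 tables with margins ≤ 30 (tests) / ≤ 20 (script)
for the exact-test oracle; and a 400 × 200 µm, 150-nucleus noise-free
stack for the image-exactness checks. These sizes give stable rates
while keeping a full run inexpensive.

## 6. Known limitations

* The aging-category rules are evaluated on exactly four comparisons;
  other designs require re-deriving the rule set.
* The enrichment universe must be chosen explicitly when tables do
  not share a feature set; the default (intersection of classified
  features) is one reasonable choice, not the only one.
* The per-section hemisphere rule (share vs full threshold) changes
  bilateral-call rates; both are exposed because the published
  procedure does not determine it.
* The decay fit assumes a monotone exponential-plus-floor form;
  non-monotone death profiles will fit poorly (inspect `rss` and the
  per-bin fractions).
* The puncta counter's exactness guarantee applies to the generator's
  rendering conventions; on real images the intensity threshold and
  merge radius need tuning.
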