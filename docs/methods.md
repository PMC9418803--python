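# Methods

`fmtstrains` reimplements a strain-level analysis of fecal microbiota
transplantation (FMT): who contributes the strains that make up a
patient's gut community after FMT — the donor, the patient themselves, or
neither — and which ecological and clinical factors determine whether a
donor strain engrafts.  Because the real clinical metagenomes behind such
analyses live in controlled-access archives, every operation here is
exercised on a synthetic cohort generator with complete ground truth; this
note describes the models, the generator, and the design decisions, and
states what the passing tests do and do not show about real data.

## SNV profiles and shared-strain calling

A sample's strain content for one species is represented as a nucleotide
variant profile: a 4 x L matrix of allele counts (A, C, G, T) over the L
columns of the species' concatenated marker-gene alignment, with a boolean
usability mask.  Profiles are denoised before comparison
(`profiles.filter_profile`):

1. `end_trim` (default 20) columns at each end of every marker are masked;
2. alleles with fewer than `min_allele_count` (2) reads or below
   `min_allele_frequency` (10%) within-column frequency are zeroed;
3. columns whose remaining depth is below `min_position_coverage` (5) are
   masked.

Step 3 runs after step 2 so the filter is exactly idempotent: any allele
surviving one pass has at least the threshold frequency of a column total
that can only shrink, so later passes change nothing.  The 10% polymorphic
threshold is the substantive parameter — it defines which alleles "exist"
at a position; the other thresholds are conservative denoising defaults
for marker-based strain callers and are configurable.

Two same-species profiles are compared over their jointly usable columns
(`comparison.compare`).  The **maximum variant profile similarity (MVS)**
is the fraction of those columns at which the two samples' allele sets
(post-filter) intersect; the **consensus similarity** is the fraction with
identical major alleles (ties broken A < C < G < T).  MVS dominates
consensus similarity by construction, and — the property the attribution
relies on — a sample carrying a 30/70 mixture of two strains reaches MVS
1.0 against a sample carrying either strain alone, because polymorphic
columns contribute both alleles.  A shared strain is called when the
overlap spans at least 5,000 columns and MVS is at least 0.999; both
bounds are inclusive and the MVS cutoff is applied by integer
cross-multiplication (counts are integers), so an MVS of exactly 0.999
passes without floating-point edge effects.  The per-column score is
binary (intersect or not); no partial credit is given for multi-allele
overlaps.  "5 kb" is measured in post-filter alignment columns.

## Origin attribution

For each species in a post-FMT sample, shared-strain calls against the
pre-FMT recipient sample and the (pooled) donor determine the origin
label:

| shared with pre | shared with donor | pre/donor shared | label |
|---|---|---|---|
| yes | no  | —   | recipient |
| no  | yes | —   | donor |
| yes | yes | no  | coexist |
| yes | yes | yes | ambiguous |
| no  | no  | —   | new |

Species present post-FMT whose required comparison lacks the 5 kb overlap
are `unresolved` (with a species-level presence fallback recorded);
species present pre-FMT or in the donor but absent post-FMT are `lost`.
The labels partition the post-FMT species set.  The `ambiguous` class
(recipient and donor already shared the lineage before FMT, so the
post-FMT strain's source is unidentifiable) is reported separately and
excluded from donor/recipient fraction denominators.  Multiple donor
samples are pooled by summing allele counts column-wise and averaging
scalar community metrics.

Case-level summaries use a fraction convention that is robust to
variable sequencing depth: the donor fraction is n_donor / (n_donor + n_recipient), with
the coexist fraction reported against the same denominator;
abundance-weighted analogs sum relative abundances.  Latest-sample
selection takes the maximum day offset, response-window summaries
restrict to ≤ 120 days, and samples flagged for post-FMT antibiotic
exposure can be excluded.  The six-way competition table (over species
present in both pre-FMT recipient and donor) maps `ambiguous` into
`unresolved` so it remains an exact partition.  In the donor-species fate
summary, the remainder bucket (1 minus the not-engrafted /
new-species / replacement fractions) holds coexisting, ambiguous, and
unresolved donor species.

## Community metrics

All logarithms are natural.  Shannon diversity is −Σ p ln p; the clr
transform subtracts the mean log abundance after closure; the Aitchison
distance is the Euclidean distance between clr vectors; PCA operates on
clr-transformed matrices (scores reproduce Aitchison distances when all
components are kept).  Zeros are replaced by an additive pseudocount of
half the smallest nonzero abundance in the matrix (configurable); when a
composition has no zeros, no pseudocount is applied.  The dysbiosis score
is log((Σ up-taxa + ε)/(Σ down-taxa + ε)) with ε = 1e-6; the up/down taxa
lists ship as replaceable configuration, to be filled with whichever
disease-association list fits the application.  Lifestyle
burdens (oral, oxygen-tolerant, spore-forming) are cumulative relative
abundances over species annotated +1 for the trait; species with missing
annotations are excluded from numerators.  Bray-Curtis and UniFrac are
deliberately out of scope — they do not enter the headline analyses.

`compare_to_controls` fits, per metric, sample type as a fixed effect
(healthy controls as the reference) with random intercepts for study and
case — Gaussian identity for continuous metrics, binomial logit for
proportion metrics, where proportions are given a configurable effective trial count
(default 100).
Post-FMT samples collected fewer than 5 days after treatment are
excluded.  Variance inflation factors are computed for model covariates
and flagged above 5.

## The mixed-model engine

Both engraftment models are binomial-logit GLMMs with crossed Gaussian
random intercepts, estimated by Laplace-approximated maximum marginal
likelihood (`glmm.MixedGLM`): for candidate variance parameters, fixed
effects and random-effect modes are found jointly by penalized IRLS with
step-halving; the profiled Laplace objective
(penalized log-likelihood − ½ log|D| − ½ log|H_uu|) is maximized over the
log random-effect SDs with L-BFGS-B.  The Gaussian family uses the same
machinery (for which Laplace is exact) with the residual SD as an extra
outer parameter.  Fixed-effect SEs are conditional Wald SEs from the
fixed-effect block of the inverse joint Hessian — the convention of
standard mixed-model software, and the tests verify agreement of
estimates and SEs with lme4's `glmer` on the same data.  Pinning all
random-effect SDs at zero (a 1e12 ridge on the intercepts) reproduces
plain logistic regression to well below 1e-4 on the linear predictor.
Non-convergence is reported via a flag and warning, never silently.
Crossed factors (donor crossing case and study in the strain model) are
handled as independent Gaussian intercept blocks under the joint Laplace
mode — a known approximation, adequate at the cohort sizes used here.

**Case-level model.**  Response: donor-derived strains (successes) vs
recipient-derived strains (failures) per post-FMT sample; random
intercepts for case and study (the study intercept is dropped, with a
warning, below two studies).  Covariates — antibiotic pretreatment, bowel
lavage, number of FMTs (ordinal 0/1/2), donor pooling, recipient and
donor Shannon diversity, recipient distance-to-controls, recipient-donor
Aitchison distance, days since FMT — are centered and scaled by
`build_case_table`, which stores the scaling constants for
back-transformation and drops zero-variance covariates with a warning.
Cases flagged as missing their pre-treatment baseline get pre-FMT metrics
imputed with the mean over observed antibiotically pretreated cases.

**Strain-level model.**  Response: the engraftment indicator of each
species detected in a case's donor; random intercepts for case, study,
and donor.  Donor and recipient relative abundances enter as z-scored
log10(a + 1e-5) (abundances are centered and scaled; taking the log first is this
package's choice, configurable in the simulator's scaling constants), their product forms the interaction term,
and the four lifestyle features (oral habitat, spore formation, oxygen
tolerance, Gram stain) are coded +1/−1 with missing values replaced by
the feature mean so imputation carries no signal.  Genus enters only
through feature aggregation, not as a random effect (a genus variance component is deliberately not fitted).

On top of the fits: `marginal_effect` averages population-level
predictions (random effects at zero) over the observed covariate rows
with one covariate substituted, with delta-method Wald CIs;
`genus_probability` reports the median predicted probability over a
genus's rows, optionally substituting the cohort-wide min/max donor
abundance; `predict_pairing` sums per-species predicted probabilities for
a (possibly counterfactual) recipient/donor pair; `donor_swap_matrix`
evaluates every recipient x donor pairing, reports log2 fold-changes
against the actual pairing (exactly 0 on the diagonal; identical donors
give identical columns), best/worst donors per recipient, and a variance
decomposition between donors vs between pairs within donor.

## The synthetic cohort generator

The generator's defaults are the study conditions for all tests.
Species catalogs (default 100 species) draw genus sizes from a Zipf-like
distribution across four phyla; marker alignments are 6-20 kb for ~90% of
species and 2-5 kb for the rest (exercising the insufficient-overlap
path); lifestyle features are ±1 with 10% missingness.  Strain lineages
derive from a per-species root genotype by binomial substitution at
1-2% divergence, so conspecific lineages differ at ≥ ~1% of columns.
Communities are log-normal (σ = 1) over per-species prevalences and
closed.  Pileups are rendered with per-column coverage ~
Poisson(depth × abundance × n_present) — `depth` (default 30×) is the
mean per-species coverage of a uniform community — and multinomial base
counts over the strain mixture blended with a uniform 0.1% error
component; zero-coverage columns are masked.

Each FMT case draws clinical covariates (antibiotics and lavage Bernoulli
½, FMT count in {1, 2, many}, post-FMT sampling days uniform on 5-120)
and an assigned donor.  Per donor species, true engraftment is Bernoulli
with logit = β'x + case + study intercepts, where x holds the case's
clinical covariates and z-scored community metrics of the actually
generated communities, and β defaults to effect sizes of the scale
reported for clinical FMT cohorts (antibiotics +2.09, lavage +1.83,
repeated FMTs +0.71, donor Shannon +0.83, recipient Shannon −0.61,
dysbiosis distance +0.46, …).  The post-FMT community is assembled from engrafted donor
strains (filling empty niches or replacing recipient strains), persisting
recipient strains (base loss rate 15%, +25 points under antibiotics),
planted conspecific coexistence (25% of engraftments into occupied
niches, mixture fractions uniform on 0.3-0.7), newly injected strains
(10% of post-FMT species), and losses; everything is recorded in the
truth table.  A configurable 5% of species present in both recipient and
donor are seeded with the *same* lineage ("ambiguous"), exercising the
attribution tie-break.  Placebo (sham) cases with no transfer can be
planted to exercise sham exclusion.

Two deliberate detectability conditions:

- **Coexistence plantability.**  Mixtures are planted only in species
  whose abundance reaches the community mean in both pre-FMT recipient
  and donor (expected coverage ≥ nominal depth on both sides) and whose
  marker alignment is ≥ 6 kb.  A 30/70 minor strain in a trace-abundance
  species or a sub-5kb alignment is undetectable by construction — the
  labels should only assert coexistence the data could in principle show.
- **Unrelated pairs.**  `generate_unrelated_pairs` forces every
  conspecific genotype pair across a pair of samples to differ at an
  exact ≥ 1% of columns, so the true shared-strain count is zero by
  construction; a divergence floor at or below the MVS threshold's
  resolving power (0.2%) triggers a warning.

Table-level simulators (`simulate_case_table`,
`simulate_strain_cohort`, `simulate_metric_cohort`) draw model-ready
tables directly from the same generative processes with covariates
already on the model scale.  They exist because parameter-recovery and
calibration experiments need hundreds of cohorts, where rendering
pileups would add nothing: the estimators never see sequence data, only
tables.  The strain cohort keeps full donor/recipient abundance profiles
so counterfactual pairings can be rebuilt for the swap simulation, and
its engineered "super-donor" carries every donor-observed species at the
maximum abundance seen in any donor.

### What the generator does not emulate

Read-level artifacts (mapping bias, chimeras, host contamination),
within-species strain multiplicity beyond two lineages, horizontal gene
transfer between lineages, compositional correlations between species,
fungal/viral fractions, and longitudinal drift of post-FMT communities
(post-FMT samples re-render the same community).  Passing tests therefore
show that the pipeline's logic is correct under the stated statistical
model of marker pileups — not that the thresholds are optimal for any
particular real sequencing protocol.

## Numerical choices and degenerate inputs

- Consensus ties break by fixed allele order A < C < G < T.
- MVS and threshold comparisons use integer arithmetic end to end.
- Empty count tables build fully masked profiles; degenerate profiles
  pass through the filter fully masked rather than erroring.
- An empty donor-species set predicts an expected engrafted count of 0;
  a zero donor+recipient denominator reports a missing fraction.
- Random-effect SDs are optimized on the log scale with a floor of
  e^-8 ≈ 3e-4 (effectively zero) and estimates at the floor are valid
  boundary solutions.
- All randomness flows through `numpy.random.default_rng` seeds; every
  cohort, table, and pipeline run is bit-reproducible given its seed.

## Problem sizes

The shipped experiments use 50-case / 100-species rendered cohorts for
attribution, 200 unrelated pairs for specificity, 20 replicate 200-case
table cohorts for case-model recovery, a 60-case / 20-donor / 120-species
strain cohort for the swap simulation, and 500 replicate null cohorts for
calibration — sizes at which the Monte-Carlo error of each check is small
compared to its acceptance margin.

## Known limitations

- Wald z reference distributions are slightly anticonservative at the
  grouping-level counts used here (~20 studies): the realized type-I
  error of the group comparison sits at roughly 6-9% for a nominal 5%,
  depending on the Monte-Carlo seed window.
- The Laplace approximation mildly attenuates variance components (and,
  with them, CI coverage sits near 85-90% rather than 95% for
  strongly clustered binomial data) — the same behavior the reference
  implementation in lme4 shows on identical data.
- Crossed random effects are approximated jointly, not by blocking.
- The competition table's treatment of pre-shared ("ambiguous")
  lineages as unresolved is a convention of this package.
- The dysbiosis taxa lists shipped for the demo are derived from the
  synthetic catalog's lifestyle annotations, not from a clinical
  association study.
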