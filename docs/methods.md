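# Methods

This note describes the models and procedures `metaboga` implements, the
choices made where the design was open, and what the synthetic data do and
do not establish.

## Problem setting

The pipeline targets untargeted LC-MS lipidomics cohorts spanning the
progression Control → Prediabetes → T2DM (type 2 diabetes mellitus) → DN
(diabetic nephropathy), one intensity column per annotated metabolite and
one row per patient. The analysis treats the progression as five pairwise
binary classification problems (Control-Prediabetes, Control-T2DM,
Prediabetes-T2DM, Control-DN, T2DM-DN) and asks which small sets of
metabolites discriminate each pair, and which metabolites recur across
pairs — the progression biomarker candidates.

## Inclusion filtering

Samples are kept when their stage label is one of the four recognized
stages and their feature vector is complete; feature columns still missing
values afterwards are dropped. Every exclusion is logged with the rule that
fired and a human-readable detail. No imputation is performed: a missing
intensity is grounds for exclusion, not interpolation.

## Probabilistic quotient normalization (PQN)

PQN corrects per-sample dilution under the assumption that most signals
vary with dilution only. For sample *i* with intensities `x_if`:

1. build a reference spectrum `r_f` over samples (median by default; mean
   selectable);
2. form the per-feature quotients `x_if / r_f` over the usable features
   (configurable index regions; features with non-positive reference or
   sample values are excluded);
3. aggregate them into one quotient `q_i` (median by default, mean
   selectable; an optional power `n` is applied to the quotients and
   inverted after aggregation);
4. divide the sample by `q_i`.

Where the aggregation or reference statistic is ambiguous in common usage,
the median is the default on robustness grounds, with the mean exposed for
comparison. Normalization runs once on the full filtered table before the
pairwise datasets are split off.

Two properties worth keeping apart:

* **idempotency against a fixed reference is exact**: after dividing by
  `q_i`, the quotients of the normalized data against the *same* reference
  are exactly 1 (up to float rounding). `PQNNormalizer` has these
  semantics: `fit` learns the reference, `transform` applies it.
* **self-referenced renormalization is only approximately idempotent**:
  recomputing the median reference from normalized data moves it slightly,
  so a second `pqn_normalize` yields quotients within a few percent of 1,
  not machine precision.

PQN identifies dilution only up to the overall scale of the reference
spectrum, so recovery of known dilution factors is assessed after fixing a
single global scale factor.

## The classifiers

Three distance-based classifiers act as fitness functions behind one
train/predict contract, all on Euclidean geometry:

* **KNN** — majority vote among the `k` nearest training samples
  (`k = 3` by default, odd so binary votes cannot tie). With even `k`,
  ties break toward the label whose voters are nearer in summed distance,
  then toward the lexicographically smaller label; equidistant neighbours
  resolve by training index. Predictions are therefore deterministic.
* **Nearest centroid** — per-class training means, assignment to the
  nearest centroid.
* **RBF SVM** — soft-margin SVM with kernel
  `K(x, x') = exp(−‖x − x'‖² / (2σ²))`, cost `C = 1` by default, and `σ`
  set by the median heuristic on the non-zero pairwise training distances
  unless given. The solver is libsvm (through scikit-learn); the package
  calls the low-level binding in the fitness loop because millions of tiny
  fits are made, with the standard `SVC` interface as fallback — tests
  assert prediction-level equality between the two routes.

Inside every cross-validation fold, features are z-scored using
training-fold statistics only (zero-variance features pass through
unscaled), so held-out samples never influence the scaling.

**Average accuracy** — the mean held-out accuracy over repeated stratified
k-fold cross-validation — is the single figure of merit, both as GA
fitness and for final models. The default scheme is stratified 5-fold × 4
repeats; leave-one-out is deliberately not the default because it overfits
small cohorts. Folds depend only on the labels and the scheme seed, never
on the feature subset, which makes fitness caching sound. The benchmark
experiments in the test-suite and acceptance script use 5-fold × 2 repeats
— the same estimator at desk scale.

## Genetic-algorithm wrapper selection

A **chromosome** is a set of exactly `chromosome_size` (default 5) distinct
feature indices; its fitness is the cross-validated average accuracy of the
chosen classifier restricted to those features. One **bigbang** is an
independent search:

1. initialize `population_size` (default 50) random chromosomes;
2. each generation, evaluate fitness, carry the `elite_count` (default 2)
   fittest unchanged, and fill the rest with offspring of
   fitness-proportionally (roulette) selected parents via uniform gene
   crossover, followed by per-gene mutation to a random unused index at
   rate 0.05 and repair of duplicate genes;
3. stop when the best fitness reaches `goal_fitness` (default 1.0) or at
   `max_generations` (default 200).

Chromosome validity (size, uniqueness, range) is asserted after every
operator. Elitism makes the per-bigbang max-fitness trace non-decreasing.

A **blast** runs `n_bigbangs` (default 2100) bigbangs and aggregates:

* **gene frequency** — how often each feature appears among the bigbang
  solutions (conserved: the frequencies sum to
  `chromosome_size × n_bigbangs`);
* **gene rank** — features by descending frequency, ties broken by feature
  index so reports are deterministic;
* **rank stability** — a snapshot of the rank after every bigbang; the
  per-feature standard deviation of its rank position over a trailing
  window measures how settled the ranking is;
* per-bigbang fitness traces for convergence plots.

Population size, mutation rate, elite count and roulette selection are this
engine's own conventions, exposed in `GAConfig`; the behaviour is verified
by property (operator validity, monotone traces, frequency conservation,
recovery of planted features, equality with exhaustive enumeration at small
scale), not by trace-matching any other implementation.

**Seeding.** A master seed spawns one child seed per bigbang through a
stateless rule (`SeedSequence(entropy=master, spawn_key=(i,))`), so a blast
with fewer bigbangs is an exact prefix of a longer one and reruns are
bit-identical. Fitness results are memoized per blast keyed by the sorted
gene set; since the folds are fixed per blast this cannot change results,
only runtime.

## Forward selection

Given a gene rank, nested models of sizes 1..`max_size` (default 30) are
evaluated by the same cross-validated average accuracy; the chosen model is
the *smallest* size whose accuracy is within `tolerance` (default 0.01
absolute) of the curve's maximum — accuracy first, compactness second, and
exact ties resolve to the smaller model. The full size curve is returned
for plotting and audit.

## Summary and intersection analysis

`best_models_table` lists average accuracy per comparison × method and
flags every method tied with the per-comparison maximum. Within each
comparison, the three methods' chosen metabolite lists are intersected into
four disjoint sets: all three, and each pair minus the triple. Across
comparisons, any metabolite whose reported sets recur in ≥ 2 comparisons is
a progression candidate, sorted by occurrence count then name.

Metabolite identity is exact string match after whitespace normalization
plus one mangling repair: a dot sandwiched between word characters becomes
a space (data-frame exports commonly convert spaces in compound names to
dots). Lipid shorthand such as `Cer(d18:1/24:1) i2` is untouched.

## Synthetic cohorts

Because cohorts of this kind are typically private, the package ships a
generator that emulates their statistical structure:

* intensities are log-normal — a per-feature baseline mean (drawn once,
  shared across stages), plus within-group Gaussian log-scale noise
  (`noise_sd`, default 0.3 ≈ 30% CV, typical of untargeted lipidomics);
* **planted features**: per stage-pair, selected features' mean
  log-intensity shifts by a stated effect (default 0.6, i.e. 2 within-group
  SD) in the later stage; a feature may be planted in several pairs, which
  is exactly the recurring-biomarker pattern the intersection analysis
  looks for. Overlapping plantings are reconciled by propagating shifts
  along the stage order;
* a per-sample dilution factor drawn uniformly from `dilution_range`
  (default [0.5, 2]) multiplies the whole row;
* default shape: 4 stages × 20 samples, 717 features; metabolite names are
  generated lipid-style, with five recurring biomarker names injected at
  the default planted indices so intersection reports read naturally.

Ground truth (planted features per comparison, drawn dilutions) is returned
separately and can be written to a JSON sidecar; it is never stored in the
data file.

The **dilution-recovery experiment** uses a deliberately different regime:
no planted effects and `noise_sd = 0.05`, i.e. a pooled-QC dilution series
where only dilution and ~5% technical scatter distinguish samples — the
standard design for validating a dilution correction. At cohort-level
biological noise the per-sample quotient has a sampling error of a few
percent over 717 features, so the 1%-recovery statement is a statement
about dilution series, not about patient cohorts.

What passing on synthetic data does **not** show: real lipidomics features
are correlated in blocks (co-regulated lipid classes), intensities are
heteroscedastic and occasionally missing not-at-random, and annotation
errors duplicate features. The generator models none of this, so planted
feature recovery here bounds the method's behaviour under ideal, not
clinical, conditions.

## Problem sizes in the shipped experiments

The test-suite and acceptance script run the same experiments at desk
scale, chosen as the package's own benchmark sizes: 50 bigbangs ×
≤ 100 generations for the 40 × 100 planted-recovery benchmark; 10 bigbangs
against exhaustive enumeration of all 220 subsets of a 12-feature problem;
and 3 bigbangs × 5 generations per comparison-method pair for the
reproducibility run of the full 80 × 717 pipeline. The full published-scale
configuration (2100 bigbangs × 200 generations) is the library default and
runs unchanged, just longer.

## Known limitations

* Binary comparisons only; no multi-class or ordinal modelling of the
  progression, no probability calibration, no AUC.
* The chosen model's cross-validated accuracy is reported as *the* model
  accuracy; features were selected on the same cross-validation estimator,
  so it is an optimistic estimate. An untouched hold-out set is outside
  this package's scope.
* Intersection analysis matches names as strings; it cannot merge distinct
  annotations of the same compound beyond the documented normalization.
* Fitness caching assumes the classifier is deterministic given the fold;
  all three shipped classifiers are.
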