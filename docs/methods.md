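# Methods

`transdx` benchmarks how well ICD-10 diagnostic groups in a population
cohort can be classified from tabular feature sets (imaging-derived
phenotypes, sociodemographics) against carefully matched healthy controls,
and decides "classifiable" with a deliberately conservative chance
criterion. This note records the models, the defaults and why, the
numerical choices, and what the synthetic cohorts do and do not show.

## Diagnostic grouping

Participants carry sets of ICD-10 codes from chapters V (`F`, mental and
behavioral disorders) and VI (`G`, diseases of the nervous system). Two
levels of the hierarchy are used: *narrow* groups are single second-level
codes (`F32`); *broad* groups are contiguous first-level ranges
(`G35-G37`). Decimal subcodes (`F32.1`) roll up to their second-level
parent. Retention uses one threshold, `min_n` (default 125 cases): a
narrow group is retained when it reaches `min_n`; a broad range is
retained only when none of its narrow members qualifies alone but the
pooled range does. When one narrow sibling qualifies, under-threshold
siblings are dropped, not merged — the rule is applied exactly as written,
which means a range can contribute either narrow groups or one broad
group, never both.

Comorbidity is summarized as the proportion of diagnosed individuals
(members of ≥ 1 retained group) who belong to more than one, plus the
conditional overlap matrix P(member of b | member of a). The multiclass
analysis uses the *unique case list*: individuals in exactly one retained
group.

## Case-control matching

Each case receives a unique control from the pool of participants with no
chapter V/VI codes. Matching is lexicographic in the priority order sex >
age > head motion: the control must have identical sex; among unused
same-sex controls the minimal |age difference| wins, ties broken by
minimal |motion difference|, then by smallest control ID so reruns are
reproducible. Controls are consumed at most once across *all* groups.
Groups are matched in ascending size (small groups would otherwise be
starved of close matches) and cases within a group in a seed-shuffled
order. Matching is greedy per case, not a global optimal assignment: the
criterion "as close as possible, in this order of priority" is a per-case
rule, and a transport-style optimum would trade one case's best match
against another's.

A practical consequence of the lexicographic rule: when ages are
continuous, the age-nearest control is almost surely unique and the motion
tie-break never engages, leaving matched motion essentially random (t-test
p ≈ Uniform). When ages are recorded in whole years — the usual
granularity of cohort age fields — exact-age tie sets are large, motion
matching engages, and matched cohorts show the expected pattern (sex
chi-square p = 1 exactly, age p ≈ 1, motion p comfortably high). The
matcher itself compares floats and is granularity-agnostic; the balance
tests use whole-year ages for this reason.

Size-matched subgroups are built by letting each case of a reference group
(typically the smallest) claim the nearest unused case of the target group
under the same sex > age > motion rule; selected cases keep their original
controls. This equalizes both size and covariate composition across
groups.

## Classification engine

Every evaluation uses the same estimator: per-feature standardization →
PCA → classifier, with all three stages fit on training rows only.
Hyperparameters, including the PCA rank, are selected by stratified
k-fold cross-validation (default 5 folds, accuracy scoring) nested inside
the training portion of each outer split; with a single-point grid the
estimator is fitted directly. Feature columns constant across all rows are
dropped with a warning before splitting.

The primary scheme is repeated stratified shuffle-splits: default 100
splits at 80/20 train/validation, reporting the vector of per-split
validation accuracies. Families and default grids (all config-overridable;
the defaults are package choices, not reconstructions of any particular
study's grid):

| family | fixed | tuned |
|---|---|---|
| random forest | 250 trees, gini | max depth {None, 5, 10}; split-feature fraction {sqrt, 0.25, 0.5} |
| support vector | — | C {0.1, 1, 10}; kernel {linear, RBF} |
| k-nearest neighbors | — | k {5, 15, 31}; weights {uniform, distance}; metric {Euclidean, Manhattan} |

PCA rank candidates are {10, 25, 50, max}, with `max` resolving to the
largest rank the smallest inner training fold supports; candidates are
clipped and deduplicated per split.

Leave-one-site-out (LOGO) folds reuse the same estimator, one model per
held-out acquisition site; a held-out site lacking one class is skipped
with a warning. LOGO is the site-robustness check: when features carry a
site signature correlated with the labels, shuffle-splits can learn the
shortcut while LOGO collapses to or below chance.

The multiclass formulation is one-vs-rest: one random forest (250 trees,
gini, random state 42) per class, a sample's label being the class with
maximal positive-class probability, ties to the earlier class in the
ordered label list. Held-out predictions are accumulated over repeated
stratified 5-fold CV (default 2–5 repeats) and each subject's final label
is the majority vote over its held-out folds. Repeated k-fold rather than
shuffle-splits is a deliberate choice: every subject is held out the same
number of times, so confusion-matrix row sums equal the true class sizes
exactly at any repeat count. Classes must be disjoint (built from the
unique case list) and size-matched by subsampling to the smallest class.

## Significance: the conservative chance criterion

For one (group × feature set × model) cell with split accuracies
a_1..a_n, the decision statistic is

    t = (mean(a) − 0.5) / sd(a),    p = P(T_n ≥ t)

with T_n Student-t distributed on df equal to the *number of splits* n
(not n − 1 — implemented literally; the numerical difference at n = 100
is negligible but the convention is part of the criterion's definition).
Two properties matter:

* dividing by the standard deviation of split accuracies rather than the
  standard error of their mean makes the criterion a factor ~sqrt(n) more
  conservative than a one-sample t-test whenever the mean is above
  chance. The question answered is whether a single re-drawn validation
  split of *this* dataset would classify above chance, not whether the
  population mean accuracy exceeds 0.5.
* under a true null the criterion's rejection rate is far below its
  nominal alpha = 0.05 (empirically ≈ 0 at 20 splits), so "significant"
  cells are strong findings and "not significant" is *not* evidence of
  chance-level information.

Zero-variance vectors degenerate: p is reported as 0, 0.5, or 1 for mean
above, at, or below chance, with a degeneracy flag.

Multiple-comparison control is Benjamini–Hochberg FDR applied within each
(group, model) across the feature sets named in the correction scope —
never across diagnostic groups. Results tables flag `significant`
(corrected p < 0.05) and `trend` (0.05 ≤ corrected p < 0.10). Because the
BH burden grows with the family size, a cell can be significant under a
2-set scope and not under a 20-set scope with identical per-set p-values.

## Age-extremes benchmark

As an upper-bound reference, the oldest (67–70 y) and youngest (40–42 y)
members of the combined case + healthy pool are classified with the
identical engine. Old candidates are visited in descending age; each
claims the youngest unused same-sex candidate (maximal age difference),
equal-age ties broken by nearest head motion, then smallest ID, so the
arms cannot be told apart by sex or motion. Two balanced groups are built,
size-matched to the largest and smallest diagnostic groups; by default the
small group is a fresh pairing rather than a subset of the large one
(switchable with `small_from_large`). When sizes are not configured, the
pipeline caps the defaults at the sex-matched pair capacity of the
cohort's age tails; explicitly requested sizes instead raise an
infeasibility error naming the limiting sex stratum.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with planted
ground truth, so every stage is testable without access-restricted data:

* covariates: sex ~ Bernoulli (default P(F) = 0.53), age ~ Uniform(40, 70)
  years, head motion ~ log-normal (median ≈ 0.15, a typical resting-state
  framewise-displacement summary), site ~ uniform categorical (default 3).
* diagnoses: per-group base log-odds from the prevalence, optionally
  shifted linearly by age/motion and by sex; pairwise log-odds coupling
  between groups sampled by 10 full Gibbs passes of an Ising-style model.
  With zero coupling the draw is exactly independent Bernoulli. Coupling
  is the single knob for comorbidity: the study-like defaults (one strong
  anxiety–depression-style link of 2.8, weak 0.6 background) put the
  overall comorbidity rate near 40% of diagnosed individuals with the
  mood-disorder overlap dominating.
* features: Gaussian noise (sd `noise_sd`) in which group membership
  shifts configured columns by a Cohen's d in units of `noise_sd`; linear
  age slopes (feature units per year about the age midpoint), a
  standardized sex shift, and additive per-site, per-feature offsets.

The `study_like_config` defaults plant the qualitative pattern of
interest: a small nervous-system group (prevalence 2.7%) with a strong
effect (d = 1.0 on 12 of 153 "volumetric" features) and a large mood
group (prevalence 8.5%) with a weak effect (d = 0.35 on 10 of 36
"sociodemographic" features), all other groups null. One emergent and
intended behavior: with positive coupling, a comorbid group partially
inherits its partner's planted effect in proportion to the overlap.

What the generator does *not* emulate: real covariance structure between
imaging features (columns are independent given the planted effects),
non-Gaussian feature distributions, diagnosis dates or longitudinal
structure, missing data, and any raw-image-level processing. Passing
tests therefore demonstrate correctness of the pipeline's selection,
matching, evaluation, and inference logic under known ground truth — not
that any particular real dataset is or is not classifiable.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down designs chosen to keep
the statistical checks meaningful: 20 shuffle-splits per cell instead of
100, forests of 25–60 trees where the cell count is large (500-cell null
Monte Carlo, 10-seed planted-recovery runs), single-point tuning grids in
Monte-Carlo loops (the nested search is exercised separately), and
study-like cohorts of ~6,000 participants with the largest group in the
hundreds of cases. Tolerances follow from the constructions: oracle
agreement for p-values at 1e-10 (numerical integration of the t density),
BH against brute-force step-up exactly, Monte-Carlo assertions at 2–4
standard errors. All randomness flows from explicit integer seeds;
rerunning any configuration reproduces byte-identical outputs.

## Known limitations

* Greedy matching is order-dependent by design; the shipped order
  (ascending group size, seed-shuffled cases) is one reasonable choice.
* The criterion's df = n convention and the std-dev denominator make
  power comparisons with standard t-tests non-obvious; use the provided
  `one_sample_ttest_p` for reference.
* The default ICD-10 hierarchy enumerates second-level codes for chapters
  V/VI as a convenience; projects with curated phenotype hierarchies
  should supply their own.
* Feature independence in the generator means planted multivariate
  effects are easier than correlated real-world effects of equal
  univariate size; planted d values are calibrated for qualitative
  patterns, not effect-size realism.
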