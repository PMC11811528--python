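# transdx

Transdiagnostic case-control classification benchmarking for ICD-10 coded
cohorts.

Machine-learning classifiers are routinely trained to separate diagnosed
cases from healthy controls using imaging-derived phenotypes (IDPs) or
sociodemographic features, but almost always one disease at a time.
`transdx` is a pipeline for asking the comparative question: across *many*
ICD-10 diagnostic groups drawn from one epidemiological cohort, evaluated
with one rigorously matched and validated protocol, which groups can
actually be classified above chance — and how does that compare to an
easy reference target such as age? It is aimed at researchers working
with population-imaging cohorts (biobank-style participant tables with
linked diagnostic codes and tabular feature matrices) who want a
specificity-aware benchmark rather than a single-disease accuracy number.

The pipeline:

1. **Group selection** — participants' ICD-10 codes (chapters V and VI)
   are organized into *narrow* (second-level code, e.g. `F32`) and
   *broad* (first-level range, e.g. `G35-G37`) diagnostic groups. A
   narrow group is retained when it has at least `min_n` (default 125)
   cases; a broad range is retained only when no narrow member qualifies
   but the pooled range does. Comorbidity is quantified, and a unique
   (single-diagnosis) case list is derived for multiclass analysis.
2. **Matching** — every case gets a unique healthy control (no F/G
   codes), matched on sex exactly, then nearest age, then nearest head
   motion, with controls never reused across groups. Balance diagnostics
   (sex chi-square, age/motion t-tests, site chi-square) are emitted per
   group. Groups can additionally be subsampled to a common size against
   a reference group with the same rule.
3. **Classification** — a scale → PCA → classifier estimator (random
   forest with 250 trees by default; linear/RBF support vector and
   k-nearest-neighbors variants) evaluated over stratified 80/20
   shuffle-splits (default 100), with hyperparameters including the PCA
   rank tuned by nested 5-fold CV on training rows only. Leave-one-site-
   out folds and a one-vs-rest multiclass formulation (17 groups +
   controls style) are available, as is an oldest-vs-youngest age
   benchmark built with the same engine.
4. **Inference** — each cell's split accuracies a₁…aₙ are tested with the
   conservative chance criterion

   t = (mean(a) − 0.5) / sd(a),  p = P(Tₙ ≥ t),  df = n,

   i.e. the denominator is the standard deviation of split accuracies,
   *not* the standard error of the mean — a factor √n more stringent than
   a one-sample t-test. Benjamini–Hochberg FDR is applied within each
   group across feature sets (never across groups), with significant
   (p_c < 0.05) and trend (0.05 ≤ p_c < 0.10) flags.

Because real cohorts of this kind are access-restricted, the package
ships a synthetic cohort generator that reproduces the structure the
analysis assumes — covariate distributions, ICD-10 code assignment with
controllable prevalence and pairwise comorbidity coupling, and feature
sets with planted standardized group/age/sex/site effects — so the whole
pipeline is testable against known ground truth. See `docs/methods.md`
for the models, defaults, and limitations.

## Worked example

Run the core pipeline on a study-like synthetic cohort of 4,000
participants (a large weak-effect mood group, a small strong-effect
nervous-system group, coupled comorbidity, and null filler groups),
classifying every retained group from two feature sets:

```python
import pandas as pd
from transdx import run_pipeline

config = {
    "seed": 7,
    "cohort": {"study_like": {"n_participants": 4000}},
    "stages": ["groups", "match", "classify", "infer"],
    "groups": {"min_n": 60},
    "classify": {
        "models": ["rf"],
        "n_splits": 20,
        "tuning_grid": {"pca_rank": [10], "max_depth": [None], "max_features": ["sqrt"]},
        "fixed_settings": {"n_estimators": 50},
    },
}
out = run_pipeline(config, "run")
res = pd.read_csv(out / "results.csv")
cols = ["group", "feature_set", "mean_acc", "t", "p_uncorrected", "p_fdr", "significant"]
print(res[cols].round(3).to_string(index=False))
```

```
group       feature_set  mean_acc      t  p_uncorrected  p_fdr  significant
  F10  sociodemographic     0.523  0.301          0.383  0.383        False
  F10 structural_volume     0.530  0.431          0.336  0.383        False
  F20  sociodemographic     0.448 -0.504          0.690  0.690        False
  F20 structural_volume     0.467 -0.289          0.612  0.690        False
  F32  sociodemographic     0.648  5.152          0.000  0.000         True
  F32 structural_volume     0.492 -0.181          0.571  0.571        False
  F41  sociodemographic     0.547  1.277          0.108  0.216        False
  F41 structural_volume     0.512  0.378          0.355  0.355        False
  G35  sociodemographic     0.543  0.690          0.249  0.249        False
  G35 structural_volume     0.835  7.153          0.000  0.000         True
  G40  sociodemographic     0.501  0.017          0.493  0.493        False
  G40 structural_volume     0.522  0.289          0.388  0.493        False
  G43  sociodemographic     0.499 -0.012          0.505  0.663        False
  G43 structural_volume     0.476 -0.427          0.663  0.663        False
```

Reading the table: each row is one group × feature-set cell; `mean_acc`
averages the 20 held-out split accuracies, `t` is the chance criterion's
statistic, and `p_fdr` is BH-corrected within each group across the two
feature sets. Exactly the two planted effects are recovered — the small
group `G35` from the volumetric-style features (0.835) and the large
group `F32` from the sociodemographic-style features (0.648) — while all
null cells, whose accuracies hover around 0.5, stay far from
significance. That is the pipeline's qualitative contract: strong effects
in small groups and weak effects in large groups are both detectable,
and the conservative criterion keeps effect-free cells quiet.

The output directory also contains `groups.json` (retained groups,
comorbidity rate, pairwise overlap), `matches.csv` and `balance.json`
(pairings and covariate balance; sex chi-square p is exactly 1 by
construction), `accuracies.csv` (tidy per-split accuracies, ready for
swarm plots), and a `manifest.json` recording the config hash, seed, and
per-stage status. Optional stages add `confusion.csv` (multiclass),
`logo.json` (leave-one-site-out), and `age_groups.csv` /
`age_results.csv` (age benchmark).

The same runs are available from a shell:

```sh
transdx run-all --config run.yaml --out run/ --seed 7
transdx simulate --config run.yaml --out cohort/        # write the cohort CSVs
```

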