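# Methods

## Data model

The analysis substrate is a sample × feature table with a two-level
group label (`control` / `antibiotic`) and per-feature metadata
(assay ∈ {flow_frequency, mrna_foldchange, cytokine}, compartment,
unit). Three assay-level transforms are provided:

- **z-score normalization** — per feature, `(x − mean) / sd` with the
  population convention (ddof = 0). Constant features map to zeros
  with a warning; an all-missing feature is an error. Chosen because
  the panel mixes percentages, fold-changes and pg/mL concentrations;
  z-scoring is the standard way to put such mixed-unit features on a
  common scale. Normalization is applied globally per feature, not per
  tissue.
- **LPS background correction** — stimulated minus unstimulated
  cytokine concentration, per analyte. Negative results are *retained*
  and flagged, never clamped: subtraction can legitimately go below
  zero, and clamping would bias group comparisons.
- **relative expression** — `2^−(Ct_target − Ct_reference)` (ΔCt
  fold-change against the β-actin reference).

Missing values are permitted in the table. Classifiers receive
complete data via per-feature median imputation fitted on the training
portion of each CV fold (no leakage); univariate tests drop missing
values pairwise.

## Recursive ensemble feature selection

Eight classifier families are used: bagging, gradient boosting,
logistic regression, passive-aggressive, random forest, ridge, SGD on
a linear model, and a linear-kernel SVC. Hyperparameters are the
scikit-learn library defaults, frozen in the classifier factory
(`ensemble.make_classifier`); the passive-aggressive family is
constructed as `SGDClassifier(loss="hinge", penalty=None,
learning_rate="pa1", eta0=1.0)`, which is the PA-I algorithm in
current scikit-learn.

Each family is run `n_repeats = 10` times under stratified k-fold CV
with `n_folds = 10`. With 8 treated animals, 10-fold stratification is
impossible; the effective fold count falls back to
`min(n_folds, minority class size)` (8 for the default cohort) with a
log note. Repeat *r* always uses seed `base_seed + r`, for every
family and at every elimination iteration, so iterations differ only
in their feature set and the whole recursion is deterministic given
`base_seed`.

**Importance extraction.** Linear families contribute the absolute
value of their coefficients; the two tree ensembles their
impurity-based importances; bagging the mean of its base estimators'
importances. Each vector is rescaled to sum 1 (an all-zero vector
passes through, flagged), then averaged over the folds of its run.

**Aggregation.** For feature *f* over all runs (family × repeat):
`freq(f)` = fraction of runs with importance > 0, `meanimp(f)` = mean
normalized importance, `score(f) = meanimp(f) × freq(f)`. The product
realizes both weighting factors (coefficient magnitude and
contribution frequency) and is invariant to the number of runs. Ties
break lexicographically by feature name, making the ordering total and
deterministic.

**Elimination.** Each step retains the top
`k = floor(0.8 × n)` features, clamped to `[1, n − 1]` so the set
strictly shrinks and never empties (129 → 103 → 82 → 65 → 52 → … → 1,
18 iterations in total). The ranking is recomputed at every iteration
rather than reused from the first pass, matching the repeated
stepwise character of the procedure.

**Selection.** The *global average accuracy* of an iteration is the
unweighted mean of held-out accuracy over all (family, repeat, fold)
triples — plain accuracy, not balanced accuracy, configurable. The
selected signature is the iteration with the smallest feature count
whose global average accuracy ≥ the 90% cutoff; if none qualifies the
most accurate iteration is returned with an explicit
`cutoff_not_met` flag. Accuracy here is an in-sample model-selection
quantity: the same 19 animals drive both the ranking and the accuracy
estimate, which is inherent to the procedure and the reason the null
behavior (below) must be verified.

## Evaluation

- **ROC/AUC** — per-sample decision scores are pooled from a single
  seeded CV pass (each sample scored by the model that did not train
  on it); the AUC uses the rank formula `U/(n₁n₀)` with ties counted
  half, which is exactly the Mann–Whitney U identity. The curve is a
  threshold sweep.
- **PCA** — on per-feature z-scores (correlation PCA), with a
  deterministic sign convention (largest-magnitude loading positive).
- **Accuracy curve** — per-iteration table (feature count, per-family
  mean accuracy, global mean) plus a figure with the cutoff line.

## Univariate and diversity statistics

The univariate screen applies the two-sided Mann–Whitney test per
feature and flags raw p < 0.05 with *no* multiplicity correction —
this mirrors the exploratory univariate procedure the pipeline
accompanies; a Benjamini–Hochberg column is emitted alongside for
users but never drives the flags. Exact enumeration is used when
`n₁·n₂ ≤ 400` and the data are tie-free, otherwise the normal
approximation with tie and continuity corrections.

Shannon diversity is `H = −Σ pᵢ ln pᵢ` in nats (natural-log units are
the common convention in QIIME-era reports; the closed forms ln k for
uniform and 0 for single-genus compositions anchor the tests). Groups
are compared with the same two-sided rank-sum engine. The CLR
transform replaces zeros by default with a 0.5 pseudocount added to
zero cells on the count scale (deterministic), with Bayesian-style
multiplicative replacement available as the alternative strategy;
compositions are re-closed before logs, and every output row sums to
zero. Genera absent from all samples are dropped with a warning.

## Synthetic cohort generator

The generator emulates the *outputs* of the study's assays, not the
assays themselves (no FCS gating, no amplification curves, no reads).
Defaults are the study conditions: 11 control / 8 treated samples,
129 features partitioned as 101 flow + 12 mRNA + 16 cytokine
(the exact panel composition is configurable; the flow compartments
carry 20 subsets each plus one placenta-only subset, and the mRNA
block holds 5 genes × 2 tissues plus 2 placenta-only markers).

Noise families per assay, chosen for realism:

- flow frequencies: logit-normal rescaled to [0, 100] (bounded,
  skewed for rare subsets); latent locations span ≈1–50% populations;
- cytokines: log-normal (positive, multiplicative noise; ≈3–150
  pg/mL); the splenocyte-supernatant panel is generated as stimulated
  minus unstimulated background, so it can be legitimately negative
  while both components are positive pre-correction;
- fold-changes: log-normal centered at 1.

Informative features (default: the four signature features, effect
size 2.0) have their treated-group mean shifted by
`direction × effect_size × sd` on the latent (pre-transform) scale,
where the latent sd is 0.5 throughout; because the transforms are
monotone, the standardized group separation is preserved in rank
terms. Effect directions alternate (two up, two down in the treated
group) to mirror a mixed-direction signature. The returned ground
truth records the planted names, directions and realized group means,
making the planted set exactly recoverable for benchmarks.

Randomness is counter-based: feature *j* draws from a stream spawned
from `(seed, j)`, so adding features never perturbs earlier columns.
Features are generated independently; real immune panels have strong
within-tissue correlation blocks, which the generator deliberately
omits (an optional correlation knob was considered and left out).
Passing recovery tests on these cohorts therefore demonstrates that
the machinery works under the planted model, not that real cohorts
carry equally clean signal.

Genus count tables draw per-sample genus proportions from a symmetric
Dirichlet (concentration 1.0 for control, 0.2 for treated — lower
concentration concentrates mass on few genera, lowering evenness and
hence Shannon diversity) and counts from a multinomial at depth
10,000 over 30 genera.

## Problem sizes used in the checks

One full recursion on the default cohort costs
18 iterations × 8 families × 10 repeats × 8 folds ≈ 11,500 model fits
(≈5 min on one CPU), so the end-to-end checks use small replicate
counts: the test suite runs 2 replicate cohorts for selection
recovery plus 1 null cohort, and `scripts/acceptance.py` runs 3
replicate cohorts and summarizes mode/median across them. Fast
numerical oracles (aggregation brute force, exact Mann–Whitney
enumeration, all-pairs AUC, CLR/Shannon closed forms) run at full
spec-level instance counts. Expected behavior under the defaults: a
compact signature (≈1–4 features, dominated by planted ones) at
≥90% global accuracy, near-perfect ridge AUC, and a raised
cutoff-not-met flag on zero-effect cohorts.

## Known limitations

- The selection accuracy is optimistically biased (features selected
  and evaluated on the same 19 animals); an outer validation loop is
  out of scope because the emulated procedure has none.
- Independent features in the generator understate the redundancy of
  real panels; recovery rates on real data will be lower.
- With strong planted effects, single features can clear the 90%
  cutoff in some cohort draws, so the selected-signature *size*
  fluctuates between draws; the accuracy and AUC criteria are the
  stable quantities.
- No differential-abundance testing (ANCOM-style) and no 16S read
  processing; the diversity arm consumes genus count tables directly.
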