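# Methods

## Model

`medivote` classifies labeled feature tables with a three-member
heterogeneous ensemble:

1. **Rule tree** (`rule_induction`). Recursive partitioning over a fully
   categorical table. At a node holding rows R with candidate
   attributes OA:
   - if OA is empty → leaf labeled with the majority target value of R
     (ties broken to the first-encountered value, a consequence of the
     strict-inequality maximum scan);
   - if R has a single target value → pure leaf;
   - otherwise compute the global disorder amount
     GDA = −Σ p_v log₂ p_v over the target column of R, the local
     disorder LDA of each candidate attribute's own value column, score
     each attribute as GDA − LDA, and split on the minimum score
     (stable ascending sort; ties → first attribute in column order).
     One child per distinct attribute value, ordered by first
     occurrence; the split attribute is removed from the candidates, so
     depth ≤ |OA| and termination is structural.

   Because GDA is constant across attributes at a given node, minimizing
   GDA − LDA is the same as maximizing the attribute's own entropy. This
   is deliberately different from classical ID3, which maximizes
   information gain GDA − H(target | attribute). The package treats the
   attribute-entropy criterion as its defining behavior and also offers
   `gain="class_conditional"`, where the score is the negated
   information gain, so the same minimum-score selection reproduces the
   classical criterion.

2. **Two MLP members** (`neural_members`). Member A: one hidden layer of
   width ⌈(n_features + n_classes)/2⌉, logistic activation. Member B:
   hidden layers (64, 32), ReLU. Both use Adam (scikit-learn
   `MLPClassifier`), learning rate 10⁻³, at most 500 epochs, no
   early stopping, seeded. The two architectures are intentionally
   different so the ensemble is not two copies of one model. Fitted
   weights are extracted into plain arrays; prediction is an explicit
   forward pass, which makes models serializable to a single JSON
   document and independent of library internals at predict time.

3. **Majority-vote cascade** (`ensemble`). With member predictions
   (p₁, p₂, p₃): if p₁=p₂ → p₁; elif p₁=p₃ → p₁; elif p₂=p₃ → p₂; else
   ABSTAIN. Consequences asserted by tests: the final answer equals any
   label appearing at least twice; if two members are identical
   predictors the ensemble never abstains; a binary problem never
   abstains. Abstention is surfaced explicitly because a monitoring
   caller must see an undecided case; opt-in fallbacks (`rule`,
   `member_a`) replace it when a forced decision is preferred. In every
   metric an abstained row counts as an error and never credits a class.

## Preprocessing

- **Discretization.** The rule learner branches on exact value
  equality, so continuous features are discretized by per-column
  equal-frequency binning (default `bin_count=5`), fitted on training
  data only. Coinciding quantile boundaries are merged (a constant
  column becomes one bin); out-of-range test values clamp to the outer
  bins; the target is never discretized. Equal-frequency was chosen
  over equal-width for robustness to skewed sensor magnitudes.
- **Encoding for the MLPs.** One-hot over training-encounter-order
  categories (unseen tokens → all-zeros block), z-scoring for numerics
  (zero deviation → divisor 1, NaN → training mean). The members consume
  the raw encoded features rather than the discretized table: the
  discretization exists only to make rule induction well-defined, and
  the neural members should not inherit its information loss.
- **Missing values.** The reserved token `?` is a category of its own
  during induction; rows with a missing target are dropped with a
  logged warning. Numeric missing values are NaN in memory and `?` on
  disk (ARFF convention).

## Numerical choices

- 0·log₂ 0 = 0 throughout.
- Entropies accumulate with correctly rounded summation (`math.fsum`),
  so attribute scores that are mathematically tied compare exactly
  equal and the documented first-column tie-break is actually reached,
  independent of term order.
- Ties in majority computations resolve to the first-encountered value;
  ties in attribute selection to the first column. Column order in the
  input file is therefore part of the model definition.
- Model serialization is versioned JSON with sorted keys; two fits with
  the same seed produce byte-identical files.

## Synthetic data

`generate_fall_cohort` emulates a wearable fall study: subjects ×
(fall actions + daily-living actions) × repetitions, with features
named `unit_device_axis_stat` over 6 body positions × 3 tri-axial
devices × 4 summary statistics. Defaults (14 subjects, 20 falls, 16
ADLs) follow the emulated study design; repetitions default to 5 so the
default cohort has 14 × 36 × 5 = 2520 trials. Each action has its own
Gaussian signature across all features; fall actions additionally carry
an impact magnitude (uniform in [1, 2]) on the dynamic accelerometer
statistics (std, max), while some ADLs carry a small near-fall shift
(uniform in [0, 0.4]); subjects contribute N(0, 0.3) offsets and trials
N(0, 0.8) noise. The auxiliary `action_id` column names the movement
and is a perfect proxy for the class; benchmark runs and the acceptance
script drop it so the reported numbers reflect the sensor features.

What this generator does *not* emulate: raw 25-Hz waveforms, feature
extraction from time series, sensor drift, inter-lab protocol
differences, or class overlap as severe as real deployments. Because
every action's 216-feature signature is distinct and the noise is
moderate, the default cohort is close to fully separable and all five
benchmarked algorithms score near 100% on it; passing tests on this
cohort demonstrate pipeline correctness and determinism, not real-world
fall-detection accuracy.

`generate_planted` draws rows uniformly over declared categorical
domains and labels them with a known rule tree, flipping each label to
a uniformly different one with probability `label_noise`. It is the
ground-truth fixture for recovery tests: with noise 0 and all reachable
value combinations present in training, the induced tree reproduces the
planted function exactly.

`worked_example_table` is the fixed 8-trial table whose full induction
trace is: target entropy −(3/8 log₂ 3/8 + 5/8 log₂ 5/8) = 0.954434
bits; both attributes split 5/3 so both scores are exactly 0; the tie
breaks to `motion`; the `high` branch re-splits on `posture` into pure
leaves (lying → fall, upright → adl) and the `low` branch is a pure
`adl` leaf.

## Evaluation protocol

Default protocol: stratified 70/30 holdout with a required seed;
stratified 10-fold with pooled out-of-fold predictions as the
alternative. Macro averages are the headline and weighted averages are
reported alongside, bracketing the two common conventions. Baseline
hyperparameters are library defaults, recorded verbatim in the report.
Wall-clock timings are collected but excluded from the canonical report
tables so reports are bit-for-bit reproducible under a seed.

Problem sizes used by the test suite and the acceptance script —
planted tables of 300–1000 rows, the 2520-trial default cohort, 50–100
random tables for consistency and reference-agreement checks — were
chosen as the smallest sizes at which every asserted property is
non-trivially exercised.

## Known limitations

- The attribute-entropy split criterion ignores the class when scoring
  attributes; on data where an uninformative high-cardinality attribute
  coexists with an informative low-entropy one it will split on the
  former. This is the defining behavior, not a bug; use the
  class-conditional mode for classical behavior.
- No pruning and no ordinal/threshold splits: deep trees memorize
  consistent training data (the consistency property depends on this)
  and can overfit noisy data.
- Equal-frequency binning with few bins can hide fine class boundaries
  in a single bin.
- ARFF support covers the common Weka dialect (numeric/nominal/string,
  `?` missing, `%` comments); sparse rows and date attributes are not
  parsed.
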