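# medivote

Entropy-driven rule induction with a dual-MLP majority-vote ensemble for
tabular health-monitoring data.

## The problem

Wearable-sensor health monitoring produces labeled feature tables: one
row per trial or patient record (a fall trial summarized from body-worn
inertial units, a set of clinical symptoms), one column per feature,
plus a class label (FALL vs ADL, disease vs healthy). `medivote`
implements a heterogeneous three-member classifier for such tables,
aimed at monitoring pipelines where an interpretable rule set and an
explicit "the members disagree" outcome both matter.

## The method

**Rule member.** A classification-rule tree is induced recursively over
a categorical table. At each node the learner computes the *disorder
amount* (Shannon entropy, bits) of the target column,

&nbsp;&nbsp;&nbsp;&nbsp;GDA = −Σ<sub>v</sub> p<sub>v</sub> log₂ p<sub>v</sub>,

and the disorder LDA of each candidate attribute's own value column,
scores each attribute as `GDA − LDA`, and splits on the attribute with
the **minimum** score (ties → first column). Note this selects the
attribute with the largest own-value entropy — deliberately *not*
classical ID3 information gain, which conditions on the class; an
optional `gain="class_conditional"` mode provides the classical
criterion. Recursion stops on pure partitions or when attributes run
out (majority leaf, first-encountered value wins ties). Continuous
features are first discretized by per-column equal-frequency binning
(default 5 bins) fitted on training data only. Every node stores its
training majority so prediction is total: a branch value never seen in
training falls back to that majority.

**Neural members.** Two multilayer perceptrons trained on the raw
(one-hot / z-scored) features: member A has a single hidden layer of
width ⌈(n_features + n_classes)/2⌉ with logistic activation, member B
two hidden layers (64, 32) with ReLU. Both are fully seeded.

**Vote.** For each row the three predictions are resolved by a fixed
cascade: `pred1==pred2 → pred1; elif pred1==pred3 → pred1; elif
pred2==pred3 → pred2; else ABSTAIN`. A three-way disagreement is
surfaced explicitly (abstentions count as errors in every metric);
opt-in fallback policies (`rule`, `member_a`) can replace it. A binary
problem can never abstain.

The evaluation harness benchmarks the ensemble against Gaussian Naive
Bayes, RBF-kernel SVM, KNN (k=5) and a single MLP ("ANN") under one
shared stratified split, reporting accuracy and per-class/macro/weighted
precision, recall and F-measure.

## Worked example

```sh
python examples/worked_example.py
```

```
8 trials, attributes ['motion', 'posture', 'state'], target 'state'

global disorder amount (target entropy): 0.954434 bits
  motion   local disorder 0.954434  score +0.000000
  posture  local disorder 0.954434  score +0.000000
both attributes tie at score 0; the first column wins the tie

IF motion = high
  IF posture = lying
    THEN state = fall
  IF posture = upright
    THEN state = adl
IF motion = low
  THEN state = adl
```

The 8-trial table has 3 falls and 5 daily-living activities, so the
target entropy is −(3/8 log₂ 3/8 + 5/8 log₂ 5/8) = 0.954434 bits. Both
attributes split the rows 5/3, so both local disorders equal the global
one, both scores are 0, and the stable tie-break picks the first column
(`motion`). The induced tree classifies every training trial correctly.

Other narrative examples: `examples/fall_cohort.py` (the synthetic
wearable-sensor cohort: 2520 trials × 216 features),
`examples/planted_recovery.py` (exact recovery of a planted decision
rule on held-out data), `examples/compare_algorithms.py` (the five-way
benchmark on a noisy table).

## Command line

```sh
medivote synth fall --seed 1 --out fall.csv
medivote fit --input fall.csv --target action_class --seed 1 --out-dir run/
medivote predict --model run/model.json --input fall.csv --out pred.csv
medivote compare --input fall.csv --target action_class --drop action_id \
    --seed 1 --out-dir cmp/
```

Exit codes: 0 success, 2 usage/configuration, 3 data/schema, 4 internal.
CSV (RFC 4180) and Weka-style ARFF are supported throughout.

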