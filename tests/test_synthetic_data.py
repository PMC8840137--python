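"""Synthetic cohort and planted-rule generators."""

import numpy as np
import pytest

from medivote import (FallCohortConfig, PlantedRuleConfig, RuleNode,
                      compute_metrics, default_planted_config, fit,
                      generate_fall_cohort, generate_planted, predict,
                      predict_rule, random_rule_tree, worked_example_table)
from medivote.errors import ConfigurationError


def test_default_cohort_trial_and_feature_counts():
    cfg = FallCohortConfig()
    t = generate_fall_cohort(cfg)
    assert cfg.n_trials == t.n_rows == 14 * (20 + 16) * 5 == 2520
    assert cfg.n_features == 6 * 3 * 3 * 4 == 216
    # features + action_id + target
    assert len(t.attributes) == 218
    assert t.target == "action_class"
    assert set(t.column("action_class")) == {"FALL", "ADL"}


def test_cohort_counts_follow_config_products():
    cfg = FallCohortConfig(n_subjects=3, n_fall_actions=2, n_adl_actions=2,
                           repetitions=2, n_units=2, devices_per_unit=2,
                           axes_per_device=2, stats_per_channel=2, seed=9)
    t = generate_fall_cohort(cfg)
    assert t.n_rows == 3 * 4 * 2
    assert len(t.other_attributes) == 2 * 2 * 2 * 2 + 1  # + action_id


def test_cohort_deterministic():
    t1 = generate_fall_cohort(FallCohortConfig(seed=5))
    t2 = generate_fall_cohort(FallCohortConfig(seed=5))
    assert t1.equals(t2)
    t3 = generate_fall_cohort(FallCohortConfig(seed=6))
    assert not t1.equals(t3)


def test_cohort_rejects_zero_counts():
    with pytest.raises(ConfigurationError):
        FallCohortConfig(n_subjects=0)


def test_default_ensemble_learns_cohort_from_sensor_features():
    """Regression: the default ensemble separates FALL from ADL at >=0.9
    held-out accuracy on the default cohort (sensor features only)."""
    from medivote.evaluation import _stratified_holdout
    t = generate_fall_cohort(FallCohortConfig(seed=0)).drop_attributes(["action_id"])
    y = [str(v) for v in t.column("action_class")]
    tr, te = _stratified_holdout(y, 0.3, seed=0)
    model = fit(t.subset(tr), seed=0)
    votes = predict(model, t.subset(te))
    rep = compute_metrics(t.subset(te).column("action_class"), votes)
    assert rep.accuracy >= 0.9


# ---------------------------------------------------------------------------
# planted rules
# ---------------------------------------------------------------------------

def test_noiseless_labels_match_planted_function():
    cfg = default_planted_config(n_rows=500, seed=13)
    t = generate_planted(cfg)
    for row in t.rows():
        assert row["label"] == predict_rule(cfg.planted_tree, row)


def test_full_noise_flips_every_binary_label():
    cfg = default_planted_config(n_rows=200, label_noise=1.0, seed=13)
    t = generate_planted(cfg)
    assert all(row["label"] != predict_rule(cfg.planted_tree, row)
               for row in t.rows())


def test_noise_fraction_within_binomial_bound():
    cfg = default_planted_config(n_rows=10000, label_noise=0.2, seed=17)
    t = generate_planted(cfg)
    flipped = sum(row["label"] != predict_rule(cfg.planted_tree, row)
                  for row in t.rows())
    # 3-sigma binomial bound: sqrt(0.2*0.8/10000)*3 = 0.012
    assert abs(flipped / 10000 - 0.2) <= 0.012


def test_planted_deterministic():
    cfg = default_planted_config(n_rows=100, label_noise=0.3, seed=2)
    assert generate_planted(cfg).equals(generate_planted(cfg))


def test_planted_rejects_undeclared_values():
    leaf = lambda v: RuleNode("leaf", "label", class_value=v, node_majority=v)
    bad = RuleNode("internal", "a", branch_values=["no_such_value"],
                   children=[leaf("x")], node_majority="x")
    with pytest.raises(ConfigurationError):
        generate_planted(PlantedRuleConfig(
            n_rows=10, attribute_domains=[("a", ["u", "v"])],
            planted_tree=bad, seed=0))


def test_planted_rejects_bad_noise():
    with pytest.raises(ConfigurationError):
        default_planted_config(label_noise=1.5)


def test_random_rule_tree_is_total_over_domains():
    rng = np.random.default_rng(3)
    domains = [(f"a{i}", ["x", "y", "z"]) for i in range(3)]
    for _ in range(20):
        tree = random_rule_tree(domains, ["p", "q"], rng)
        cfg = PlantedRuleConfig(n_rows=50, attribute_domains=domains,
                                planted_tree=tree, seed=1)
        t = generate_planted(cfg)
        assert t.n_rows == 50
        assert set(t.column("label")) <= {"p", "q"}


# ---------------------------------------------------------------------------
# worked example fixture
# ---------------------------------------------------------------------------

def test_worked_example_shape_and_determinism():
    t = worked_example_table()
    assert t.n_rows == 8
    assert t.attributes == ["motion", "posture", "state"]
    assert t.equals(worked_example_table())


def test_worked_example_documented_trace():
    """The induction trace documented in docs/methods.md holds exactly."""
    import math

    from medivote import attribute_scores, disorder_amount, generate_rules

    t = worked_example_table()
    gda = disorder_amount(t.column("state"))
    expected = -(3 / 8 * math.log2(3 / 8) + 5 / 8 * math.log2(5 / 8))
    assert gda == pytest.approx(expected, abs=1e-12)
    assert gda == pytest.approx(0.954434, abs=1e-6)
    scores = attribute_scores(t)
    # both attributes split 5/3, so both LDAs equal the GDA and tie at 0
    for _, lda, score in scores.per_attribute:
        assert lda == pytest.approx(gda, abs=1e-12)
        assert score == pytest.approx(0.0, abs=1e-12)
    tree = generate_rules(t)
    assert tree.attribute == "motion"  # stable tie-break: first column
    assert tree.branch_values == ["high", "low"]
    high, low = tree.children
    assert low.is_leaf and low.class_value == "adl"
    assert high.attribute == "posture"
    assert high.branch_values == ["lying", "upright"]
    assert [c.class_value for c in high.children] == ["fall", "adl"]
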