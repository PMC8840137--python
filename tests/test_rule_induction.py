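"""Entropy bookkeeping and the recursive rule generation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from medivote import (DisorderScores, LabeledTable, attribute_scores,
                      disorder_amount, generate_rules, partition_by,
                      select_hpa)
from medivote.errors import ConfigurationError

from _reference import ref_entropy


def make_table(cols: dict, target: str) -> LabeledTable:
    return LabeledTable(pd.DataFrame(cols), target)


# ---------------------------------------------------------------------------
# disorder_amount
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("values,expected", [
    (["fall"] * 10, 0.0),
    (["fall"] * 5 + ["ADL"] * 5, 1.0),
    (["A", "A", "B", "C"], 1.5),
])
def test_disorder_amount_known_values(values, expected):
    assert disorder_amount(values) == pytest.approx(expected, abs=1e-12)


def test_disorder_amount_empty_errors():
    with pytest.raises(ValueError):
        disorder_amount([])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.sampled_from("abcde"), min_size=1, max_size=50),
       st.randoms(use_true_random=False))
def test_disorder_amount_permutation_invariant(values, rnd):
    shuffled = list(values)
    rnd.shuffle(shuffled)
    assert disorder_amount(shuffled) == pytest.approx(disorder_amount(values),
                                                      abs=1e-12)


@pytest.mark.parametrize("k", [2, 3, 4, 8])
def test_disorder_amount_maximal_for_uniform(k):
    uniform = [f"c{i}" for i in range(k)] * 5
    assert disorder_amount(uniform) == pytest.approx(math.log2(k), abs=1e-12)
    skewed = uniform + ["c0"]
    assert disorder_amount(skewed) < math.log2(k)


# ---------------------------------------------------------------------------
# attribute_scores / select_hpa
# ---------------------------------------------------------------------------

def test_scores_constant_attribute_scores_gda():
    t = make_table({"a": ["k"] * 4, "y": ["p", "q", "p", "q"]}, "y")
    s = attribute_scores(t)
    assert s.gda == pytest.approx(1.0)
    assert s.per_attribute == [("a", 0.0, pytest.approx(1.0))]


def test_scores_hand_computed_subtraction():
    # gda = H({p:2, q:1, r:1}) = 1.5 ; lda([x,x,x,y]) = H(3/4,1/4)
    t = make_table({"a": ["x", "x", "x", "y"], "y": ["p", "p", "q", "r"]}, "y")
    s = attribute_scores(t)
    lda = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
    assert s.gda == pytest.approx(1.5, abs=1e-12)
    assert s.per_attribute[0][1] == pytest.approx(lda, abs=1e-12)
    assert s.per_attribute[0][2] == pytest.approx(1.5 - lda, abs=1e-12)
    assert s.per_attribute[0][2] == pytest.approx(0.688722, abs=1e-6)


def test_scores_constant_target_yields_nonpositive_scores():
    t = make_table({"a": ["x", "y", "x"], "b": ["u", "u", "v"],
                    "y": ["p", "p", "p"]}, "y")
    s = attribute_scores(t)
    assert s.gda == 0.0
    assert all(score <= 0 for _, _, score in s.per_attribute)


def test_scores_reject_numeric_column():
    t = make_table({"a": [1.0, 2.0], "y": ["p", "q"]}, "y")
    with pytest.raises(ConfigurationError):
        attribute_scores(t)


def test_select_hpa_minimum_and_stable_ties():
    assert select_hpa(DisorderScores(1.0, [("A", 0.8, 0.2), ("B", 0.5, 0.5)])) == "A"
    assert select_hpa(DisorderScores(1.0, [("A", 0.7, 0.3), ("B", 0.7, 0.3)])) == "A"
    assert select_hpa(DisorderScores(1.0, [("A", 0.1, 0.9)])) == "A"
    with pytest.raises(ValueError):
        select_hpa(DisorderScores(1.0, []))


def test_classic_gain_mode_uses_conditional_entropy():
    # 'a' perfectly predicts y; 'b' is an uninformative high-entropy column
    t = make_table({"a": ["x", "x", "y", "y"],
                    "b": ["u", "v", "u", "v"],
                    "y": ["p", "p", "q", "q"]}, "y")
    s = attribute_scores(t, gain="class_conditional")
    by_name = {a: (lda, score) for a, lda, score in s.per_attribute}
    assert by_name["a"][0] == pytest.approx(0.0)   # H(y|a) = 0
    assert by_name["b"][0] == pytest.approx(1.0)   # H(y|b) = 1
    assert select_hpa(s) == "a"


# ---------------------------------------------------------------------------
# partition_by
# ---------------------------------------------------------------------------

def test_partition_two_groups():
    t = make_table({"a": ["x", "x", "y", "y"], "y": list("pqpq")}, "y")
    parts = partition_by(t, "a")
    assert [(v, p.n_rows) for v, p in parts] == [("x", 2), ("y", 2)]
    assert all("a" not in p.attributes for _, p in parts)


def test_partition_single_value_degenerate():
    t = make_table({"a": ["x"] * 3, "b": list("uvw"), "y": list("pqp")}, "y")
    parts = partition_by(t, "a")
    assert len(parts) == 1
    v, sub = parts[0]
    assert v == "x" and sub.n_rows == 3
    assert sub.other_attributes == ["b"]


def test_partition_first_occurrence_order_and_row_order():
    t = make_table({"a": ["x", "y", "z", "x"], "y": list("pqrs")}, "y")
    parts = partition_by(t, "a")
    assert [v for v, _ in parts] == ["x", "y", "z"]
    assert parts[0][1].column("y") == ["p", "s"]  # rows 1 and 4, in order
    assert parts[1][1].column("y") == ["q"]
    assert parts[2][1].column("y") == ["r"]


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.sampled_from("xyz"), min_size=1, max_size=20))
def test_partition_conserves_rows(vals):
    t = make_table({"a": vals, "y": ["c"] * len(vals)}, "y")
    parts = partition_by(t, "a")
    assert sum(p.n_rows for _, p in parts) == t.n_rows
    assert sorted(v for v, _ in parts) == sorted(set(vals))


# ---------------------------------------------------------------------------
# generate_rules
# ---------------------------------------------------------------------------

def test_single_class_base_case():
    t = make_table({"a": ["x", "y"], "y": ["walking", "walking"]}, "y")
    node = generate_rules(t)
    assert node.is_leaf and node.class_value == "walking"


def test_majority_base_case_no_attributes_left():
    t = LabeledTable(pd.DataFrame({"y": ["fall", "fall", "ADL"]}), "y")
    node = generate_rules(t)
    assert node.is_leaf and node.class_value == "fall"


def test_majority_tie_breaks_to_first_encountered():
    t = LabeledTable(pd.DataFrame({"y": ["b", "a", "b", "a"]}), "y")
    assert generate_rules(t).class_value == "b"


def test_toy_table_splits_on_determining_attribute():
    # A determines the class; B is constant (lda 0, score = gda > score(A))
    t = make_table({"A": ["0", "0", "1", "1"],
                    "B": ["k", "k", "k", "k"],
                    "y": ["ADL", "ADL", "fall", "fall"]}, "y")
    node = generate_rules(t)
    assert not node.is_leaf and node.attribute == "A"
    assert node.branch_values == ["0", "1"]
    assert [c.class_value for c in node.children] == ["ADL", "fall"]
    assert node.node_majority == "ADL"  # first-encountered of the 2-2 tie


def test_empty_table_errors():
    t = LabeledTable(pd.DataFrame({"a": [], "y": []}), "y")
    with pytest.raises(ValueError):
        generate_rules(t)


def test_depth_bounded_by_attribute_count():
    rng = np.random.default_rng(5)
    cols = {f"a{i}": [f"v{rng.integers(2)}" for _ in range(30)] for i in range(4)}
    cols["y"] = [f"c{rng.integers(3)}" for _ in range(30)]
    t = make_table(cols, "y")
    node = generate_rules(t)
    assert node.depth() <= 4


def test_no_attribute_repeats_on_any_path():
    rng = np.random.default_rng(11)
    cols = {f"a{i}": [f"v{rng.integers(3)}" for _ in range(40)] for i in range(3)}
    cols["y"] = [f"c{rng.integers(2)}" for _ in range(40)]
    node = generate_rules(make_table(cols, "y"))

    def walk(n, seen):
        if n.is_leaf:
            return
        assert n.attribute not in seen
        for c in n.children:
            walk(c, seen | {n.attribute})

    walk(node, set())


def test_entropy_matches_reference_on_mixed_tokens():
    vals = ["a", "b", "b", "c", "c", "c", "d"]
    assert disorder_amount(vals) == pytest.approx(ref_entropy(vals), abs=1e-12)
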