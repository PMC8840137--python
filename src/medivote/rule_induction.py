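"""Entropy-driven recursive rule induction.

The rule learner builds a classification-rule tree over a fully
categorical table.  At each node it computes the *disorder amount*
(Shannon entropy, in bits) of the target column (the global disorder
amount, GDA) and of each candidate attribute's own value column (the
local disorder amount, LDA), scores each attribute as ``GDA - LDA`` and
splits on the attribute with the *minimum* score — equivalently, the
attribute whose own value distribution carries the most entropy.  This
deliberately differs from classical ID3 information gain, which would
use the class-conditional entropy of the partitions; an optional
``gain="class_conditional"`` mode provides the classical criterion.

Recursion stops when a partition is pure (single target value) or when
no candidate attributes remain (majority-class leaf, first-encountered
value winning ties).  Every node additionally stores the majority class
of the training rows that reached it, so that prediction can fall back
gracefully on branch values never seen in training.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .data_model import LabeledTable
from .errors import ConfigurationError

__all__ = [
    "RuleNode",
    "DisorderScores",
    "disorder_amount",
    "attribute_scores",
    "select_hpa",
    "partition_by",
    "generate_rules",
    "render_rules",
]


# ---------------------------------------------------------------------------
# Rule tree
# ---------------------------------------------------------------------------

@dataclass
class RuleNode:
    """One node of a classification-rule tree.

    A leaf carries ``class_value``; an internal node carries the split
    ``attribute``, the ordered ``branch_values`` observed in training and
    one child per branch value.  ``node_majority`` is the majority target
    value among the training rows that reached the node.
    """

    node_kind: str  # "leaf" | "internal"
    attribute: str
    class_value: str | None = None
    branch_values: list[str] = field(default_factory=list)
    children: list["RuleNode"] = field(default_factory=list)
    node_majority: str | None = None

    def __post_init__(self) -> None:
        if self.node_kind not in ("leaf", "internal"):
            raise ValueError(f"bad node_kind {self.node_kind!r}")
        if len(self.branch_values) != len(self.children):
            raise ValueError("branch_values and children length mismatch")

    @property
    def is_leaf(self) -> bool:
        return self.node_kind == "leaf"

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children)

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.n_leaves() for c in self.children)

    def to_dict(self) -> dict:
        d = {
            "node_kind": self.node_kind,
            "attribute": self.attribute,
            "node_majority": self.node_majority,
        }
        if self.is_leaf:
            d["class_value"] = self.class_value
        else:
            d["branch_values"] = list(self.branch_values)
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RuleNode":
        if d["node_kind"] == "leaf":
            return cls("leaf", d["attribute"], class_value=d["class_value"],
                       node_majority=d.get("node_majority"))
        return cls(
            "internal", d["attribute"],
            branch_values=list(d["branch_values"]),
            children=[cls.from_dict(c) for c in d["children"]],
            node_majority=d.get("node_majority"),
        )

    def structurally_equal(self, other: "RuleNode") -> bool:
        """Node-for-node equality of split structure and leaf labels."""
        if self.node_kind != other.node_kind or self.attribute != other.attribute:
            return False
        if self.is_leaf:
            return self.class_value == other.class_value
        if self.branch_values != other.branch_values:
            return False
        return all(a.structurally_equal(b)
                   for a, b in zip(self.children, other.children))


def render_rules(node: RuleNode, _indent: int = 0) -> str:
    """Indented human-readable ``IF value THEN ...`` rendering."""
    pad = "  " * _indent
    if node.is_leaf:
        return f"{pad}THEN {node.attribute} = {node.class_value}\n"
    out = []
    for val, child in zip(node.branch_values, node.children):
        out.append(f"{pad}IF {node.attribute} = {val}\n")
        out.append(render_rules(child, _indent + 1))
    return "".join(out)


# ---------------------------------------------------------------------------
# Disorder-amount bookkeeping
# ---------------------------------------------------------------------------

def disorder_amount(values) -> float:
    """Shannon entropy (bits) of the empirical token distribution.

    ``-sum_v p_v log2 p_v`` with ``p_v`` the relative frequency of token
    ``v``; ``0 * log2(0)`` is taken as 0.
    """
    arr = np.asarray(list(values), dtype=object)
    if arr.size == 0:
        raise ValueError("disorder_amount of an empty value list")
    _, counts = np.unique(arr.astype(str), return_counts=True)
    p = counts / counts.sum()
    # fsum: correctly rounded independent of term order, so mathematically
    # tied attribute scores compare exactly equal
    return -math.fsum(p * np.log2(p))


@dataclass
class DisorderScores:
    """Global disorder of the target plus per-attribute local disorder.

    ``per_attribute`` preserves attribute (column) order; each entry is
    ``(attribute, lda, score)`` with ``score = gda - lda``.
    """

    gda: float
    per_attribute: list[tuple[str, float, float]]


def _check_categorical(table: LabeledTable) -> None:
    numeric = [c for c in table.other_attributes if table.is_numeric(c)]
    if numeric:
        raise ConfigurationError(
            f"rule induction requires categorical columns; discretize first "
            f"(numeric: {numeric})"
        )


def attribute_scores(table: LabeledTable, gain: str = "attribute_entropy") -> DisorderScores:
    """Score every non-target attribute by ``GDA - LDA``.

    In the default mode, LDA is the entropy of the attribute's *own*
    value distribution and ``score = gda - lda``.  With
    ``gain="class_conditional"`` LDA is the partition-weighted
    conditional entropy of the target given the attribute (the classical
    decision-tree criterion) and the score is ``lda - gda`` (the negated
    information gain), so the unchanged minimum-score selection then
    coincides with maximum information gain.
    """
    if table.n_rows < 1 or not table.other_attributes:
        raise ValueError("attribute_scores needs >=1 row and >=1 non-target attribute")
    _check_categorical(table)
    gda = disorder_amount(table.column(table.target))
    per = []
    target_col = table.column(table.target)
    n = table.n_rows
    for attr in table.other_attributes:
        col = table.column(attr)
        if gain == "attribute_entropy":
            lda = disorder_amount(col)
            score = gda - lda
        elif gain == "class_conditional":
            lda = 0.0
            for val, cnt in Counter(col).items():
                sub = [t for a, t in zip(col, target_col) if a == val]
                lda += (cnt / n) * disorder_amount(sub)
            score = lda - gda  # negated information gain
        else:
            raise ConfigurationError(f"unknown gain mode {gain!r}")
        per.append((attr, lda, score))
    return DisorderScores(gda=gda, per_attribute=per)


def select_hpa(scores: DisorderScores) -> str:
    """Highest-priority attribute: minimum score, stable on ties.

    Implemented as a stable ascending sort on the score, keeping the
    first attribute in column order among equals.
    """
    if not scores.per_attribute:
        raise ValueError("select_hpa on empty scores")
    ordered = sorted(scores.per_attribute, key=lambda t: t[2])
    return ordered[0][0]


def partition_by(table: LabeledTable, attribute: str):
    """Split rows by the values of ``attribute``.

    Returns ordered ``(value, subtable)`` pairs — one per distinct value,
    ordered by first occurrence in the column; each subtable preserves
    original row order and has the partitioning attribute removed.
    """
    if attribute not in table.other_attributes:
        raise ValueError(f"cannot partition on {attribute!r}")
    col = table.column(attribute)
    groups: dict = {}
    for i, v in enumerate(col):
        groups.setdefault(v, []).append(i)
    out = []
    for v, idx in groups.items():
        out.append((v, table.subset(idx).drop_attributes([attribute])))
    return out


def _majority(values) -> str:
    """Majority token; the first-encountered maximum wins ties."""
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best, best_n = None, -1
    for v, n in counts.items():  # insertion order = encounter order
        if n > best_n:
            best, best_n = v, n
    return best


def generate_rules(table: LabeledTable, gain: str = "attribute_entropy") -> RuleNode:
    """Induce a classification-rule tree from a categorical table.

    Base cases: no candidate attributes left -> majority-class leaf;
    a single remaining target value -> pure leaf.  Otherwise split on
    :func:`select_hpa` and recurse on each partition.  Recursion depth is
    bounded by the number of non-target attributes, since every split
    removes its attribute from the candidates.
    """
    if table.n_rows == 0:
        raise ValueError("generate_rules on an empty table")
    _check_categorical(table)
    return _generate(table, gain)


def _generate(table: LabeledTable, gain: str) -> RuleNode:
    target_col = table.column(table.target)
    majority = _majority(target_col)
    tav = list(dict.fromkeys(target_col))
    if not table.other_attributes:
        return RuleNode("leaf", table.target, class_value=majority,
                        node_majority=majority)
    if len(tav) == 1:
        return RuleNode("leaf", table.target, class_value=tav[0],
                        node_majority=tav[0])
    hpa = select_hpa(attribute_scores(table, gain=gain))
    branch_values, children = [], []
    for val, sub in partition_by(table, hpa):
        branch_values.append(str(val))
        children.append(_generate(sub, gain))
    return RuleNode("internal", hpa, branch_values=branch_values,
                    children=children, node_majority=majority)
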