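"""Three-member heterogeneous ensemble: rule tree + two MLPs, majority vote.

Training fits all three members on the same table: the rule tree on its
discretized form, the MLP members on the encoded raw features.
Prediction collects one label from each member and resolves them by the
fixed cascade

    if pred1 == pred2: final = pred1
    elif pred1 == pred3: final = pred1
    elif pred2 == pred3: final = pred2
    else: final = ABSTAIN

so the final answer always agrees with any label that appears at least
twice, and a three-way disagreement is surfaced explicitly as an
abstention (optionally replaced by a configured fallback).  With only
two classes the three predictions can never be pairwise distinct, so a
binary problem never abstains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .data_model import (DiscretizationMap, LabeledTable, apply_discretizer,
                         fit_discretizer)
from .errors import ConfigurationError, SchemaError
from .neural_members import (FittedMember, MemberConfig, TableEncoder,
                             default_member_configs, train_member)
from .rule_induction import RuleNode, generate_rules

__all__ = ["ABSTAIN", "VoteResult", "EnsembleModel", "fit",
           "predict_rule", "vote", "predict",
           "model_to_json", "model_from_json"]

#: Sentinel label for a three-way disagreement.
ABSTAIN = "ABSTAIN"

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class VoteResult:
    """The three member predictions and the resolved decision."""

    pred1: str  # rule tree
    pred2: str  # member A
    pred3: str  # member B
    final: str
    abstained: bool


def predict_rule(tree: RuleNode, row: dict) -> str:
    """Traverse the rule tree for one (discretized) instance.

    At a leaf, the stored class value is returned.  At an internal node
    the instance's value for the split attribute selects the matching
    branch; a value never seen in training falls back to the node's
    training-majority class, which makes traversal total.
    """
    node = tree
    while not node.is_leaf:
        val = str(row.get(node.attribute, ""))
        try:
            i = node.branch_values.index(val)
        except ValueError:
            return node.node_majority
        node = node.children[i]
    return node.class_value


def vote(pred1: str, pred2: str, pred3: str) -> VoteResult:
    """Resolve three member predictions by the majority cascade."""
    if pred1 == pred2 or pred1 == pred3:
        return VoteResult(pred1, pred2, pred3, pred1, False)
    if pred2 == pred3:
        return VoteResult(pred1, pred2, pred3, pred2, False)
    return VoteResult(pred1, pred2, pred3, ABSTAIN, True)


@dataclass
class EnsembleModel:
    """Fitted rule tree + two neural members + shared preprocessing."""

    rule_tree: RuleNode
    member_a: FittedMember
    member_b: FittedMember
    discretizer: DiscretizationMap
    label_vocabulary: list[str]
    target: str
    attributes: list[str]
    seed: int = 0
    bin_count: int = 5

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "target": self.target,
            "attributes": self.attributes,
            "label_vocabulary": self.label_vocabulary,
            "seed": self.seed,
            "bin_count": self.bin_count,
            "rule_tree": self.rule_tree.to_dict(),
            "discretizer": self.discretizer.to_dict(),
            "member_a": self.member_a.to_dict(),
            "member_b": self.member_b.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported model schema version {d.get('schema_version')!r}")
        return cls(
            rule_tree=RuleNode.from_dict(d["rule_tree"]),
            member_a=FittedMember.from_dict(d["member_a"]),
            member_b=FittedMember.from_dict(d["member_b"]),
            discretizer=DiscretizationMap.from_dict(d["discretizer"]),
            label_vocabulary=list(d["label_vocabulary"]),
            target=d["target"],
            attributes=list(d["attributes"]),
            seed=int(d["seed"]),
            bin_count=int(d["bin_count"]),
        )


def fit(table: LabeledTable,
        member_configs: tuple[MemberConfig, MemberConfig] | None = None,
        bin_count: int = 5,
        seed: int = 0,
        gain: str = "attribute_entropy") -> EnsembleModel:
    """Train the full three-member ensemble on one labeled table.

    The discretizer and feature encoder are fitted on this table only;
    the rule tree is induced on the discretized view while both MLP
    members see the raw encoded features.  Deterministic given ``seed``
    (or explicit member seeds).
    """
    if table.n_rows == 0:
        raise ValueError("fit on an empty table")
    if member_configs is None:
        member_configs = default_member_configs(seed)
    disc = fit_discretizer(table, bin_count=bin_count)
    cat = apply_discretizer(disc, table)
    if cat.other_attributes:
        tree = generate_rules(cat, gain=gain)
    else:  # no predictive attributes at all: majority stump
        from .rule_induction import _majority
        maj = _majority(cat.column(cat.target))
        tree = RuleNode("leaf", cat.target, class_value=maj, node_majority=maj)
    encoder = TableEncoder().fit(table)
    member_a = train_member(table, member_configs[0], encoder=encoder)
    member_b = train_member(table, member_configs[1], encoder=encoder)
    return EnsembleModel(
        rule_tree=tree,
        member_a=member_a,
        member_b=member_b,
        discretizer=disc,
        label_vocabulary=[str(v) for v in table.target_values],
        target=table.target,
        attributes=list(table.attributes),
        seed=seed,
        bin_count=bin_count,
    )


def predict(model: EnsembleModel, rows: LabeledTable,
            fallback: str = "abstain") -> list[VoteResult]:
    """Predict every row: rule-tree label, two MLP labels, majority vote.

    ``fallback`` governs a three-way disagreement: ``"abstain"`` keeps
    the explicit ABSTAIN outcome, ``"rule"`` substitutes the rule tree's
    label, ``"member_a"`` member A's.
    """
    if fallback not in ("abstain", "rule", "member_a"):
        raise ConfigurationError(f"unknown fallback policy {fallback!r}")
    missing = [a for a in model.attributes if a != model.target
               and a not in rows.attributes]
    if missing:
        raise SchemaError(f"prediction rows lack attribute(s) {missing}")
    if rows.n_rows == 0:
        return []
    has_target = model.target in rows.attributes
    view = rows if has_target else _with_dummy_target(rows, model.target)
    cat = apply_discretizer(model.discretizer, view)
    p2 = model.member_a.predict(view)
    p3 = model.member_b.predict(view)
    results = []
    for row, b, c in zip(cat.rows(), p2, p3):
        a = predict_rule(model.rule_tree, row)
        v = vote(a, b, c)
        if v.abstained and fallback != "abstain":
            final = v.pred1 if fallback == "rule" else v.pred2
            v = VoteResult(v.pred1, v.pred2, v.pred3, final, True)
        results.append(v)
    return results


def _with_dummy_target(rows: LabeledTable, target: str) -> LabeledTable:
    df = rows.df.copy()
    df[target] = "?"
    return LabeledTable(df, target, rows.provenance)


def model_to_json(model: EnsembleModel) -> str:
    return json.dumps(model.to_dict(), indent=1, sort_keys=True)


def model_from_json(text: str) -> EnsembleModel:
    return EnsembleModel.from_dict(json.loads(text))
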