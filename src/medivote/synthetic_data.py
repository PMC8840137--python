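"""Synthetic datasets: fall-detection-style cohorts and planted-rule tables.

``generate_fall_cohort`` emulates a body-worn inertial-sensor fall study:
a cohort of subjects each performs a set of fall actions (four
trajectories: forward, backward, left, right, plus further variants) and
activities of daily living (lying, walking, standing, ...), several
repetitions each, wearing six sensor units with three tri-axial devices
(accelerometer, gyroscope, magnetometer) per unit.  One row is one
trial; features are per-channel summary statistics.  The defaults — 14
subjects, 20 fall actions, 16 ADLs, 5 repetitions — yield 2520 trials
with 216 features.  Signatures are Gaussian per action with
subject-level random offsets, and fall actions carry an extra shift on
the accelerometer channels so the two classes are learnably separable.

``generate_planted`` draws categorical rows uniformly over declared
attribute domains and labels them with a known rule tree, optionally
flipping labels with a configured noise probability — the ground-truth
recovery fixture for the rule learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import LabeledTable
from .ensemble import predict_rule
from .errors import ConfigurationError
from .rule_induction import RuleNode

__all__ = ["FallCohortConfig", "PlantedRuleConfig", "generate_fall_cohort",
           "generate_planted", "worked_example_table",
           "default_planted_config", "random_rule_tree"]


_FALL_NAMES = ["fall_forward", "fall_backward", "fall_left", "fall_right"]
_ADL_NAMES = ["lying", "walking", "standing"]
_UNIT_NAMES = ["head", "chest", "waist", "rwrist", "rthigh", "rankle"]
_DEVICE_NAMES = ["acc", "gyro", "mag"]
_AXIS_NAMES = ["x", "y", "z"]
_STAT_NAMES = ["mean", "std", "min", "max"]


def _names(base: list[str], n: int, prefix: str) -> list[str]:
    out = list(base[:n])
    out += [f"{prefix}{i + 1}" for i in range(len(out), n)]
    return out


@dataclass
class FallCohortConfig:
    """Structure of a synthetic fall-detection cohort.

    Total trials = n_subjects x (n_fall_actions + n_adl_actions) x
    repetitions; feature count = n_units x devices_per_unit x
    axes_per_device x stats_per_channel.
    """

    n_subjects: int = 14
    n_fall_actions: int = 20
    n_adl_actions: int = 16
    repetitions: int = 5
    n_units: int = 6
    devices_per_unit: int = 3
    axes_per_device: int = 3
    stats_per_channel: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_subjects, self.n_fall_actions, self.n_adl_actions,
                  self.repetitions, self.n_units, self.devices_per_unit,
                  self.axes_per_device, self.stats_per_channel)
        if any(c < 1 for c in counts):
            raise ConfigurationError("all cohort counts must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_subjects * (self.n_fall_actions + self.n_adl_actions) * self.repetitions

    @property
    def n_features(self) -> int:
        return (self.n_units * self.devices_per_unit * self.axes_per_device
                * self.stats_per_channel)


def generate_fall_cohort(config: FallCohortConfig = FallCohortConfig()) -> LabeledTable:
    """One row per (subject, action, repetition), fully seeded.

    Columns: the summary features, an auxiliary ``action_id`` naming the
    performed action (a perfect proxy for the class — drop it to model
    from the sensor features alone, or retarget on it for a multi-class
    problem), and the target ``action_class`` in {FALL, ADL}.
    """
    rng = np.random.default_rng(config.seed)
    units = _names(_UNIT_NAMES, config.n_units, "unit")
    devices = _names(_DEVICE_NAMES, config.devices_per_unit, "dev")
    axes = _names(_AXIS_NAMES, config.axes_per_device, "axis")
    stats = _names(_STAT_NAMES, config.stats_per_channel, "stat")
    feat_names = [f"{u}_{d}_{a}_{s}"
                  for u in units for d in devices for a in axes for s in stats]
    # falls announce themselves in accelerometer *dynamics*: the spread/peak
    # statistics of the acceleration channels, not their averages
    dyn_stats = {s for s in stats if s in ("std", "max")} or {stats[-1]}
    dyn_mask = np.array([d == devices[0] and s in dyn_stats
                         for u in units for d in devices
                         for a in axes for s in stats])

    actions = (_names(_FALL_NAMES, config.n_fall_actions, "fall_type")
               + _names(_ADL_NAMES, config.n_adl_actions, "adl_type"))
    classes = ["FALL"] * config.n_fall_actions + ["ADL"] * config.n_adl_actions

    n_actions, n_feat = len(actions), len(feat_names)
    # per-action Gaussian signatures; every fall action carries its own
    # impact magnitude on the dynamic accelerometer features, and some
    # ADLs (e.g. sitting down briskly) sit close to the fall boundary
    signature = rng.normal(0.0, 1.0, size=(n_actions, n_feat))
    for ai, cls in enumerate(classes):
        impact = rng.uniform(1.0, 2.0) if cls == "FALL" else rng.uniform(0.0, 0.4)
        signature[ai, dyn_mask] += impact
    subject_offset = rng.normal(0.0, 0.3, size=(config.n_subjects, n_feat))

    rows_feat, rows_action, rows_class = [], [], []
    for s in range(config.n_subjects):
        for ai in range(n_actions):
            noise = rng.normal(0.0, 0.8, size=(config.repetitions, n_feat))
            trial = signature[ai] + subject_offset[s] + noise
            rows_feat.append(trial)
            rows_action.extend([actions[ai]] * config.repetitions)
            rows_class.extend([classes[ai]] * config.repetitions)
    X = np.vstack(rows_feat)
    df = pd.DataFrame(X, columns=feat_names)
    df["action_id"] = rows_action
    df["action_class"] = rows_class
    return LabeledTable(df, "action_class",
                        provenance=f"synthetic fall cohort seed={config.seed}")


# ---------------------------------------------------------------------------
# Planted-rule tables
# ---------------------------------------------------------------------------

@dataclass
class PlantedRuleConfig:
    """A table whose labels come from a known rule tree plus label noise."""

    n_rows: int
    attribute_domains: list[tuple[str, list[str]]]
    planted_tree: RuleNode
    label_noise: float = 0.0
    target: str = "label"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise <= 1.0:
            raise ConfigurationError("label_noise must lie in [0, 1]")
        if self.n_rows < 1:
            raise ConfigurationError("n_rows must be >= 1")


def _tree_labels(node: RuleNode, acc: dict) -> None:
    if node.is_leaf:
        acc[node.class_value] = None
    else:
        for c in node.children:
            _tree_labels(c, acc)


def _validate_tree(node: RuleNode, domains: dict[str, list[str]]) -> None:
    if node.is_leaf:
        return
    if node.attribute not in domains:
        raise ConfigurationError(f"planted tree uses undeclared attribute {node.attribute!r}")
    for v in node.branch_values:
        if v not in domains[node.attribute]:
            raise ConfigurationError(
                f"planted tree branches on undeclared value {v!r} of {node.attribute!r}")
    for c in node.children:
        _validate_tree(c, domains)


def generate_planted(config: PlantedRuleConfig) -> LabeledTable:
    """Uniform rows over the domains, labeled by the planted tree.

    With probability ``label_noise`` a row's label is flipped to a
    uniformly chosen *different* label from the tree's label set.
    """
    domains = dict(config.attribute_domains)
    _validate_tree(config.planted_tree, domains)
    labels: dict = {}
    _tree_labels(config.planted_tree, labels)
    label_set = list(labels)
    rng = np.random.default_rng(config.seed)
    cols = {}
    for name, values in config.attribute_domains:
        cols[name] = rng.choice(np.asarray(values, dtype=object), size=config.n_rows)
    df = pd.DataFrame(cols)
    y = []
    for row in df.itertuples(index=False):
        y.append(predict_rule(config.planted_tree,
                              dict(zip(df.columns, row))))
    y = np.asarray(y, dtype=object)
    if config.label_noise > 0 and len(label_set) > 1:
        flip = rng.random(config.n_rows) < config.label_noise
        for i in np.flatnonzero(flip):
            others = [l for l in label_set if l != y[i]]
            y[i] = others[rng.integers(len(others))]
    df[config.target] = y
    return LabeledTable(df, config.target,
                        provenance=f"planted rule table seed={config.seed}")


def default_planted_config(n_rows: int = 1000, label_noise: float = 0.0,
                           seed: int = 0) -> PlantedRuleConfig:
    """A disease-style table: 4 three-valued symptom attributes, binary label.

    The planted tree reads at most two attributes per path, so a modest
    sample covers every reachable combination.
    """
    domains = [(f"symptom{i}", ["low", "mid", "high"]) for i in range(1, 5)]
    leaf = lambda v: RuleNode("leaf", "label", class_value=v, node_majority=v)
    sub1 = RuleNode("internal", "symptom2",
                    branch_values=["low", "mid", "high"],
                    children=[leaf("disease"), leaf("healthy"), leaf("disease")],
                    node_majority="disease")
    sub2 = RuleNode("internal", "symptom3",
                    branch_values=["low", "mid", "high"],
                    children=[leaf("healthy"), leaf("disease"), leaf("healthy")],
                    node_majority="healthy")
    tree = RuleNode("internal", "symptom1",
                    branch_values=["low", "mid", "high"],
                    children=[sub1, leaf("healthy"), sub2],
                    node_majority="healthy")
    return PlantedRuleConfig(n_rows=n_rows, attribute_domains=domains,
                             planted_tree=tree, label_noise=label_noise,
                             seed=seed)


def random_rule_tree(domains: list[tuple[str, list[str]]], labels: list[str],
                     rng: np.random.Generator, max_depth: int = 3,
                     target: str = "label") -> RuleNode:
    """A random total rule tree over the declared domains (for tests)."""
    def build(avail: list[int], depth: int) -> RuleNode:
        if not avail or depth >= max_depth or rng.random() < 0.3:
            lab = labels[rng.integers(len(labels))]
            return RuleNode("leaf", target, class_value=lab, node_majority=lab)
        ai = avail[rng.integers(len(avail))]
        name, values = domains[ai]
        rest = [a for a in avail if a != ai]
        children = [build(rest, depth + 1) for _ in values]
        return RuleNode("internal", name, branch_values=list(values),
                        children=children,
                        node_majority=labels[0])
    node = build(list(range(len(domains))), 0)
    if node.is_leaf and domains:  # ensure at least one split exists
        name, values = domains[0]
        lab0 = labels[0]
        lab1 = labels[-1]
        kids = [RuleNode("leaf", target, class_value=(lab0 if i % 2 == 0 else lab1),
                         node_majority=lab0) for i in range(len(values))]
        node = RuleNode("internal", name, branch_values=list(values),
                        children=kids, node_majority=lab0)
    return node


def worked_example_table() -> LabeledTable:
    """The fixed 8-trial categorical table used in the documentation.

    Two attributes describe a monitored person's state (``motion`` in
    {high, low}, ``posture`` in {lying, upright}); the target ``state``
    is fall/adl.  Its full induction trace (disorder amounts, scores,
    chosen split, final tree) is documented in docs/methods.md.
    """
    rows = [
        ("high", "lying", "fall"),
        ("high", "lying", "fall"),
        ("high", "upright", "adl"),
        ("high", "upright", "adl"),
        ("low", "lying", "adl"),
        ("low", "upright", "adl"),
        ("low", "lying", "adl"),
        ("high", "lying", "fall"),
    ]
    df = pd.DataFrame(rows, columns=["motion", "posture", "state"])
    return LabeledTable(df, "state", provenance="worked example")
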