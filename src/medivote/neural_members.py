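"""Neural ensemble members: two differently configured multilayer perceptrons.

The ensemble pairs the rule learner with two MLP members that must not
be copies of one model: member ``A`` uses a single hidden layer of width
``ceil((n_features + n_classes) / 2)`` with logistic activation (the
classic heuristic width), member ``B`` two hidden layers (64, 32) with
rectified activation.  Both consume the raw (encoded) feature table —
one-hot for categoricals, z-scored for numerics, fitted on training data
only — and are fully seeded: same config + data + seed reproduces the
same predictions.

Training is delegated to scikit-learn's ``MLPClassifier``; the fitted
weights are extracted so members serialize to plain JSON and predict via
an explicit forward pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import MISSING, LabeledTable
from .errors import SchemaError

__all__ = ["MemberConfig", "TableEncoder", "FittedMember",
           "train_member", "member_predict", "default_member_configs"]


@dataclass
class MemberConfig:
    """Hyperparameters of one MLP member.

    ``hidden_layout=None`` means "resolve at fit time" (member A's width
    depends on the encoded feature count).
    """

    member_id: str = "A"
    hidden_layout: tuple[int, ...] | None = None
    activation: str = "logistic"
    learning_rate: float = 1e-3
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layout is not None and len(self.hidden_layout) == 0:
            raise ValueError("hidden_layout must be non-empty when given")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_dict(self) -> dict:
        return {
            "member_id": self.member_id,
            "hidden_layout": list(self.hidden_layout) if self.hidden_layout else None,
            "activation": self.activation,
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MemberConfig":
        hl = d.get("hidden_layout")
        return cls(
            member_id=d["member_id"],
            hidden_layout=tuple(hl) if hl else None,
            activation=d["activation"],
            learning_rate=float(d["learning_rate"]),
            max_epochs=int(d["max_epochs"]),
            seed=int(d["seed"]),
        )


def default_member_configs(seed: int = 0) -> tuple[MemberConfig, MemberConfig]:
    """The two default heterogeneous members (seeds derived from ``seed``)."""
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    a = MemberConfig(member_id="A", hidden_layout=None, activation="logistic",
                     seed=int(ss[0]))
    b = MemberConfig(member_id="B", hidden_layout=(64, 32), activation="relu",
                     seed=int(ss[1]))
    return a, b


class TableEncoder:
    """Numeric feature encoding for a labeled table.

    Categorical columns become one-hot blocks over the categories seen in
    training (encounter order); tokens unseen at training time encode to
    an all-zeros block.  Numeric columns are z-scored with the training
    mean and standard deviation (a zero deviation falls back to 1), NaN
    imputed to the training mean.
    """

    def __init__(self) -> None:
        self.columns: list[str] = []
        self.kind: dict[str, str] = {}
        self.categories: dict[str, list[str]] = {}
        self.mean: dict[str, float] = {}
        self.std: dict[str, float] = {}

    def fit(self, table: LabeledTable) -> "TableEncoder":
        self.columns = list(table.other_attributes)
        for c in self.columns:
            if table.is_numeric(c):
                vals = table.df[c].to_numpy(float)
                vals = vals[~np.isnan(vals)]
                mu = float(vals.mean()) if len(vals) else 0.0
                sd = float(vals.std()) if len(vals) else 1.0
                self.kind[c] = "numeric"
                self.mean[c] = mu
                self.std[c] = sd if sd > 0 else 1.0
            else:
                self.kind[c] = "categorical"
                self.categories[c] = list(dict.fromkeys(
                    str(v) for v in table.df[c] if str(v) != MISSING))
        return self

    @property
    def n_features(self) -> int:
        return sum(1 if self.kind[c] == "numeric" else len(self.categories[c])
                   for c in self.columns)

    def transform(self, table: LabeledTable) -> np.ndarray:
        missing = [c for c in self.columns if c not in table.attributes]
        if missing:
            raise SchemaError(f"table lacks encoded column(s) {missing}")
        blocks = []
        for c in self.columns:
            if self.kind[c] == "numeric":
                if not table.is_numeric(c):
                    raise SchemaError(f"column {c!r} was numeric in training")
                v = table.df[c].to_numpy(float)
                v = np.where(np.isnan(v), self.mean[c], v)
                blocks.append(((v - self.mean[c]) / self.std[c])[:, None])
            else:
                cats = self.categories[c]
                index = {t: i for i, t in enumerate(cats)}
                block = np.zeros((table.n_rows, len(cats)))
                for r, tok in enumerate(table.df[c].astype(str)):
                    i = index.get(tok)
                    if i is not None:
                        block[r, i] = 1.0
                blocks.append(block)
        if not blocks:
            return np.zeros((table.n_rows, 0))
        out = np.hstack(blocks)
        if not np.isfinite(out).all():
            raise ValueError("non-finite feature after encoding")
        return out

    def to_dict(self) -> dict:
        return {
            "columns": self.columns, "kind": self.kind,
            "categories": self.categories, "mean": self.mean, "std": self.std,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TableEncoder":
        enc = cls()
        enc.columns = list(d["columns"])
        enc.kind = dict(d["kind"])
        enc.categories = {c: list(v) for c, v in d["categories"].items()}
        enc.mean = {c: float(v) for c, v in d["mean"].items()}
        enc.std = {c: float(v) for c, v in d["std"].items()}
        return enc


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "tanh":
        return np.tanh(z)
    if name == "identity":
        return z
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class FittedMember:
    """A trained MLP member (or degenerate constant predictor).

    Prediction runs an explicit forward pass over the stored weights, so
    a member round-trips losslessly through its JSON form.
    """

    config: MemberConfig
    label_vocabulary: list[str]
    encoder: TableEncoder
    classes: list[str] = field(default_factory=list)
    coefs: list[np.ndarray] = field(default_factory=list)
    intercepts: list[np.ndarray] = field(default_factory=list)
    constant: str | None = None

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        h = X
        for i, (W, b) in enumerate(zip(self.coefs, self.intercepts)):
            z = h @ W + b
            h = z if i == len(self.coefs) - 1 else _act(self.config.activation, z)
        return h

    def predict_encoded(self, X: np.ndarray) -> list[str]:
        if self.constant is not None:
            return [self.constant] * X.shape[0]
        out = self.decision_values(X)
        if out.shape[1] == 1:  # binary: single logit, threshold at 0
            idx = (out[:, 0] > 0).astype(int)
        else:
            idx = np.argmax(out, axis=1)
        return [self.classes[i] for i in idx]

    def predict(self, table: LabeledTable) -> list[str]:
        return self.predict_encoded(self.encoder.transform(table))

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "label_vocabulary": self.label_vocabulary,
            "encoder": self.encoder.to_dict(),
            "classes": self.classes,
            "coefs": [W.tolist() for W in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "constant": self.constant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedMember":
        return cls(
            config=MemberConfig.from_dict(d["config"]),
            label_vocabulary=list(d["label_vocabulary"]),
            encoder=TableEncoder.from_dict(d["encoder"]),
            classes=list(d["classes"]),
            coefs=[np.asarray(W, dtype=float) for W in d["coefs"]],
            intercepts=[np.asarray(b, dtype=float) for b in d["intercepts"]],
            constant=d.get("constant"),
        )


def train_member(table: LabeledTable, config: MemberConfig,
                 encoder: TableEncoder | None = None) -> FittedMember:
    """Train one MLP member on a labeled table.

    A single-class table yields a constant predictor of that class.  The
    default layout for member A (``hidden_layout=None``) resolves to one
    hidden layer of width ``ceil((n_features + n_classes) / 2)``.
    """
    if table.n_rows == 0:
        raise ValueError("train_member on an empty table")
    if encoder is None:
        encoder = TableEncoder().fit(table)
    vocab = [str(v) for v in table.target_values]
    y = [str(v) for v in table.column(table.target)]
    if len(vocab) == 1:
        return FittedMember(config=config, label_vocabulary=vocab,
                            encoder=encoder, constant=vocab[0])
    X = encoder.transform(table)
    layout = config.hidden_layout
    if layout is None:
        layout = (max(1, math.ceil((X.shape[1] + len(vocab)) / 2)),)
        config = replace(config, hidden_layout=layout)

    from sklearn.neural_network import MLPClassifier

    clf = MLPClassifier(
        hidden_layer_sizes=layout,
        activation=config.activation,
        learning_rate_init=config.learning_rate,
        max_iter=config.max_epochs,
        early_stopping=False,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return FittedMember(
        config=config,
        label_vocabulary=vocab,
        encoder=encoder,
        classes=[str(c) for c in clf.classes_],
        coefs=[np.asarray(W, dtype=float) for W in clf.coefs_],
        intercepts=[np.asarray(b, dtype=float) for b in clf.intercepts_],
    )


def member_predict(member: FittedMember, rows: LabeledTable) -> list[str]:
    """One label per row, each from the member's label vocabulary."""
    return member.predict(rows)
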