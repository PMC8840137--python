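"""Metric suite and the five-way classifier comparison harness.

Metrics are computed from an explicit confusion matrix whose predicted
axis may include an ABSTAIN column: an abstention counts as an error for
accuracy and never credits any class, so the reported numbers are
honest about undecided cases.  Macro averages (unweighted class means)
are the headline; class-frequency-weighted averages are reported
alongside, since either convention is common.

The comparison harness benchmarks the proposed rule + dual-MLP voting
ensemble against four stock classifiers — Gaussian Naive Bayes,
RBF-kernel SVM, k-nearest neighbours (k=5) and a single MLP ("ANN") —
under one shared stratified split (70/30 holdout by default, or
stratified k-fold with pooled predictions), all seeded.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import LabeledTable
from .ensemble import ABSTAIN, VoteResult, fit as fit_ensemble, predict as predict_ensemble
from .errors import ConfigurationError
from .neural_members import MemberConfig, TableEncoder

__all__ = ["MetricsReport", "compute_metrics", "ComparisonReport", "run_comparison"]


@dataclass
class MetricsReport:
    """Accuracy, per-class precision/recall/F and a full confusion matrix."""

    accuracy: float
    per_class: dict[str, dict[str, float]]  # label -> precision/recall/f_measure/support
    macro: dict[str, float]
    weighted: dict[str, float]
    confusion: pd.DataFrame  # rows = true labels, columns = predicted (may incl. ABSTAIN)
    n_test: int
    n_abstained: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro": self.macro,
            "weighted": self.weighted,
            "n_test": self.n_test,
            "n_abstained": self.n_abstained,
            "confusion": {t: dict(r) for t, r in self.confusion.iterrows()},
        }


def _as_labels(predicted) -> list[str]:
    out = []
    for p in predicted:
        out.append(p.final if isinstance(p, VoteResult) else str(p))
    return out


def compute_metrics(true_labels, predicted) -> MetricsReport:
    """Compute the full metric report for one prediction vector.

    ``predicted`` may be plain labels or :class:`VoteResult` objects (their
    ``final`` field is scored).  Abstentions count as errors and appear as
    a distinct predicted column in the confusion matrix; per-class
    precision/recall/F are computed over the true classes only.
    """
    y_true = [str(t) for t in true_labels]
    y_pred = _as_labels(predicted)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    n = len(y_true)
    classes = list(dict.fromkeys(y_true + [p for p in y_pred if p != ABSTAIN]))
    pred_cols = classes + ([ABSTAIN] if ABSTAIN in y_pred else [])
    cm = pd.DataFrame(0, index=classes, columns=pred_cols, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    per_class = {}
    for c in classes:
        tp = int(cm.loc[c, c]) if c in cm.columns else 0
        fp = int(cm[c].sum()) - tp if c in cm.columns else 0
        fn = int(cm.loc[c].sum()) - tp
        support = int(cm.loc[c].sum())
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[c] = {"precision": prec, "recall": rec,
                        "f_measure": f, "support": support}
    supports = np.array([per_class[c]["support"] for c in classes], dtype=float)
    weights = supports / supports.sum() if supports.sum() else supports
    macro, weighted = {}, {}
    for m in ("precision", "recall", "f_measure"):
        vals = np.array([per_class[c][m] for c in classes])
        macro[m] = float(vals.mean()) if len(vals) else 0.0
        weighted[m] = float((vals * weights).sum()) if len(vals) else 0.0
    accuracy = sum(t == p for t, p in zip(y_true, y_pred)) / n if n else 0.0
    return MetricsReport(
        accuracy=accuracy, per_class=per_class, macro=macro, weighted=weighted,
        confusion=cm, n_test=n, n_abstained=y_pred.count(ABSTAIN),
    )


# ---------------------------------------------------------------------------
# Comparison harness
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """One metric report per algorithm under a shared split."""

    rows: list[tuple[str, MetricsReport, float, dict]] = field(default_factory=list)
    protocol: str = "holdout"
    seed: int = 0

    def append(self, name: str, report: MetricsReport, seconds: float,
               params: dict) -> None:
        self.rows.append((name, report, seconds, params))

    def to_dataframe(self, include_timings: bool = False) -> pd.DataFrame:
        """Tabular summary; wall-clock timings are informational and kept
        out of the default table so reports are bit-for-bit reproducible."""
        recs = []
        for name, rep, secs, _ in self.rows:
            rec = {
                "Algorithm": name,
                "Accuracy (%)": round(100 * rep.accuracy, 1),
                "Precision (%)": round(100 * rep.macro["precision"], 1),
                "Recall (%)": round(100 * rep.macro["recall"], 1),
                "F-measure (%)": round(100 * rep.macro["f_measure"], 1),
                "Weighted F (%)": round(100 * rep.weighted["f_measure"], 1),
            }
            if include_timings:
                rec["Time (s)"] = round(secs, 3)
            recs.append(rec)
        return pd.DataFrame.from_records(recs)

    @property
    def timings(self) -> dict[str, float]:
        return {name: secs for name, _, secs, _ in self.rows}

    def to_markdown(self) -> str:
        df = self.to_dataframe()
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
        lines = [header, sep]
        for _, r in df.iterrows():
            lines.append("| " + " | ".join(str(v) for v in r) + " |")
        return "\n".join(lines) + "\n"

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv(index=False)


def _stratified_holdout(y: list[str], test_size: float, seed: int):
    from sklearn.model_selection import train_test_split
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_size, random_state=seed,
                              stratify=np.asarray(y, dtype=object))
    return np.sort(tr), np.sort(te)


def run_comparison(table: LabeledTable, protocol: str = "holdout",
                   seed: int = 0, k: int = 10, test_size: float = 0.3,
                   bin_count: int = 5,
                   member_configs: tuple[MemberConfig, MemberConfig] | None = None,
                   fallback: str = "abstain") -> ComparisonReport:
    """Benchmark the voting ensemble against four stock classifiers.

    All five algorithms see identical stratified train/test data (or
    identical folds); baselines consume the one-hot/z-score encoded
    features.  Baseline hyperparameters are library defaults and are
    recorded verbatim in the report for provenance.  Timings are
    informational only.
    """
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    y_all = [str(v) for v in table.column(table.target)]
    class_counts = pd.Series(y_all).value_counts()
    if len(class_counts) < 2:
        raise ConfigurationError("comparison needs at least two classes")
    if protocol not in ("holdout", "kfold"):
        raise ConfigurationError(f"unknown protocol {protocol!r}")
    if protocol == "kfold" and int(class_counts.min()) < k:
        raise ConfigurationError(
            f"class {class_counts.idxmin()!r} has {int(class_counts.min())} rows, "
            f"fewer than k={k} folds; reduce k or use protocol='holdout'")

    if protocol == "holdout":
        splits = [_stratified_holdout(y_all, test_size, seed)]
    else:
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = [(tr, te) for tr, te in
                  skf.split(np.zeros(len(y_all)), np.asarray(y_all, dtype=object))]

    baselines = [
        ("Naive Bayes", lambda: GaussianNB()),
        ("SVM", lambda: SVC(kernel="rbf")),
        ("KNN", lambda: KNeighborsClassifier(n_neighbors=5)),
        ("ANN", lambda: MLPClassifier(random_state=seed)),
    ]

    report = ComparisonReport(protocol=protocol, seed=seed)
    # pooled predictions across folds (a single pass for holdout)
    pooled: dict[str, list] = {name: [] for name, _ in baselines}
    pooled["AI rule+MLP vote ensemble"] = []
    pooled_true: list[str] = []
    timers: dict[str, float] = {name: 0.0 for name in pooled}
    params: dict[str, dict] = {}

    for tr, te in splits:
        train, test = table.subset(tr), table.subset(te)
        y_test = [str(v) for v in test.column(test.target)]
        pooled_true.extend(y_test)
        enc = TableEncoder().fit(train)
        X_tr, X_te = enc.transform(train), enc.transform(test)
        y_tr = [str(v) for v in train.column(train.target)]
        for name, make in baselines:
            clf = make()
            params[name] = {k2: str(v) for k2, v in clf.get_params().items()}
            t0 = time.perf_counter()
            import warnings
            with warnings.catch_warnings():
                from sklearn.exceptions import ConvergenceWarning
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X_tr, y_tr)
                pooled[name].extend(str(p) for p in clf.predict(X_te))
            timers[name] += time.perf_counter() - t0
        t0 = time.perf_counter()
        model = fit_ensemble(train, member_configs=member_configs,
                             bin_count=bin_count, seed=seed)
        votes = predict_ensemble(model, test, fallback=fallback)
        timers["AI rule+MLP vote ensemble"] += time.perf_counter() - t0
        pooled["AI rule+MLP vote ensemble"].extend(votes)
        params["AI rule+MLP vote ensemble"] = {
            "bin_count": str(bin_count), "fallback": fallback, "seed": str(seed)}

    for name, _ in baselines:
        report.append(name, compute_metrics(pooled_true, pooled[name]),
                      timers[name], params[name])
    name = "AI rule+MLP vote ensemble"
    report.append(name, compute_metrics(pooled_true, pooled[name]),
                  timers[name], params[name])
    return report
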