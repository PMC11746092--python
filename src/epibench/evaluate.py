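"""Metrics and the repeated-holdout evaluation protocol.

Evaluation follows a repeated random-split design: each cycle draws a
fresh stratified 60:40 train/test partition, fits the model on the 60%
and measures accuracy, AUC-ROC, AUC-PR, precision, recall and F1 on the
held-out portion. Neural families further split the 40% into equal
validation and independent-test halves; validation drives early stopping,
checkpoint selection and grid search, and metrics are reported on the
independent test half only. Aggregates are mean, standard deviation and a
normal-approximation 95% confidence interval over cycles.

Note this is repeated holdout, not k-fold cross-validation: partitions
are redrawn independently each cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split

from .models import (
    ClassifierSpec,
    FittedClassifier,
    build_classifier,
    grid_search,
    one_hot_encode,
)
from .simulate import Dataset, rng_for

__all__ = [
    "METRIC_NAMES",
    "MetricsReport",
    "binary_metrics",
    "cross_validate",
    "replicate_summary",
    "write_report",
    "read_report",
]

METRIC_NAMES = ("accuracy", "auc_roc", "auc_pr", "precision", "recall", "f1")


def binary_metrics(
    labels: np.ndarray,
    probabilities: np.ndarray,
    threshold: float = 0.5,
) -> dict[str, float]:
    """The six classification metrics at a probability threshold.

    AUC-ROC is the Mann-Whitney rank statistic with half credit for tied
    scores; AUC-PR is the step-wise (non-interpolated) precision-recall
    integral. Threshold-dependent metrics use ``probability >= threshold``.
    """
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if y.min() == y.max():
        raise ValueError("AUC undefined: only one class present in labels")
    pred = (p >= threshold).astype(int)
    return {
        "accuracy": float(accuracy_score(y, pred)),
        "auc_roc": float(roc_auc_score(y, p)),
        "auc_pr": float(average_precision_score(y, p)),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
        "f1": float(f1_score(y, pred, zero_division=0)),
    }


@dataclass
class MetricsReport:
    """Per-cycle metrics with mean / sd / 95% CI aggregates."""

    per_cycle: list[dict[str, float]]
    metadata: dict = field(default_factory=dict)

    @property
    def aggregate(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        n = len(self.per_cycle)
        for name in self.per_cycle[0]:
            vals = np.array([c[name] for c in self.per_cycle])
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            half = 1.96 * sd / np.sqrt(n)
            out[name] = {"mean": mean, "sd": sd,
                         "ci_low": mean - half, "ci_high": mean + half}
        return out

    def mean(self, metric: str) -> float:
        return self.aggregate[metric]["mean"]


def _stratified_split(y: np.ndarray, test_fraction: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(y.size)
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed)
    return train, test


def cross_validate(
    spec: ClassifierSpec | str,
    dataset: Dataset,
    cycles: int = 5,
    test_fraction: float = 0.4,
    seed: int = 0,
    threshold: float = 0.5,
    use_grid_search: bool = False,
) -> MetricsReport:
    """Repeated stratified holdout evaluation of one classifier family.

    Each cycle: fresh stratified split (default 60:40); neural families
    split the held-out fraction equally into validation and independent
    test subsets, with metrics reported on the independent half. With
    ``use_grid_search`` the spec's full hyperparameter grid is searched
    per cycle on the validation subset (non-neural families are then also
    given a validation subset to select on); otherwise family defaults
    are used.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if isinstance(spec, str):
        spec = ClassifierSpec(family=spec)
    y = np.asarray(dataset.labels)
    if y.min() == y.max():
        raise ValueError("dataset must contain both classes")
    x = one_hot_encode(dataset.genotypes)
    needs_val = spec.is_neural or use_grid_search
    per_cycle: list[dict[str, float]] = []
    for cycle in range(cycles):
        split_seed = int(rng_for(seed, "splits", cycle).integers(2**31))
        train_idx, held_idx = _stratified_split(y, test_fraction, split_seed)
        if needs_val:
            val_idx, test_idx = _stratified_split(
                y[held_idx], 0.5, split_seed + 1)
            val_idx, test_idx = held_idx[val_idx], held_idx[test_idx]
        else:
            val_idx, test_idx = None, held_idx
        x_train, y_train = x[train_idx], y[train_idx]
        x_test, y_test = x[test_idx], y[test_idx]
        if use_grid_search:
            fitted = grid_search(spec, None, x_train, y_train,
                                 x[val_idx], y[val_idx], seed=seed + cycle)
        else:
            clf = build_classifier(spec.family, protocol=spec.protocol)
            if val_idx is not None:
                clf.fit(x_train, y_train, x[val_idx], y[val_idx],
                        seed=seed + cycle)
            else:
                clf.fit(x_train, y_train, seed=seed + cycle)
            fitted = FittedClassifier(spec=spec, chosen_hyperparameters={},
                                      model=clf)
        per_cycle.append(binary_metrics(
            y_test, fitted.predict_proba(x_test), threshold))
    metadata = {
        "family": spec.family,
        "cycles": cycles,
        "test_fraction": test_fraction,
        "seed": seed,
        "grid_search": use_grid_search,
        "provenance": dict(dataset.provenance),
    }
    return MetricsReport(per_cycle=per_cycle, metadata=metadata)


def replicate_summary(
    reports: dict[str, list[MetricsReport]],
) -> pd.DataFrame:
    """Benchmark-table summary: model families x metrics, mean ± sd.

    ``reports`` maps family name to its per-replicate reports; each
    replicate contributes its cycle-mean, and the table shows the mean
    and standard deviation of those replicate means.
    """
    rows = []
    metric_sets = set()
    for family, family_reports in reports.items():
        if not family_reports:
            raise ValueError(f"no reports for family {family!r}")
        for rep in family_reports:
            metric_sets.add(tuple(sorted(rep.per_cycle[0])))
        if len(metric_sets) > 1:
            raise ValueError("reports carry inconsistent metric sets")
        row: dict[str, object] = {"family": family}
        for name in family_reports[0].per_cycle[0]:
            means = np.array([r.mean(name) for r in family_reports])
            row[f"{name}_mean"] = float(means.mean())
            row[f"{name}_sd"] = (float(means.std(ddof=1))
                                 if means.size > 1 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("family")


# -- serialization ---------------------------------------------------------

def write_report(report: MetricsReport, path: str | Path) -> None:
    """TSV of per-cycle metrics plus a JSON sidecar mirroring the report."""
    path = Path(path)
    frame = pd.DataFrame(report.per_cycle)
    frame.index.name = "cycle"
    frame.to_csv(path, sep="\t")
    payload = {"per_cycle": report.per_cycle, "aggregate": report.aggregate,
               "metadata": report.metadata}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(payload, indent=2, default=str))


def read_report(path: str | Path) -> MetricsReport:
    payload = json.loads(Path(path).with_suffix(
        Path(path).suffix + ".json").read_text())
    return MetricsReport(per_cycle=payload["per_cycle"],
                         metadata=payload.get("metadata", {}))
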