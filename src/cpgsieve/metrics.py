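"""Classification metrics: correct-classification rate, sensitivity, specificity.

The disease class (label 1) is the positive class, so sensitivity is the
detection rate among diseased samples and specificity the true-negative
rate among controls.  Metrics with an empty denominator are reported as
NaN ("undefined"), never as 0, and the repeated-holdout report excludes
undefined partitions from its means while counting the exclusions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifiers
from .classifiers import ClassifierSpec
from .data import BetaMatrix, LabelVector, SplitPlan, ValidationError

METRIC_NAMES = ("accuracy", "sensitivity", "specificity")


@dataclass
class ConfusionCounts:
    """Binary confusion counts with disease (label 1) as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count tp/fp/tn/fn from aligned truth and prediction vectors."""
    if isinstance(y_true, LabelVector):
        y_true = y_true.labels
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValidationError(f"length mismatch: {t.shape} truth vs {p.shape} predictions")
    for name, arr in (("y_true", t), ("y_pred", p)):
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity and specificity; NaN where undefined."""
    out: dict[str, float] = {}
    out["accuracy"] = (c.tp + c.tn) / c.total if c.total > 0 else math.nan
    pos = c.tp + c.fn
    out["sensitivity"] = c.tp / pos if pos > 0 else math.nan
    neg = c.tn + c.fp
    out["specificity"] = c.tn / neg if neg > 0 else math.nan
    return out


@dataclass
class HoldoutReport:
    """Mean and per-partition test-set metrics for a fixed CpG list."""

    per_partition: pd.DataFrame
    mean: dict[str, float]
    n_excluded: dict[str, int]

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table_path = out_dir / "metrics_per_partition.tsv"
        self.per_partition.to_csv(table_path, sep="\t", index=False)
        summary_path = out_dir / "metrics_summary.json"
        summary_path.write_text(
            json.dumps(
                {
                    "mean": {k: (None if math.isnan(v) else v) for k, v in self.mean.items()},
                    "n_excluded": self.n_excluded,
                    "n_partitions": int(len(self.per_partition)),
                },
                indent=2,
            )
        )
        return {"table": table_path, "summary": summary_path}


def repeated_holdout_report(
    bm: BetaMatrix,
    labels: LabelVector,
    cpgs: Sequence[str],
    plan: SplitPlan,
    spec: ClassifierSpec,
) -> HoldoutReport:
    """Train on each partition's training slice, report test-set metrics.

    Accuracy/sensitivity/specificity are computed on test samples only and
    averaged (unweighted) over partitions; per-partition values whose
    denominator is empty are excluded from the corresponding mean.
    """
    if len(cpgs) == 0:
        raise ValidationError("cpgs must be non-empty")
    idx = bm.column_index(cpgs)
    plan.validate_for(bm.n_samples)
    X = bm.values[:, idx]
    y = labels.labels
    rows = []
    for r, (train, test) in enumerate(plan.partitions):
        model = classifiers.train(spec, X[train], y[train], list(cpgs))
        pred = classifiers.predict(model, X[test])
        row = {"partition": r, "n_test": len(test)}
        row.update(metrics(confusion(y[test], pred)))
        rows.append(row)
    frame = pd.DataFrame(rows)
    mean: dict[str, float] = {}
    n_excluded: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = frame[name].to_numpy(dtype=float)
        defined = ~np.isnan(vals)
        n_excluded[name] = int((~defined).sum())
        mean[name] = float(vals[defined].mean()) if defined.any() else math.nan
    return HoldoutReport(per_partition=frame, mean=mean, n_excluded=n_excluded)
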