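"""Stage 1: per-CpG repeated-holdout screening.

Every CpG is scored individually: for each train/test partition of the
shared :class:`~cpgsieve.data.SplitPlan`, the classifier is trained on the
single CpG column and its test-set accuracy F is recorded; the per-CpG
score MF is the mean of F over the plan's repetitions.  CpGs with
MF >= MFc (the cutoff) survive to stage 2; only MF < MFc is excluded, so
a CpG sitting exactly on the cutoff is retained.

The same split plan is reused for every CpG (common random numbers) so MF
values are comparable across CpGs — comparability is the whole point of
the filter.  For the closed-form backends (logistic, threshold_stub,
majority_stub) all CpG columns of a partition are fitted simultaneously by
the batched solvers in :mod:`cpgsieve.classifiers`, which is what makes
screening hundreds of thousands of probes tractable on one CPU.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import classifiers
from .classifiers import ClassifierSpec
from .data import BetaMatrix, LabelVector, SplitPlan, ValidationError

logger = logging.getLogger(__name__)

#: Default stage-1 cutoff MFc.  The analysis that motivated this package
#: never reports the value it used; 0.70 is a conservative default and the
#: quantile mode (retain the top fraction of CpGs) is the alternative.
DEFAULT_CUTOFF = 0.70


class DegenerateResultError(RuntimeError):
    """A selection step produced an empty/unusable result."""


@dataclass
class ScreenResult:
    """Per-CpG mean holdout accuracies plus the cutoff-filtered list."""

    cpg_ids: list[str]
    mf: np.ndarray
    per_repeat_accuracy: np.ndarray | None
    cutoff: float | None
    retained_cpgs: list[str] | None
    plan: SplitPlan
    spec: ClassifierSpec

    @property
    def n_retained(self) -> int:
        return len(self.retained_cpgs) if self.retained_cpgs is not None else 0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"cpg_id": self.cpg_ids, "mf": self.mf})
        if self.retained_cpgs is not None:
            retained = set(self.retained_cpgs)
            frame["retained"] = [c in retained for c in self.cpg_ids]
        return frame


# ---------------------------------------------------------------------------
# Accuracy computation
# ---------------------------------------------------------------------------


def _batch_partition_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    spec: ClassifierSpec,
) -> np.ndarray:
    """Test accuracy of a single-feature classifier for every column of X."""
    y_train, y_test = y[train], y[test]
    n = X.shape[1]
    classes = np.unique(y_train)
    if len(classes) < 2:
        # constant-predictor fallback, identical for every CpG
        return np.full(n, float(np.mean(y_test == classes[0])))

    if spec.backend == "majority_stub":
        majority = 1 if (y_train == 1).sum() >= (y_train == 0).sum() else 0
        return np.full(n, float(np.mean(y_test == majority)))

    Xtr, Xte = X[train], X[test]
    if spec.backend == "threshold_stub":
        c0 = Xtr[y_train == 0].mean(axis=0)
        c1 = Xtr[y_train == 1].mean(axis=0)
        d0 = np.abs(Xte - c0[None, :])
        d1 = np.abs(Xte - c1[None, :])
        tot = d0 + d1
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(tot > 0, d0 / np.where(tot > 0, tot, 1.0), 0.5)
    elif spec.backend == "logistic":
        mean, sd = classifiers.standardize_stats(Xtr)
        b, w = classifiers.fit_logistic_1d_batch((Xtr - mean) / sd, y_train)
        score = classifiers._sigmoid(b[None, :] + (Xte - mean) / sd * w[None, :])
    else:
        raise ValueError(f"backend {spec.backend!r} has no batched path")
    pred = (score >= spec.decision_threshold).astype(int)
    return (pred == y_test[:, None]).mean(axis=0)


def _percpg_partition_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    spec: ClassifierSpec,
    feature_ids: Sequence[str],
) -> np.ndarray:
    """Generic (non-batched) route: one train/predict call per CpG."""
    acc = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, [j]]
        model = classifiers.train(spec, col[train], y[train], [feature_ids[j]])
        pred = classifiers.predict(model, col[test])
        acc[j] = float(np.mean(pred == y[test]))
    return acc


def _accuracy_matrix(
    X: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    spec: ClassifierSpec,
    feature_ids: Sequence[str],
) -> np.ndarray:
    """(n_repeats, n_cpgs) matrix of per-partition test accuracies F."""
    batched = spec.backend in ("logistic", "threshold_stub", "majority_stub")
    rows = []
    for train, test in plan.partitions:
        if batched:
            rows.append(_batch_partition_accuracy(X, y, train, test, spec))
        else:
            rows.append(_percpg_partition_accuracy(X, y, train, test, spec, feature_ids))
    return np.vstack(rows)


def score_single_cpg(
    bm: BetaMatrix,
    labels: LabelVector,
    cpg_id: str,
    plan: SplitPlan,
    spec: ClassifierSpec,
) -> tuple[float, np.ndarray]:
    """MF_i for one CpG: mean test accuracy over the plan's partitions.

    Returns ``(mf, per_repeat_accuracies)``.
    """
    idx = bm.column_index([cpg_id])
    plan.validate_for(bm.n_samples)
    if len(labels) != bm.n_samples:
        raise ValidationError("label length does not match sample count")
    acc = _accuracy_matrix(bm.values[:, idx], labels.labels, plan, spec, [cpg_id])[:, 0]
    return float(acc.mean()), acc


def screen_all(
    bm: BetaMatrix,
    labels: LabelVector,
    plan: SplitPlan,
    spec: ClassifierSpec,
    n_workers: int = 1,
    keep_per_repeat: bool = True,
    chunk_size: int = 2000,
) -> ScreenResult:
    """Score every CpG; returns MF aligned to ``bm.cpg_ids``.

    CpG columns are processed in contiguous chunks; each chunk's
    computation is independent of scheduling order (deterministic backends,
    fixed classifier seed), so the result is identical for any
    ``n_workers``.
    """
    plan.validate_for(bm.n_samples)
    if len(labels) != bm.n_samples:
        raise ValidationError("label length does not match sample count")
    n = bm.n_cpgs
    chunks = [
        (start, min(start + chunk_size, n)) for start in range(0, n, chunk_size)
    ]

    def one_chunk(start: int, stop: int) -> np.ndarray:
        t0 = time.perf_counter()
        acc = _accuracy_matrix(
            bm.values[:, start:stop],
            labels.labels,
            plan,
            spec,
            bm.cpg_ids[start:stop],
        )
        logger.info(
            "screened CpGs %d..%d (%.2fs)", start, stop - 1, time.perf_counter() - t0
        )
        return acc

    if n_workers > 1 and len(chunks) > 1:
        try:
            parts = Parallel(n_jobs=n_workers)(
                delayed(one_chunk)(a, b) for a, b in chunks
            )
        except Exception as exc:  # pragma: no cover - worker diagnostics
            raise RuntimeError(f"screening worker failed: {exc}") from exc
    else:
        parts = [one_chunk(a, b) for a, b in chunks]
    acc = np.hstack(parts)
    mf = acc.mean(axis=0)
    return ScreenResult(
        cpg_ids=list(bm.cpg_ids),
        mf=mf,
        per_repeat_accuracy=acc if keep_per_repeat else None,
        cutoff=None,
        retained_cpgs=None,
        plan=plan,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Cutoff filtering
# ---------------------------------------------------------------------------


def filter_by_cutoff(
    mf: np.ndarray, cpg_ids: Sequence[str], cutoff: float
) -> list[str]:
    """CpGs with MF >= cutoff, in input order (boundary values retained)."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError("cutoff must be in [0, 1]")
    mf = np.asarray(mf, dtype=float)
    if len(mf) != len(cpg_ids):
        raise ValidationError("mf length does not match cpg_ids")
    retained = [c for c, v in zip(cpg_ids, mf) if v >= cutoff]
    if not retained:
        raise DegenerateResultError(
            f"no CpGs reach MF >= {cutoff}; max MF is {mf.max():.4f} — "
            "lower the cutoff (or use the quantile mode)"
        )
    return retained


def top_fraction_cpgs(
    mf: np.ndarray, cpg_ids: Sequence[str], top_fraction: float
) -> tuple[list[str], float]:
    """Rank-based quantile filter: the top ``top_fraction`` of CpGs by MF.

    Retains exactly ``round(top_fraction * n)`` CpGs (at least one);
    ties at the boundary are broken by input order, which keeps the
    retained count fixed even when many noise CpGs share one MF value
    (common under class imbalance, where every uninformative CpG scores
    the majority-class accuracy).  Returns ``(retained_ids, cutoff)``
    where the cutoff is the smallest retained MF.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValidationError("top_fraction must be in (0, 1]")
    mf = np.asarray(mf, dtype=float)
    if len(mf) != len(cpg_ids):
        raise ValidationError("mf length does not match cpg_ids")
    k = max(1, int(np.floor(top_fraction * len(mf) + 0.5)))
    order = np.argsort(-mf, kind="stable")[:k]
    keep = np.sort(order)
    return [cpg_ids[i] for i in keep], float(mf[order[-1]])


def quantile_cutoff(mf: np.ndarray, top_fraction: float) -> float:
    """The effective MFc of the rank-based quantile filter (k-th largest MF)."""
    _, cutoff = top_fraction_cpgs(mf, [str(i) for i in range(len(mf))], top_fraction)
    return cutoff


def apply_cutoff(
    result: ScreenResult,
    cutoff: float | None = None,
    top_fraction: float | None = None,
) -> ScreenResult:
    """Attach a cutoff (explicit MFc, or rank-based quantile) to a ScreenResult."""
    if (cutoff is None) == (top_fraction is None):
        raise ValidationError("give exactly one of cutoff or top_fraction")
    if cutoff is None:
        retained, cutoff = top_fraction_cpgs(result.mf, result.cpg_ids, top_fraction)
        logger.info(
            "quantile filter: top %.1f%% -> %d CpGs, effective MFc=%.4f",
            100 * top_fraction,
            len(retained),
            cutoff,
        )
    else:
        retained = filter_by_cutoff(result.mf, result.cpg_ids, cutoff)
    logger.info("retained %d / %d CpGs at MFc=%.4f", len(retained), len(result.cpg_ids), cutoff)
    return ScreenResult(
        cpg_ids=result.cpg_ids,
        mf=result.mf,
        per_repeat_accuracy=result.per_repeat_accuracy,
        cutoff=float(cutoff),
        retained_cpgs=retained,
        plan=result.plan,
        spec=result.spec,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_screen_result(result: ScreenResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the MF table (TSV) and a JSON sidecar with the run settings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / "screen_mf.tsv"
    result.to_frame().to_csv(table_path, sep="\t", index=False)
    meta = {
        "cutoff": result.cutoff,
        "n_cpgs": len(result.cpg_ids),
        "n_retained": result.n_retained if result.retained_cpgs is not None else None,
        "plan": {
            "seed": result.plan.seed,
            "n_repeats": result.plan.n_repeats,
            "train_fraction": result.plan.train_fraction,
            "stratified": result.plan.stratified,
        },
        "classifier": result.spec.to_dict(),
    }
    meta_path = out_dir / "screen_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    paths = {"table": table_path, "meta": meta_path}
    if result.retained_cpgs is not None:
        retained_path = out_dir / "retained_cpgs.txt"
        retained_path.write_text("\n".join(result.retained_cpgs) + "\n")
        paths["retained"] = retained_path
    return paths
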