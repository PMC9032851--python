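"""Stage 2: randomized greedy backward elimination over the retained CpGs.

Starting from the stage-1 list, each iteration removes one CpG chosen
uniformly at random, re-estimates the subset's mean holdout accuracy MF**
on the same split plan, and keeps the removal only if MF** strictly
exceeds the incumbent accuracy MF* (ties reject).  The search stops at
``itermax`` iterations, when the incumbent accuracy reaches the target
MFp, or when the list would shrink below ``min_subset_size``.

Because accepted moves require strict improvement, the incumbent accuracy
trajectory is strictly increasing and the subset chain is nested — both
are asserted by the test suite on full histories.

The incumbent and every candidate are evaluated on the identical split
plan (common random numbers), so an accept decision reflects the removed
CpG rather than split noise.  The stopping target is interpreted as
"stop once the desired accuracy level has been achieved"
(MFcurrent >= MFp): the incumbent never decreases, so a lower bound is
the only direction under which the target can act as a stopping rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifiers
from .classifiers import ClassifierSpec
from .data import BetaMatrix, LabelVector, SplitPlan, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Stopping rules and randomness for the elimination search."""

    itermax: int = 300
    mf_target: float = 0.95
    min_subset_size: int = 1
    seed: int = 0
    reevaluate_incumbent: bool = False

    def __post_init__(self) -> None:
        if self.itermax < 1:
            raise ValidationError("itermax must be >= 1")
        if not (0.0 <= self.mf_target <= 1.0):
            raise ValidationError("mf_target must be in [0, 1]")
        if self.min_subset_size < 1:
            raise ValidationError("min_subset_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HistoryRecord:
    iteration: int
    removed_cpg: str
    candidate_mf: float
    accepted: bool


@dataclass
class SearchState:
    """Current subset, its accuracy, and the accept/reject history."""

    current_cpgs: list[str]
    mf_current: float
    history: list[HistoryRecord] = field(default_factory=list)
    iteration: int = 0

    @property
    def accepted_mfs(self) -> list[float]:
        return [h.candidate_mf for h in self.history if h.accepted]

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": h.iteration,
                    "removed_cpg": h.removed_cpg,
                    "candidate_mf": h.candidate_mf,
                    "accepted": h.accepted,
                }
                for h in self.history
            ],
            columns=["iteration", "removed_cpg", "candidate_mf", "accepted"],
        )


# ---------------------------------------------------------------------------
# Subset evaluation
# ---------------------------------------------------------------------------


def evaluate_subset(
    bm: BetaMatrix,
    labels: LabelVector,
    cpgs: Sequence[str],
    plan: SplitPlan,
    spec: ClassifierSpec,
) -> float:
    """Mean holdout accuracy MF* of the classifier on a CpG subset."""
    if len(cpgs) == 0:
        raise ValidationError("cpgs must be non-empty")
    idx = bm.column_index(cpgs)
    plan.validate_for(bm.n_samples)
    X = bm.values[:, idx]
    y = labels.labels
    accs = []
    for train, test in plan.partitions:
        model = classifiers.train(spec, X[train], y[train], list(cpgs))
        pred = classifiers.predict(model, X[test])
        accs.append(float(np.mean(pred == y[test])))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


def elimination_step(
    state: SearchState,
    bm: BetaMatrix,
    labels: LabelVector,
    plan: SplitPlan,
    spec: ClassifierSpec,
    rng: np.random.Generator,
    min_subset_size: int = 1,
    reevaluate_incumbent: bool = False,
) -> SearchState:
    """One elimination attempt: drop a random CpG, accept iff it improves.

    Mutates and returns ``state``; a history record is appended whether or
    not the move is accepted, and the iteration counter always advances.
    """
    if len(state.current_cpgs) <= min_subset_size:
        raise ValidationError(
            f"subset already at minimum size {min_subset_size}; cannot eliminate"
        )
    if reevaluate_incumbent:
        state.mf_current = evaluate_subset(bm, labels, state.current_cpgs, plan, spec)
    drop_pos = int(rng.integers(len(state.current_cpgs)))
    removed = state.current_cpgs[drop_pos]
    candidate = state.current_cpgs[:drop_pos] + state.current_cpgs[drop_pos + 1 :]
    candidate_mf = evaluate_subset(bm, labels, candidate, plan, spec)
    accepted = candidate_mf > state.mf_current  # ties reject
    state.iteration += 1
    state.history.append(
        HistoryRecord(state.iteration, removed, candidate_mf, accepted)
    )
    if accepted:
        logger.info(
            "iter %d: removed %s, MF %.4f -> %.4f (%d CpGs left)",
            state.iteration,
            removed,
            state.mf_current,
            candidate_mf,
            len(candidate),
        )
        state.current_cpgs = candidate
        state.mf_current = candidate_mf
    return state


def run_search(
    bm: BetaMatrix,
    labels: LabelVector,
    initial_cpgs: Sequence[str],
    plan: SplitPlan,
    spec: ClassifierSpec,
    cfg: SearchConfig,
) -> SearchState:
    """Run the elimination search from the stage-1 list to completion."""
    if len(initial_cpgs) == 0:
        raise ValidationError("initial_cpgs must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    mf0 = evaluate_subset(bm, labels, initial_cpgs, plan, spec)
    state = SearchState(current_cpgs=list(initial_cpgs), mf_current=mf0)
    logger.info("search start: %d CpGs, MF*=%.4f", len(initial_cpgs), mf0)
    while (
        state.iteration < cfg.itermax
        and state.mf_current < cfg.mf_target
        and len(state.current_cpgs) > cfg.min_subset_size
    ):
        elimination_step(
            state,
            bm,
            labels,
            plan,
            spec,
            rng,
            min_subset_size=cfg.min_subset_size,
            reevaluate_incumbent=cfg.reevaluate_incumbent,
        )
    n_acc = sum(h.accepted for h in state.history)
    logger.info(
        "search done after %d iterations: %d accepted, %d CpGs, MF=%.4f",
        state.iteration,
        n_acc,
        len(state.current_cpgs),
        state.mf_current,
    )
    return state


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_search_state(
    state: SearchState,
    out_dir: str | Path,
    cfg: SearchConfig | None = None,
    spec: ClassifierSpec | None = None,
    plan: SplitPlan | None = None,
) -> dict[str, Path]:
    """Write the final CpG list, the accept/reject history, and metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    list_path = out_dir / "selected_cpgs.txt"
    list_path.write_text("\n".join(state.current_cpgs) + "\n")
    history_path = out_dir / "search_history.tsv"
    state.history_frame().to_csv(history_path, sep="\t", index=False)
    meta = {
        "n_selected": len(state.current_cpgs),
        "mf_current": state.mf_current,
        "iterations": state.iteration,
        "n_accepted": sum(h.accepted for h in state.history),
        "incumbent_trajectory": state.accepted_mfs,
        "config": cfg.to_dict() if cfg is not None else None,
        "classifier": spec.to_dict() if spec is not None else None,
        "plan": (
            {
                "seed": plan.seed,
                "n_repeats": plan.n_repeats,
                "train_fraction": plan.train_fraction,
                "stratified": plan.stratified,
            }
            if plan is not None
            else None
        ),
    }
    meta_path = out_dir / "search_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"list": list_path, "history": history_path, "meta": meta_path}
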