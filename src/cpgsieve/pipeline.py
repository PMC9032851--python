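"""End-to-end workflow: screen -> select -> evaluate.

Two performance estimates are produced, because wrapper selection run on
all samples is optimistic about its own accuracy:

* **Nested (held-out) metrics** — the headline numbers.  For each outer
  fold the samples are split into a development set and an untouched test
  set; *both* selection stages run on the development samples only, a
  final classifier is trained on them, and metrics are computed on the
  untouched test samples.  Selection never sees these test sets, so no
  selection-induced optimism can leak into the report.
* **Selection-protocol report** — repeated-holdout metrics of the final
  CpG list over fresh splits of all samples.  This mirrors the protocol
  under which the list was found (and is therefore optimistic); it is
  written alongside, clearly labelled.

The final CpG list itself is produced by running both stages on all
samples, which uses the data fully once an unbiased performance estimate
is in hand.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifiers, screen, search
from .config import RunConfig, substream_seed
from .data import (
    BetaMatrix,
    LabelVector,
    drop_incomplete_cpgs,
    make_split_plan,
)
from .metrics import (
    METRIC_NAMES,
    HoldoutReport,
    confusion,
    metrics as compute_metrics,
    repeated_holdout_report,
)
from .screen import ScreenResult
from .search import SearchState

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    final_cpgs: list[str]
    final_mf: float  # incumbent accuracy of the full-data search (optimistic)
    screen_result: ScreenResult
    search_state: SearchState
    fold_metrics: pd.DataFrame
    holdout_mean: dict[str, float]  # nested, unbiased
    holdout_excluded: dict[str, int]
    selection_report: HoldoutReport | None

    def summary(self) -> dict:
        return {
            "n_selected": len(self.final_cpgs),
            "final_mf": self.final_mf,
            "holdout_mean": {
                k: (None if math.isnan(v) else v) for k, v in self.holdout_mean.items()
            },
            "holdout_excluded": self.holdout_excluded,
            "n_outer_folds": int(len(self.fold_metrics)),
            "selection_protocol_mean": (
                {
                    k: (None if math.isnan(v) else v)
                    for k, v in self.selection_report.mean.items()
                }
                if self.selection_report is not None
                else None
            ),
        }


def _select_on(
    bm: BetaMatrix,
    labels: LabelVector,
    cfg: RunConfig,
    plan_seed: int,
    search_seed: int,
    classifier_seed: int,
) -> tuple[ScreenResult, SearchState]:
    """Run both selection stages on the given samples."""
    plan = make_split_plan(
        bm.n_samples,
        labels,
        n_repeats=cfg.n_repeats,
        train_fraction=cfg.train_fraction,
        seed=plan_seed,
        stratified=cfg.stratified,
    )
    screen_spec = replace(cfg.screen_spec, seed=classifier_seed)
    select_spec = replace(cfg.select_spec, seed=classifier_seed)
    result = screen.screen_all(bm, labels, plan, screen_spec, n_workers=cfg.n_workers)
    result = screen.apply_cutoff(
        result, cutoff=cfg.cutoff, top_fraction=cfg.top_fraction
    )
    search_cfg = replace(cfg.search, seed=search_seed)
    state = search.run_search(
        bm, labels, result.retained_cpgs, plan, select_spec, search_cfg
    )
    return result, state


def run_pipeline(
    bm: BetaMatrix,
    labels: LabelVector,
    cfg: RunConfig,
    with_selection_report: bool = True,
) -> PipelineResult:
    """Full workflow on an in-memory dataset; see the module docstring."""
    bm, cleaning = drop_incomplete_cpgs(bm)
    if cleaning.n_removed:
        logger.info("dropped %d CpGs with missing values", cleaning.n_removed)

    # --- nested evaluation: selection confined to development samples ----
    rows = []
    for fold in range(cfg.n_outer_folds):
        outer = make_split_plan(
            bm.n_samples,
            labels,
            n_repeats=1,
            train_fraction=cfg.train_fraction,
            seed=substream_seed(cfg.seed, "outer_split", (fold + 1,)),
            stratified=cfg.stratified,
        )
        dev_idx, test_idx = outer.partitions[0]
        bm_dev = bm.subset_samples(dev_idx)
        labels_dev = LabelVector(labels.labels[dev_idx], labels.class_names)
        _, fold_state = _select_on(
            bm_dev,
            labels_dev,
            cfg,
            plan_seed=substream_seed(cfg.seed, "inner_plan", (fold + 1,)),
            search_seed=substream_seed(cfg.seed, "search", (fold + 1,)),
            classifier_seed=substream_seed(cfg.seed, "classifier", (fold + 1,)),
        )
        spec = replace(
            cfg.select_spec, seed=substream_seed(cfg.seed, "classifier", (fold + 1,))
        )
        idx = bm.column_index(fold_state.current_cpgs)
        model = classifiers.train(
            spec,
            bm.values[np.ix_(dev_idx, idx)],
            labels.labels[dev_idx],
            fold_state.current_cpgs,
        )
        pred = classifiers.predict(model, bm.values[np.ix_(test_idx, idx)])
        row = {"fold": fold, "n_selected": len(fold_state.current_cpgs)}
        row.update(compute_metrics(confusion(labels.labels[test_idx], pred)))
        rows.append(row)
        logger.info(
            "outer fold %d: %d CpGs, held-out accuracy %.3f",
            fold,
            row["n_selected"],
            row["accuracy"],
        )
    fold_frame = pd.DataFrame(rows)
    holdout_mean: dict[str, float] = {}
    holdout_excluded: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = fold_frame[name].to_numpy(dtype=float)
        defined = ~np.isnan(vals)
        holdout_excluded[name] = int((~defined).sum())
        holdout_mean[name] = float(vals[defined].mean()) if defined.any() else math.nan

    # --- final selection on all samples ----------------------------------
    screen_result, state = _select_on(
        bm,
        labels,
        cfg,
        plan_seed=substream_seed(cfg.seed, "inner_plan", (0,)),
        search_seed=substream_seed(cfg.seed, "search", (0,)),
        classifier_seed=substream_seed(cfg.seed, "classifier", (0,)),
    )

    selection_report = None
    if with_selection_report:
        report_plan = make_split_plan(
            bm.n_samples,
            labels,
            n_repeats=cfg.n_repeats,
            train_fraction=cfg.train_fraction,
            seed=substream_seed(cfg.seed, "report_plan", (0,)),
            stratified=cfg.stratified,
        )
        spec = replace(
            cfg.select_spec, seed=substream_seed(cfg.seed, "classifier", (0,))
        )
        selection_report = repeated_holdout_report(
            bm, labels, state.current_cpgs, report_plan, spec
        )

    return PipelineResult(
        final_cpgs=list(state.current_cpgs),
        final_mf=state.mf_current,
        screen_result=screen_result,
        search_state=state,
        fold_metrics=fold_frame,
        holdout_mean=holdout_mean,
        holdout_excluded=holdout_excluded,
        selection_report=selection_report,
    )


def save_pipeline_result(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths.update(screen.save_screen_result(result.screen_result, out_dir))
    paths.update(search.save_search_state(result.search_state, out_dir))
    fold_path = out_dir / "outer_fold_metrics.tsv"
    result.fold_metrics.to_csv(fold_path, sep="\t", index=False)
    paths["folds"] = fold_path
    if result.selection_report is not None:
        paths.update(result.selection_report.save(out_dir))
    summary_path = out_dir / "pipeline_summary.json"
    summary_path.write_text(json.dumps(result.summary(), indent=2))
    paths["summary"] = summary_path
    return paths
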