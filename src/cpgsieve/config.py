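"""Run configuration and seed bookkeeping.

All randomness in a run derives from one global seed through named
substreams (synthesis, inner split plans, classifier initialisation, the
elimination search, outer evaluation splits, the final report plan), so
each stage is independently reproducible and no two stages share a random
stream by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .classifiers import ClassifierSpec
from .data import ValidationError
from .search import SearchConfig
from .simulate import SynthSpec

SEED_STREAMS = {
    "synthesis": 0,
    "inner_plan": 1,
    "classifier": 2,
    "search": 3,
    "outer_split": 4,
    "report_plan": 5,
}


def substream_seed(seed: int, stream: str, extra: Sequence[int] = ()) -> int:
    """Derive a child seed (< 2^31) for a named random substream."""
    if stream not in SEED_STREAMS:
        raise ValidationError(f"unknown seed stream {stream!r}")
    entropy = [int(seed), SEED_STREAMS[stream], *[int(e) for e in extra]]
    if any(e < 0 for e in entropy):
        raise ValidationError("seed stream entropy must be non-negative")
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def _default_screen_spec() -> ClassifierSpec:
    # single-feature inputs cannot exploit depth; logistic is the
    # documented fast screening default (mlp remains available)
    return ClassifierSpec(backend="logistic", n_hidden_layers=1)


def _default_select_spec() -> ClassifierSpec:
    return ClassifierSpec(backend="logistic", n_hidden_layers=4)


@dataclass
class RunConfig:
    """End-to-end workflow configuration (YAML-serializable)."""

    # input paths (None -> synthesize the default scenario)
    beta_path: str | None = None
    labels_path: str | None = None
    covariates_path: str | None = None
    orientation: str = "cpgs_in_rows"

    # repeated-holdout scheme shared by both stages
    n_repeats: int = 10
    train_fraction: float = 2 / 3
    stratified: bool = True

    # classifiers (stage 1 screening / stage 2 + final evaluation)
    screen_spec: ClassifierSpec = field(default_factory=_default_screen_spec)
    select_spec: ClassifierSpec = field(default_factory=_default_select_spec)

    # stage-1 cutoff: explicit MFc, or quantile mode (top_fraction set)
    cutoff: float | None = 0.70
    top_fraction: float | None = None

    # stage-2 search
    search: SearchConfig = field(default_factory=SearchConfig)

    # nested evaluation: selection re-run per outer fold on the
    # development samples only; metrics on the untouched outer test set
    n_outer_folds: int = 5

    # synthesis (used when no input paths are given)
    synth: SynthSpec = field(default_factory=SynthSpec)

    n_workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff is not None and self.top_fraction is not None:
            raise ValidationError("set either cutoff or top_fraction, not both")
        if self.cutoff is None and self.top_fraction is None:
            raise ValidationError("one of cutoff or top_fraction is required")
        if self.n_outer_folds < 1:
            raise ValidationError("n_outer_folds must be >= 1")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        for path_attr in ("beta_path", "labels_path", "covariates_path"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{path_attr} does not exist: {p}")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["screen_spec"] = self.screen_spec.to_dict()
        d["select_spec"] = self.select_spec.to_dict()
        d["search"] = self.search.to_dict()
        d["synth"] = self.synth.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "screen_spec" in d and isinstance(d["screen_spec"], dict):
            d["screen_spec"] = ClassifierSpec.from_dict(d["screen_spec"])
        if "select_spec" in d and isinstance(d["select_spec"], dict):
            d["select_spec"] = ClassifierSpec.from_dict(d["select_spec"])
        if "search" in d and isinstance(d["search"], dict):
            d["search"] = SearchConfig(**d["search"])
        if "synth" in d and isinstance(d["synth"], dict):
            synth = dict(d["synth"])
            if "baseline_mean_range" in synth:
                synth["baseline_mean_range"] = tuple(synth["baseline_mean_range"])
            d["synth"] = SynthSpec(**synth)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
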