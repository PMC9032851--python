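"""Synthetic methylation data with planted class structure.

Emulates, at reduced scale, the shape of the blood-methylation cohort the
pipeline targets: 76 samples (24 healthy controls vs 52 disease cases —
pre-manifest and manifest carriers pooled) with array-style beta values
per CpG.  Real arrays measure ~485k CpGs; the default here is 2,000 so the
full two-stage workflow runs in seconds while preserving the
high-dimensional, mostly-noise character of the problem.

Each CpG's beta values are Beta-distributed, parameterized by a mean and
a concentration c (shape parameters ``a = mean*c``, ``b = (1-mean)*c``).
Noise CpGs share one per-CpG baseline mean across both classes;
informative CpGs shift the case-class mean by ``effect`` (sign randomized
per CpG, shifted means kept inside (0.02, 0.98)).  The generator knows
nothing about probe-type chemistry, batch effects or cell-composition
confounding — see the methods note for what that implies about tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np

from .data import BetaMatrix, LabelVector, ValidationError, write_beta_matrix, write_labels

logger = logging.getLogger(__name__)

#: Shifted means are kept inside this open interval before Beta
#: parameterization, so both shape parameters stay strictly positive.
MEAN_CLIP = (0.02, 0.98)


@dataclass
class SynthSpec:
    """Scenario parameters for the planted-effect generator.

    Defaults mirror the target cohort composition (24 controls, 52 cases)
    at a 2,000-CpG scale with 25 informative probes shifted by 0.25 in
    beta space — a strong but realistic disease-associated differential
    methylation signal given concentration 30 (per-CpG standard deviation
    ~0.09 at mid-range means).
    """

    m_control: int = 24
    m_case: int = 52
    n_cpgs: int = 2000
    n_informative: int = 25
    effect: float = 0.25
    concentration: float = 30.0
    baseline_mean_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_control < 1 or self.m_case < 1:
            raise ValidationError("need at least one sample per class")
        if self.n_cpgs < 1:
            raise ValidationError("n_cpgs must be >= 1")
        if not (0 <= self.n_informative <= self.n_cpgs):
            raise ValidationError("n_informative must be in [0, n_cpgs]")
        if self.effect < 0:
            raise ValidationError("effect must be non-negative")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        lo, hi = self.baseline_mean_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("baseline_mean_range must satisfy 0 < lo < hi < 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_mean_range"] = list(self.baseline_mean_range)
        return d


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, conc: float, size) -> np.ndarray:
    a = mean * conc
    b = (1.0 - mean) * conc
    return rng.beta(a, b, size=size)


def generate(spec: SynthSpec) -> tuple[BetaMatrix, LabelVector, list[str]]:
    """Generate (beta matrix, labels, ground-truth informative CpG ids).

    Controls occupy the first ``m_control`` rows (label 0), cases the rest
    (label 1).  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.m_control + spec.m_case
    lo, hi = spec.baseline_mean_range

    baseline = rng.uniform(lo, hi, size=spec.n_cpgs)
    informative_idx = np.sort(
        rng.choice(spec.n_cpgs, size=spec.n_informative, replace=False)
    )
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)

    clip_lo, clip_hi = MEAN_CLIP
    case_mean = baseline.copy()
    for k, (j, sign) in enumerate(zip(informative_idx, signs)):
        shifted = baseline[j] + sign * spec.effect
        if not (clip_lo <= shifted <= clip_hi):
            shifted = baseline[j] - sign * spec.effect  # flip toward the open side
        if not (clip_lo <= shifted <= clip_hi):
            raise ValidationError(
                f"effect {spec.effect} is infeasible for baseline mean "
                f"{baseline[j]:.3f} at CpG index {j} (means clipped to {MEAN_CLIP})"
            )
        case_mean[j] = shifted

    labels = np.concatenate(
        [np.zeros(spec.m_control, dtype=int), np.ones(spec.m_case, dtype=int)]
    )
    values = np.empty((m, spec.n_cpgs))
    values[labels == 0] = _beta_draw(
        rng, baseline[None, :], spec.concentration, (spec.m_control, spec.n_cpgs)
    )
    values[labels == 1] = _beta_draw(
        rng, case_mean[None, :], spec.concentration, (spec.m_case, spec.n_cpgs)
    )

    cpg_ids = [f"cg{j:08d}" for j in range(spec.n_cpgs)]
    sample_ids = [f"S{i + 1:04d}" for i in range(m)]
    truth = [cpg_ids[j] for j in informative_idx]
    logger.info(
        "generated %d x %d beta matrix (%d informative CpGs, effect %.2f)",
        m,
        spec.n_cpgs,
        spec.n_informative,
        spec.effect,
    )
    return BetaMatrix(values, cpg_ids, sample_ids), LabelVector(labels), truth


def generate_premanifest_scenario(
    spec: SynthSpec | None = None, effect: float = 0.15
) -> tuple[BetaMatrix, LabelVector, list[str]]:
    """The harder companion scenario: controls vs pre-manifest carriers only.

    24 controls vs 19 cases with a smaller default mean shift (0.15),
    reflecting the expectation that methylation differences are weaker
    before symptom onset.
    """
    base = spec if spec is not None else SynthSpec()
    premanifest = replace(base, m_control=24, m_case=19, effect=effect)
    return generate(premanifest)


def write_scenario(
    bm: BetaMatrix,
    labels: LabelVector,
    truth: list[str],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write beta.tsv (CpGs in rows), labels.tsv and truth_cpgs.txt."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    beta_path = out_dir / "beta.tsv"
    labels_path = out_dir / "labels.tsv"
    truth_path = out_dir / "truth_cpgs.txt"
    write_beta_matrix(bm, beta_path)
    write_labels(labels, bm.sample_ids, labels_path)
    truth_path.write_text("\n".join(truth) + ("\n" if truth else ""))
    return {"beta": beta_path, "labels": labels_path, "truth": truth_path}
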