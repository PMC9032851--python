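"""Core data containers and I/O for methylation beta matrices.

The pipeline consumes a samples x CpGs matrix of methylation beta values
(fractions in [0, 1]; 1 = fully methylated) together with a binary
per-sample disease label (0 = control, 1 = disease).  This module defines
the validated containers (:class:`BetaMatrix`, :class:`LabelVector`,
:class:`SplitPlan`, :class:`CovariateTable`), the TSV/CSV readers and
writers, and the reproducible repeated-holdout partitioning scheme that
both selection stages share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tolerance for beta values marginally outside [0, 1] (floating point dust).
BETA_BOUND_TOL = 1e-9

#: Default class-name mapping: 0 is healthy control, 1 is disease.
DEFAULT_CLASS_NAMES = {0: "Control", 1: "Huntington"}

#: Accepted spellings for each class when parsing label files (lower-cased).
DEFAULT_LABEL_SYNONYMS: Mapping[str, int] = {
    "0": 0,
    "control": 0,
    "healthy": 0,
    "1": 1,
    "huntington": 1,
    "hd": 1,
    "disease": 1,
    "case": 1,
}


class ValidationError(ValueError):
    """Input data violates a container invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Samples x CpGs matrix of methylation fractions.

    Parameters
    ----------
    values
        Float array of shape ``(m_samples, n_cpgs)``.  Every entry must be
        in ``[0, 1]`` (within :data:`BETA_BOUND_TOL`) or NaN; NaNs are
        permitted until :func:`drop_incomplete_cpgs` is applied.
    cpg_ids
        Unique CpG identifiers (e.g. ``"cg00000029"``), one per column.
    sample_ids
        Unique sample identifiers, one per row.
    """

    values: np.ndarray
    cpg_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError(
                f"beta matrix must be 2-dimensional, got shape {self.values.shape}"
            )
        m, n = self.values.shape
        if len(self.sample_ids) != m:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {m} rows"
            )
        if len(self.cpg_ids) != n:
            raise ValidationError(f"{len(self.cpg_ids)} CpG ids for {n} columns")
        for kind, ids in (("sample", self.sample_ids), ("CpG", self.cpg_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {kind} ids: {dupes[:10]}")
        with np.errstate(invalid="ignore"):
            bad = (self.values < -BETA_BOUND_TOL) | (self.values > 1 + BETA_BOUND_TOL)
        bad |= np.isinf(self.values)
        if bad.any():
            rows, cols = np.nonzero(bad)
            offenders = [
                f"({self.sample_ids[r]}, {self.cpg_ids[c]}) = {self.values[r, c]!r}"
                for r, c in list(zip(rows, cols))[:10]
            ]
            raise ValidationError(
                f"{bad.sum()} beta value(s) outside [0, 1]: " + "; ".join(offenders)
            )
        # snap floating-point dust onto the bounds
        np.clip(self.values, 0.0, 1.0, out=self.values)

    # -- convenience --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def column_index(self, cpg_ids: Sequence[str]) -> np.ndarray:
        """Positions of ``cpg_ids`` in column order, erroring on unknowns."""
        lookup = {c: i for i, c in enumerate(self.cpg_ids)}
        missing = [c for c in cpg_ids if c not in lookup]
        if missing:
            raise KeyError(f"unknown CpG id(s): {missing[:10]}")
        return np.array([lookup[c] for c in cpg_ids], dtype=int)

    def subset(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        """New matrix restricted to ``cpg_ids`` (in the given order)."""
        idx = self.column_index(cpg_ids)
        return BetaMatrix(self.values[:, idx], list(cpg_ids), list(self.sample_ids))

    def subset_samples(self, row_indices: Sequence[int]) -> "BetaMatrix":
        """New matrix restricted to the given sample rows (in the given order)."""
        rows = np.asarray(row_indices, dtype=int)
        return BetaMatrix(
            self.values[rows], list(self.cpg_ids), [self.sample_ids[i] for i in rows]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            [str(c) for c in frame.columns],
            [str(s) for s in frame.index],
        )


@dataclass
class LabelVector:
    """Binary disease-status labels aligned with a :class:`BetaMatrix`."""

    labels: np.ndarray
    class_names: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be one-dimensional")
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            raise ValidationError(
                f"labels must be 0/1; offending values: {sorted(set(self.labels[bad]))}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_counts(self) -> dict[int, int]:
        return {0: int((self.labels == 0).sum()), 1: int((self.labels == 1).sum())}

    def require_both_classes(self) -> None:
        counts = self.class_counts
        if counts[0] == 0 or counts[1] == 0:
            raise ValidationError(f"need at least one sample per class, got {counts}")

    def names(self) -> list[str]:
        return [self.class_names[int(y)] for y in self.labels]


@dataclass
class CovariateTable:
    """Optional per-sample covariates (age in years, body-mass/fat index).

    Carried through I/O for completeness; no selection or modelling step
    consumes it.
    """

    table: pd.DataFrame

    def validate_against(self, sample_ids: Sequence[str]) -> None:
        if len(self.table) != len(sample_ids):
            raise ValidationError(
                f"covariate table has {len(self.table)} rows for "
                f"{len(sample_ids)} samples"
            )


@dataclass
class SplitPlan:
    """A reproducible set of train/test partitions (repeated holdout).

    Every partition uses ``train size = floor(train_fraction * m + 0.5)``
    so that for a 50/50 split of an odd sample count the training set gets
    the extra sample.  The same plan is reused for every feature or feature
    subset that is compared, so that accuracy differences reflect the
    features rather than split noise (common random numbers).
    """

    n_repeats: int
    train_fraction: float
    partitions: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    stratified: bool

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must be in (0, 1)")
        if len(self.partitions) != self.n_repeats:
            raise ValidationError("partition count does not match n_repeats")

    @property
    def n_samples(self) -> int:
        train, test = self.partitions[0]
        return len(train) + len(test)

    def validate_for(self, m: int) -> None:
        expected = train_size(m, self.train_fraction)
        for i, (train, test) in enumerate(self.partitions):
            union = np.union1d(train, test)
            if len(train) + len(test) != m or not np.array_equal(union, np.arange(m)):
                raise ValidationError(f"partition {i} does not cover all {m} samples")
            if np.intersect1d(train, test).size:
                raise ValidationError(f"partition {i} has overlapping train/test sets")
            if len(train) != expected:
                raise ValidationError(
                    f"partition {i} train size {len(train)} != {expected}"
                )
            if len(test) == 0:
                raise ValidationError(f"partition {i} has an empty test set")


def train_size(m: int, train_fraction: float) -> int:
    """Training-set size: round-half-up of ``train_fraction * m``."""
    return int(np.floor(train_fraction * m + 0.5))


# ---------------------------------------------------------------------------
# Label encoding
# ---------------------------------------------------------------------------


def encode_labels(
    raw_labels: Iterable,
    synonyms: Mapping[str, int] | None = None,
    case_insensitive: bool = True,
    class_names: Mapping[int, str] | None = None,
) -> LabelVector:
    """Map class names or 0/1 codes onto the canonical 0/1 encoding.

    ``"Control"`` (or 0) becomes 0 and ``"Huntington"`` (or 1) becomes 1;
    ordering is preserved.  Unknown entries raise a ``ValidationError``
    naming the offending value.
    """
    mapping = dict(DEFAULT_LABEL_SYNONYMS if synonyms is None else synonyms)
    if case_insensitive:
        mapping = {k.lower(): v for k, v in mapping.items()}
    encoded = []
    for raw in raw_labels:
        if isinstance(raw, (int, np.integer)) and raw in (0, 1):
            encoded.append(int(raw))
            continue
        if isinstance(raw, float) and raw in (0.0, 1.0):
            encoded.append(int(raw))
            continue
        key = str(raw).strip()
        if case_insensitive:
            key = key.lower()
        if key not in mapping:
            raise ValidationError(
                f"cannot map label {raw!r} to a class; known labels: "
                f"{sorted(mapping)}"
            )
        encoded.append(int(mapping[key]))
    names = dict(DEFAULT_CLASS_NAMES if class_names is None else class_names)
    return LabelVector(np.array(encoded, dtype=int), names)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_beta_matrix(
    path: str | Path,
    orientation: str = "cpgs_in_rows",
    delimiter: str | None = None,
) -> BetaMatrix:
    """Read a beta matrix from TSV/CSV.

    The default on-disk dialect has CpGs in rows and samples in columns
    (the GEO series-matrix convention); pass ``orientation="samples_in_rows"``
    for the transposed layout.  The first column holds row identifiers and
    the first row holds column identifiers.
    """
    path = Path(path)
    if orientation not in ("cpgs_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0, dtype=str)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValidationError(f"{path}: no samples (empty body after header)")
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & frame.notna() & (frame.apply(lambda s: s.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.nonzero(bad.to_numpy())
        where = [
            f"row {frame.index[i]!r}, column {frame.columns[j]!r}: {frame.iat[i, j]!r}"
            for i, j in list(zip(r, c))[:5]
        ]
        raise ValidationError(f"{path}: malformed numeric cell(s): " + "; ".join(where))
    # astype(float) parses exactly (round-trip); pd.to_numeric's fast path
    # can be off by one ulp, which would break write/read idempotence
    numeric = frame.astype(float)
    if orientation == "cpgs_in_rows":
        numeric = numeric.T
    return BetaMatrix.from_frame(numeric)


def write_beta_matrix(
    bm: BetaMatrix,
    path: str | Path,
    orientation: str = "cpgs_in_rows",
    delimiter: str | None = None,
) -> None:
    """Write a beta matrix at full stored precision (round-trip safe)."""
    path = Path(path)
    frame = bm.to_frame()
    if orientation == "cpgs_in_rows":
        frame = frame.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    frame.to_csv(path, sep=_sep_for(path, delimiter), float_format="%.17g")


def read_labels(
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    delimiter: str | None = None,
    **encode_kwargs,
) -> LabelVector:
    """Read a two-column (sample_id, label) TSV/CSV.

    When ``sample_ids`` is given, rows are reordered to match it and
    missing/extra samples raise an error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (sample_id, label)")
    ids = frame.iloc[:, 0].astype(str).tolist()
    raw = frame.iloc[:, 1].tolist()
    if sample_ids is not None:
        lookup = dict(zip(ids, raw))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"{path}: labels missing for samples {missing[:10]}")
        raw = [lookup[s] for s in sample_ids]
    return encode_labels(raw, **encode_kwargs)


def write_labels(labels: LabelVector, sample_ids: Sequence[str], path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": list(sample_ids), "label": labels.labels}).to_csv(
        path, sep=_sep_for(path, None), index=False
    )


def read_covariates(
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> CovariateTable:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0)
    frame.index = frame.index.astype(str)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in frame.index]
        if missing:
            raise ValidationError(f"{path}: covariates missing for {missing[:10]}")
        frame = frame.loc[list(sample_ids)]
    table = CovariateTable(frame)
    if sample_ids is not None:
        table.validate_against(sample_ids)
    return table


# ---------------------------------------------------------------------------
# Missing-value handling
# ---------------------------------------------------------------------------


@dataclass
class CleaningReport:
    removed_cpgs: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed_cpgs)


def drop_incomplete_cpgs(bm: BetaMatrix) -> tuple[BetaMatrix, CleaningReport]:
    """Remove CpG columns containing any missing value.

    CpGs are abundant and samples scarce, so incompleteness is resolved by
    dropping the probe, never the sample.
    """
    has_nan = np.isnan(bm.values).any(axis=0)
    removed = [c for c, bad in zip(bm.cpg_ids, has_nan) if bad]
    if len(removed) == bm.n_cpgs:
        raise ValidationError("no usable CpGs: every column contains missing values")
    if removed:
        keep = ~has_nan
        cleaned = BetaMatrix(
            bm.values[:, keep],
            [c for c, ok in zip(bm.cpg_ids, keep) if ok],
            list(bm.sample_ids),
        )
    else:
        cleaned = bm
    return cleaned, CleaningReport(removed)


# ---------------------------------------------------------------------------
# Repeated-holdout partitioning
# ---------------------------------------------------------------------------


def make_split_plan(
    m: int,
    labels: LabelVector | None,
    n_repeats: int = 10,
    train_fraction: float = 2 / 3,
    seed: int = 0,
    stratified: bool = True,
) -> SplitPlan:
    """Draw ``n_repeats`` independent train/test partitions of ``m`` samples.

    Stratified sampling (the default) allocates training slots per class in
    proportion to class prevalence, with leftover slots assigned by largest
    fractional remainder, so small cohorts cannot produce single-class
    training sets.  The plan is fully determined by its arguments.
    """
    if m < 4:
        raise ValidationError(f"need at least 4 samples, got {m}")
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must be in (0, 1)")
    k = train_size(m, train_fraction)
    if k == 0 or k == m:
        raise ValidationError(
            f"train_fraction={train_fraction} yields an empty train or test set for m={m}"
        )
    if stratified:
        if labels is None:
            raise ValidationError("stratified sampling requires labels")
        if len(labels) != m:
            raise ValidationError(f"{len(labels)} labels for {m} samples")
        labels.require_both_classes()

    rng = np.random.default_rng(seed)
    partitions: list[tuple[np.ndarray, np.ndarray]] = []
    all_idx = np.arange(m)
    for _ in range(n_repeats):
        if stratified:
            train_parts = []
            classes = sorted(set(labels.labels.tolist()))
            per_class = {c: all_idx[labels.labels == c] for c in classes}
            ideal = {c: train_fraction * len(per_class[c]) for c in classes}
            base = {c: int(np.floor(ideal[c])) for c in classes}
            leftovers = k - sum(base.values())
            # largest fractional remainder first; ties favour the larger
            # class, then the lower label (deterministic)
            order = sorted(
                classes,
                key=lambda c: (-(ideal[c] - base[c]), -len(per_class[c]), c),
            )
            take = dict(base)
            for c in order[:leftovers]:
                take[c] += 1
            for c in classes:
                take[c] = min(take[c], len(per_class[c]))
                perm = rng.permutation(per_class[c])
                train_parts.append(perm[: take[c]])
            train = np.sort(np.concatenate(train_parts))
            # remainder-rounding can in principle under-fill; top up from the
            # unused pool to keep the train size exact
            if len(train) < k:
                pool = np.setdiff1d(all_idx, train)
                extra = rng.permutation(pool)[: k - len(train)]
                train = np.sort(np.concatenate([train, extra]))
        else:
            perm = rng.permutation(m)
            train = np.sort(perm[:k])
        test = np.setdiff1d(all_idx, train)
        if labels is not None and len(set(labels.labels[train].tolist())) < 2:
            logger.warning(
                "partition has a single-class training set; classifier will "
                "fall back to a constant predictor"
            )
        partitions.append((train, test))
    plan = SplitPlan(n_repeats, train_fraction, partitions, seed, stratified)
    plan.validate_for(m)
    return plan
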