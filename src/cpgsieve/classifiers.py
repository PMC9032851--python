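"""Pluggable binary classifiers shared by both selection stages.

The selection algorithm is wrapper-based: it never inspects the classifier,
only its held-out accuracy, so any binary classifier phi can be plugged in.
Four backends are provided:

``mlp``
    The reference configuration: a multilayer perceptron with
    ``n_hidden_layers`` x ``units_per_layer`` sigmoid units, trained for at
    most ``max_iterations`` iterations (scikit-learn's ``MLPClassifier``
    with the lbfgs quasi-Newton optimizer standing in for scaled conjugate
    gradient, which scikit-learn does not provide).
``logistic``
    Ridge-penalized logistic regression fitted by damped Newton/IRLS.
    This is the fast default for screening, where ~10^5 single-feature
    fits are needed: a batched solver fits every CpG column of a training
    slice simultaneously.  Features are standardized internally with
    training-set statistics: beta values live on a [0, 1] scale where
    biologically large shifts (~0.25) would need enormous raw
    coefficients, so an unscaled unit-ridge fit degenerates to the
    majority rule.  On the standardized scale the objective matches
    ``sklearn.linear_model.LogisticRegression(C=1.0)`` (L2 penalty on the
    weights, intercept unpenalized), which serves as an independent
    cross-check in the test suite.
``threshold_stub``
    Nearest class-centroid rule; on a single feature this is exactly the
    midpoint-of-class-means cut.  Deterministic, closed-form — used to make
    the selection stages testable against brute-force oracles.
``majority_stub``
    Always predicts the majority training class (ties go to class 1).

All backends expose a score in [0, 1]; a sample is called positive when
its score is >= ``decision_threshold`` (default 0.5).  Training a backend
on single-class data yields a constant predictor for that class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .data import LabelVector, ValidationError

logger = logging.getLogger(__name__)

BACKENDS = ("mlp", "logistic", "threshold_stub", "majority_stub")

#: Ridge strength on non-intercept weights for the logistic backend.
#: Equals 1/C for scikit-learn's default C=1.0.
LOGISTIC_RIDGE = 1.0
_NEWTON_TOL = 1e-8
_NEWTON_MAX_ITER = 100


@dataclass
class ClassifierSpec:
    """Configuration of the classifier phi.

    Defaults follow the reference network: hidden layers of 100 sigmoid
    units (4 of them — the depth at which accuracy plateaued), at most
    1000 training iterations, one sigmoid-scored output thresholded at
    0.5.  ``optimizer`` is recorded for transparency; only the mlp backend
    consumes it.
    """

    backend: str = "mlp"
    n_hidden_layers: int = 4
    units_per_layer: int = 100
    activation: str = "sigmoid"
    max_iterations: int = 1000
    optimizer: str = "lbfgs"  # quasi-Newton substitute for scaled conjugate gradient
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValidationError(
                f"unknown backend {self.backend!r}; choose from {BACKENDS}"
            )
        if not (1 <= self.n_hidden_layers <= 10):
            raise ValidationError("n_hidden_layers must be in [1, 10]")
        if self.units_per_layer < 1 or self.max_iterations < 1:
            raise ValidationError("units_per_layer and max_iterations must be >= 1")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValidationError("decision_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        return cls(**d)


@dataclass
class TrainedClassifier:
    """A fitted phi instance bound to an ordered CpG feature list."""

    spec: ClassifierSpec
    feature_ids: list[str]
    kind: str  # "logistic" | "centroid" | "constant" | "mlp"
    params: dict = field(default_factory=dict)

    def n_features(self) -> int:
        return len(self.feature_ids)


def _as_label_array(y) -> np.ndarray:
    if isinstance(y, LabelVector):
        return y.labels
    arr = np.asarray(y, dtype=int)
    if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
        raise ValidationError("labels must be a 1-D array of 0/1")
    return arr


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Logistic backend (damped Newton / IRLS)
# ---------------------------------------------------------------------------


def standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature training mean and standard deviation (0 -> 1)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _logistic_loss(z: np.ndarray, y: np.ndarray, w: np.ndarray, ridge: float) -> float:
    # sum log(1 + e^z) - y z, computed stably, plus ridge/2 ||w||^2
    loss = np.logaddexp(0.0, z) - y * z
    return float(loss.sum() + 0.5 * ridge * np.dot(w, w))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = LOGISTIC_RIDGE,
    tol: float = _NEWTON_TOL,
    max_iter: int = _NEWTON_MAX_ITER,
) -> tuple[float, np.ndarray]:
    """Fit ridge-penalized logistic regression; returns (intercept, coef).

    Damped Newton iterations on the penalized log-loss; the ridge term
    keeps the Hessian positive definite even for p > n or separable data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, p = X.shape
    beta = np.zeros(p + 1)  # [intercept, weights]
    z = np.zeros(m)
    loss = _logistic_loss(z, y, beta[1:], ridge)
    for _ in range(max_iter):
        prob = _sigmoid(z)
        resid = prob - y
        grad = np.empty(p + 1)
        grad[0] = resid.sum()
        grad[1:] = X.T @ resid + ridge * beta[1:]
        if np.max(np.abs(grad)) < tol:
            break
        s = np.clip(prob * (1.0 - prob), 1e-12, None)
        H = np.empty((p + 1, p + 1))
        H[0, 0] = s.sum()
        sx = X * s[:, None]
        H[0, 1:] = H[1:, 0] = sx.sum(axis=0)
        H[1:, 1:] = X.T @ sx + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        # backtracking keeps Newton from overshooting on near-separable data
        t = 1.0
        for _halve in range(40):
            cand = beta - t * step
            z_cand = cand[0] + X @ cand[1:]
            cand_loss = _logistic_loss(z_cand, y, cand[1:], ridge)
            if cand_loss <= loss + 1e-12:
                beta, z, loss = cand, z_cand, cand_loss
                break
            t *= 0.5
        else:
            break
    return float(beta[0]), beta[1:]


def fit_logistic_1d_batch(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = LOGISTIC_RIDGE,
    tol: float = _NEWTON_TOL,
    max_iter: int = _NEWTON_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one single-feature logistic model per column of ``X`` at once.

    Solves n independent 2-parameter problems with vectorized damped
    Newton steps (closed-form 2x2 Hessian solves); used by stage-1
    screening where each CpG is fitted individually.  Returns
    ``(intercepts, coefs)``, each of shape ``(n,)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)[:, None]
    m, n = X.shape
    b = np.zeros(n)
    w = np.zeros(n)
    z = np.zeros((m, n))

    def losses(zm, wv):
        return (np.logaddexp(0.0, zm) - y * zm).sum(axis=0) + 0.5 * ridge * wv**2

    loss = losses(z, w)
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        prob = _sigmoid(z)
        resid = prob - y
        g_b = resid.sum(axis=0)
        g_w = (X * resid).sum(axis=0) + ridge * w
        active &= np.maximum(np.abs(g_b), np.abs(g_w)) >= tol
        if not active.any():
            break
        s = np.clip(prob * (1.0 - prob), 1e-12, None)
        h_bb = s.sum(axis=0)
        h_bw = (s * X).sum(axis=0)
        h_ww = (s * X * X).sum(axis=0) + ridge
        det = h_bb * h_ww - h_bw**2
        step_b = np.where(active, (h_ww * g_b - h_bw * g_w) / det, 0.0)
        step_w = np.where(active, (h_bb * g_w - h_bw * g_b) / det, 0.0)
        t = np.where(active, 1.0, 0.0)
        for _halve in range(40):
            nb = b - t * step_b
            nw = w - t * step_w
            nz = nb[None, :] + X * nw[None, :]
            nloss = losses(nz, nw)
            ok = (nloss <= loss + 1e-12) | ~active
            if ok.all():
                b, w, z, loss = nb, nw, nz, nloss
                break
            t = np.where(ok, t, t * 0.5)
        else:
            # no improving damped step left for some columns; accept where ok
            improved = nloss <= loss + 1e-12
            b = np.where(improved, nb, b)
            w = np.where(improved, nw, w)
            z = np.where(improved[None, :], nz, z)
            loss = np.where(improved, nloss, loss)
            active &= improved
    return b, w


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------


def train(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train,
    feature_ids: Sequence[str] | None = None,
) -> TrainedClassifier:
    """Fit phi on a (samples x features) training slice."""
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("X_train must be 2-D with at least one feature column")
    y = _as_label_array(y_train)
    if X.shape[0] != len(y):
        raise ValidationError(
            f"{X.shape[0]} training rows for {len(y)} labels"
        )
    ids = (
        [str(f) for f in feature_ids]
        if feature_ids is not None
        else [f"f{i}" for i in range(X.shape[1])]
    )
    if len(ids) != X.shape[1]:
        raise ValidationError("feature_ids length does not match X_train columns")

    classes = np.unique(y)
    if len(classes) < 2:
        constant = int(classes[0])
        if spec.backend in ("mlp", "logistic"):
            logger.warning(
                "single-class training set: %s backend falls back to the "
                "constant predictor for class %d",
                spec.backend,
                constant,
            )
        return TrainedClassifier(spec, ids, "constant", {"value": constant})

    if spec.backend == "majority_stub":
        # ties go to class 1 (documented convention)
        majority = 1 if (y == 1).sum() >= (y == 0).sum() else 0
        return TrainedClassifier(spec, ids, "constant", {"value": majority})

    if spec.backend == "threshold_stub":
        c0 = X[y == 0].mean(axis=0)
        c1 = X[y == 1].mean(axis=0)
        return TrainedClassifier(spec, ids, "centroid", {"c0": c0, "c1": c1})

    if spec.backend == "logistic":
        mean, sd = standardize_stats(X)
        intercept, coef = fit_logistic((X - mean) / sd, y)
        return TrainedClassifier(
            spec,
            ids,
            "logistic",
            {"intercept": intercept, "coef": coef, "mean": mean, "sd": sd},
        )

    # mlp
    from sklearn.neural_network import MLPClassifier

    est = MLPClassifier(
        hidden_layer_sizes=(spec.units_per_layer,) * spec.n_hidden_layers,
        activation="logistic" if spec.activation == "sigmoid" else spec.activation,
        solver=spec.optimizer if spec.optimizer in ("lbfgs", "adam", "sgd") else "lbfgs",
        max_iter=spec.max_iterations,
        random_state=spec.seed,
    )
    est.fit(X, y)
    return TrainedClassifier(spec, ids, "mlp", {"estimator": est})


def decision_scores(model: TrainedClassifier, X_test: np.ndarray) -> np.ndarray:
    """Score in [0, 1] per test row (probability-like; higher = class 1)."""
    X = np.asarray(X_test, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X_test must be 2-D")
    if X.shape[0] == 0:
        raise ValidationError("test set must be non-empty")
    if X.shape[1] != model.n_features():
        raise ValidationError(
            f"feature mismatch: model trained on {model.n_features()} features "
            f"({model.feature_ids[:5]}...), got {X.shape[1]} columns"
        )
    if model.kind == "constant":
        return np.full(X.shape[0], float(model.params["value"]))
    if model.kind == "centroid":
        d0 = np.linalg.norm(X - model.params["c0"], axis=1)
        d1 = np.linalg.norm(X - model.params["c1"], axis=1)
        tot = d0 + d1
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(tot > 0, d0 / tot, 0.5)
        return score
    if model.kind == "logistic":
        Xs = (X - model.params["mean"]) / model.params["sd"]
        return _sigmoid(model.params["intercept"] + Xs @ model.params["coef"])
    return model.params["estimator"].predict_proba(X)[:, 1]


def predict(
    model: TrainedClassifier,
    X_test: np.ndarray,
    feature_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """0/1 predictions; errors if the feature set/order does not match."""
    if feature_ids is not None:
        given = [str(f) for f in feature_ids]
        if given != model.feature_ids:
            missing = [f for f in model.feature_ids if f not in given]
            extra = [f for f in given if f not in model.feature_ids]
            raise ValidationError(
                f"feature mismatch: missing {missing[:5]}, unexpected {extra[:5]}"
                if missing or extra
                else "feature order does not match the trained model"
            )
    scores = decision_scores(model, X_test)
    return (scores >= model.spec.decision_threshold).astype(int)
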