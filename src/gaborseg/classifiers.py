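"""Pixel classifiers: quadratic Gaussian, K-nearest-neighbor, and a
three-layer perceptron trained by back-propagation.

All three score a pixel's 15-D feature vector with a vessel probability in
[0, 1] behind one interface (:func:`predict_proba` / :func:`classify`), so
they are interchangeable in the pipeline. Inputs are assumed standardized
with the training-set statistics stored on the model.

Quadratic Gaussian (QG)
    Bayes classifier with Gaussian class-conditional densities and
    class-specific covariances; discriminant for class c at x is
    ``log p(c) − ½log|Σc| − ½(x−μc)ᵀΣc⁻¹(x−μc)`` and the vessel probability
    is the normalized class likelihood.

K-nearest-neighbor (KNN)
    Exact brute-force Euclidean search (no approximate index); the score is
    the fraction of the k nearest training points labeled vessel. Distance
    ties are broken by lower training-row index; the default k = 5 is odd
    so label votes cannot tie.

Multilayer perceptron (MLP)
    15 → H → 1 with logistic-sigmoid hidden and output units, H ∈ [2, 20].
    Trained by mini-batch gradient descent on mean binary cross-entropy
    (standard back-propagation). After every epoch the validation error is
    evaluated; training stops when it has not improved for ``patience``
    epochs and the weights of the best validation epoch are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .dataset import LabeledDataset

__all__ = [
    "QGModel", "KNNModel", "MLPModel",
    "train_qg", "train_knn", "predict_knn", "train_mlp", "select_architecture",
    "predict_proba", "classify", "qg_discriminants", "mlp_forward", "mlp_gradients",
]


# ---------------------------------------------------------------------------
# Quadratic Gaussian


@dataclass
class QGModel:
    means: np.ndarray        # (2, D) class means, index = label
    covariances: np.ndarray  # (2, D, D), regularized
    priors: np.ndarray       # (2,), sums to 1
    standardization: tuple | None = None

    def __post_init__(self):
        for c, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T):
                raise ValueError(f"class {c} covariance is not symmetric")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")

    @property
    def dim(self) -> int:
        return self.means.shape[1]


def train_qg(train: LabeledDataset, reg_scale: float = 1e-6) -> QGModel:
    """Fit class means, covariances (maximum likelihood) and empirical priors.

    Each covariance gets ``reg_scale·trace(Σ)/D`` added to its diagonal,
    which guards the near-singular case of windows of constant color.
    """
    X, y = train.features.features, train.labels
    d = X.shape[1]
    means, covs, priors = [], [], []
    for c in (0, 1):
        Xc = X[y == c]
        if Xc.shape[0] < d + 1:
            raise ValueError(
                f"class {c} has {Xc.shape[0]} samples; need at least D+1 = {d + 1}"
            )
        mu = Xc.mean(axis=0)
        cov = np.atleast_2d(np.cov(Xc, rowvar=False, bias=True))
        cov = cov + np.eye(d) * (reg_scale * np.trace(cov) / d)
        # positive-definiteness check; Cholesky raises if regularization failed
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"class {c} covariance singular despite regularization"
            ) from exc
        means.append(mu)
        covs.append(cov)
        priors.append(Xc.shape[0] / X.shape[0])
    return QGModel(means=np.array(means), covariances=np.array(covs),
                   priors=np.array(priors),
                   standardization=train.features.standardization
                   if not isinstance(train.features.standardization, str) else None)


def qg_discriminants(model: QGModel, X: np.ndarray) -> np.ndarray:
    """Per-class quadratic discriminant values, shape (N, 2)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], 2))
    for c in (0, 1):
        diff = X - model.means[c]
        L = np.linalg.cholesky(model.covariances[c])
        sol = np.linalg.solve(L, diff.T)              # L z = diff
        maha = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, c] = np.log(model.priors[c]) - 0.5 * logdet - 0.5 * maha
    return out


# ---------------------------------------------------------------------------
# K-nearest-neighbor


@dataclass
class KNNModel:
    X: np.ndarray            # (N, D) stored training features
    y: np.ndarray            # (N,) binary labels
    k: int = 5
    standardization: tuple | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] == 0:
            raise ValueError("empty training set")
        if not (1 <= self.k <= self.X.shape[0]):
            raise ValueError(f"k={self.k} outside [1, {self.X.shape[0]}]")

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def train_knn(train: LabeledDataset, k: int = 5) -> KNNModel:
    return KNNModel(
        X=train.features.features.copy(), y=train.labels.copy(), k=k,
        standardization=train.features.standardization
        if not isinstance(train.features.standardization, str) else None,
    )


def knn_neighbor_indices(model: KNNModel, X: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Indices of the k Euclidean-nearest training rows per query, (N, k).

    Exact exhaustive search; equal distances rank by lower training index
    (stable sort), making the neighbor set fully deterministic.
    """
    from scipy.spatial.distance import cdist

    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], model.k), dtype=int)
    for start in range(0, X.shape[0], chunk):
        d = cdist(X[start:start + chunk], model.X)
        out[start:start + chunk] = np.argsort(d, axis=1, kind="stable")[:, :model.k]
    return out


def predict_knn(model: KNNModel, X: np.ndarray) -> np.ndarray:
    """Vessel score = fraction of the k nearest training points labeled vessel."""
    nbrs = knn_neighbor_indices(model, X)
    return model.y[nbrs].mean(axis=1)


# ---------------------------------------------------------------------------
# Multilayer perceptron


@dataclass
class TrainingRecord:
    epochs_run: int = 0
    best_epoch: int = 0
    best_val_error: float = np.inf
    seed: int | None = None
    learning_rate: float = 0.05


@dataclass
class MLPModel:
    W1: np.ndarray           # (D, H)
    b1: np.ndarray           # (H,)
    W2: np.ndarray           # (H, 1)
    b2: np.ndarray           # (1,)
    record: TrainingRecord = field(default_factory=TrainingRecord)
    standardization: tuple | None = None

    @property
    def dim(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden(self) -> int:
        return self.W1.shape[1]


def mlp_forward(model: MLPModel, X: np.ndarray):
    """Forward pass; returns (hidden activations, output probabilities)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A1 = expit(X @ model.W1 + model.b1)
    out = expit(A1 @ model.W2 + model.b2)
    return A1, out[:, 0]


def _bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).mean())


def mlp_gradients(model: MLPModel, X: np.ndarray, y: np.ndarray):
    """Back-propagation gradients of mean binary cross-entropy.

    With a sigmoid output the output-layer delta simplifies to ``p − y``.
    Returns a dict with keys W1, b1, W2, b2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    A1, p = mlp_forward(model, X)
    delta2 = (p - y)[:, None] / n                      # (N, 1)
    gW2 = A1.T @ delta2
    gb2 = delta2.sum(axis=0)
    delta1 = (delta2 @ model.W2.T) * A1 * (1 - A1)     # (N, H)
    gW1 = X.T @ delta1
    gb1 = delta1.sum(axis=0)
    return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


def _init_mlp(d: int, h: int, rng: np.random.Generator) -> MLPModel:
    r1 = np.sqrt(6.0 / (d + h))
    r2 = np.sqrt(6.0 / (h + 1))
    return MLPModel(
        W1=rng.uniform(-r1, r1, size=(d, h)),
        b1=np.zeros(h),
        W2=rng.uniform(-r2, r2, size=(h, 1)),
        b2=np.zeros(1),
    )


def train_mlp(train: LabeledDataset, val: LabeledDataset, hidden: int = 10,
              learning_rate: float = 0.05, max_epochs: int = 1000,
              patience: int = 20, batch_size: int = 128, seed: int = 0,
              verbose: bool = False) -> MLPModel:
    """Train by mini-batch back-propagation with validation-monitored stopping.

    The validation error (mean cross-entropy) is evaluated after every
    epoch; the returned weights are those of the best validation epoch, and
    training halts once ``patience`` epochs pass without improvement.
    Bit-reproducible for a fixed seed.
    """
    if not (2 <= hidden <= 20):
        raise ValueError(f"hidden units must be in [2, 20], got {hidden}")
    if learning_rate <= 0:
        raise ValueError("learning rate must be positive")
    X, y = train.features.features, train.labels.astype(float)
    Xv, yv = val.features.features, val.labels.astype(float)

    rng = np.random.default_rng(seed)
    model = _init_mlp(X.shape[1], hidden, rng)
    best = {k: getattr(model, k).copy() for k in ("W1", "b1", "W2", "b2")}
    # epoch-0 baseline: the untrained network's validation error
    best_err, best_epoch, since_best = _bce(mlp_forward(model, Xv)[1], yv), 0, 0

    epoch = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], batch_size):
            idx = order[start:start + batch_size]
            g = mlp_gradients(model, X[idx], y[idx])
            model.W1 -= learning_rate * g["W1"]
            model.b1 -= learning_rate * g["b1"]
            model.W2 -= learning_rate * g["W2"]
            model.b2 -= learning_rate * g["b2"]
        _, p_tr = mlp_forward(model, X)
        train_loss = _bce(p_tr, y)
        if not np.isfinite(train_loss):
            raise FloatingPointError(
                f"training diverged (loss became non-finite at epoch {epoch}); "
                f"try a smaller learning rate than {learning_rate}"
            )
        _, pv = mlp_forward(model, Xv)
        val_err = _bce(pv, yv)
        if verbose:
            import sys
            print(f"epoch {epoch:4d}  train loss {train_loss:.5f}  "
                  f"val error {val_err:.5f}", file=sys.stderr)
        if val_err < best_err:
            best_err, best_epoch, since_best = val_err, epoch, 0
            best = {k: getattr(model, k).copy() for k in ("W1", "b1", "W2", "b2")}
        else:
            since_best += 1
            if since_best >= patience:
                break

    model.W1, model.b1 = best["W1"], best["b1"]
    model.W2, model.b2 = best["W2"], best["b2"]
    model.record = TrainingRecord(
        epochs_run=epoch, best_epoch=best_epoch, best_val_error=best_err,
        seed=seed, learning_rate=learning_rate,
    )
    std = train.features.standardization
    model.standardization = std if not isinstance(std, str) else None
    return model


def select_architecture(train: LabeledDataset, val: LabeledDataset,
                        h_grid=range(2, 21), seed: int = 0, **train_kwargs) -> MLPModel:
    """Train one MLP per hidden-layer size and keep the best on validation.

    Ties in validation error go to the smallest H. Each candidate trains
    from its own seeded initialization derived from ``seed``.
    """
    h_grid = list(h_grid)
    if not h_grid:
        raise ValueError("empty hidden-unit grid")
    best_model = None
    for h in h_grid:
        m = train_mlp(train, val, hidden=h, seed=seed, **train_kwargs)
        if best_model is None or m.record.best_val_error < best_model.record.best_val_error:
            best_model = m
    return best_model


# ---------------------------------------------------------------------------
# Common scoring interface


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Vessel probability in [0, 1] for each feature row, any model type."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.dim:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} does not match model "
            f"dimensionality {model.dim}"
        )
    if isinstance(model, QGModel):
        g = qg_discriminants(model, X)
        return np.exp(g[:, 1] - logsumexp(g, axis=1))
    if isinstance(model, KNNModel):
        return predict_knn(model, X)
    if isinstance(model, MLPModel):
        return mlp_forward(model, X)[1]
    raise TypeError(f"unknown model type {type(model).__name__}")


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary vessel labels: score ≥ threshold."""
    return np.asarray(scores) >= threshold


# ---------------------------------------------------------------------------
# Serialization hooks used by gaborseg.io


def _std_state(model):
    if model.standardization is None:
        return None
    mean, sd = model.standardization
    return [np.asarray(mean, dtype=float), np.asarray(sd, dtype=float)]


def model_state(model) -> dict:
    if isinstance(model, QGModel):
        return {"model_type": "qg", "means": model.means,
                "covariances": model.covariances, "priors": model.priors,
                "standardization": _std_state(model)}
    if isinstance(model, KNNModel):
        return {"model_type": "knn", "X": model.X, "y": model.y, "k": model.k,
                "standardization": _std_state(model)}
    if isinstance(model, MLPModel):
        return {"model_type": "mlp", "W1": model.W1, "b1": model.b1,
                "W2": model.W2, "b2": model.b2,
                "record": {"epochs_run": model.record.epochs_run,
                           "best_epoch": model.record.best_epoch,
                           "best_val_error": float(model.record.best_val_error),
                           "seed": model.record.seed,
                           "learning_rate": model.record.learning_rate},
                "standardization": _std_state(model)}
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def model_from_state(model_type: str, state: dict):
    std = state.get("standardization")
    std = tuple(std) if std is not None else None
    if model_type == "qg":
        return QGModel(means=state["means"], covariances=state["covariances"],
                       priors=state["priors"], standardization=std)
    if model_type == "knn":
        return KNNModel(X=state["X"], y=state["y"], k=int(state["k"]),
                        standardization=std)
    if model_type == "mlp":
        rec = state.get("record", {})
        return MLPModel(W1=state["W1"], b1=state["b1"], W2=state["W2"],
                        b2=state["b2"],
                        record=TrainingRecord(**rec) if rec else TrainingRecord(),
                        standardization=std)
    raise ValueError(f"unknown model type {model_type!r} in model file")
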