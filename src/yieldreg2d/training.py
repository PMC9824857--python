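"""Model fitting: masked mean-squared-error objective, Adadelta
optimization with mini-batches of 96, best-validation-checkpoint selection,
and the closed-form multiple-linear-regression (MLR) baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._nn import Adadelta
from .hyper3dnetreg import Hyper3DNetReg
from .raster_core import CovariatePatch, YieldPatch

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "masked_mse",
    "train",
    "fit_mlr",
    "predict_mlr",
    "stack_patches",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Mini-batch size 96 and the Adadelta optimizer (rho=0.95, eps=1e-6,
    lr=1.0 — no hand-tuned learning rate) follow the training protocol the
    architecture was designed for; the epoch budget and early-stopping
    patience are package choices, config-exposed.
    """

    batch_size: int = 96
    max_epochs: int = 500
    patience: int = 50
    rho: float = 0.95
    eps: float = 1e-6
    lr: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


@dataclass
class TrainHistory:
    """Per-epoch training record."""

    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int

    def as_rows(self):
        return [{"epoch": e + 1, "train_mse": t, "val_mse": v}
                for e, (t, v) in enumerate(zip(self.train_loss, self.val_loss))]


def masked_mse(pred: np.ndarray, target: np.ndarray,
               valid: np.ndarray | None = None) -> float:
    """Mean squared error over valid target pixels only."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if valid is None:
        valid = np.isfinite(target)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != target.shape:
            raise ValueError("valid mask shape mismatch")
    n = valid.sum()
    if n == 0:
        raise ValueError("no valid target pixel")
    diff = np.where(valid, pred - target, 0.0)
    return float((diff * diff).sum() / n)


def stack_patches(samples: list[tuple[CovariatePatch, YieldPatch]],
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack patch pairs into (X, Y, valid) batch arrays.

    X is (B, W, W, n); Y is (B, N, N) with NaN at invalid pixels (or (B,)
    for N = 1); valid is the boolean loss mask of Y.
    """
    X = np.stack([x.data for x, _ in samples]).astype(np.float32)
    Y = np.stack([y.data for _, y in samples])
    V = np.stack([y.valid for _, y in samples])
    if Y.shape[1:] == (1, 1):
        Y, V = Y[:, 0, 0], V[:, 0, 0]
    return X, Y, V


def _eval_loss(model: Hyper3DNetReg, X, Y, V, batch_size: int) -> float:
    se, n = 0.0, 0
    for i in range(0, len(X), batch_size):
        pred = model.forward(X[i:i + batch_size], train=False)
        v = V[i:i + batch_size]
        d = np.where(v, pred - np.nan_to_num(Y[i:i + batch_size]), 0.0)
        se += float((d * d).sum())
        n += int(v.sum())
    if n == 0:
        raise ValueError("no valid target pixel in evaluation set")
    return se / n


def _get_weights(model: Hyper3DNetReg):
    state = {}
    for ly in model.layers():
        for k, v in ly.params.items():
            state[(ly.name, k)] = v.copy()
        if hasattr(ly, "running_mean"):
            state[(ly.name, "_rm")] = ly.running_mean.copy()
            state[(ly.name, "_rv")] = ly.running_var.copy()
    return state


def _set_weights(model: Hyper3DNetReg, state) -> None:
    for ly in model.layers():
        for k in ly.params:
            ly.params[k] = state[(ly.name, k)].copy()
        if hasattr(ly, "running_mean"):
            ly.running_mean = state[(ly.name, "_rm")].copy()
            ly.running_var = state[(ly.name, "_rv")].copy()


def train(model: Hyper3DNetReg,
          train_set: list[tuple[CovariatePatch, YieldPatch]],
          val_set: list[tuple[CovariatePatch, YieldPatch]] | None,
          cfg: TrainConfig,
          callback=None) -> tuple[Hyper3DNetReg, TrainHistory]:
    """Fit the network by masked MSE with Adadelta mini-batch descent.

    Each epoch shuffles the training patches (seeded generator), runs
    mini-batches of ``cfg.batch_size``, and evaluates the validation MSE in
    evaluation mode; the weights achieving the best validation MSE are
    restored at the end (when no validation set is given, the training MSE
    plays that role). Early stopping triggers after ``cfg.patience`` epochs
    without improvement. Runs are fully reproducible given the seeds.
    """
    if not train_set:
        raise ValueError("empty training set")
    Xt, Yt, Vt = stack_patches(train_set)
    if Vt.sum() == 0:
        raise ValueError("all training target pixels are masked")
    Yt0 = np.nan_to_num(Yt)
    if val_set:
        Xv, Yv, Vv = stack_patches(val_set)

    rng = np.random.default_rng(cfg.seed)
    opt = Adadelta(model.layers(), rho=cfg.rho, eps=cfg.eps, lr=cfg.lr)
    history = TrainHistory([], [], best_epoch=0)
    best = (np.inf, _get_weights(model))
    since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xt))
        ep_se, ep_n = 0.0, 0
        model.training_mode = True
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            pred = model.forward(Xt[idx], train=True)
            v = Vt[idx]
            nv = int(v.sum())
            if nv == 0:
                continue
            diff = np.where(v, pred - Yt0[idx], 0.0)
            ep_se += float((diff * diff).sum())
            ep_n += nv
            model.backward(2.0 * diff / nv)
            opt.step()
        model.training_mode = False
        train_loss = ep_se / max(ep_n, 1)
        val_loss = _eval_loss(model, Xv, Yv, Vv, cfg.batch_size) if val_set \
            else _eval_loss(model, Xt, Yt, Vt, cfg.batch_size)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, _get_weights(model))
            history.best_epoch = epoch + 1
            since_best = 0
        else:
            since_best += 1
        if callback is not None and callback(epoch, train_loss, val_loss):
            break
        if since_best >= cfg.patience:
            break

    if cfg.max_epochs > 0:
        _set_weights(model, best[1])
    return model, history


# ---------------------------------------------------------------------------
# MLR baseline


def fit_mlr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ordinary least squares on vectorized 8-feature samples.

    Returns the coefficient vector ``[intercept, b_1..b_n]``. A
    rank-deficient design triggers a documented ridge fallback
    (lambda = 1e-8) with a warning rather than an unstable solve.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    A = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient design matrix; using ridge fallback "
                      "(lambda=1e-8)", stacklevel=2)
        lam = 1e-8
        coef = np.linalg.solve(A.T @ A + lam * np.eye(A.shape[1]), A.T @ y)
    else:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


def predict_mlr(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Predict scalar yield per row from fitted MLR coefficients."""
    X = np.asarray(X, dtype=np.float64)
    return coef[0] + X @ coef[1:]
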