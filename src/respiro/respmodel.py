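"""Linear airflow predictor: normalization, ridge fit, LOOCV penalty choice.

The model is f_norm(l) ~= <W, X(l)> + b with W a (grid, grid, 2) weight
tensor over the per-frame optical-flow field and b a scalar intercept.  The
airflow target is z-scored with training-set statistics (population SD);
W solves the L2-penalized least-squares problem with the intercept left
unpenalized (implemented by centering features and target).  The penalty is
selected by exact leave-one-out cross-validation using the hat-matrix
shortcut, which for a linear smoother equals brute-force refitting.

Fits use the kernel (dual) form K = Xc Xc^T, so the cost is O(L^3) in the
number of training frames rather than the 3200-dimensional feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateSignalError, IllPosedError, ValidationError
from .flowfield import FlowTensorSeries

__all__ = [
    "NormStats",
    "RidgeModel",
    "normalize_flow",
    "denormalize_flow",
    "predict_normalized",
    "fit_ridge",
    "select_lambda",
    "default_lambda_grid",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NormStats:
    """Training-phase airflow statistics (L/s): mean and population SD."""

    mu_f: float
    sigma_f: float

    def __post_init__(self) -> None:
        if not self.sigma_f > 0:
            raise DegenerateSignalError(f"sigma_f must be positive, got {self.sigma_f}")


def normalize_flow(
    flow: np.ndarray, stats: NormStats | None = None
) -> tuple[np.ndarray, NormStats]:
    """z-score airflow; estimate (mu, sigma) from the input when not given.

    Uses the population standard deviation (ddof 0) so that round trips with
    :func:`denormalize_flow` are exact and re-normalizing an already
    normalized trace is the identity.
    """
    flow = np.asarray(flow, dtype=float)
    if stats is None:
        if flow.size < 2:
            raise ValidationError("need at least two samples to estimate NormStats")
        mu = float(np.mean(flow))
        sigma = float(np.std(flow))
        if sigma < 1e-12 * max(1.0, abs(mu)):
            raise DegenerateSignalError("constant airflow trace cannot be normalized")
        stats = NormStats(mu_f=mu, sigma_f=sigma)
    return (flow - stats.mu_f) / stats.sigma_f, stats


def denormalize_flow(f_norm: np.ndarray, stats: NormStats) -> np.ndarray:
    """Affine inverse of :func:`normalize_flow`: sigma_f * f_norm + mu_f."""
    return stats.sigma_f * np.asarray(f_norm, dtype=float) + stats.mu_f


@dataclass
class RidgeModel:
    """Fitted linear flow predictor."""

    W: np.ndarray  # (grid, grid, 2)
    b: float
    lam: float
    norm: NormStats
    lam_grid: np.ndarray | None = None
    cv_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 3 or self.W.shape[-1] != 2:
            raise ValidationError("W must have shape (grid, grid, 2)")

    @property
    def grid_size(self) -> int:
        return self.W.shape[0]


def predict_normalized(X: np.ndarray | FlowTensorSeries, model: RidgeModel) -> np.ndarray | float:
    """<W, X> + b: the triple sum over (m, n, k) plus the intercept.

    Accepts a single tensor (returns a scalar) or a stacked (L, grid, grid, 2)
    array / FlowTensorSeries (returns a length-L vector).
    """
    if isinstance(X, FlowTensorSeries):
        X = X.tensors
    X = np.asarray(X, dtype=float)
    if X.shape[-3:] != model.W.shape:
        raise ValidationError(
            f"flow tensor shape {X.shape[-3:]} does not match weights {model.W.shape}"
        )
    out = np.tensordot(X, model.W, axes=3) + model.b
    return float(out) if out.ndim == 0 else out


def _flatten(X: np.ndarray | FlowTensorSeries) -> np.ndarray:
    if isinstance(X, FlowTensorSeries):
        X = X.tensors
    X = np.asarray(X, dtype=float)
    if X.ndim != 4 or X.shape[-1] != 2:
        raise ValidationError("expected stacked flow tensors of shape (L, grid, grid, 2)")
    return X.reshape(X.shape[0], -1)


def fit_ridge(
    Xs: np.ndarray | FlowTensorSeries,
    f_norm: np.ndarray,
    lam: float,
    stats: NormStats | None = None,
) -> RidgeModel:
    """Solve min_W,b sum_l (<W, X(l)> + b - f_norm(l))^2 + lam * ||W||^2.

    The intercept is not penalized: features and target are centered, the
    ridge system is solved in the dual, and b = ybar - <w, xbar>.
    """
    if not lam > 0:
        raise ValidationError(f"penalty lam must be positive, got {lam}")
    Xf = _flatten(Xs)
    y = np.asarray(f_norm, dtype=float)
    if len(Xf) != len(y):
        raise ValidationError(f"{len(Xf)} tensors vs {len(y)} flow samples")
    if len(y) < 2:
        raise ValidationError("need at least two training samples")
    xbar = Xf.mean(axis=0)
    ybar = float(y.mean())
    Xc = Xf - xbar
    yc = y - ybar
    K = Xc @ Xc.T
    alpha = np.linalg.solve(K + lam * np.eye(len(yc)), yc)
    w = Xc.T @ alpha
    b = ybar - float(w @ xbar)
    grid = Xs.tensors.shape[1] if isinstance(Xs, FlowTensorSeries) else np.asarray(Xs).shape[1]
    if stats is None:
        stats = NormStats(mu_f=0.0, sigma_f=1.0)
    return RidgeModel(W=w.reshape(grid, grid, 2), b=b, lam=float(lam), norm=stats)


def default_lambda_grid() -> np.ndarray:
    """13 penalties log-spaced in [1e-3, 1e3]."""
    return np.logspace(-3, 3, 13)


def loocv_scores(
    Xs: np.ndarray | FlowTensorSeries, f_norm: np.ndarray, lam_grid: np.ndarray
) -> np.ndarray:
    """Exact leave-one-out mean squared prediction error per candidate penalty.

    Uses the linear-smoother identity: the held-out residual for sample i is
    e_i / (1 - H_ii), with H the hat matrix of the centered ridge smoother
    plus the 1/n intercept contribution.  A single eigendecomposition of the
    kernel serves every candidate.
    """
    Xf = _flatten(Xs)
    y = np.asarray(f_norm, dtype=float)
    n = len(y)
    if len(Xf) != n:
        raise ValidationError(f"{len(Xf)} tensors vs {n} flow samples")
    if n < 3:
        raise ValidationError("leave-one-out selection needs at least three samples")
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0 or np.any(lam_grid <= 0):
        raise ValidationError("lam_grid must be non-empty with positive entries")
    Xc = Xf - Xf.mean(axis=0)
    yc = y - y.mean()
    K = Xc @ Xc.T
    evals, Q = np.linalg.eigh(K)
    evals = np.clip(evals, 0.0, None)
    yq = Q.T @ yc
    scores = np.empty(lam_grid.size)
    for j, lam in enumerate(lam_grid):
        inv = 1.0 / (evals + lam)
        resid = lam * (Q @ (inv * yq))  # y - yhat, intercept included
        h_diag = 1.0 / n + np.einsum("ij,j,ij->i", Q, evals * inv, Q)
        denom = 1.0 - h_diag
        if np.any(denom < 1e-10):
            raise IllPosedError(
                f"leverage of 1 encountered at lam={lam:g}; a fold is ill posed"
            )
        scores[j] = float(np.mean((resid / denom) ** 2))
    return scores


def select_lambda(
    Xs: np.ndarray | FlowTensorSeries,
    f_norm: np.ndarray,
    lam_grid: np.ndarray | None = None,
    stats: NormStats | None = None,
) -> RidgeModel:
    """Refit on all data at the LOOCV-optimal penalty (ties -> larger lam)."""
    if lam_grid is None:
        lam_grid = default_lambda_grid()
    lam_grid = np.sort(np.asarray(lam_grid, dtype=float))
    scores = loocv_scores(Xs, f_norm, lam_grid)
    best = int(np.flatnonzero(scores == scores.min())[-1])
    model = fit_ridge(Xs, f_norm, lam_grid[best], stats=stats)
    model.lam_grid = lam_grid
    model.cv_scores = scores
    return model


def save_model(model: RidgeModel, path: str | Path) -> Path:
    """Serialize to an NPZ (tensor) + JSON (scalars) pair sharing a stem."""
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    np.savez(
        npz,
        W=model.W,
        lam_grid=model.lam_grid if model.lam_grid is not None else np.array([]),
        cv_scores=model.cv_scores if model.cv_scores is not None else np.array([]),
    )
    meta = {"b": model.b, "lam": model.lam, "mu_f": model.norm.mu_f, "sigma_f": model.norm.sigma_f}
    npz.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return npz


def load_model(path: str | Path) -> RidgeModel:
    npz = Path(path)
    if npz.suffix != ".npz":
        npz = npz.with_suffix(".npz")
    data = np.load(npz)
    meta = json.loads(npz.with_suffix(".json").read_text())
    lam_grid = data["lam_grid"] if data["lam_grid"].size else None
    cv_scores = data["cv_scores"] if data["cv_scores"].size else None
    return RidgeModel(
        W=data["W"],
        b=float(meta["b"]),
        lam=float(meta["lam"]),
        norm=NormStats(mu_f=float(meta["mu_f"]), sigma_f=float(meta["sigma_f"])),
        lam_grid=lam_grid,
        cv_scores=cv_scores,
    )
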