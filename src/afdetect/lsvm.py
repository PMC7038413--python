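"""Lagrangian Support Vector Machine (LSVM) classifier.

The LSVM replaces the soft-margin SVM's hinge penalty with squared
slacks and penalises the offset together with the weights,

    min_{w, w0, xi}  (||w||^2 + w0^2)/2 + (gamma/2) ||xi||^2
    s.t.             D (X0 w - 1 w0) + xi >= 1,

whose dual has non-negativity constraints only:

    min_{lambda >= 0}  (1/2) lambda' Q lambda - 1' lambda,
    Q = I/gamma + H H',   H = D [X0, -1]          (linear)
    Q = I/gamma + D K(X0e, X0e') D                (kernel).

The Karush-Kuhn-Tucker conditions give the linearly convergent
fixed-point iteration

    lambda^{k+1} = Q^{-1} (1 + (Q lambda^k - 1 - alpha lambda^k)_+),

convergent from any start whenever 0 < alpha < 2/gamma; we iterate from
lambda = 0.  Q is symmetric positive definite, so Q^{-1} is applied via
one Cholesky factorisation computed before iterating.

For the linear machine the plane is recovered as w = X0' D lambda,
w0 = -1' D lambda; the kernel decision surface is K(x_e, X0e') D lambda
with the input augmented by a constant -1 coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .core import InvalidInputError


@dataclass(frozen=True)
class LSVMConfig:
    """Hyperparameters of the LSVM trainer.

    gamma trades margin width against training error; chi is the
    Gaussian-kernel width; alpha is the iteration step (default 1.9/gamma,
    always inside the (0, 2/gamma) convergence band); iteration stops
    after ``max_iter`` steps or when the Euclidean change in the dual
    variables drops to ``tol``.
    """

    gamma: float = 10.0
    chi: float = 4.0
    alpha: float | None = None
    max_iter: int = 100
    tol: float = 1e-5
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if self.kernel == "rbf" and self.chi <= 0:
            raise ValueError("chi must be positive for the rbf kernel")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        a = self.effective_alpha
        if not 0 < a < 2.0 / self.gamma:
            raise ValueError(
                f"alpha={a} outside the convergence band (0, {2.0 / self.gamma})"
            )

    @property
    def effective_alpha(self) -> float:
        return 1.9 / self.gamma if self.alpha is None else self.alpha


HYPERPARAM_LADDER: tuple[float, ...] = tuple(
    m * 10.0**e for e in range(-5, 5) for m in (1, 4, 7)
) + (1e5,)
"""The 1-4-7 decade grid {1e-5, 4e-5, 7e-5, ..., 7e4, 1e5} searched for
both gamma and chi."""


@dataclass
class ScalingParams:
    """Per-feature min/max of the training data, mapping onto [-1, +1].

    Test data are mapped with the same affine transform and are not
    clipped; a constant training feature maps to 0 everywhere.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "ScalingParams":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit scaling on empty data")
        return cls(X.min(axis=0), X.max(axis=0))

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.minimum.shape[0]:
            raise ValueError(
                f"feature count {X.shape[-1]} != fitted {self.minimum.shape[0]}"
            )
        span = self.maximum - self.minimum
        mid = (self.maximum + self.minimum) / 2.0
        out = np.zeros_like(X, dtype=float)
        nz = span > 0
        out[..., nz] = 2.0 * (X[..., nz] - mid[nz]) / span[nz]
        return out


def scale_fit(X_train: np.ndarray) -> ScalingParams:
    """Fit the [-1, +1] feature scaling on training data."""
    return ScalingParams.fit(X_train)


def scale_apply(params: ScalingParams, X: np.ndarray) -> np.ndarray:
    """Apply a fitted scaling (no clipping outside [-1, +1])."""
    return params.apply(X)


def rbf_kernel(A: np.ndarray, B: np.ndarray, chi: float) -> np.ndarray:
    """Gaussian kernel K[i, j] = exp(-chi * ||a_i - b_j||^2)."""
    if chi <= 0:
        raise ValueError("chi must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must share the feature dimension")
    return np.exp(-chi * cdist(A, B, "sqeuclidean"))


def _augment(X: np.ndarray) -> np.ndarray:
    """Append the constant -1 coordinate (folds the offset into the kernel)."""
    return np.hstack([X, -np.ones((X.shape[0], 1))])


@dataclass
class LSVMModel:
    """Trained LSVM state.

    Holds the dual variables ``lam``, the class labels ``y`` (the
    diagonal of D), the scaled training inputs ``X0`` (kernel case), the
    recovered plane ``(w, w0)`` (linear case), the slacks ``xi =
    lam/gamma``, the fitted scaler and the config.
    """

    config: LSVMConfig
    scaler: ScalingParams
    lam: np.ndarray
    y: np.ndarray
    X0: np.ndarray
    w: np.ndarray | None
    w0: float | None
    iterations_run: int
    converged: bool
    #: Euclidean change of the dual vector at each iteration.
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def xi(self) -> np.ndarray:
        return self.lam / self.config.gamma

    def decision(self, X: np.ndarray, *, scaled: bool = False) -> np.ndarray:
        """Decision scores; positive means AF side of the surface.

        Raw features are scaled with the model's scaler unless
        ``scaled=True`` marks them as already scaled.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = X if scaled else self.scaler.apply(X)
        if self.config.kernel == "linear":
            return Xs @ self.w - self.w0
        K = rbf_kernel(_augment(Xs), _augment(self.X0), self.config.chi)
        return K @ (self.y * self.lam)

    def predict(self, X: np.ndarray, *, scaled: bool = False) -> np.ndarray:
        """Labels +1 (AF) where the score is > 0, else -1 (non-AF).

        A score of exactly 0 is assigned to the negative class
        (conservative toward non-AF).
        """
        return np.where(self.decision(X, scaled=scaled) > 0, 1, -1)

    # -- serialization: JSON archive, exact float round-trip ------------

    def save(self, path: str | Path) -> None:
        """Write the model as a self-describing JSON archive."""
        blob = {
            "format": "afdetect-lsvm",
            "version": 1,
            "config": {
                "gamma": self.config.gamma,
                "chi": self.config.chi,
                "alpha": self.config.alpha,
                "max_iter": self.config.max_iter,
                "tol": self.config.tol,
                "kernel": self.config.kernel,
            },
            "scaler": {
                "minimum": self.scaler.minimum.tolist(),
                "maximum": self.scaler.maximum.tolist(),
            },
            "lam": self.lam.tolist(),
            "y": self.y.tolist(),
            "X0": self.X0.tolist(),
            "w": None if self.w is None else self.w.tolist(),
            "w0": self.w0,
            "iterations_run": self.iterations_run,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "LSVMModel":
        blob = json.loads(Path(path).read_text())
        if blob.get("format") != "afdetect-lsvm":
            raise ValueError(f"{path}: not an afdetect LSVM model archive")
        cfg = LSVMConfig(**blob["config"])
        scaler = ScalingParams(
            np.array(blob["scaler"]["minimum"], dtype=float),
            np.array(blob["scaler"]["maximum"], dtype=float),
        )
        return cls(
            config=cfg,
            scaler=scaler,
            lam=np.array(blob["lam"], dtype=float),
            y=np.array(blob["y"], dtype=float),
            X0=np.array(blob["X0"], dtype=float),
            w=None if blob["w"] is None else np.array(blob["w"], dtype=float),
            w0=blob["w0"],
            iterations_run=blob["iterations_run"],
            converged=blob["converged"],
        )


def lsvm_train(
    X: np.ndarray,
    y: np.ndarray,
    config: LSVMConfig = LSVMConfig(),
    *,
    prescaled: bool = False,
) -> LSVMModel:
    """Train an LSVM by the fixed-point dual iteration.

    Parameters
    ----------
    X
        Training inputs, one row per sample.  Scaled to [-1, +1]
        internally unless ``prescaled`` (in which case an identity-like
        scaler over the observed range is still fitted for later use).
    y
        Class labels in {-1, +1}; +1 marks AF.
    config
        Hyperparameters; see :class:`LSVMConfig`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} labels")
    if not np.isfinite(X).all():
        raise InvalidInputError("training features contain non-finite values")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be coded -1 / +1")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one sample of each class")

    scaler = ScalingParams.fit(X)
    Xs = X if prescaled else scaler.apply(X)
    if prescaled:
        # decision() must not rescale: make the stored transform identity
        scaler = ScalingParams(
            np.full(X.shape[1], -1.0), np.full(X.shape[1], 1.0)
        )

    n = Xs.shape[0]
    gamma = config.gamma
    alpha = config.effective_alpha

    if config.kernel == "linear":
        H = y[:, None] * _augment(Xs)
        Q = np.eye(n) / gamma + H @ H.T
    else:
        Xe = _augment(Xs)
        K = rbf_kernel(Xe, Xe, config.chi)
        Q = np.eye(n) / gamma + (y[:, None] * K) * y[None, :]

    chol = cho_factor(Q, lower=True)
    one = np.ones(n)
    lam = np.zeros(n)
    converged = False
    it = 0
    deltas: list[float] = []
    for it in range(1, config.max_iter + 1):
        resid = Q @ lam - one
        lam_new = cho_solve(chol, one + np.maximum(resid - alpha * lam, 0.0))
        delta = float(np.linalg.norm(lam_new - lam))
        deltas.append(delta)
        lam = lam_new
        if delta <= config.tol:
            converged = True
            break

    if config.kernel == "linear":
        w = Xs.T @ (y * lam)
        w0 = float(-np.sum(y * lam))
    else:
        w, w0 = None, None

    return LSVMModel(
        config=config,
        scaler=scaler,
        lam=lam,
        y=y,
        X0=Xs,
        w=w,
        w0=w0,
        iterations_run=it,
        converged=converged,
        residual_history=np.asarray(deltas),
    )


def lsvm_decision(model: LSVMModel, X: np.ndarray, **kw) -> np.ndarray:
    """Functional alias for :meth:`LSVMModel.decision`."""
    return model.decision(X, **kw)


def lsvm_predict(model: LSVMModel, X: np.ndarray, **kw) -> np.ndarray:
    """Functional alias for :meth:`LSVMModel.predict`."""
    return model.predict(X, **kw)
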