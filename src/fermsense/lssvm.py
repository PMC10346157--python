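"""Least squares support vector machine (LS-SVM) regression with an RBF kernel.

LS-SVM replaces the standard SVM's inequality constraints and epsilon-insensitive
loss with equality constraints and a squared-error loss, so training reduces to a
single symmetric (n+1)x(n+1) linear system derived from the KKT conditions:

    [[0,  1^T        ],   [b    ]   [0]
     [1,  K + I/gamma]] @ [alpha] = [y]

where K is the RBF kernel Gram matrix K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)),
gamma > 0 is the regularization parameter (large gamma -> closer interpolation)
and sigma > 0 is the kernel width.  Prediction is the kernel expansion
f(x) = sum_i alpha_i K(x, x_i) + b.

The solve uses a symmetric-indefinite LAPACK factorization (the KKT matrix is a
saddle system) and refuses, rather than pseudo-inverts, when the reciprocal
condition estimate indicates the system is numerically singular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import lapack
from scipy.spatial.distance import cdist

from .exceptions import NumericalError, ShapeError, ValidationError

__all__ = [
    "Dataset",
    "LSSVMHyperparams",
    "LSSVMModel",
    "rbf_kernel_matrix",
    "lssvm_fit",
    "lssvm_predict",
]

#: Baseline hyperparameters used when none are supplied: the fixed configuration
#: of the un-tuned reference model (gamma = 125, sigma = 10).
DEFAULT_GAMMA = 125.0
DEFAULT_SIGMA = 10.0

# Refuse the solve when the reciprocal condition estimate drops below this.
_RCOND_FLOOR = 1e-12


def _as_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ShapeError(f"{name} must be a 2-D matrix, got ndim={X.ndim}")
    return X


@dataclass(frozen=True)
class Dataset:
    """A feature matrix with one real-valued label per row.

    The universal currency of the package: rows are time points of one or more
    fermentation batches, columns are (normalized) auxiliary variables, and the
    label is a quality variable such as cell or product concentration in g/L.
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        X = _as_matrix(self.X)
        y = np.asarray(self.y, dtype=float).ravel()
        if X.shape[0] < 2:
            raise ValidationError(f"Dataset needs n >= 2 samples, got {X.shape[0]}")
        if X.shape[1] < 1:
            raise ValidationError("Dataset needs d >= 1 features")
        if y.shape[0] != X.shape[0]:
            raise ShapeError(
                f"label length {y.shape[0]} != number of rows {X.shape[0]}"
            )
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValidationError("Dataset contains non-finite values")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class LSSVMHyperparams:
    """Regularization parameter gamma and RBF kernel width sigma (both > 0)."""

    gamma: float = DEFAULT_GAMMA
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self):
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValidationError(f"gamma must be positive, got {self.gamma}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValidationError(f"sigma must be positive, got {self.sigma}")


def rbf_kernel_matrix(A, B, sigma: float) -> np.ndarray:
    """Gram matrix of the Gaussian kernel exp(-||a - b||^2 / (2 sigma^2)).

    Entries lie in (0, 1]; the matrix is symmetric PSD when ``A is B``.
    """
    if not (np.isfinite(sigma) and sigma > 0):
        raise ValidationError(f"sigma must be positive, got {sigma}")
    A = _as_matrix(A, "A")
    B = _as_matrix(B, "B")
    if A.shape[1] != B.shape[1]:
        raise ShapeError(
            f"column mismatch: A has {A.shape[1]} features, B has {B.shape[1]}"
        )
    sq = cdist(A, B, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma * sigma))


@dataclass
class LSSVMModel:
    """A fitted LS-SVM: dual coefficients, bias, hyperparameters and the
    training inputs retained for kernel evaluation at prediction time."""

    alpha: np.ndarray
    b: float
    hyperparams: LSSVMHyperparams
    train_X: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.train_X = _as_matrix(self.train_X, "train_X")
        if self.alpha.shape[0] != self.train_X.shape[0]:
            raise ShapeError(
                f"alpha length {self.alpha.shape[0]} != training rows "
                f"{self.train_X.shape[0]}"
            )
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.b)):
            raise ValidationError("model coefficients must be finite")

    def predict(self, Xnew) -> np.ndarray:
        return lssvm_predict(self, Xnew)

    def save(self, path) -> None:
        """Persist as plain structured text (JSON) with lossless round trip."""
        payload = {
            "format": "fermsense-lssvm",
            "version": 1,
            "gamma": self.hyperparams.gamma,
            "sigma": self.hyperparams.sigma,
            "b": self.b,
            "alpha": self.alpha.tolist(),
            "train_X": self.train_X.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "LSSVMModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "fermsense-lssvm":
            raise ValidationError(f"{path} is not a saved LS-SVM model")
        return cls(
            alpha=np.array(payload["alpha"], dtype=float),
            b=float(payload["b"]),
            hyperparams=LSSVMHyperparams(payload["gamma"], payload["sigma"]),
            train_X=np.array(payload["train_X"], dtype=float),
        )


def _solve_symmetric(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve the symmetric-indefinite KKT system, refusing on ill-conditioning."""
    ldu, ipiv, info = lapack.dsytrf(M)
    if info != 0:
        raise NumericalError(f"sytrf factorization failed (info={info})")
    anorm = np.linalg.norm(M, 1)
    rcond, cinfo = lapack.dsycon(ldu, ipiv, anorm)
    if cinfo != 0 or not np.isfinite(rcond) or rcond < _RCOND_FLOOR:
        raise NumericalError(
            "KKT system is numerically singular: reciprocal condition estimate "
            f"{rcond:.3e} below {_RCOND_FLOOR:.0e} (condition ~ {1.0 / max(rcond, 1e-300):.3e})"
        )
    x, sinfo = lapack.dsytrs(ldu, ipiv, rhs[:, None])
    if sinfo != 0:
        raise NumericalError(f"sytrs solve failed (info={sinfo})")
    return x.ravel()


def lssvm_fit(data: Dataset, hp: LSSVMHyperparams | None = None) -> LSSVMModel:
    """Fit by assembling and solving the (n+1)x(n+1) KKT system.

    Postcondition (checked): the returned (b, alpha) satisfy the assembled
    system with residual norm <= 1e-8 * (1 + ||y||).
    """
    if not isinstance(data, Dataset):
        data = Dataset(*data)
    hp = hp if hp is not None else LSSVMHyperparams()
    n = data.n
    K = rbf_kernel_matrix(data.X, data.X, hp.sigma)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / hp.gamma
    rhs = np.concatenate([[0.0], data.y])
    sol = _solve_symmetric(M, rhs)
    resid = np.linalg.norm(M @ sol - rhs)
    tol = 1e-8 * (1.0 + np.linalg.norm(data.y))
    if resid > tol:
        raise NumericalError(
            f"KKT residual {resid:.3e} exceeds tolerance {tol:.3e}"
        )
    return LSSVMModel(alpha=sol[1:], b=float(sol[0]), hyperparams=hp, train_X=data.X)


def lssvm_predict(model: LSSVMModel, Xnew) -> np.ndarray:
    """Evaluate the kernel expansion f(x) = sum_i alpha_i K(x, x_i) + b."""
    Xnew = _as_matrix(Xnew, "Xnew")
    if Xnew.shape[1] != model.train_X.shape[1]:
        raise ShapeError(
            f"query has {Xnew.shape[1]} features, model expects "
            f"{model.train_X.shape[1]}"
        )
    K = rbf_kernel_matrix(Xnew, model.train_X, model.hyperparams.sigma)
    return K @ model.alpha + model.b
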