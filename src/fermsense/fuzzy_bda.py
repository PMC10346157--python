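"""Balanced distribution adaptation (BDA) for regression via percentile fuzzy sets.

BDA aligns a labelled source domain with an unlabelled target domain by
minimizing a weighted sum of the marginal and conditional maximum mean
discrepancy (MMD) between them, in a linear subspace A:

    min_A  tr(A^T X [(1-mu) M0 + mu MR] X^T A) + lam ||A||_F^2
    s.t.   A^T X H X^T A = I

with X = [Xs, Xt] (features in columns), H the centering matrix, M0 the
marginal MMD matrix and MR = M1 + M2 + M3 the conditional one.  Classic BDA
needs class labels to form the conditional terms; for regression the label
axis is softened into three fuzzy sets (small / medium / large) anchored at
the 5th, 50th and 95th label percentiles, and each sample contributes to each
set with its normalized membership.  The stationarity condition of the
Lagrangian turns the problem into a generalized eigenproblem

    (X M X^T + lam I) A = X H X^T A Phi

whose eigenvectors with smallest eigenvalues form the transformation matrix.
Because target labels are unknown, conditional terms use soft labels from a
regressor, optionally refined by alternating solve / re-predict rounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .exceptions import NumericalError, PipelineError, ShapeError, ValidationError

__all__ = [
    "FuzzySets",
    "MembershipMatrix",
    "BDAConfig",
    "BDAResult",
    "fit_fuzzy_sets",
    "membership_matrix",
    "build_M0",
    "build_Mc",
    "build_MR",
    "weighted_mmd",
    "solve_bda",
    "bda_adapt",
]

logger = logging.getLogger("fermsense.fuzzy_bda")

N_SETS = 3  # small, medium, large — fixed by the three percentile anchors


@dataclass(frozen=True)
class FuzzySets:
    """Three fuzzy sets over the label axis anchored at label percentiles.

    small: 1 below p5, falling linearly to 0 at p50.
    medium: triangular — 0 at p5, 1 at p50, 0 at p95.
    large: 0 below p50, rising linearly to 1 at p95, 1 beyond.

    When all labels coincide (``degenerate``) membership collapses to
    all-medium.
    """

    p5: float
    p50: float
    p95: float
    degenerate: bool = False

    def __post_init__(self):
        if not (self.p5 <= self.p50 <= self.p95):
            raise ValidationError(
                f"percentiles must be ordered, got {self.p5}, {self.p50}, {self.p95}"
            )

    def memberships(self, y) -> np.ndarray:
        """Raw membership matrix, one row per label, columns (small, medium, large)."""
        y = np.asarray(y, dtype=float).ravel()
        out = np.zeros((y.size, N_SETS))
        if self.degenerate:
            out[:, 1] = 1.0
            return out
        lo, mid, hi = self.p5, self.p50, self.p95
        left = max(mid - lo, 0.0)
        right = max(hi - mid, 0.0)
        # small
        if left > 0:
            out[:, 0] = np.clip((mid - y) / left, 0.0, 1.0)
        else:
            out[:, 0] = (y <= lo).astype(float)
        # medium
        rise = np.clip((y - lo) / left, 0.0, 1.0) if left > 0 else (y >= mid).astype(float)
        fall = np.clip((hi - y) / right, 0.0, 1.0) if right > 0 else (y <= mid).astype(float)
        out[:, 1] = np.minimum(rise, fall)
        # large
        if right > 0:
            out[:, 2] = np.clip((y - mid) / right, 0.0, 1.0)
        else:
            out[:, 2] = (y >= hi).astype(float)
        return out


def fit_fuzzy_sets(labels) -> FuzzySets:
    """Anchor the three sets at the 5th/50th/95th percentiles of the labels
    (linear interpolation between order statistics)."""
    y = np.asarray(labels, dtype=float).ravel()
    if y.size < 3:
        raise ValidationError(f"need at least 3 labels, got {y.size}")
    if not np.isfinite(y).all():
        raise ValidationError("labels contain non-finite values")
    p5, p50, p95 = np.percentile(y, [5.0, 50.0, 95.0])
    degenerate = bool((p95 - p5) <= 1e-12 * max(1.0, abs(p50)))
    if degenerate:
        logger.warning("all labels (nearly) identical: degenerate fuzzy sets, all-medium")
    return FuzzySets(float(p5), float(p50), float(p95), degenerate=degenerate)


@dataclass(frozen=True)
class MembershipMatrix:
    """Raw memberships alpha (n x 3) and column-normalized memberships
    alpha-bar whose non-empty columns sum to one."""

    raw: np.ndarray
    normalized: np.ndarray

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of fuzzy sets with non-zero total membership."""
        return self.raw.sum(axis=0) > 0


def membership_matrix(labels, sets: FuzzySets) -> MembershipMatrix:
    raw = sets.memberships(labels)
    sums = raw.sum(axis=0)
    normalized = np.zeros_like(raw)
    for c in range(N_SETS):
        if sums[c] > 0:
            normalized[:, c] = raw[:, c] / sums[c]
        else:
            logger.info("fuzzy set %d has zero total membership; excluded", c)
    return MembershipMatrix(raw=raw, normalized=normalized)


def build_M0(n: int, m: int) -> np.ndarray:
    """Marginal MMD matrix: 1/n^2 on source-source, 1/m^2 on target-target,
    -1/(nm) on cross blocks.  Rank-one PSD with zero entry-sum."""
    if n < 1 or m < 1:
        raise ValidationError("n and m must be >= 1")
    v = np.concatenate([np.full(n, 1.0 / n), np.full(m, -1.0 / m)])
    return np.outer(v, v)


def build_Mc(memb_src: MembershipMatrix, memb_tgt: MembershipMatrix, c: int) -> np.ndarray:
    """Conditional MMD matrix for fuzzy set ``c`` from normalized memberships:
    outer product of [alpha-bar_src; -alpha-bar_tgt].  With crisp 0/1
    memberships this is the classic per-class BDA matrix."""
    if not 0 <= c < N_SETS:
        raise ValidationError(f"class index must be in 0..{N_SETS - 1}, got {c}")
    a = np.concatenate([memb_src.normalized[:, c], -memb_tgt.normalized[:, c]])
    return np.outer(a, a)


def build_MR(memb_src: MembershipMatrix, memb_tgt: MembershipMatrix) -> np.ndarray:
    """Sum of the conditional matrices over the fuzzy sets active in both domains."""
    n = memb_src.raw.shape[0]
    m = memb_tgt.raw.shape[0]
    MR = np.zeros((n + m, n + m))
    for c in range(N_SETS):
        MR += build_Mc(memb_src, memb_tgt, c)
    return MR


def _check_features(Xs, Xt):
    Xs = np.asarray(Xs, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    if Xs.ndim != 2 or Xt.ndim != 2:
        raise ShapeError("Xs and Xt must be 2-D (samples x features)")
    if Xs.shape[1] != Xt.shape[1]:
        raise ShapeError(
            f"feature mismatch: source d={Xs.shape[1]}, target d={Xt.shape[1]}"
        )
    return Xs, Xt


def weighted_mmd(Xs, Xt, memb_src: MembershipMatrix, memb_tgt: MembershipMatrix,
                 mu: float) -> float:
    """Fuzzy-weighted MMD: (1-mu)*||mean_s - mean_t||^2 plus mu times the sum
    over fuzzy sets of the squared distance between membership-weighted means.

    Equals the trace form tr(X[(1-mu)M0 + mu*MR]X^T) evaluated with an
    identity transformation.
    """
    Xs, Xt = _check_features(Xs, Xt)
    if not 0.0 <= mu <= 1.0:
        raise ValidationError(f"mu must be in [0, 1], got {mu}")
    marginal = float(np.sum((Xs.mean(axis=0) - Xt.mean(axis=0)) ** 2))
    conditional = 0.0
    for c in range(N_SETS):
        ms = memb_src.normalized[:, c] @ Xs
        mt = memb_tgt.normalized[:, c] @ Xt
        conditional += float(np.sum((ms - mt) ** 2))
    return (1.0 - mu) * marginal + mu * conditional


@dataclass(frozen=True)
class BDAConfig:
    """Balance factor mu in [0,1], ridge lam > 0, subspace dimension and the
    number of soft-label refinement rounds."""

    mu: float = 0.62
    lam: float = 0.1
    dims: int | None = None  # None -> automatic spectral cut (see solve_bda)
    refine_iters: int = 10
    refine_tol: float = 1e-4

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValidationError(f"mu must be in [0, 1], got {self.mu}")
        if not self.lam > 0:
            raise ValidationError(f"lam must be positive, got {self.lam}")
        if self.dims is not None and self.dims < 1:
            raise ValidationError(f"dims must be >= 1, got {self.dims}")
        if self.refine_iters < 1:
            raise ValidationError("refine_iters must be >= 1")


@dataclass
class BDAResult:
    """Learned transformation and diagnostics."""

    A: np.ndarray
    eigenvalues: np.ndarray
    fuzzy_src: FuzzySets
    fuzzy_tgt: FuzzySets
    mmd_before: float
    mmd_after: float

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.A.shape[0]:
            raise ShapeError(
                f"X has {X.shape[1]} features, transformation expects {self.A.shape[0]}"
            )
        return X @ self.A

    def save(self, path) -> None:
        payload = {
            "format": "fermsense-bda",
            "version": 1,
            "A": self.A.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "fuzzy_src": [self.fuzzy_src.p5, self.fuzzy_src.p50, self.fuzzy_src.p95,
                          self.fuzzy_src.degenerate],
            "fuzzy_tgt": [self.fuzzy_tgt.p5, self.fuzzy_tgt.p50, self.fuzzy_tgt.p95,
                          self.fuzzy_tgt.degenerate],
            "mmd_before": self.mmd_before,
            "mmd_after": self.mmd_after,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "BDAResult":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "fermsense-bda":
            raise ValidationError(f"{path} is not a saved BDA result")
        fs = payload["fuzzy_src"]
        ft = payload["fuzzy_tgt"]
        return cls(
            A=np.array(payload["A"], dtype=float),
            eigenvalues=np.array(payload["eigenvalues"], dtype=float),
            fuzzy_src=FuzzySets(fs[0], fs[1], fs[2], degenerate=bool(fs[3])),
            fuzzy_tgt=FuzzySets(ft[0], ft[1], ft[2], degenerate=bool(ft[3])),
            mmd_before=float(payload["mmd_before"]),
            mmd_after=float(payload["mmd_after"]),
        )


_RESIDUAL_TOL = 1e-6


_SPECTRAL_GAP_FACTOR = 10.0


def solve_bda(Xs, ys, Xt, soft_labels, config: BDAConfig) -> BDAResult:
    """One BDA solve: fuzzy sets on both label vectors, MMD matrices, and the
    generalized eigenproblem; A holds the eigenvectors with smallest
    eigenvalues.  Each column's eigen-residual is checked against 1e-6.

    With ``config.dims = None`` the subspace dimension is chosen
    automatically: trailing generalized eigenvalues more than 10x the median
    mark directions whose objective value is dominated by the ridge penalty
    (they amplify near-null-variance directions of the data by 1/sqrt of
    their variance) and are dropped.  When the spectrum is flat the full
    feature count is kept.
    """
    Xs, Xt = _check_features(Xs, Xt)
    ys = np.asarray(ys, dtype=float).ravel()
    soft_labels = np.asarray(soft_labels, dtype=float).ravel()
    n, m = Xs.shape[0], Xt.shape[0]
    if ys.size != n:
        raise ShapeError(f"ys length {ys.size} != source rows {n}")
    if soft_labels.size != m:
        raise ShapeError(f"soft_labels length {soft_labels.size} != target rows {m}")
    d = Xs.shape[1]
    auto_dims = config.dims is None
    dims = d if auto_dims else config.dims
    if dims > d:
        raise ValidationError(f"dims={dims} exceeds feature count {d}")

    fuzzy_src = fit_fuzzy_sets(ys)
    fuzzy_tgt = fit_fuzzy_sets(soft_labels)
    memb_src = membership_matrix(ys, fuzzy_src)
    memb_tgt = membership_matrix(soft_labels, fuzzy_tgt)

    M = (1.0 - config.mu) * build_M0(n, m) + config.mu * build_MR(memb_src, memb_tgt)
    X = np.vstack([Xs, Xt]).T  # d x (n+m), features in rows
    N = n + m
    H = np.eye(N) - np.full((N, N), 1.0 / N)  # centering matrix
    Sa = X @ M @ X.T + config.lam * np.eye(d)
    Sb = X @ H @ X.T
    Sa = 0.5 * (Sa + Sa.T)
    Sb = 0.5 * (Sb + Sb.T)
    try:
        w, V = scipy.linalg.eigh(Sa, Sb, subset_by_index=[0, dims - 1])
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(
            "generalized eigenproblem failed: constraint matrix X H X^T is not "
            f"positive definite (min diag {np.diag(Sb).min():.3e}, "
            f"cond {np.linalg.cond(Sb):.3e})"
        ) from exc

    if auto_dims:
        cut = _SPECTRAL_GAP_FACTOR * np.median(w)
        keep = max(1, int(np.sum(w <= cut)))
        if keep < dims:
            logger.info(
                "spectral cut keeps %d of %d directions (eigenvalues %s)",
                keep, dims, np.array2string(w, precision=3),
            )
        dims = keep
        w, V = w[:dims], V[:, :dims]

    scale = np.linalg.norm(Sa, 2) + abs(w).max() * np.linalg.norm(Sb, 2)
    for j in range(dims):
        resid = np.linalg.norm(Sa @ V[:, j] - w[j] * (Sb @ V[:, j]))
        if resid > _RESIDUAL_TOL * max(1.0, scale):
            raise NumericalError(
                f"eigenvector {j} residual {resid:.3e} exceeds tolerance"
            )

    mmd_before = weighted_mmd(Xs, Xt, memb_src, memb_tgt, config.mu)
    mmd_after = weighted_mmd(Xs @ V, Xt @ V, memb_src, memb_tgt, config.mu)
    return BDAResult(
        A=V,
        eigenvalues=w,
        fuzzy_src=fuzzy_src,
        fuzzy_tgt=fuzzy_tgt,
        mmd_before=float(mmd_before),
        mmd_after=float(mmd_after),
    )


def bda_adapt(
    Xs,
    ys,
    Xt,
    trainer,
    config: BDAConfig,
    initial_soft_labels=None,
):
    """Alternate BDA solves with soft-label refinement.

    ``trainer(X, y)`` must return a predictor callable.  Round i solves BDA
    with the current soft labels, transforms both domains, retrains on the
    transformed source and re-predicts the target; iteration stops after
    ``config.refine_iters`` rounds or when soft labels change by less than
    ``config.refine_tol`` in relative norm.  With ``refine_iters=1`` and
    supplied soft labels this reduces to a single :func:`solve_bda`.

    Returns ``(BDAResult, transformed Xs, transformed Xt, final soft labels)``.
    """
    Xs, Xt = _check_features(Xs, Xt)
    ys = np.asarray(ys, dtype=float).ravel()
    if initial_soft_labels is None:
        try:
            model = trainer(Xs, ys)
            soft = np.asarray(model(Xt), dtype=float).ravel()
        except Exception as exc:
            raise PipelineError(
                f"BDA adaptation failed computing initial soft labels: {exc}"
            ) from exc
    else:
        soft = np.asarray(initial_soft_labels, dtype=float).ravel()

    result = None
    Zs = Zt = None
    for it in range(config.refine_iters):
        result = solve_bda(Xs, ys, Xt, soft, config)
        Zs, Zt = result.transform(Xs), result.transform(Xt)
        if it == config.refine_iters - 1:
            break
        try:
            model = trainer(Zs, ys)
            new_soft = np.asarray(model(Zt), dtype=float).ravel()
        except Exception as exc:
            raise PipelineError(
                f"BDA adaptation failed at refinement round {it + 1}: {exc}"
            ) from exc
        change = np.linalg.norm(new_soft - soft) / (np.linalg.norm(soft) + 1e-12)
        soft = new_soft
        if change < config.refine_tol:
            logger.info("soft labels converged after %d refinement rounds", it + 1)
            result = solve_bda(Xs, ys, Xt, soft, config)
            Zs, Zt = result.transform(Xs), result.transform(Xt)
            break
    return result, Zs, Zt, soft
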