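"""End-to-end soft-sensor workflow and the four-model comparison.

The workflow follows six steps: (1) assemble and min-max normalize the data
on the source domain only; (2) select the LS-SVM hyperparameters (gamma,
sigma) by particle swarm search over cross-validated RMSE; (3) train on the
labelled source; (4) predict provisional soft labels for the unlabelled
target; (5) run fuzzy balanced distribution adaptation to learn a
transformation A matching the two domains, refining the soft labels
iteratively; (6) re-tune and re-train on the transformed source and predict
the transformed target.  Four model variants are compared: a fixed-parameter
LS-SVM (gamma=125, sigma=10), PSO-tuned, IPSO-tuned, and the full
BDA-IPSO-LSSVM with domain adaptation.

Reported metrics are RMSE, the coefficient of determination R^2 and MAE,
computed on predictions mapped back to original label units (g/L).
"""

from __future__ import annotations

import logging
import time as _time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import PipelineError, ShapeError, ValidationError
from .fuzzy_bda import BDAConfig, BDAResult, bda_adapt
from .ipso import OptimizeResult, SwarmConfig, ipso_optimize, pso_optimize
from .lssvm import (
    DEFAULT_GAMMA,
    DEFAULT_SIGMA,
    Dataset,
    LSSVMHyperparams,
    LSSVMModel,
    lssvm_fit,
)
from .simulate import TransferScenario

__all__ = [
    "VARIANTS",
    "PipelineConfig",
    "EvaluationReport",
    "MinMaxScaler",
    "normalize_fit_apply",
    "evaluate",
    "tune_lssvm",
    "train_soft_sensor",
    "compare_models",
    "SoftSensorResult",
]

logger = logging.getLogger("fermsense.pipeline")

VARIANTS = ("lssvm", "pso-lssvm", "ipso-lssvm", "bda-ipso-lssvm")

# Hyperparameter search box: gamma in (0, 300], sigma in (0, 50]; the first
# particle's gamma coordinate starts at 100.
GAMMA_MAX = 300.0
SIGMA_MAX = 50.0
GAMMA_INIT = 100.0
_BOX_LOWER = 1e-3

_CV_PENALTY = 1e6  # objective value when a fold's linear solve is refused


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full workflow.

    ``swarm_size``/``tune_iters`` control the hyperparameter search (the
    library defaults match the reference configuration: swarm 100, up to 200
    iterations); ``bda`` holds the adaptation settings (mu = 0.62 by
    default); ``folds`` is the number of contiguous cross-validation blocks.
    """

    variant: str = "bda-ipso-lssvm"
    normalization: str = "minmax"
    folds: int = 5
    swarm_size: int = 100
    tune_iters: int = 200
    fitness_threshold: float | None = None
    bda: BDAConfig = field(default_factory=BDAConfig)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValidationError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )
        if self.normalization != "minmax":
            raise ValidationError("only min-max normalization is supported")
        if self.folds < 2:
            raise ValidationError(f"folds must be >= 2, got {self.folds}")
        if self.swarm_size < 3 or self.tune_iters < 1:
            raise ValidationError("swarm_size must be >= 3 and tune_iters >= 1")


class MinMaxScaler:
    """Column-wise min-max scaling to [0, 1], fitted on the source domain only.

    Values outside the training range extrapolate beyond [0, 1] (no clipping);
    zero-range columns are flagged and mapped to the constant 0.5.
    """

    def __init__(self):
        self.min_ = None
        self.range_ = None
        self.constant_ = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        self.constant_ = rng == 0
        if self.constant_.any():
            logger.warning(
                "zero-range column(s) %s mapped to 0.5",
                np.nonzero(self.constant_)[0].tolist(),
            )
        self.range_ = np.where(self.constant_, 1.0, rng)
        return self

    def _check(self, X):
        if self.min_ is None:
            raise PipelineError("scaler used before fit")
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        if X.shape[1] != self.min_.size:
            raise ShapeError(
                f"scaler fitted on {self.min_.size} columns, got {X.shape[1]}"
            )
        return X, squeeze

    def transform(self, X) -> np.ndarray:
        X, squeeze = self._check(X)
        Z = (X - self.min_) / self.range_
        Z[:, self.constant_] = 0.5
        return Z.ravel() if squeeze else Z

    def inverse_transform(self, Z) -> np.ndarray:
        Z, squeeze = self._check(Z)
        X = Z * self.range_ + self.min_
        X[:, self.constant_] = self.min_[self.constant_]
        return X.ravel() if squeeze else X


def normalize_fit_apply(train: Dataset, others=()):
    """Fit feature and label scalers on ``train`` and apply to all inputs.

    ``others`` may contain feature matrices (scaled with the feature scaler).
    Returns ``(train_scaled, scaled_others, x_scaler, y_scaler)``.
    """
    x_scaler = MinMaxScaler().fit(train.X)
    y_scaler = MinMaxScaler().fit(train.y)
    train_scaled = Dataset(x_scaler.transform(train.X), y_scaler.transform(train.y))
    scaled = [x_scaler.transform(np.asarray(o, dtype=float)) for o in others]
    return train_scaled, scaled, x_scaler, y_scaler


@dataclass(frozen=True)
class EvaluationReport:
    """RMSE, R^2 and MAE of a prediction against ground truth.

    R^2 is ``None`` (with a warning) when the truth is constant, since its
    denominator — total variation about the mean — vanishes.
    """

    rmse: float
    r2: float | None
    mae: float
    n: int


def evaluate(y_true, y_pred) -> EvaluationReport:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ShapeError(
            f"length mismatch: y_true {y_true.size}, y_pred {y_pred.size}"
        )
    if y_true.size < 2:
        raise ValidationError("need at least 2 samples to evaluate")
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    denom = float(np.sum((y_true - y_true.mean()) ** 2))
    if denom == 0.0:
        warnings.warn("constant y_true: R^2 undefined", stacklevel=2)
        r2 = None
    else:
        r2 = float(1.0 - np.sum(err**2) / denom)
    return EvaluationReport(rmse=rmse, r2=r2, mae=mae, n=y_true.size)


def _contiguous_folds(n: int, k: int):
    """Contiguous-block splits: time-series data would leak autocorrelation
    under random splits."""
    bounds = np.linspace(0, n, k + 1).astype(int)
    for i in range(k):
        test = np.arange(bounds[i], bounds[i + 1])
        train = np.concatenate([np.arange(0, bounds[i]), np.arange(bounds[i + 1], n)])
        yield train, test


def cv_rmse(data: Dataset, hp: LSSVMHyperparams, folds: int) -> float:
    """k-fold cross-validated RMSE of an LS-SVM at the given hyperparameters."""
    errs = []
    for tr, te in _contiguous_folds(data.n, folds):
        try:
            model = lssvm_fit(Dataset(data.X[tr], data.y[tr]), hp)
            pred = model.predict(data.X[te])
        except Exception:
            return _CV_PENALTY
        errs.append(np.mean((pred - data.y[te]) ** 2))
    return float(np.sqrt(np.mean(errs)))


def tune_lssvm(
    train: Dataset,
    optimizer: str = "ipso",
    config: PipelineConfig | None = None,
) -> tuple[LSSVMHyperparams, OptimizeResult]:
    """Select (gamma, sigma) minimizing k-fold CV RMSE over the search box."""
    config = config if config is not None else PipelineConfig()
    if optimizer not in ("ipso", "pso"):
        raise ValidationError(f"optimizer must be 'ipso' or 'pso', got {optimizer!r}")
    if train.n < config.folds + 2:
        raise ValidationError(
            f"dataset of {train.n} samples too small for {config.folds}-fold CV"
        )

    def objective(pos):
        gamma, sigma = pos
        try:
            hp = LSSVMHyperparams(float(gamma), float(sigma))
        except ValidationError:
            return _CV_PENALTY
        return cv_rmse(train, hp, config.folds)

    swarm = SwarmConfig(
        size=config.swarm_size,
        dims=2,
        lower=(_BOX_LOWER, _BOX_LOWER),
        upper=(GAMMA_MAX, SIGMA_MAX),
        max_iter=config.tune_iters,
        fitness_threshold=config.fitness_threshold,
        seed=config.seed,
        # the first particle starts at the documented initial gamma
        init_positions=((GAMMA_INIT, SIGMA_MAX / 2.0),),
    )
    run = ipso_optimize if optimizer == "ipso" else pso_optimize
    result = run(objective, swarm)
    gamma, sigma = result.x
    hp = LSSVMHyperparams(float(np.clip(gamma, _BOX_LOWER, GAMMA_MAX)),
                          float(np.clip(sigma, _BOX_LOWER, SIGMA_MAX)))
    return hp, result


@dataclass
class SoftSensorResult:
    """Predictions in original label units plus all fitted artifacts."""

    predictions: np.ndarray
    variant: str
    hyperparams: LSSVMHyperparams
    model: LSSVMModel
    x_scaler: MinMaxScaler
    y_scaler: MinMaxScaler
    tune_trace: np.ndarray | None = None
    bda: BDAResult | None = None


def _stage(name):
    logger.info("stage: %s", name)
    return _time.perf_counter()


def train_soft_sensor(
    source: Dataset, target_X, config: PipelineConfig
) -> SoftSensorResult:
    """Run the six-step workflow for one variant and one quality variable."""
    target_X = np.asarray(target_X, dtype=float)
    if target_X.ndim != 2 or target_X.shape[1] != source.d:
        raise ShapeError(
            f"target features must be 2-D with d={source.d} columns"
        )
    t0 = _stage("normalize")
    try:
        src, (tgt,), x_scaler, y_scaler = normalize_fit_apply(source, [target_X])
    except Exception as exc:
        raise PipelineError(f"stage 'normalize' failed: {exc}") from exc

    trace = None
    try:
        if config.variant == "lssvm":
            hp = LSSVMHyperparams(DEFAULT_GAMMA, DEFAULT_SIGMA)
        else:
            _stage("tune")
            optimizer = "pso" if config.variant == "pso-lssvm" else "ipso"
            hp, opt = tune_lssvm(src, optimizer, config)
            trace = opt.trace
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'tune' failed: {exc}") from exc

    try:
        _stage("fit-source")
        model = lssvm_fit(src, hp)
    except Exception as exc:
        raise PipelineError(f"stage 'fit-source' failed: {exc}") from exc

    bda_result = None
    if config.variant == "bda-ipso-lssvm":
        try:
            _stage("adapt")
            soft = model.predict(tgt)

            # Matched domains are fed back through the full model, whose first
            # step is normalization: each trainer call re-scales the (possibly
            # transformed) features before fitting.
            def trainer(X, y):
                scaler = MinMaxScaler().fit(X)
                inner = lssvm_fit(Dataset(scaler.transform(X), y), hp)

                def predictor(Xnew):
                    return inner.predict(scaler.transform(Xnew))

                return predictor

            bda_result, Zs, Zt, _ = bda_adapt(
                src.X, src.y, tgt, trainer, config.bda, initial_soft_labels=soft
            )
            _stage("retune-transformed")
            src_t = Dataset(Zs, src.y)
            hp, opt = tune_lssvm(src_t, "ipso", config)
            trace = opt.trace
            _stage("fit-transformed")
            model = lssvm_fit(src_t, hp)
            tgt = Zt
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'adapt' failed: {exc}") from exc

    try:
        _stage("predict")
        pred_scaled = model.predict(tgt)
        predictions = y_scaler.inverse_transform(pred_scaled)
    except Exception as exc:
        raise PipelineError(f"stage 'predict' failed: {exc}") from exc
    logger.info("pipeline finished in %.2f s", _time.perf_counter() - t0)
    return SoftSensorResult(
        predictions=predictions,
        variant=config.variant,
        hyperparams=hp,
        model=model,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        tune_trace=trace,
        bda=bda_result,
    )


def compare_models(
    scenario: TransferScenario,
    seeds,
    config: PipelineConfig | None = None,
    variants=VARIANTS,
    labels=("C", "P"),
) -> pd.DataFrame:
    """Evaluate each variant on each quality variable, median over seeds.

    Returns one row per (variant, output) with median RMSE, R^2 and MAE
    against the held-out target ground truth.
    """
    config = config if config is not None else PipelineConfig()
    rows = []
    for label in labels:
        source, target_X, truth = scenario.for_label(label)
        for variant in variants:
            per_seed = []
            for seed in seeds:
                cfg = replace(config, variant=variant, seed=int(seed))
                result = train_soft_sensor(source, target_X, cfg)
                rep = evaluate(truth, result.predictions)
                per_seed.append(
                    (rep.rmse, rep.r2 if rep.r2 is not None else np.nan, rep.mae)
                )
            arr = np.array(per_seed, dtype=float)
            rows.append(
                {
                    "variant": variant,
                    "output": label,
                    "rmse": float(np.median(arr[:, 0])),
                    "r2": float(np.median(arr[:, 1])),
                    "mae": float(np.median(arr[:, 2])),
                    "n_seeds": len(seeds),
                }
            )
            logger.info(
                "%s / %s: median RMSE %.4f", variant, label, rows[-1]["rmse"]
            )
    return pd.DataFrame(rows)
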