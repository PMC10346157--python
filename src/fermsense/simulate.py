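"""Mechanistic batch-fermentation simulator.

Emulates a 90 h *Pichia pastoris*-style batch cultivation sampled every 0.5 h
(180 samples per batch).  Biomass X, substrate S and product P follow Monod
growth with a Luedeking-Piret product law:

    dX/dt = mu_max * f(T, pH) * S/(Ks + S) * X
    dS/dt = -(1/Yxs) * dX/dt
    dP/dt = alpha_LP * dX/dt + beta_LP * X

where f(T, pH) is a product of quadratic penalties peaking at the process
optima (28 degC, pH 5.0).  Six auxiliary channels are generated around the
states: stirring speed v and airflow q ramp up with oxygen demand
(controller-like behaviour in the stated 300-400 rpm and 150-300 L/min
bands), dissolved oxygen Do declines with demand and recovers with
agitation/airflow, temperature and pH hold their setpoints, and headspace
pressure follows a mild scheduled ramp within 0.02-0.05 MPa.  Every channel
carries seeded Gaussian measurement noise.

Cross-batch distribution shift — the reason the transfer machinery exists —
is produced by giving the target domain different setpoints (e.g. +3 degC)
and tweaked kinetics (mu_max, Yxs), which shifts both the marginal
distribution of the auxiliary variables and the conditional relation between
them and the quality variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .lssvm import Dataset

__all__ = [
    "BatchConditions",
    "FermentationBatch",
    "TransferScenario",
    "source_conditions",
    "target_conditions",
    "simulate_batch",
    "make_transfer_scenario",
]

#: Batch grid: 180 samples at 0.5 h spacing over a 90 h cycle, t = 0.5 .. 90.
CYCLE_HOURS = 90.0
SAMPLE_INTERVAL = 0.5
N_SAMPLES = 180
_ODE_STEP = 0.05  # internal RK4 step, h

AUX_COLUMNS = ["v_rpm", "T_C", "q_Lmin", "pH", "Do_pct", "p_MPa"]

_DEFAULT_NOISE = {
    "v_rpm": 3.0,
    "T_C": 0.1,
    "q_Lmin": 2.0,
    "pH": 0.02,
    "Do_pct": 1.0,
    "p_MPa": 0.001,
}


@dataclass(frozen=True)
class BatchConditions:
    """Operating setpoints, kinetic parameters and noise levels for one batch."""

    temp_setpoint: float = 28.0  # degC
    ph_setpoint: float = 5.0
    agitation_base: float = 350.0  # rpm
    airflow_base: float = 225.0  # L/min
    pressure_base: float = 0.035  # MPa
    substrate_init: float = 40.0  # g/L
    biomass_init: float = 0.2  # g/L
    mu_max: float = 0.18  # 1/h
    ks: float = 0.5  # g/L
    yield_xs: float = 0.5  # g biomass / g substrate
    alpha_lp: float = 0.12  # g product / g biomass (growth-associated)
    beta_lp: float = 0.004  # g/(g h) (non-growth-associated)
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    seed: int = 0

    def __post_init__(self):
        if not 20.0 <= self.temp_setpoint <= 35.0:
            raise ValidationError(
                f"temp_setpoint must be in [20, 35] degC, got {self.temp_setpoint}"
            )
        if not 3.0 <= self.ph_setpoint <= 7.0:
            raise ValidationError(
                f"ph_setpoint must be in [3, 7], got {self.ph_setpoint}"
            )
        for name in ("agitation_base", "airflow_base", "pressure_base",
                     "substrate_init", "mu_max", "ks", "yield_xs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.biomass_init < 0 or self.alpha_lp < 0 or self.beta_lp < 0:
            raise ValidationError("biomass_init, alpha_lp, beta_lp must be >= 0")
        for ch, sd in self.noise_sd.items():
            if ch not in _DEFAULT_NOISE:
                raise ValidationError(f"unknown noise channel {ch!r}")
            if sd < 0:
                raise ValidationError(f"noise sd for {ch} must be >= 0")


def source_conditions(**overrides) -> BatchConditions:
    """Source-domain defaults: the stated process setpoints (28 degC, pH 5.0,
    300-400 rpm band, 150-300 L/min airflow, 0.02-0.05 MPa)."""
    return BatchConditions(**overrides)


def target_conditions(
    base: BatchConditions | None = None,
    *,
    temp_offset: float = 3.0,
    mu_max_factor: float = 0.85,
    yield_factor: float = 0.9,
    **overrides,
) -> BatchConditions:
    """Shifted target-domain conditions: a setpoint offset plus a kinetics
    tweak, producing both marginal and conditional distribution shift."""
    base = base if base is not None else BatchConditions()
    return replace(
        base,
        temp_setpoint=base.temp_setpoint + temp_offset,
        mu_max=base.mu_max * mu_max_factor,
        yield_xs=base.yield_xs * yield_factor,
        **overrides,
    )


@dataclass(frozen=True)
class FermentationBatch:
    """One simulated batch: the time grid, six auxiliary channels, quality
    variables (cell concentration C and product P) and the substrate
    trajectory kept for diagnostics."""

    time: np.ndarray  # hours, length 180
    aux: np.ndarray  # 180 x 6, columns AUX_COLUMNS
    C: np.ndarray  # g/L
    P: np.ndarray  # g/L
    S: np.ndarray  # g/L (not part of the file schema)
    conditions: BatchConditions

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.aux, columns=AUX_COLUMNS)
        df.insert(0, "time_h", self.time)
        df["C_gL"] = self.C
        df["P_gL"] = self.P
        return df


def _growth_modifier(T: float, pH: float) -> float:
    """Quadratic penalties peaking at 28 degC and pH 5.0."""
    ft = max(0.0, 1.0 - ((T - 28.0) / 8.0) ** 2)
    fp = max(0.0, 1.0 - ((pH - 5.0) / 1.5) ** 2)
    return ft * fp


def _integrate(cond: BatchConditions):
    """Fixed-step RK4 on (X, S, P), sampled onto the 0.5 h grid (t = 0.5..90)."""
    f_env = _growth_modifier(cond.temp_setpoint, cond.ph_setpoint)

    def rhs(state):
        X, S, P = state
        mu = cond.mu_max * f_env * S / (cond.ks + S) if S > 0 else 0.0
        dX = mu * X
        return np.array([dX, -dX / cond.yield_xs, cond.alpha_lp * dX + cond.beta_lp * X])

    steps_per_sample = round(SAMPLE_INTERVAL / _ODE_STEP)
    state = np.array([cond.biomass_init, cond.substrate_init, 0.0])
    X_out = np.empty(N_SAMPLES)
    S_out = np.empty(N_SAMPLES)
    P_out = np.empty(N_SAMPLES)
    dX_out = np.empty(N_SAMPLES)
    h = _ODE_STEP
    for i in range(N_SAMPLES):
        for _ in range(steps_per_sample):
            k1 = rhs(state)
            k2 = rhs(state + 0.5 * h * k1)
            k3 = rhs(state + 0.5 * h * k2)
            k4 = rhs(state + h * k3)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            state[1] = max(state[1], 0.0)  # substrate cannot go negative
        X_out[i], S_out[i], P_out[i] = state
        dX_out[i] = rhs(state)[0]
    time = SAMPLE_INTERVAL * np.arange(1, N_SAMPLES + 1)
    return time, X_out, S_out, P_out, dX_out


def simulate_batch(cond: BatchConditions) -> FermentationBatch:
    """Simulate one batch; deterministic under a fixed ``cond.seed``."""
    rng = np.random.default_rng(cond.seed)
    time, X, S, P, dX = _integrate(cond)

    # Oxygen demand (growth + maintenance), saturating controller signal.
    demand = dX + 0.05 * X
    u = demand / (demand + 1.0)
    v = cond.agitation_base + 100.0 * u
    q = cond.airflow_base + 150.0 * u
    kla_rel = (v / 400.0) * (q / 300.0)
    do = 100.0 * (1.0 - 0.8 * demand / (demand + 2.0 * kla_rel))
    p = cond.pressure_base + 0.01 * (time / CYCLE_HOURS) + 0.004 * u
    T = np.full(N_SAMPLES, cond.temp_setpoint)
    ph = np.full(N_SAMPLES, cond.ph_setpoint)

    clean = np.column_stack([v, T, q, ph, do, p])
    noise = np.column_stack(
        [rng.normal(0.0, cond.noise_sd.get(ch, 0.0), N_SAMPLES) for ch in AUX_COLUMNS]
    )
    aux = clean + noise
    do_col = AUX_COLUMNS.index("Do_pct")
    aux[:, do_col] = np.clip(aux[:, do_col], 0.0, 100.0)

    if not np.isfinite(aux).all():
        raise ValidationError("simulation produced non-finite auxiliary values")
    return FermentationBatch(
        time=time, aux=aux, C=X, P=P, S=S, conditions=cond
    )


@dataclass(frozen=True)
class TransferScenario:
    """A source/target pair of multi-batch datasets with held-out target labels."""

    source_aux: np.ndarray
    source_C: np.ndarray
    source_P: np.ndarray
    target_aux: np.ndarray
    target_C: np.ndarray  # ground truth, never shown to the pipeline
    target_P: np.ndarray
    source_batches: list
    target_batches: list

    def for_label(self, label: str):
        """Return ``(source Dataset, target features, target ground truth)``
        for quality variable ``label`` in {"C", "P"}."""
        if label not in ("C", "P"):
            raise ValidationError(f"label must be 'C' or 'P', got {label!r}")
        y_s = self.source_C if label == "C" else self.source_P
        y_t = self.target_C if label == "C" else self.target_P
        return Dataset(self.source_aux, y_s), self.target_aux, y_t


def _batch_jitter(cond: BatchConditions, rng) -> BatchConditions:
    """Small batch-to-batch variability in inoculum and medium within a domain."""
    return replace(
        cond,
        biomass_init=cond.biomass_init * (1.0 + rng.uniform(-0.1, 0.1)),
        substrate_init=cond.substrate_init * (1.0 + rng.uniform(-0.05, 0.05)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_transfer_scenario(
    source_cond: BatchConditions,
    target_cond: BatchConditions,
    n_source_batches: int = 2,
    n_target_batches: int = 1,
    seed: int = 0,
) -> TransferScenario:
    """Simulate a cross-batch transfer scenario.

    Target labels are returned separately as ground truth and must never be
    given to the soft-sensor pipeline.  Requesting identical conditions is
    allowed (useful as a no-shift control) but warned about.
    """
    if n_source_batches < 1 or n_target_batches < 1:
        raise ValidationError("need at least one batch per domain")
    comparable = replace(source_cond, seed=0), replace(target_cond, seed=0)
    if comparable[0] == comparable[1]:
        warnings.warn(
            "source and target conditions are identical; scenario has no "
            "distribution shift",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    src = [
        simulate_batch(_batch_jitter(source_cond, rng))
        for _ in range(n_source_batches)
    ]
    tgt = [
        simulate_batch(_batch_jitter(target_cond, rng))
        for _ in range(n_target_batches)
    ]
    return TransferScenario(
        source_aux=np.vstack([b.aux for b in src]),
        source_C=np.concatenate([b.C for b in src]),
        source_P=np.concatenate([b.P for b in src]),
        target_aux=np.vstack([b.aux for b in tgt]),
        target_C=np.concatenate([b.C for b in tgt]),
        target_P=np.concatenate([b.P for b in tgt]),
        source_batches=src,
        target_batches=tgt,
    )
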