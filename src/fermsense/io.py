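"""Batch-file readers/writers and pipeline configuration loading.

Single file dialect: UTF-8 CSV, comma delimiter, '.' decimal, header
required.  Labelled batch files carry nine columns
(time_h, v_rpm, T_C, q_Lmin, pH, Do_pct, p_MPa, C_gL, P_gL); unlabelled
target files carry the first seven.  Validation is strict — a missing column
or a non-numeric cell is an error naming the file, column and row, never a
silent coercion — and nothing ever writes NaN to disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError
from .fuzzy_bda import BDAConfig
from .pipeline import PipelineConfig
from .simulate import AUX_COLUMNS, FermentationBatch

__all__ = [
    "BATCH_COLUMNS",
    "LABEL_COLUMNS",
    "BatchData",
    "write_batch",
    "read_batches",
    "load_config",
    "save_config",
    "setup_logging",
]

logger = logging.getLogger("fermsense.io")

BATCH_COLUMNS = ["time_h"] + AUX_COLUMNS  # the seven unlabelled columns
LABEL_COLUMNS = ["C_gL", "P_gL"]

_FLOAT_FORMAT = "%.17g"  # lossless round trip for doubles


@dataclass
class BatchData:
    """Row-concatenated batches: auxiliary features, optional labels, and the
    batch of origin recorded per row.  ``labels`` is ``None`` — an explicit
    absent marker, never zeros — when label columns are missing."""

    time: np.ndarray
    X: np.ndarray  # n x 6 auxiliary matrix
    labels: dict | None  # {"C": ..., "P": ...} in g/L
    batch_index: np.ndarray
    paths: list


def write_batch(batch, path) -> None:
    """Write one batch (a :class:`FermentationBatch` or a ready dataframe)."""
    df = batch.to_dataframe() if isinstance(batch, FermentationBatch) else batch
    missing = [c for c in BATCH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {path}: missing column(s) {missing}")
    if df.isna().any().any():
        raise ValidationError(f"refusing to write NaN values to {path}")
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT, encoding="utf-8")


def _read_one(path: Path, require_labels: bool | None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in BATCH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    has_labels = all(c in df.columns for c in LABEL_COLUMNS)
    if require_labels and not has_labels:
        raise SchemaError(f"{path}: label column(s) {LABEL_COLUMNS} required")
    cols = BATCH_COLUMNS + (LABEL_COLUMNS if has_labels else [])
    for col in cols:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
        else:
            continue
        row = int(np.nonzero(bad.isna().to_numpy() & df[col].notna().to_numpy())[0][0])
        raise SchemaError(
            f"{path}: non-numeric cell in column {col!r} at row {row}"
        )
    if df[cols].isna().any().any():
        raise SchemaError(f"{path}: missing values are not allowed")
    return df[cols]


def read_batches(paths, require_labels: bool | None = None) -> BatchData:
    """Read and row-concatenate one or more batch files.

    All files must agree on whether labels are present; mixing labelled and
    unlabelled files is a schema error.
    """
    paths = [Path(p) for p in (paths if isinstance(paths, (list, tuple)) else [paths])]
    if not paths:
        raise ValidationError("no paths given")
    frames = [_read_one(p, require_labels) for p in paths]
    labelled = [set(LABEL_COLUMNS) <= set(f.columns) for f in frames]
    if len(set(labelled)) > 1:
        raise SchemaError("cannot mix labelled and unlabelled batch files")
    df = pd.concat(frames, ignore_index=True)
    batch_index = np.concatenate(
        [np.full(len(f), i) for i, f in enumerate(frames)]
    )
    labels = None
    if labelled[0]:
        labels = {"C": df["C_gL"].to_numpy(), "P": df["P_gL"].to_numpy()}
    return BatchData(
        time=df["time_h"].to_numpy(),
        X=df[AUX_COLUMNS].to_numpy(),
        labels=labels,
        batch_index=batch_index,
        paths=paths,
    )


def write_scenario_csvs(scenario, out_dir) -> list:
    """Write a transfer scenario as per-batch CSVs: labelled source batches,
    unlabelled target batches, and the held-out target labels in separate
    ``*_labels.csv`` files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, batch in enumerate(scenario.source_batches, start=1):
        p = out / f"source_{i:02d}.csv"
        write_batch(batch, p)
        paths.append(p)
    for i, batch in enumerate(scenario.target_batches, start=1):
        df = batch.to_dataframe()
        p = out / f"target_{i:02d}.csv"
        write_batch(df[BATCH_COLUMNS], p)
        paths.append(p)
        lp = out / f"target_{i:02d}_labels.csv"
        df[["time_h"] + LABEL_COLUMNS].to_csv(
            lp, index=False, float_format=_FLOAT_FORMAT, encoding="utf-8"
        )
        paths.append(lp)
    return paths


# --- configuration ---------------------------------------------------------

_BDA_KEYS = {f.name for f in fields(BDAConfig)}
_PIPE_KEYS = {f.name for f in fields(PipelineConfig)} - {"bda"}


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration.

    An empty file yields all documented defaults (search box gamma <= 300,
    sigma <= 50, mu = 0.62, swarm size 100).  Unknown keys are rejected and
    every value is validated against its type invariant; the effective
    configuration is echoed to the log.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _PIPE_KEYS - {"bda"}
    if unknown:
        raise ValidationError(
            f"{path}: unknown configuration key(s) {sorted(unknown)}"
        )
    bda_raw = raw.pop("bda", {}) or {}
    if not isinstance(bda_raw, dict):
        raise ValidationError(f"{path}: 'bda' must be a mapping")
    unknown = set(bda_raw) - _BDA_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown bda key(s) {sorted(unknown)}")
    try:
        config = PipelineConfig(bda=BDAConfig(**bda_raw), **raw)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    logger.info("loaded configuration: %s", config)
    return config


def save_config(config: PipelineConfig, path) -> None:
    payload = {
        f.name: getattr(config, f.name) for f in fields(PipelineConfig)
        if f.name != "bda"
    }
    payload["bda"] = {f.name: getattr(config.bda, f.name) for f in fields(BDAConfig)}
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=False), encoding="utf-8"
    )


def setup_logging(level=logging.INFO) -> None:
    """Timestamp / level / stage / message format on the package logger."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s")
    )
    root = logging.getLogger("fermsense")
    root.setLevel(level)
    if not root.handlers:
        root.addHandler(handler)
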