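"""Reading and writing the package's delimited-text formats.

Long-format measurements (patient_id, hours_postop, cortisol_mcg_dl),
one-row-per-patient covariates, per-patient label CSVs, and YAML/JSON
generator configs.  Missing cells are absent rows / empty fields, never
sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ClusterProfile, GeneratorConfig, make_default_profiles
from .kpod import DataMatrix
from .pipeline import bin_to_grid, censor_after_steroids

logger = logging.getLogger(__name__)

__all__ = [
    "read_measurements", "read_covariates", "read_labels", "write_labels",
    "matrix_from_measurements", "load_config", "dump_config",
]


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "hours_postop", "cortisol_mcg_dl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurements file lacks columns: {sorted(missing)}")
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("covariates file needs a patient_id column")
    return df


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_labels(path, row_ids, labels) -> None:
    pd.DataFrame({"patient_id": row_ids, "cluster": labels}).to_csv(path, index=False)


def matrix_from_measurements(df: pd.DataFrame, grid,
                             steroid_times: dict | None = None) -> DataMatrix:
    """Pivot long-format measurements to the grid; steroid censoring is
    applied per patient when times are supplied; patients with no
    observed on-grid value are dropped with a logged count."""
    rows, ids = [], []
    dropped = 0
    for pid, g in df.groupby("patient_id", sort=True):
        traj = bin_to_grid(g["hours_postop"].to_numpy(),
                           g["cortisol_mcg_dl"].to_numpy(),
                           grid=grid, patient_id=str(pid))
        if steroid_times is not None:
            traj = censor_after_steroids(traj, steroid_times.get(pid))
        if traj.observed_mask.any():
            rows.append(traj.values)
            ids.append(pid)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d patients with no on-grid observed values", dropped)
    if not rows:
        raise ValueError("no patients with observed values on the grid")
    return DataMatrix(np.vstack(rows), row_ids=ids,
                      col_hours=np.asarray(grid, dtype=float))


def load_config(path) -> GeneratorConfig:
    """YAML/JSON mirror of GeneratorConfig; profiles may be given inline
    as {label, mean_curve, sd_curve, mixing_weight} or named by group."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    profiles = raw.pop("profiles", None)
    if isinstance(profiles, str):
        raw["covariate_group"] = raw.get("covariate_group", profiles)
        profiles = make_default_profiles(profiles)
    elif profiles is not None:
        profiles = [ClusterProfile(**p) for p in profiles]
    for key in ("grid", "fixed_counts"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return GeneratorConfig(profiles=tuple(profiles) if profiles else None, **raw)


def dump_config(config: GeneratorConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["profiles"] = [dataclasses.asdict(p) for p in config.profiles]
    Path(path).write_text(yaml.safe_dump(_jsonable(d), sort_keys=False))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
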