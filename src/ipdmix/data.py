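"""Participant-level IPD tables: schema, validation and CSV round-trip.

An IPD table is a long-format :class:`pandas.DataFrame` with one row per
participant and the columns

    study_id   integer study label
    treatment  0/1 arm indicator
    x1..x4     standard-normal baseline covariates
    y_cont     continuous outcome (NaN when missing)
    y_bin      binary outcome in {0, 1} (NaN when missing)

Missing outcomes are marked with NaN; the observed/missing indicators
``r_cont``/``r_bin`` are derived, never stored.  This module is the lingua
franca shared by the data generator, the samplers and the imputers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

IPD_COLUMNS = ["study_id", "treatment", "x1", "x2", "x3", "x4", "y_cont", "y_bin"]
COVARIATES = ["x1", "x2", "x3", "x4"]


def validate_ipd(df: pd.DataFrame) -> pd.DataFrame:
    """Check the IPD schema and invariants; return the validated frame.

    Raises ``ValueError`` with a specific message on the first violation.
    """
    missing_cols = [c for c in IPD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"IPD table missing columns: {missing_cols}")
    if len(df) == 0:
        raise ValueError("IPD table is empty")
    treat = df["treatment"].to_numpy()
    if not np.isin(treat, [0, 1]).all():
        raise ValueError("treatment must be 0/1")
    yb = df["y_bin"].to_numpy(dtype=float)
    obs = ~np.isnan(yb)
    if not np.isin(yb[obs], [0.0, 1.0]).all():
        raise ValueError("observed y_bin values must lie in {0, 1}")
    counts = df.groupby("study_id").size()
    if (counts < 1).any():
        raise ValueError("every study must contain at least one row")
    return df


def observed_mask(df: pd.DataFrame, outcome: str) -> np.ndarray:
    """Boolean array, True where ``outcome`` ('y_cont' or 'y_bin') is observed."""
    return ~df[outcome].isna().to_numpy()


def is_complete(df: pd.DataFrame) -> bool:
    return bool(observed_mask(df, "y_cont").all() and observed_mask(df, "y_bin").all())


def design_matrix(df: pd.DataFrame) -> np.ndarray:
    """Fixed-effect design (intercept, treatment, x1..x4), shape (n, 6).

    Both outcome margins condition on the full covariate set so that every
    variable entering a missingness mechanism is also in the analysis model,
    the standard requirement for missing-at-random validity.
    """
    n = len(df)
    X = np.empty((n, 6))
    X[:, 0] = 1.0
    X[:, 1] = df["treatment"].to_numpy(dtype=float)
    X[:, 2:] = df[COVARIATES].to_numpy(dtype=float)
    return X


def study_index(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Map study_id to a dense 0..J-1 index; returns (index array, unique ids)."""
    ids, idx = np.unique(df["study_id"].to_numpy(), return_inverse=True)
    return idx.astype(np.int64), ids


def write_ipd_csv(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write an IPD table as CSV (empty fields mark missing outcomes).

    Optional run metadata (seeds, scenario parameters) goes in a JSON sidecar
    next to the CSV.
    """
    path = Path(path)
    validate_ipd(df)
    df.to_csv(path, index=False, columns=IPD_COLUMNS)
    if metadata is not None:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(metadata, indent=2, default=float)
        )


def read_ipd_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["study_id"] = df["study_id"].astype(int)
    df["treatment"] = df["treatment"].astype(int)
    return validate_ipd(df)
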