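"""Readers, writers and configuration.

Runner records and split profiles travel as CSV; the deposited study
database (a MATLAB .mat file) can be ingested when present but is never
required.  YAML configs map one block per model family onto estimator
parameters.  Loaders validate rows and report exclusion counts rather than
failing on individual bad records.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ddpmix")

__all__ = ["Dataset", "read_runners_csv", "read_splits_csv", "read_mat_database", "load_config"]

RUNNER_COLUMNS = ("age", "gender", "finish_time")


@dataclass
class Dataset:
    """Validated records plus provenance."""

    records: pd.DataFrame
    schema: dict
    provenance: dict = field(default_factory=dict)
    n_excluded: int = 0


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def read_runners_csv(path, unit: str = "minutes", required=RUNNER_COLUMNS) -> Dataset:
    """Load finishing-time records; invalid rows (non-positive or missing
    times) are excluded with a logged count.  ``unit='hours'`` converts
    times to minutes on load."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing} (found {list(df.columns)})")
    n0 = len(df)
    ok = pd.to_numeric(df["finish_time"], errors="coerce") > 0
    df = df[ok.fillna(False)].copy()
    df["finish_time"] = df["finish_time"].astype(float)
    if unit == "hours":
        df["finish_time"] *= 60.0
    elif unit != "minutes":
        raise ValueError(f"unit must be 'minutes' or 'hours', got {unit!r}")
    n_excluded = n0 - len(df)
    if n_excluded:
        logger.info("read_runners_csv: excluded %d invalid rows of %d", n_excluded, n0)
    return Dataset(
        records=df.reset_index(drop=True),
        schema={"unit": "minutes", "columns": list(df.columns)},
        provenance={"path": str(path), "sha256": _checksum(path)},
        n_excluded=n_excluded,
    )


def read_splits_csv(path, unit: str = "minutes", interval_lengths=None) -> Dataset:
    """Load cumulative split records (columns ``split_1..split_D``); rows
    with non-monotone or non-positive cumulative times are excluded.

    An interval scheme may be declared in a ``<name>.scheme.json`` sidecar
    (key ``interval_lengths``) or passed directly.
    """
    path = Path(path)
    df = pd.read_csv(path)
    split_cols = [c for c in df.columns if c.startswith("split_")]
    if not split_cols:
        raise ValueError("no split_* columns found")
    split_cols = sorted(split_cols, key=lambda c: int(c.split("_")[1]))
    sidecar = path.with_suffix(".scheme.json")
    if interval_lengths is None and sidecar.exists():
        with open(sidecar) as fh:
            interval_lengths = json.load(fh).get("interval_lengths")
    vals = df[split_cols].to_numpy(dtype=float)
    if unit == "hours":
        vals *= 60.0
    ok = (
        np.all(np.isfinite(vals), axis=1)
        & (vals[:, 0] > 0)
        & np.all(np.diff(vals, axis=1) > 0, axis=1)
    )
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("read_splits_csv: excluded %d non-monotone rows of %d", n_excluded, len(df))
    out = df.loc[ok].copy()
    out[split_cols] = vals[ok]
    return Dataset(
        records=out.reset_index(drop=True),
        schema={
            "unit": "minutes",
            "split_columns": split_cols,
            "interval_lengths": list(interval_lengths) if interval_lengths is not None else None,
        },
        provenance={"path": str(path), "sha256": _checksum(path)},
        n_excluded=n_excluded,
    )


def read_mat_database(path) -> Dataset:
    """Best-effort ingest of the deposited MATLAB race database.

    The internal layout is discovered at runtime: any numeric 2-d array is
    offered as a candidate record table, and conventional variable names
    (age / gender / sex / time / net) are mapped when present.  Raises a
    descriptive error listing the variables found when no mapping works.
    """
    from scipy.io import loadmat

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MAT database not found: {path}")
    raw = loadmat(path, squeeze_me=True, struct_as_record=False)
    variables = {k: v for k, v in raw.items() if not k.startswith("__")}
    frames = {}
    for name, val in variables.items():
        arr = np.asarray(val)
        lname = name.lower()
        if arr.dtype.kind in "if" and arr.ndim in (1, 2):
            frames[lname] = arr
    cols = {}
    for key, aliases in {
        "age": ("age", "ages"),
        "gender": ("gender", "sex"),
        "finish_time": ("finish_time", "net_time", "time", "nettime", "finish"),
    }.items():
        for a in aliases:
            if a in frames and frames[a].ndim == 1:
                cols[key] = frames[a]
                break
    if len(cols) == 3 and len({len(v) for v in cols.values()}) == 1:
        df = pd.DataFrame(cols)
        logger.info("read_mat_database: %d runner records from %s", len(df), path.name)
        return Dataset(
            records=df,
            schema={"unit": "minutes", "columns": list(df.columns)},
            provenance={"path": str(path), "sha256": _checksum(path)},
        )
    raise ValueError(
        "could not map MAT contents to runner records; variables found: "
        + ", ".join(f"{k}{np.shape(v)}" for k, v in variables.items())
    )


def load_config(path) -> dict:
    """Load a YAML config with one block per model family (``addp``,
    ``hdp``, ``synthetic``); unknown blocks are preserved verbatim."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
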