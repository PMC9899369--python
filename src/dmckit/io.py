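"""Trial-table and effects CSV input/output with strict schema validation.

The interchange format for trial-level data is a comma-delimited, UTF-8 CSV
with a header and columns ``participant, task, condition, rt_ms, correct``
(plus an optional ``block`` and any extra columns, which are preserved).
RTs are in milliseconds; ``correct`` is 0/1; ``condition`` is one of
congruent / incongruent / neutral.  Malformed files raise
:class:`TrialTableError` naming the offending column or 1-based file line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CONDITIONS
from .preprocessing import REQUIRED_COLUMNS

__all__ = [
    "TrialTableError",
    "read_trial_table",
    "write_trial_table",
    "read_effects",
    "run_log",
]


class TrialTableError(ValueError):
    """Raised for schema violations in a trial-table CSV."""


def _bad_lines(mask: pd.Series) -> str:
    # +2: one for the header, one for 0- vs 1-based indexing
    lines = (np.flatnonzero(mask.to_numpy()) + 2)[:5]
    return ", ".join(map(str, lines))


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialTableError(f"{path.name}: missing required column {col!r}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    if rt.isna().any():
        raise TrialTableError(
            f"{path.name}: non-numeric rt_ms on line(s) {_bad_lines(rt.isna())}"
        )
    if (rt <= 0).any():
        raise TrialTableError(
            f"{path.name}: non-positive rt_ms on line(s) {_bad_lines(rt <= 0)}"
        )
    df["rt_ms"] = rt.astype(float)
    correct = pd.to_numeric(df["correct"], errors="coerce")
    bad = ~correct.isin([0, 1])
    if bad.any():
        raise TrialTableError(
            f"{path.name}: correct must be 0 or 1 on line(s) {_bad_lines(bad)}"
        )
    df["correct"] = correct.astype(int)
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        raise TrialTableError(
            f"{path.name}: unknown condition label on line(s) {_bad_lines(bad)}"
        )
    return df


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (round-trips through read_trial_table)."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise TrialTableError(f"cannot write table missing column {col!r}")
    table.to_csv(path, index=False)


def read_effects(path) -> pd.DataFrame:
    """Read a correlations CSV (columns: measure, rho, n, dataset_id)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("measure", "rho", "n", "dataset_id"):
        if col not in df.columns:
            raise TrialTableError(f"{path.name}: missing required column {col!r}")
    rho = pd.to_numeric(df["rho"], errors="coerce")
    if rho.isna().any() or (rho.abs() >= 1).any():
        raise TrialTableError(f"{path.name}: rho must be numeric with |rho| < 1")
    return df


def run_log(out_dir, command: str, seed: int | None, config: dict, counts: dict | None = None) -> Path:
    """Write a JSON run log (seed, config and its hash, package version,
    bookkeeping counts) sufficient to re-run the command bit-identically."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    log = {
        "command": command,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "dmckit_version": __version__,
        "counts": counts or {},
    }
    path = out_dir / f"{command}_log.json"
    path.write_text(json.dumps(log, indent=2, default=str))
    return path
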