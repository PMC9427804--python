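"""CSV interchange for syllectograms and cohort tables.

There is no community file standard for syllectograms, so the package
fixes a minimal CSV layout: required columns ``time_s`` and ``intensity``,
any further columns treated as constant per-file metadata.  Times are
re-based so the first sample is t = 0 (the offset is logged) because
recordings are referenced to the end of stirring, not to the acquisition
clock.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .kinetics import Syllectogram

__all__ = [
    "read_syllectogram_csv",
    "write_syllectogram_csv",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_REQUIRED = ("time_s", "intensity")
_FLOAT_FMT = "%.12g"  # round-trips doubles well below the 1e-9 contract


def read_syllectogram_csv(path: str | Path) -> Syllectogram:
    """Read and validate a syllectogram CSV.

    Raises descriptive errors (with 1-based data row numbers) for missing
    columns, fewer than 8 rows, non-monotone times or non-positive
    intensities.  Extra columns are collapsed into ``meta`` when constant.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) < 8:
        raise ValueError(f"{path}: only {len(df)} rows; a recording needs >= 8")
    t = df["time_s"].to_numpy(dtype=float)
    y = df["intensity"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
        row = int(np.argmax(~(np.isfinite(t) & np.isfinite(y)))) + 1
        raise ValueError(f"{path}: non-finite value at data row {row}")
    bad = np.diff(t) <= 0
    if bad.any():
        row = int(np.argmax(bad)) + 2
        raise ValueError(f"{path}: time not strictly increasing at data row {row}")
    if (y <= 0).any():
        row = int(np.argmax(y <= 0)) + 1
        raise ValueError(f"{path}: non-positive intensity at data row {row}")
    if t[0] != 0.0:
        logger.info("%s: re-basing times by -%.6g s", path, t[0])
        t = t - t[0]
    meta: dict[str, Any] = {"source": str(path)}
    for col in df.columns:
        if col in _REQUIRED:
            continue
        vals = df[col].unique()
        if len(vals) == 1:
            meta[col] = vals[0]
    return Syllectogram(t, y, meta)


def write_syllectogram_csv(s: Syllectogram, path: str | Path) -> Path:
    """Write a syllectogram to CSV (columns ``time_s``, ``intensity``).

    Scalar metadata entries become constant extra columns so they survive a
    round trip.
    """
    path = Path(path)
    df = pd.DataFrame({"time_s": s.times, "intensity": s.intensities})
    for key, val in s.meta.items():
        if isinstance(val, (str, int, float, bool)):
            df[key] = val
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_manifest(path: str | Path, **entries: Any) -> Path:
    """Write a reproducibility manifest (config, seeds, package version) as JSON."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"eakit_version": __version__, **entries}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
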