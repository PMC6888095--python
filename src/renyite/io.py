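"""Plain-text I/O: numeric CSV trials, result tables, JSON manifests."""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError

__all__ = ["read_series_csv", "write_series_csv", "write_results", "write_manifest"]


def read_series_csv(path):
    """Read one trial from CSV (columns = channels, rows = samples).

    A header row is auto-detected when its cells are non-numeric.  Returns
    ``(data, channel_names)`` with ``data`` of shape (channels, samples).
    """
    path = Path(path)
    try:
        first = path.open().readline()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if not first.strip():
        raise ParseError(f"{path} is empty")
    tokens = [t.strip() for t in first.strip().split(",")]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens)
    df = pd.read_csv(
        path, header=0 if has_header else None, float_precision="round_trip"
    )
    names = [str(c) for c in df.columns] if has_header else [
        f"ch{i}" for i in range(df.shape[1])
    ]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + (2 if has_header else 1)
            raise ParseError(f"{path}: non-numeric value on line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + (2 if has_header else 1)
            raise ParseError(f"{path}: missing value on line {line}")
        df[col] = coerced
    return df.to_numpy(dtype=float).T, names


def write_series_csv(data: np.ndarray, path, channel_names=None) -> None:
    """Write a (channels, samples) array as CSV columns, full precision."""
    data = np.asarray(data, dtype=float)
    names = channel_names or [f"ch{i}" for i in range(data.shape[0])]
    pd.DataFrame(data.T, columns=names).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_manifest(path, payload: dict) -> None:
    """JSON manifest with a content hash for tamper/mix-up detection."""
    body = json.dumps(payload, sort_keys=True, default=str)
    payload = dict(payload)
    payload["manifest_hash"] = hashlib.sha256(body.encode()).hexdigest()[:12]
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
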