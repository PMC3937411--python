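"""Delimited-text matrix I/O and structured JSON result records."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

__all__ = ["read_matrix", "write_matrix", "read_vector", "inputs_hash", "write_result"]

_FMT = "%.17g"  # lossless round-trip for float64


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a comma-separated matrix; a leading non-numeric row is a header."""
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    with path.open() as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split(",")]
            try:
                row = [float(c) for c in cells]
            except ValueError:
                if lineno == 0:
                    continue  # header row
                raise ValueError(f"{path}: non-numeric value on line {lineno + 1}")
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(f"{path}: ragged row on line {lineno + 1}")
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def write_matrix(path: str | Path, mat: np.ndarray, header: str | None = None) -> Path:
    path = Path(path)
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, mat, fmt=_FMT, delimiter=",", header=header or "", comments="")
    return path


def read_vector(path: str | Path) -> np.ndarray:
    mat = read_matrix(path)
    if 1 not in mat.shape and mat.ndim > 1 and min(mat.shape) > 1:
        raise ValueError(f"{path}: expected a vector, got shape {mat.shape}")
    return mat.ravel()


def inputs_hash(*arrays: np.ndarray) -> str:
    """Stable hash of the numeric inputs of a computation."""
    h = hashlib.sha256()
    for arr in arrays:
        a = np.ascontiguousarray(np.asarray(arr, dtype=float))
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()[:16]


def write_result(path: str | Path, record: dict, seed: int | None = None) -> Path:
    """Write a JSON result record, echoing seed, timestamp and version."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(record)
    payload.setdefault("seed", seed)
    payload.setdefault("version", __version__)
    payload.setdefault("timestamp", time.strftime("%Y-%m-%dT%H:%M:%S"))
    path.write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
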