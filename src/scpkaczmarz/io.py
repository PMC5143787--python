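"""Readers and writers: MatrixMarket matrices, single-column CSV vectors,
flat key-value configuration files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import ParseError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_vector",
    "write_vector",
    "read_config",
    "write_config",
]


def read_matrix(path) -> np.ndarray:
    """Read a real MatrixMarket file (coordinate or array format) as a dense array."""
    path = Path(path)
    try:
        m = scipy.io.mmread(path)
    except Exception as exc:
        raise ParseError(f"{path}: not a valid MatrixMarket file ({exc})") from exc
    if sp.issparse(m):
        m = m.toarray()
    return np.asarray(m, dtype=float)


def write_matrix(matrix: np.ndarray, path) -> None:
    """Write a matrix in MatrixMarket array format at full double precision."""
    scipy.io.mmwrite(Path(path), np.asarray(matrix, dtype=float), precision=17)


def read_vector(path) -> np.ndarray:
    """Read a single-column CSV vector (one header line naming the node order)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    values = []
    for row, line in enumerate(lines[1:], start=2):
        cell = line.strip()
        if not cell:
            continue
        try:
            values.append(float(cell))
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric cell {cell!r} at row {row}") from exc
    return np.asarray(values, dtype=float)


def write_vector(vector: np.ndarray, path, header: str = "value_row_major") -> None:
    """Write a vector as single-column CSV; the header names the row ordering."""
    vector = np.asarray(vector, dtype=float).ravel()
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for v in vector:
            fh.write(f"{v:.17g}\n")


def read_config(path) -> dict[str, str]:
    """Read a flat ``key = value`` configuration file; '#' starts a comment."""
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}: line {lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        key = key.strip()
        if not key:
            raise ParseError(f"{path}: line {lineno}: empty key")
        if key in out:
            raise ParseError(f"{path}: line {lineno}: duplicate key {key!r}")
        out[key] = value.strip()
    return out


def write_config(config: dict, path) -> None:
    """Write a flat key-value configuration file."""
    with open(path, "w") as fh:
        for key, value in config.items():
            fh.write(f"{key} = {value}\n")
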