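"""Readers and writers for the workbench's on-disk formats.

TIFF stacks (tifffile), CSV tables (pandas), plain-text contour files with
one "x y" pair per line, FASTA (Biopython) and JSON configs.  Image
coordinates are 0-based (row, col); contour files use (x, y) image
coordinates with y increasing downward.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

__all__ = [
    "read_tiff",
    "write_tiff",
    "read_contour",
    "write_contour",
    "read_fasta",
    "write_fasta",
    "read_csv",
    "write_csv",
    "read_sweeps_csv",
    "write_sweeps_csv",
    "file_digest",
    "DataError",
]


class DataError(RuntimeError):
    """Malformed input data (names file and offending record)."""


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing input: {p}")
    return p


def read_tiff(path: str | Path) -> np.ndarray:
    try:
        return tifffile.imread(_require(path))
    except (tifffile.TiffFileError, ValueError) as err:
        raise DataError(f"{path}: not a readable TIFF ({err})") from err


def write_tiff(path: str | Path, array: np.ndarray) -> None:
    arr = np.asarray(array)
    kwargs = {"photometric": "minisblack"} if arr.ndim == 3 else {}
    tifffile.imwrite(path, arr, **kwargs)


def read_contour(path: str | Path) -> np.ndarray:
    """Plain-text outline: one "x y" pair per line."""
    pts = []
    for lineno, line in enumerate(_require(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise DataError(f"{path}:{lineno}: expected 'x y', got {line!r}")
        try:
            pts.append((float(parts[0]), float(parts[1])))
        except ValueError as err:
            raise DataError(f"{path}:{lineno}: non-numeric coordinate") from err
    if len(pts) < 3:
        raise DataError(f"{path}: a contour needs at least 3 points")
    return np.asarray(pts, dtype=float)


def write_contour(path: str | Path, contour: np.ndarray) -> None:
    lines = [f"{x:.12g} {y:.12g}" for x, y in np.asarray(contour, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list:
    try:
        records = list(SeqIO.parse(str(_require(path)), "fasta"))
    except ValueError as err:
        raise DataError(f"{path}: malformed FASTA ({err})") from err
    if not records:
        raise DataError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, records: list) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(_require(path))
    except pd.errors.ParserError as err:
        raise DataError(f"{path}: malformed CSV ({err})") from err


def write_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_sweeps_csv(path: str | Path, time_s: np.ndarray, sweeps: np.ndarray) -> None:
    """Sweep matrix as CSV: column 0 = time, one column per sweep."""
    data = {"time_s": np.asarray(time_s, dtype=float)}
    for k, sweep in enumerate(np.atleast_2d(sweeps)):
        data[f"sweep_{k:02d}"] = sweep
    pd.DataFrame(data).to_csv(path, index=False)


def read_sweeps_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise DataError(f"{path}: expected a time_s column followed by sweeps")
    return df["time_s"].to_numpy(), df.iloc[:, 1:].to_numpy().T


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    try:
        return json.loads(_require(path).read_text())
    except json.JSONDecodeError as err:
        raise DataError(f"{path}: malformed JSON ({err})") from err
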