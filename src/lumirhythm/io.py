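"""Reading and writing plate recordings.

On-disk dialect
---------------
A plate is a wide UTF-8 CSV: first column ``time_h`` (hours, decimal point,
no thousands separators), one column per well.  Conditions and replicate
indices live in a YAML sidecar::

    conditions:
      A1: NIH3T3
      A2: NIH3T3
    replicates:
      A1: 1
      A2: 2

``write_plate`` stores numbers with shortest round-trip ``repr`` precision,
so a write → read cycle reproduces every value bit-for-bit.  The reader
validates and rejects; it never silently repairs.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import PlateConfigError, PlateFormatError
from .trace import LuminescenceTrace, PlateRecording

_SIDECAR_SUFFIX = ".meta.yaml"


def default_sidecar_path(plate_path: str | Path) -> Path:
    """Sidecar path conventionally paired with a plate CSV."""
    p = Path(plate_path)
    return p.with_name(p.name + _SIDECAR_SUFFIX)


def _read_header(path: Path) -> list[str]:
    with path.open(newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if not header:
        raise PlateFormatError(f"{path}: empty file")
    return [h.strip() for h in header]


def read_plate(
    path: str | Path, metadata_path: str | Path | None = None
) -> PlateRecording:
    """Read a wide plate CSV plus its metadata sidecar.

    Parameters
    ----------
    path
        Plate CSV whose first column header is ``time_h`` and whose remaining
        headers are unique well ids.
    metadata_path
        YAML sidecar with ``conditions`` and optional ``replicates`` blocks.
        When omitted, ``<path>.meta.yaml`` is used and must exist.

    Raises
    ------
    PlateFormatError
        Malformed CSV: wrong first header, duplicate well column, non-numeric
        cell (row/column named), or a non-increasing time axis (row named).
    PlateConfigError
        Metadata that does not map every plate well to a condition, or that
        names wells absent from the plate.
    """
    path = Path(path)
    if not path.exists():
        raise PlateFormatError(f"plate file not found: {path}")

    header = _read_header(path)
    if header[0] != "time_h":
        raise PlateFormatError(
            f"{path}: first column header must be 'time_h', got {header[0]!r}"
        )
    wells = header[1:]
    if not wells:
        raise PlateFormatError(f"{path}: no well columns")
    if len(set(wells)) != len(wells):
        dup = next(w for w in wells if wells.count(w) > 1)
        raise PlateFormatError(f"{path}: duplicate well column {dup!r}")

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            # numpy's string→float conversion is correctly rounded, so a
            # write/read cycle reproduces every value bit-for-bit
            values[:, j] = raw[col].to_numpy(dtype=str).astype(float)
        except ValueError:
            converted = pd.to_numeric(raw[col], errors="coerce")
            i = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise PlateFormatError(
                f"{path}: non-numeric cell {raw.iloc[i, j]!r} at data row "
                f"{i + 1}, column {col!r}"
            ) from None
    if values.shape[0] < 2:
        raise PlateFormatError(f"{path}: need at least 2 data rows")

    time_h = values[:, 0]
    nonmono = np.flatnonzero(np.diff(time_h) <= 0)
    if nonmono.size:
        i = int(nonmono[0]) + 1
        raise PlateFormatError(
            f"{path}: time_h not strictly increasing at data row {i + 1} "
            f"(t={time_h[i]})"
        )

    conditions, replicates = _read_sidecar(path, metadata_path, wells)

    traces = tuple(
        LuminescenceTrace(w, time_h, values[:, j + 1])
        for j, w in enumerate(wells)
    )
    return PlateRecording(traces, conditions, replicates)


def _read_sidecar(
    plate_path: Path,
    metadata_path: str | Path | None,
    wells: list[str],
) -> tuple[dict[str, str], dict[str, int]]:
    if metadata_path is None:
        metadata_path = default_sidecar_path(plate_path)
        if not Path(metadata_path).exists():
            raise PlateConfigError(
                f"no metadata sidecar given and {metadata_path} does not exist"
            )
    metadata_path = Path(metadata_path)
    if not metadata_path.exists():
        raise PlateConfigError(f"metadata file not found: {metadata_path}")
    with metadata_path.open(encoding="utf-8") as fh:
        meta = yaml.safe_load(fh) or {}
    if not isinstance(meta, dict) or "conditions" not in meta:
        raise PlateConfigError(
            f"{metadata_path}: expected a mapping with a 'conditions' block"
        )
    conditions = {str(k): str(v) for k, v in (meta["conditions"] or {}).items()}
    for w in wells:
        if w not in conditions:
            raise PlateConfigError(
                f"{metadata_path}: well {w!r} has no condition entry"
            )
    for w in conditions:
        if w not in wells:
            raise PlateConfigError(
                f"{metadata_path}: condition entry for unknown well {w!r}"
            )
    replicates = {
        str(k): int(v) for k, v in (meta.get("replicates") or {}).items()
    }
    for w in replicates:
        if w not in wells:
            raise PlateConfigError(
                f"{metadata_path}: replicate entry for unknown well {w!r}"
            )
    return conditions, replicates


def write_plate(
    plate: PlateRecording,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a plate to the wide CSV dialect plus its YAML sidecar.

    Values are written with ``repr`` precision so that
    ``read_plate(write_plate(plate))`` reproduces the numbers exactly.
    """
    path = Path(path)
    if metadata_path is None:
        metadata_path = default_sidecar_path(path)
    data = {"time_h": plate.time_h}
    for tr in plate.traces:
        data[tr.well_id] = tr.signal
    df = pd.DataFrame(data)
    df.to_csv(path, index=False, lineterminator="\n")

    meta = {
        "conditions": {w: plate.condition_of[w] for w in plate.wells},
        "replicates": {w: int(plate.replicate_of[w]) for w in plate.wells},
    }
    with Path(metadata_path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
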