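"""Plain-text file formats: sweep archives and tidy metrics tables.

A sweep archive is a tab-delimited trace matrix (rows = sweeps, columns
= samples, values in uV) plus a YAML sidecar carrying the acquisition
metadata (``sample_rate_hz``, ``onset_s``, and free-form fields such as
animal id, genotype, stimulus descriptors and seed).  Text was chosen
over a binary container so that desk-scale recordings remain directly
inspectable; units are fixed package-wide (uV, s, nm, mW/cm^2, photons
per um^2).

Tidy metrics tables are long-format CSVs with one row per (animal,
genotype, dose, metric, value); duplicate (animal, dose, metric) keys
are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .preprocess import SweepSet

__all__ = [
    "SweepArchiveError",
    "write_sweep_archive",
    "read_sweep_archive",
    "write_tidy_metrics",
    "read_tidy_metrics",
    "TIDY_COLUMNS",
]

#: Fixed column order of the tidy long-format metrics table.
TIDY_COLUMNS = ("animal_id", "genotype", "dose_photons_um2", "metric", "value")

_REQUIRED_SIDECAR_KEYS = ("sample_rate_hz", "onset_s")


class SweepArchiveError(ValueError):
    """Malformed sweep archive (ragged matrix, bad cell, missing key)."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml") if path.suffix != ".yaml" else path


def write_sweep_archive(path: str | Path, sweeps: SweepSet) -> None:
    """Write ``path`` (TSV trace matrix) and ``path + '.yaml'`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, sweeps.traces, fmt="%.8g", delimiter="\t")
    sidecar: dict[str, Any] = {
        "sample_rate_hz": float(sweeps.sample_rate_hz),
        "onset_s": float(sweeps.onset_s),
        "n_sweeps": int(sweeps.n_sweeps),
        "n_samples": int(sweeps.n_samples),
        "units": {"trace": "uV", "time": "s"},
        "meta": _plain(sweeps.meta),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars so YAML stays plain-text."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_sweep_archive(path: str | Path) -> SweepSet:
    """Read a sweep archive back into a validated :class:`SweepSet`.

    Malformed rows are reported with their 1-based line number; a
    missing sidecar key is reported by name.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not path.exists():
        raise SweepArchiveError(f"trace matrix not found: {path}")
    if not side.exists():
        raise SweepArchiveError(f"sidecar not found: {side}")
    with open(side) as fh:
        sidecar = yaml.safe_load(fh)
    if not isinstance(sidecar, dict):
        raise SweepArchiveError(f"sidecar {side} does not parse to a mapping")
    for key in _REQUIRED_SIDECAR_KEYS:
        if key not in sidecar:
            raise SweepArchiveError(f"sidecar {side} is missing required key {key!r}")

    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise SweepArchiveError(
                    f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {width})"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise SweepArchiveError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise SweepArchiveError(f"{path}: no sweeps found")
    traces = np.asarray(rows, dtype=float)
    n_sweeps = sidecar.get("n_sweeps")
    if n_sweeps is not None and int(n_sweeps) != traces.shape[0]:
        raise SweepArchiveError(
            f"{path}: sidecar declares {n_sweeps} sweeps, matrix has {traces.shape[0]}"
        )
    n_samples = sidecar.get("n_samples")
    if n_samples is not None and int(n_samples) != traces.shape[1]:
        raise SweepArchiveError(
            f"{path}: sidecar declares {n_samples} samples, matrix has {traces.shape[1]}"
        )
    return SweepSet(
        traces=traces,
        sample_rate_hz=float(sidecar["sample_rate_hz"]),
        onset_s=float(sidecar["onset_s"]),
        meta=dict(sidecar.get("meta") or {}),
    )


def write_tidy_metrics(path: str | Path, table: pd.DataFrame) -> None:
    """Write a validated tidy metrics table as CSV."""
    _validate_tidy(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.loc[:, list(TIDY_COLUMNS)].to_csv(path, index=False)


def read_tidy_metrics(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy metrics CSV."""
    table = pd.read_csv(path)
    _validate_tidy(table)
    return table


def _validate_tidy(table: pd.DataFrame) -> None:
    missing = [c for c in TIDY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"tidy metrics table is missing columns {missing}")
    keys = table[["animal_id", "dose_photons_um2", "metric"]]
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].drop_duplicates().to_dict("records")
        raise ValueError(f"duplicate (animal, dose, metric) keys: {dupes[:5]}")
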