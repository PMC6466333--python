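"""Validated CSV I/O for concentration tables and stage outputs.

A concentration table CSV has the exact header
``sample_id,region,Cr,Ni,Cu,Zn,As,Cd,Pb`` with concentrations in mg/kg
dry weight.  Lines starting with ``#`` are metadata comments; outputs are
written with a comment header recording package version, seed and a
config hash so any run is auditable from its files alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .metals import METAL_COLUMNS

CONCENTRATION_COLUMNS = ("sample_id", "region", *METAL_COLUMNS)


def read_concentration_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a concentration table.

    Rejects missing/extra columns, duplicate sample ids, and non-numeric
    or negative concentration cells (citing 1-based data row numbers).
    """
    table = pd.read_csv(path, comment="#", dtype={"sample_id": str, "region": str})
    if tuple(table.columns) != CONCENTRATION_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {', '.join(CONCENTRATION_COLUMNS)}; "
            f"found {', '.join(table.columns)}"
        )
    if len(table) == 0:
        raise ValueError(f"{path}: no samples")
    dupes = table["sample_id"][table["sample_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate sample_id values: {', '.join(dupes)}")
    for col in METAL_COLUMNS:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[values.isna()] + 1
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} concentration in row(s) "
                + ", ".join(map(str, bad))
            )
        neg = table.index[values < 0] + 1
        if len(neg):
            raise ValueError(
                f"{path}: negative {col} concentration in row(s) "
                + ", ".join(map(str, neg))
            )
        table[col] = values.astype(float)
    return table


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _metadata_header(metadata: Mapping[str, Any] | None) -> str:
    from . import __version__

    fields = {"fertrisk": __version__, **(metadata or {})}
    return "".join(f"# {k}: {v}\n" for k, v in fields.items())


def write_csv(
    frame: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
    index: bool = True,
) -> Path:
    """Write any stage output with a metadata comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_header(metadata))
        frame.to_csv(fh, index=index)
    return path


def write_concentration_csv(
    table: pd.DataFrame, path: str | Path, metadata: Mapping[str, Any] | None = None
) -> Path:
    """Write a concentration table (round-trips through the reader)."""
    missing = [c for c in CONCENTRATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns: {', '.join(missing)}")
    return write_csv(
        table[list(CONCENTRATION_COLUMNS)], path, metadata=metadata, index=False
    )
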