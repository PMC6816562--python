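"""Delimited-text readers and writers.

Genotype tables use one row per dog with columns ``dog_id``, ``breed``,
``population`` followed by one column per marker holding copy counts
(0/1/2) or ``NA`` for failed assays.  IBD edge lists are four-column
tables: ``breed_a``, ``breed_b``, ``value``, ``significant``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .interpret import DogRecord
from .trait_model import GeneCatalog, default_catalog

ID_COLUMNS = ("dog_id", "breed", "population")


def marker_columns(catalog: Optional[GeneCatalog] = None) -> list[str]:
    catalog = catalog or default_catalog()
    cols: list[str] = []
    for model in catalog:
        cols.extend(m for m in model.marker_ids if m not in cols)
    return cols


def write_genotype_table(
    dogs: Iterable[DogRecord],
    path: str | Path,
    catalog: Optional[GeneCatalog] = None,
    sep: str = ",",
) -> None:
    cols = marker_columns(catalog)
    rows = []
    for dog in dogs:
        row: dict[str, object] = {
            "dog_id": dog.dog_id,
            "breed": dog.breed,
            "population": dog.population,
        }
        for m in cols:
            c = dog.marker_calls.get(m)
            row[m] = "NA" if c is None else c
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(ID_COLUMNS) + cols)
    frame.to_csv(path, sep=sep, index=False)


def read_genotype_table(path: str | Path, sep: str = ",") -> list[DogRecord]:
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_ids = [c for c in ("dog_id", "breed") if c not in frame.columns]
    if missing_ids:
        raise ValueError(f"genotype table lacks required columns: {missing_ids}")
    markers = [c for c in frame.columns if c not in ID_COLUMNS]
    dogs = []
    for _, row in frame.iterrows():
        calls: dict[str, Optional[int]] = {}
        for m in markers:
            raw = row[m].strip()
            calls[m] = None if raw in ("", "NA", "nan") else int(raw)
        dogs.append(
            DogRecord(
                dog_id=row["dog_id"],
                breed=row["breed"],
                population=row.get("population", ""),
                marker_calls=calls,
            )
        )
    return dogs


def read_ibd_edges(path: str | Path, sep: str = ",") -> list[tuple]:
    """Read an IBD-sharing edge list; returns (breed_a, breed_b, value, significant)."""
    frame = pd.read_csv(path, sep=sep)
    required = {"breed_a", "breed_b", "significant"}
    if not required.issubset(frame.columns):
        raise ValueError(f"edge list lacks required columns: {sorted(required - set(frame.columns))}")
    edges = []
    for _, row in frame.iterrows():
        value = float(row["value"]) if "value" in frame.columns and pd.notna(row["value"]) else None
        sig = str(row["significant"]).strip().lower() in ("1", "true", "yes", "y")
        edges.append((str(row["breed_a"]), str(row["breed_b"]), value, sig))
    return edges


def write_table(frame: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    frame.to_csv(path, sep=sep, index=False)


def read_table(path: str | Path, sep: str = ",", columns: Sequence[str] | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep)
    if columns is not None:
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise ValueError(f"table lacks required columns: {missing}")
    return frame
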