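"""Reading and writing compound tables with aligned activity matrices.

Input is a delimited table (CSV/TSV/semicolon, or whitespace ``.smi``) with
one SMILES column, an optional compound-id column and any number of numeric
activity columns on the pKI/pIC50 scale. Missing activity cells are kept as
an explicit boolean mask rather than silently imputed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents treated as a missing activity value (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


@dataclass
class ActivityMatrix:
    """Compounds x endpoints numeric matrix (pKI units) with explicit missingness.

    ``values[i, j]`` is meaningful only where ``missing_mask[i, j]`` is False;
    masked cells hold NaN.
    """

    values: np.ndarray
    endpoint_names: list[str]
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.ndim != 2:
            raise ValueError("activity matrix must be 2-D")
        if self.values.shape[1] != len(self.endpoint_names):
            raise ValueError("endpoint_names length does not match matrix width")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def row(self, i: int) -> np.ma.MaskedArray:
        """One compound's activities as a masked array."""
        return np.ma.MaskedArray(self.values[i], mask=self.missing_mask[i])

    def take_rows(self, indices: Sequence[int]) -> "ActivityMatrix":
        idx = list(indices)
        return ActivityMatrix(
            values=self.values[idx],
            endpoint_names=list(self.endpoint_names),
            missing_mask=self.missing_mask[idx],
        )

    @staticmethod
    def empty(n: int) -> "ActivityMatrix":
        """Zero-endpoint matrix for datasets without activity columns."""
        return ActivityMatrix(
            values=np.empty((n, 0)), endpoint_names=[], missing_mask=np.empty((n, 0), bool)
        )


@dataclass
class RawDataset:
    """Ordered (id, smiles) records with a row-aligned :class:`ActivityMatrix`."""

    records: list[tuple[str, str]] = field(default_factory=list)
    activities: ActivityMatrix | None = None

    def __post_init__(self) -> None:
        if self.activities is None:
            self.activities = ActivityMatrix.empty(len(self.records))
        if self.activities.n != len(self.records):
            raise ValueError("activities must have exactly one row per record")
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique")
        for rid, smi in self.records:
            if not smi:
                raise ValueError(f"record {rid!r} has an empty SMILES")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r[1] for r in self.records]


def _is_missing(cell: object) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and np.isnan(cell):
        return True
    return str(cell).strip().lower() in MISSING_TOKENS


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text(encoding="utf-8")[:8192]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _uniquify_ids(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for rid in ids:
        if rid in seen:
            seen[rid] += 1
            new = f"{rid}_{seen[rid]}"
            logger.warning("duplicate id %r renamed to %r", rid, new)
            out.append(new)
        else:
            seen[rid] = 0
            out.append(rid)
    return out


def _read_smi(path: Path) -> pd.DataFrame:
    """Whitespace-separated SMILES [id] lines, no header, no activities."""
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        parts = line.split()
        if not parts:
            continue
        rows.append({"smiles": parts[0], "id": parts[1] if len(parts) > 1 else ""})
    return pd.DataFrame(rows)


def read_dataset(
    path: str | Path,
    smiles_col: str = "smiles",
    id_col: str | None = "id",
    activity_cols: Sequence[str] | str = "auto",
    delimiter: str | None = None,
) -> RawDataset:
    """Read a compound table into a :class:`RawDataset`.

    Parameters
    ----------
    path
        CSV/TSV/semicolon-delimited file with a header row, or a ``.smi``
        file (``SMILES [whitespace] id`` per line, no activities).
    smiles_col, id_col
        Column names. If ``id_col`` is missing/None, stable ids
        ``CPD_0001`` ... are assigned in input order.
    activity_cols
        Explicit list of activity column names, or ``"auto"`` to take every
        numeric column other than the id and SMILES columns.
    delimiter
        Force a delimiter instead of auto-detecting among comma/tab/semicolon.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if path.suffix.lower() == ".smi":
        df = _read_smi(path)
        smiles_col, id_col = "smiles", "id"
        if activity_cols == "auto":
            activity_cols = []
    else:
        delim = delimiter or _sniff_delimiter(path)
        df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)

    if smiles_col not in df.columns:
        raise ValueError(f"SMILES column {smiles_col!r} not found in {list(df.columns)}")

    # Drop rows with an empty SMILES cell, keeping count for the log.
    keep = ~df[smiles_col].map(_is_missing)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d rows with empty SMILES", n_dropped)
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no usable rows in {path}")

    if id_col and id_col in df.columns and not df[id_col].map(_is_missing).all():
        ids = _uniquify_ids([str(v).strip() for v in df[id_col]])
    else:
        ids = [f"CPD_{i + 1:04d}" for i in range(len(df))]

    if activity_cols == "auto":
        candidates = [c for c in df.columns if c not in {smiles_col, id_col}]
        activity_cols = [
            c
            for c in candidates
            if pd.to_numeric(df[c].where(~df[c].map(_is_missing)), errors="coerce").notna().any()
        ]
    activity_cols = list(activity_cols)
    for c in activity_cols:
        if c not in df.columns:
            raise ValueError(f"activity column {c!r} not found")

    n = len(df)
    values = np.full((n, len(activity_cols)), np.nan)
    mask = np.ones((n, len(activity_cols)), dtype=bool)
    for j, c in enumerate(activity_cols):
        for i, cell in enumerate(df[c]):
            if not _is_missing(cell):
                values[i, j] = float(cell)
                mask[i, j] = False

    records = list(zip(ids, (str(s).strip() for s in df[smiles_col])))
    return RawDataset(
        records=records,
        activities=ActivityMatrix(values=values, endpoint_names=activity_cols, missing_mask=mask),
    )


def write_table(rows: pd.DataFrame | RawDataset, path: str | Path) -> None:
    """Write a tabular result (or a whole dataset) as UTF-8 CSV.

    Missing cells become empty fields; ``read_dataset`` of a written
    :class:`RawDataset` round-trips values and the missing mask.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    if isinstance(rows, RawDataset):
        act = rows.activities
        df = pd.DataFrame({"id": rows.ids, "smiles": rows.smiles})
        for j, name in enumerate(act.endpoint_names):
            col = [
                "" if act.missing_mask[i, j] else f"{act.values[i, j]:.6f}" for i in range(act.n)
            ]
            df[name] = col
        df.to_csv(path, index=False, encoding="utf-8")
    else:
        rows.to_csv(path, index=False, encoding="utf-8", na_rep="")
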