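"""CSV recording table: the metadata sheet plus computed D columns.

Schema (header row, UTF-8, ISO-8601 datetimes):
``filename, datetime, location, camera, condition, label, d_filter1,
d_filter2``.  Label and condition are optional on input; D columns are
written at full precision so a written table reads back loss-free.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .classification import LabeledRecording
from .filters import METHODS

__all__ = ["TABLE_COLUMNS", "read_table", "write_table", "table_to_recordings",
           "recordings_to_table"]

TABLE_COLUMNS = [
    "filename",
    "datetime",
    "location",
    "camera",
    "condition",
    "label",
    "d_filter1",
    "d_filter2",
]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a recording table, tolerating missing optional columns."""
    df = pd.read_csv(path, dtype={"filename": str})
    if "filename" not in df.columns:
        raise ValueError(f"{path}: recording table requires a 'filename' column")
    if df["filename"].duplicated().any():
        dupes = df.loc[df["filename"].duplicated(), "filename"].tolist()
        raise ValueError(f"{path}: duplicate filenames {dupes}")
    for col in TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    for m in METHODS:
        col = df[f"d_{m}"].astype(float)
        if (col.dropna() < 0).any():
            raise ValueError(f"{path}: negative D values in d_{m}")
        df[f"d_{m}"] = col
    return df[TABLE_COLUMNS]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the table as CSV; repr-round-trip precision on the D columns."""
    df.to_csv(path, index=False, float_format="%.17g")


def table_to_recordings(
    df: pd.DataFrame, duration_s: float = 15.0, require_label: bool = True
) -> list[LabeledRecording]:
    """Convert table rows to LabeledRecording objects for analysis."""
    recs = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label", None)
        if pd.isna(label):
            if require_label:
                raise ValueError(f"recording {row.filename} has no label")
            label = "non-target"
        cond = getattr(row, "condition", None)
        cond = "unknown" if pd.isna(cond) else str(cond)
        d_values = {}
        for m in METHODS:
            v = getattr(row, f"d_{m}")
            if not pd.isna(v):
                d_values[m] = float(v)
        recs.append(
            LabeledRecording(
                source_id=str(row.filename),
                d_values=d_values,
                label=str(label),
                condition=cond,
                duration_s=duration_s,
            )
        )
    return recs


def recordings_to_table(recordings: Sequence[LabeledRecording]) -> pd.DataFrame:
    """Tabulate recordings (synthetic populations included) as a table."""
    rows = []
    for r in recordings:
        rows.append(
            {
                "filename": r.source_id,
                "datetime": pd.NA,
                "location": pd.NA,
                "camera": pd.NA,
                "condition": r.condition,
                "label": r.label,
                "d_filter1": r.d_values.get("filter1", pd.NA),
                "d_filter2": r.d_values.get("filter2", pd.NA),
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
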