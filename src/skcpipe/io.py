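"""Canonical tabular I/O for scan tables.

The pipeline's interchange format is a UTF-8 CSV with one row per scan:
identifier columns (patient_id, eye, visit_date), the 21 feature columns in
canonical order, and metadata (oc, sc, true_group, site, artifact_tag).
Reading validates the schema and collects malformed numeric cells into an
error report instead of silently dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import FEATURES, ID_COLUMNS, SCHEMA_COLUMNS

NUMERIC_COLUMNS = tuple(FEATURES) + ("oc", "sc")
REQUIRED_COLUMNS = ID_COLUMNS + tuple(FEATURES) + ("oc", "sc")


@dataclass
class ReadReport:
    """Rows removed while reading, with the offending cell locations."""

    n_rows: int = 0
    n_bad: int = 0
    errors: list = field(default_factory=list)  # (row_number, column, raw value)


def read_scan_table(path, errors: str = "report",
                    ) -> tuple[pd.DataFrame, ReadReport]:
    """Read a canonical scan CSV into a typed table.

    Raises on missing required columns (naming the first one). Cells in
    numeric columns that fail to parse route their whole row into the
    report (``errors="report"``, default) or raise (``errors="raise"``).
    Missing optional metadata columns are added with default values.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    report = ReadReport(n_rows=len(df))
    bad_rows = set()
    for col in NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col].replace("", "nan"), errors="coerce")
        bad = parsed.isna() & (df[col].str.strip() != "") \
            & (df[col].str.lower() != "nan")
        for i in df.index[bad]:
            report.errors.append((int(i) + 2, col, df.at[i, col]))  # 1-based + header
            bad_rows.add(i)
        df[col] = parsed
    if bad_rows and errors == "raise":
        r, c, v = report.errors[0]
        raise ValueError(f"malformed value {v!r} in column {c} at line {r}")
    report.n_bad = len(bad_rows)
    df = df.drop(index=sorted(bad_rows)).reset_index(drop=True)
    df["visit_date"] = df["visit_date"].astype(float).astype(int)
    for col, default in (("true_group", ""), ("site", "main"),
                         ("artifact_tag", "")):
        if col not in df.columns:
            df[col] = default
    return df[list(SCHEMA_COLUMNS)], report


def write_scan_table(records: pd.DataFrame, path) -> None:
    """Write a scan table in canonical column order (UTF-8 CSV)."""
    records[list(SCHEMA_COLUMNS)].to_csv(path, index=False)
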