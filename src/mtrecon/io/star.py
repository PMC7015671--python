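"""Particle-metadata tables as STAR (single loop block) or TSV.

The STAR dialect is deliberately small: one ``data_<block>`` with one
``loop_``, column names written as ``_<name> #<i>``. Column names, row
order and unknown columns are preserved on round-trip; numbers are
written with full float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_table", "read_table", "require_columns", "ALIGNMENT_COLUMNS"]

ALIGNMENT_COLUMNS = (
    "segment_id",
    "filament_id",
    "segment_index",
    "rot_deg",
    "tilt_deg",
    "psi_deg",
    "shift_x_A",
    "shift_y_A",
)


def require_columns(df: pd.DataFrame, columns=ALIGNMENT_COLUMNS) -> None:
    """Raise naming every mandatory column that is absent."""
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing mandatory columns: {', '.join(missing)}")


def write_table(path, df: pd.DataFrame, block: str = "particles") -> None:
    path = Path(path)
    if path.suffix == ".star":
        lines = [f"data_{block}", "", "loop_"]
        for i, c in enumerate(df.columns, start=1):
            lines.append(f"_{c} #{i}")
        for _, row in df.iterrows():
            lines.append(" ".join(_fmt(v) for v in row))
        path.write_text("\n".join(lines) + "\n")
    else:
        df.to_csv(path, sep="\t", index=False)


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if v is pd.NA or (isinstance(v, float) and np.isnan(v)):
        return "<NA>"
    return str(v)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix != ".star":
        return pd.read_csv(path, sep="\t")
    cols, rows = [], []
    in_loop = False
    for line in path.read_text().splitlines():
        t = line.strip()
        if not t or t.startswith("data_"):
            continue
        if t == "loop_":
            in_loop = True
            continue
        if in_loop and t.startswith("_"):
            cols.append(t.split()[0][1:])
            continue
        if in_loop:
            vals = t.split()
            if len(vals) != len(cols):
                raise ValueError(f"{path}: row has {len(vals)} fields, expected {len(cols)}")
            rows.append(vals)
    if not cols:
        raise ValueError(f"{path}: no loop_ columns found")
    df = pd.DataFrame(rows, columns=cols).replace("<NA>", pd.NA)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df
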