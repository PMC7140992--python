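"""Rounding and summary-row conventions shared by the audit reports.

All reported percentages round half-away-from-zero; pairwise-comparison
tables print repeatability and R2 to two decimals and the classification
percentages to one.  Mean rows are recomputed from the printed (already
rounded) constituent values in exact decimal arithmetic so that a reader can
re-derive every mean cell from the rows above it.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "round_half_away",
    "decimal_mean",
    "build_table1",
    "table3_with_summary",
    "error_sum_percent",
    "TABLE1_ROUNDING",
]

#: decimal places used for each numeric pairwise-table column
TABLE1_ROUNDING = {
    "repeatability": 2,
    "procanova_r2_percent": 2,
    "pgm_error_change_percent": 1,
    "fossil_pgm_change_percent": 1,
}

SOURCE_ORDER = ("intraobserver", "interobserver", "device", "presentation")


def round_half_away(x, ndigits: int = 1) -> float:
    """Round half away from zero (so 2.65 -> 2.7, -2.65 -> -2.7)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def decimal_mean(values, ndigits: int) -> float:
    """Mean of printed decimal values, computed exactly then rounded half-away.

    Each value is interpreted through its decimal representation so that
    means of already-rounded table entries reproduce the printed mean cells
    (e.g. mean(16.56, ..., 27.84) -> 19.885 -> 19.89) without binary float
    artefacts.
    """
    vals = [Decimal(repr(float(v))) for v in values]
    if not vals:
        return float("nan")
    mean = sum(vals) / len(vals)
    q = Decimal(1).scaleb(-ndigits)
    return float(mean.quantize(q, rounding=ROUND_HALF_UP))


def build_table1(rows: pd.DataFrame, source_order=SOURCE_ORDER) -> pd.DataFrame:
    """Round a pairwise-comparison table and insert per-source mean rows.

    ``rows`` needs columns ``comparison``, ``error_source`` and any of the
    numeric columns named in :data:`TABLE1_ROUNDING`.  Values are rounded to
    the column's precision; a ``Mean (<source>)`` row, recomputed from the
    rounded values, follows each error-source block.
    """
    out_rows = []
    num_cols = [c for c in TABLE1_ROUNDING if c in rows.columns]
    for source in source_order:
        block = rows[rows["error_source"] == source]
        if block.empty:
            continue
        rounded = block.copy()
        for col in num_cols:
            rounded[col] = [round_half_away(v, TABLE1_ROUNDING[col]) for v in block[col]]
        out_rows.append(rounded)
        mean_row = {"comparison": f"Mean ({source})", "error_source": source}
        for col in num_cols:
            mean_row[col] = decimal_mean(rounded[col], TABLE1_ROUNDING[col])
        out_rows.append(pd.DataFrame([mean_row]))
    if not out_rows:
        return rows.iloc[0:0].copy()
    return pd.concat(out_rows, ignore_index=True)


def table3_with_summary(df: pd.DataFrame, count_cols, error_col="error_percent") -> pd.DataFrame:
    """Append Mean and Range rows to a per-dataset fossil count table."""
    body = df.copy()
    if body.empty:
        return body
    body[error_col] = [round_half_away(v, 1) for v in body[error_col]]
    mean_row = {"dataset": "Mean"}
    range_row = {"dataset": "Range"}
    for col in list(count_cols) + [error_col]:
        nd = 1
        mean_row[col] = decimal_mean(body[col], nd)
        lo, hi = body[col].min(), body[col].max()
        if col in count_cols:
            lo, hi = int(lo), int(hi)
        range_row[col] = f"{lo}" if lo == hi else f"{lo}-{hi}"
    return pd.concat([body, pd.DataFrame([mean_row, range_row])], ignore_index=True)


def error_sum_percent(r2_values) -> float:
    """Summed acquisition-error R2 fractions expressed as a percentage."""
    total = sum(Decimal(repr(float(v))) for v in r2_values)
    return float(total * 100)
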