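"""Descriptive summaries: daily-count tables, exposure tables, Spearman matrix.

Quantiles use linear interpolation between order statistics (the
type-7 rule) throughout, and Spearman correlations use average ranks
for ties — both the standard conventions, fixed here for
reproducibility.  Correlations with absolute value at or above the
strong-correlation threshold (0.6 by default) are flagged; the flags
drive the default pollutant-adjustment screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConstantVariableError, SchemaError

__all__ = [
    "summarize_counts",
    "summarize_continuous",
    "share_table",
    "spearman_matrix",
]

_QUANTS = (0.25, 0.5, 0.75)
_STAT_COLUMNS = ["mean", "minimum", "q25", "median", "q75", "maximum"]


def _summary_row(values: np.ndarray) -> list[float]:
    q25, med, q75 = np.quantile(values, _QUANTS)
    return [float(values.mean()), float(values.min()), float(q25), float(med), float(q75), float(values.max())]


def summarize_counts(
    series: pd.DataFrame,
    columns,
    total_column: str = "deaths_total",
    *,
    round_daily: bool = True,
) -> pd.DataFrame:
    """Per-group daily-count summaries with totals and percentage shares.

    Daily summary statistics are rounded to integers (the customary
    presentation for sparse daily death counts) unless ``round_daily``
    is False; shares are percentages of the grand total, rounded to two
    decimals.
    """
    if series.empty:
        raise SchemaError("empty series")
    grand_total = int(series[total_column].sum())
    rows = {}
    for col in list(columns) + [total_column]:
        if col not in series.columns:
            raise SchemaError(f"count column {col!r} missing")
        values = np.asarray(series[col], dtype=float)
        stats = _summary_row(values)
        if round_daily:
            stats = [int(round(s)) for s in stats]
        total = int(values.sum())
        rows[col] = stats + [total, round(100.0 * total / grand_total, 2)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=_STAT_COLUMNS + ["total", "share_pct"]
    )


def summarize_continuous(series: pd.DataFrame, columns) -> pd.DataFrame:
    """Mean/min/quartiles/max table for exposure and confounder columns."""
    if series.empty:
        raise SchemaError("empty series")
    rows = {}
    for col in columns:
        if col not in series.columns:
            raise SchemaError(f"column {col!r} missing")
        values = np.asarray(series[col], dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            raise SchemaError(f"column {col!r} has no finite values")
        rows[col] = _summary_row(values)
    return pd.DataFrame.from_dict(rows, orient="index", columns=_STAT_COLUMNS)


def share_table(totals: dict[str, int]) -> pd.DataFrame:
    """Percentage shares of a partition of counts (two-decimal rounding).

    ``share_pct`` values sum to 100 up to rounding of the printed
    figures.
    """
    grand = sum(int(v) for v in totals.values())
    if grand <= 0:
        raise SchemaError("totals must sum to a positive count")
    rows = {
        name: [int(v), round(100.0 * int(v) / grand, 2)] for name, v in totals.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["total", "share_pct"])
    out.loc["total"] = [grand, 100.0]
    return out


def spearman_matrix(
    variables: pd.DataFrame, strong_threshold: float = 0.6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation matrix with strong-correlation flags.

    Requires at least 3 complete rows; raises on constant variables,
    for which a rank correlation is undefined.
    """
    data = variables.dropna()
    if len(data) < 3:
        raise SchemaError("need at least 3 complete days for a correlation matrix")
    for col in data.columns:
        if np.unique(np.asarray(data[col], dtype=float)).size < 2:
            raise ConstantVariableError(f"variable {col!r} is constant; correlation undefined")
    corr = data.corr(method="spearman")
    flags = corr.abs() >= strong_threshold
    return corr, flags
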