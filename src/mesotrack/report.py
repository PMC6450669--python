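"""Group-comparison tables from per-cell record tables.

Turns a table of per-cell measurements (one row per cell, one column
per metric, one grouping column) into the machine-readable twin of a
publication summary table: n, mean, SEM per group plus the
gate-selected test, its statistic and two-sided p-value per metric.
The same function recomputes cohort statistics from deposited per-cell
source-data records and from this package's own summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import ValidationError
from .stats import compare_groups

__all__ = ["compare_table"]

COMPARISON_COLUMNS = [
    "metric", "group_a", "group_b", "n_a", "n_b",
    "mean_a", "sem_a", "mean_b", "sem_b",
    "test_used", "statistic", "p_value",
]


def compare_table(
    records: pd.DataFrame,
    value_cols: list[str],
    group_col: str = "region",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group mean ± SEM and test per metric column.

    ``records`` must contain exactly two distinct values in
    ``group_col`` (rows with missing group are dropped); NaN metric
    values are excluded per metric, so cells flagged missing upstream do
    not bias the comparison.
    """
    groups = sorted(records[group_col].dropna().astype(str).unique())
    if len(groups) != 2:
        raise ValidationError(
            f"need exactly 2 groups in {group_col!r}, found {groups!r}"
        )
    ga, gb = groups
    rows = []
    for metric in value_cols:
        a = records.loc[records[group_col].astype(str) == ga, metric].to_numpy(float)
        b = records.loc[records[group_col].astype(str) == gb, metric].to_numpy(float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        cmp = compare_groups(a, b, name_a=ga, name_b=gb, alpha=alpha)
        rows.append((
            metric, ga, gb, cmp.n_a, cmp.n_b,
            cmp.mean_a, cmp.sem_a, cmp.mean_b, cmp.sem_b,
            cmp.test_used, cmp.statistic, cmp.p_value,
        ))
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
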