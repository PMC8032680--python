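"""Condition comparisons of blob features.

The experimental unit is the cell: blob features are first averaged per
cell, then conditions are compared feature-by-feature with Welch's
two-tailed unpaired t-test, globally and per blob class.  Percent change
is reported relative to the first condition.  No multiple-testing
correction is applied by default; Benjamini-Hochberg is available as a
flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["per_cell_means", "compare_conditions"]


def per_cell_means(features: pd.DataFrame, by_class: bool = False
                   ) -> pd.DataFrame:
    """Average blob features per cell (optionally per cell x class).

    ``features`` needs columns ``condition``, ``cell_id`` (and ``class``
    when ``by_class``) plus numeric feature columns.
    """
    keys = ["condition", "cell_id"] + (["class"] if by_class else [])
    num = features.select_dtypes("number").columns.difference(["blob_id"])
    return (features.groupby(keys, observed=True)[list(num)]
            .mean().reset_index())


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    res = sps.ttest_ind(a, b, equal_var=False)
    df = getattr(res, "df", np.nan)
    return float(res.statistic), float(df), float(res.pvalue)


def compare_conditions(cell_means: pd.DataFrame,
                       conditions: tuple[str, str] | None = None,
                       bh_correction: bool = False) -> pd.DataFrame:
    """Welch two-tailed unpaired t-test per feature across cells.

    ``cell_means`` is per-cell feature summaries (see
    :func:`per_cell_means`) with a ``condition`` column and optionally a
    ``class`` column (adding per-class rows alongside the global ones).
    Percent change is ``100 * (mean_B - mean_A) / mean_A`` with A the
    first condition.

    Raises ``ValueError`` if either condition has fewer than 2 cells.
    """
    if conditions is None:
        found = sorted(cell_means["condition"].unique())
        if len(found) != 2:
            raise ValueError(f"need exactly 2 conditions, found {found}")
        conditions = (found[0], found[1])
    cond_a, cond_b = conditions
    for cond in conditions:
        n = cell_means.loc[cell_means["condition"] == cond, "cell_id"].nunique()
        if n < 2:
            raise ValueError(f"condition {cond!r} has {n} cell(s); need >= 2")
    feat_cols = [c for c in cell_means.select_dtypes("number").columns
                 if c not in ("blob_id",)]
    scopes = [("global", cell_means)]
    if "class" in cell_means.columns:
        scopes += [(cls, grp) for cls, grp in cell_means.groupby("class",
                                                                 observed=True)]
    rows = []
    for scope, frame in scopes:
        a_frame = frame[frame["condition"] == cond_a]
        b_frame = frame[frame["condition"] == cond_b]
        for feat in feat_cols:
            a = a_frame[feat].to_numpy(dtype=float)
            b = b_frame[feat].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                continue
            mean_a, mean_b = a.mean(), b.mean()
            t, df, p = _welch(a, b)
            pct = 100.0 * (mean_b - mean_a) / mean_a if mean_a != 0 else np.nan
            rows.append({"feature": feat, "scope": scope,
                         f"mean_{cond_a}": mean_a, f"mean_{cond_b}": mean_b,
                         "percent_change": pct, "t_statistic": t,
                         "df": df, "p_value": p,
                         f"n_cells_{cond_a}": len(a),
                         f"n_cells_{cond_b}": len(b)})
    table = pd.DataFrame(rows)
    if bh_correction and not table.empty:
        ok = table["p_value"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                table.loc[ok, "p_value"], method="fdr_bh")[1]
        table["p_value_bh"] = adj
    return table
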