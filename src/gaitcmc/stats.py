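"""Group-level statistics: FDR control, effect sizes, two-sample screen.

The study design compares five spectral measures in five frequency bands
(25 tests) between groups; the false discovery rate over that grid is
controlled with the Benjamini-Hochberg step-up procedure.  Definitive
group inference in the study used linear mixed models in external
statistics software; this module exports the tidy outcome table for that
purpose and ships a Welch two-sample screen for self-contained testing.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj[i] = min_{j: p_j >= p_i} (m * p_j / rank_j)`` capped at 1; the
    adjusted values are monotone non-decreasing in the raw values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def cohens_ds(group_a, group_b) -> float:
    """Cohen's d_s for two independent groups (pooled-SD denominator).

    ``d_s = (mean_a - mean_b) / s_p`` with
    ``s_p^2 = ((n_a - 1) s_a^2 + (n_b - 1) s_b^2) / (n_a + n_b - 2)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def welch_screen(outcomes, group_a: str, group_b: str):
    """Per-(measure, band) Welch t-test between two groups, BH-adjusted.

    ``outcomes`` is the tidy outcome table (one row per record x side x
    measure x band) produced by the pipeline.  Returns a DataFrame with
    raw and adjusted p-values and Cohen's d_s per cell.  This is a
    self-contained screen, not a replacement for the repeated-measures
    mixed-model analysis the tidy table is exported for.
    """
    import pandas as pd

    rows = []
    for (measure, band), cell in outcomes.groupby(["measure", "band"], sort=False):
        va = cell.loc[cell["group"] == group_a, "value"].to_numpy()
        vb = cell.loc[cell["group"] == group_b, "value"].to_numpy()
        if va.size < 2 or vb.size < 2:
            continue
        t, p = sstats.ttest_ind(va, vb, equal_var=False)
        if np.isnan(p):  # degenerate cell (e.g. both groups constant)
            t, p = 0.0, 1.0
        rows.append(
            {
                "measure": measure,
                "band": band,
                "mean_a": va.mean(),
                "mean_b": vb.mean(),
                "t": float(t),
                "p": float(p),
                "cohens_ds": cohens_ds(va, vb),
                "n_a": va.size,
                "n_b": vb.size,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adjusted"] = bh_adjust(table["p"].to_numpy())
    return table
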