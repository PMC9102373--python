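"""Two-group Mann-Whitney differential expression with Benjamini-Hochberg FDR.

One test per miRNA on the normalized log2 relative expression, applicable to
any annotated contrast (tumor vs control, OSC vs SCCC, metastatic vs
non-metastatic, recurrent vs non-recurrent).  Missing values are dropped per
assay (pairwise complete), matching the platform's per-assay detectability.

The exact null distribution is used when both groups have at most
``EXACT_MAX_N`` observations and the pooled data are tie-free; larger or tied
inputs fall back to the normal approximation with tie correction and
continuity correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mann_whitney",
    "bh_fdr",
    "differential_expression",
    "select_candidates",
    "significance_stars",
]

#: Largest per-group n for which the exact (enumeration) p-value is computed.
EXACT_MAX_N = 8


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` with U counted for ``x`` (number of (x_i, y_j) pairs
    with x_i > y_j, ties counting 1/2) and a two-sided p-value.  Missing
    values are dropped; an empty group after dropping is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty after dropping missing")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N
                         and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def significance_stars(p: float) -> str:
    """Report convention: * p<=0.05, ** p<=0.01, *** p<=0.001, else blank."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def differential_expression(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    contrast: tuple[str, str],
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Per-assay Mann-Whitney test between the two groups of ``contrast``.

    Parameters
    ----------
    expr : samples x assays normalized log2 relative expression.
    annot : sample annotation with ``sample_id`` and ``group`` columns.
    contrast : (group_a, group_b); direction is reported for B relative to A.
    min_per_group : assays with fewer non-missing values in either group are
        reported with ``skipped`` True rather than silently dropped.

    Returns a table with one row per assay: group sizes, U statistic (for
    group B), two-sided p, BH q over the tested assays, direction of group B
    vs group A by median, and the two group medians.
    """
    group_a, group_b = contrast
    annot = annot.set_index("sample_id") if "sample_id" in annot.columns else annot
    for g in contrast:
        if g not in set(annot["group"]):
            raise ValueError(f"unknown group label {g!r}")
    samples_a = [s for s in expr.index if annot.loc[s, "group"] == group_a]
    samples_b = [s for s in expr.index if annot.loc[s, "group"] == group_b]
    if len(samples_a) < min_per_group or len(samples_b) < min_per_group:
        raise ValueError(
            f"contrast {group_a!r} vs {group_b!r} needs >= {min_per_group} "
            f"samples per group (have {len(samples_a)}, {len(samples_b)})"
        )

    rows = []
    for assay in expr.columns:
        a = expr.loc[samples_a, assay].dropna()
        b = expr.loc[samples_b, assay].dropna()
        row = {
            "assay_id": assay,
            "n_a": int(a.size),
            "n_b": int(b.size),
            "median_a": float(a.median()) if a.size else np.nan,
            "median_b": float(b.median()) if b.size else np.nan,
        }
        if a.size < min_per_group or b.size < min_per_group:
            row.update(U=np.nan, p_value=np.nan, skipped=True, direction="")
        else:
            u, p = mann_whitney(b.to_numpy(), a.to_numpy())
            row.update(
                U=u,
                p_value=p,
                skipped=False,
                direction="up" if row["median_b"] > row["median_a"] else "down",
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    table["q_value"] = np.nan
    tested = ~table["skipped"]
    if tested.any():
        table.loc[tested, "q_value"] = bh_fdr(table.loc[tested, "p_value"])
    cols = ["assay_id", "n_a", "n_b", "U", "p_value", "q_value", "direction",
            "median_a", "median_b", "skipped"]
    return table[cols]


def select_candidates(
    table: pd.DataFrame,
    p_max: float | None = None,
    fdr_max: float | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Filter and rank DE results for validation picks.

    Assays passing every supplied threshold, ranked by p ascending; ties are
    broken by absolute median difference descending, then by assay id.
    """
    for name, v in (("p_max", p_max), ("fdr_max", fdr_max)):
        if v is not None and not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    sel = table[~table["skipped"]].copy()
    if p_max is not None:
        sel = sel[sel["p_value"] <= p_max]
    if fdr_max is not None:
        sel = sel[sel["q_value"] <= fdr_max]
    sel["_absdiff"] = (sel["median_b"] - sel["median_a"]).abs()
    sel = sel.sort_values(
        ["p_value", "_absdiff", "assay_id"], ascending=[True, False, True]
    ).drop(columns="_absdiff")
    if top_k is not None:
        sel = sel.head(top_k)
    return sel.reset_index(drop=True)
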