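"""Colony-level transcript-abundance analysis.

The abundance matrix is a samples x targets table of CE peak areas with
per-sample metadata (day, condition, cell count).  Analysis follows the
published procedure: only reactions with a GAPDH peak count as successful
assays of live cells; areas are normalised to cell number; splice-variant
co-occurrence, growth rates, day-to-day fold changes with Mann-Whitney
significance, and cross-target correlation are computed on the gated matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import TARGETS, VARIANTS
from .errors import DataError

__all__ = [
    "FoldChangeResult",
    "gate_and_normalize",
    "cooccurrence",
    "growth_rates",
    "mann_whitney_u",
    "fold_change_analysis",
    "expression_correlation",
]


@dataclass
class FoldChangeResult:
    """Day-to-day change in mean per-cell abundance for one target.

    ``significant`` requires both the Mann-Whitney threshold (p <= 0.01 by
    default) and a biologically relevant fold change (> 2 or < 0.5).  When
    the first day's mean is zero the fold change is undefined
    (``defined = False``) and no call is made.
    """

    target: str
    mean_day1: float
    mean_day2: float
    fold_change: float
    mw_p: float
    significant: bool
    defined: bool
    n_day1: int = 0
    n_day2: int = 0


def gate_and_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """GAPDH-gate an abundance matrix and normalise areas to cell number.

    Samples without a GAPDH peak are dropped (failed assays / dead cells).
    For the retained samples each target column is divided by the cell count
    into ``norm_<target>`` columns.  A gated sample with zero recorded cells
    but nonzero areas is contradictory and raises :class:`DataError`.
    """
    required = {"cells", *TARGETS}
    missing = required - set(matrix.columns)
    if missing:
        raise DataError(f"abundance matrix missing column(s): {sorted(missing)}")
    gated = matrix[matrix["GAPDH"] > 0].copy()
    gated["gapdh_positive"] = True
    bad = gated[(gated["cells"] <= 0)]
    if len(bad):
        raise DataError(
            f"zero cell count with nonzero areas for sample(s): {list(bad.index[:5])}"
        )
    for t in TARGETS:
        gated[f"norm_{t}"] = gated[t] / gated["cells"]
    return gated


def total_htert(gated: pd.DataFrame) -> pd.Series:
    """Summed per-cell-normalised abundance of the four splice variants."""
    return gated[[f"norm_{v}" for v in VARIANTS]].sum(axis=1)


def cooccurrence(gated: pd.DataFrame, day: int | None = None) -> pd.DataFrame:
    """Dominant-variant fractions per hTERT-positive sample.

    Returns one row per sample carrying any hTERT signal: the total
    normalised hTERT abundance, the fraction contributed by the largest
    variant, and the number of distinct variants detected, ordered by
    decreasing total abundance (the layout of the co-expression panels).
    """
    df = gated if day is None else gated[gated["day"] == day]
    if df.empty:
        return pd.DataFrame(columns=["total_htert", "dominant_fraction",
                                     "dominant_variant", "n_variants"])
    norm = df[[f"norm_{v}" for v in VARIANTS]].to_numpy(dtype=float)
    total = norm.sum(axis=1)
    pos = total > 0
    norm = norm[pos]
    total_pos = total[pos]
    dom_idx = norm.argmax(axis=1)
    out = pd.DataFrame(
        {
            "total_htert": total_pos,
            "dominant_fraction": norm.max(axis=1) / total_pos,
            "dominant_variant": [VARIANTS[i] for i in dom_idx],
            "n_variants": (norm > 0).sum(axis=1),
        },
        index=df.index[pos],
    )
    return out.sort_values("total_htert", ascending=False)


def growth_rates(truth: pd.DataFrame, final_day: int | None = None):
    """Per-colony growth rates and a Welch t-test between conditions.

    Rates are ``ln(cells_final / cells_day0) / days`` per colony (founding
    cells > 0); doubling time is ``ln 2 / rate``.  Returns ``(per_colony,
    p_value)`` where ``p_value`` is the two-tailed Welch t-test between the
    two conditions (None when fewer than two conditions are present).
    """
    required = {"droplet_id", "day", "founding_cells", "cell_count"}
    if not required <= set(truth.columns):
        raise DataError(f"growth table needs columns {sorted(required)}")
    if final_day is None:
        final_day = int(truth["day"].max())
    df = truth[(truth["day"] == final_day) & (truth["founding_cells"] > 0)
               & (truth["cell_count"] > 0)].copy()
    if "condition" not in df.columns:
        df["condition"] = "all"
    rate = np.log(df["cell_count"] / df["founding_cells"]) / final_day  # per day
    per_colony = pd.DataFrame(
        {
            "droplet_id": df["droplet_id"],
            "condition": df["condition"],
            "rate_per_day": rate,
            "doubling_time_h": np.where(rate > 0, np.log(2) / rate * 24.0, np.inf),
        }
    )
    conds = sorted(per_colony["condition"].unique())
    p_value = None
    if len(conds) == 2:
        a = per_colony.loc[per_colony["condition"] == conds[0], "rate_per_day"]
        b = per_colony.loc[per_colony["condition"] == conds[1], "rate_per_day"]
        if len(a) >= 2 and len(b) >= 2:
            t = stats.ttest_ind(a, b, equal_var=False)
            if np.isfinite(t.pvalue):
                p_value = float(t.pvalue)
            else:  # zero variance in both groups: p is 1 iff the means agree
                p_value = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return per_colony, p_value


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when the pooled sample is small (<= 20) without
    ties, and the tie-corrected normal approximation otherwise.  Returns
    ``(U_a, p)`` with U counted for the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fold_change_analysis(
    gated: pd.DataFrame,
    target: str,
    condition: str | None = None,
    day_pair: tuple[int, int] = (1, 2),
    p_threshold: float = 0.01,
    fc_upper: float = 2.0,
    fc_lower: float = 0.5,
) -> FoldChangeResult:
    """Fold change of mean per-cell abundance between two days.

    ``fold_change = mean(day2) / mean(day1)`` on the normalised areas within
    one condition; significance requires the Mann-Whitney p-value at or below
    ``p_threshold`` *and* fold change outside ``[fc_lower, fc_upper]``.
    """
    col = f"norm_{target}"
    if col not in gated.columns:
        raise DataError(f"no normalised column for target {target!r}; gate first")
    df = gated if condition is None else gated[gated["condition"] == condition]
    d1 = df.loc[df["day"] == day_pair[0], col].to_numpy(dtype=float)
    d2 = df.loc[df["day"] == day_pair[1], col].to_numpy(dtype=float)
    if d1.size == 0 or d2.size == 0:
        return FoldChangeResult(target, np.nan, np.nan, np.nan, np.nan,
                                significant=False, defined=False,
                                n_day1=d1.size, n_day2=d2.size)
    m1, m2 = float(d1.mean()), float(d2.mean())
    if m1 == 0.0:
        return FoldChangeResult(target, m1, m2, np.nan, np.nan,
                                significant=False, defined=False,
                                n_day1=d1.size, n_day2=d2.size)
    fc = m2 / m1
    _, p = mann_whitney_u(d1, d2)
    significant = (p <= p_threshold) and (fc > fc_upper or fc < fc_lower)
    return FoldChangeResult(target, m1, m2, fc, p, significant, True,
                            n_day1=d1.size, n_day2=d2.size)


def expression_correlation(gated: pd.DataFrame, target_x: str, target_y: str) -> float:
    """Squared Pearson correlation of two targets' per-cell abundances.

    Returns ``nan`` (undefined sentinel) when either target has zero variance
    or fewer than 3 gated samples are available.
    """
    x = gated[f"norm_{target_x}"].to_numpy(dtype=float)
    y = gated[f"norm_{target_y}"].to_numpy(dtype=float)
    if x.size < 3 or np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
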