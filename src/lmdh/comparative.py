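"""Nonparametric group comparisons and correlations.

Wilcoxon rank-sum tests compare fixation indices and diversification proxies
between dispersive and non-dispersive groups; Spearman rank correlations
relate per-genus mean fixation indices to endemic species richness.  All
p-values are two-sided; ties take midranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComparisonResult", "wilcoxon_rank_sum", "spearman", "genus_aggregate"]

EXACT_MAX_N = 20


@dataclass
class ComparisonResult:
    test: str                 # "wilcoxon" or "spearman"
    statistic: float
    p_two_sided: float
    n: tuple[int, int] | int
    method: str               # "exact", "normal_approx" or "t_approx"


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_rank_sum(x, y) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when both samples have <= 20 observations and the
    pooled sample is tie-free; otherwise the normal approximation with
    tie-corrected variance and continuity correction.  The statistic reported
    is the rank sum W of ``x`` (midranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not _has_ties(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U1 -> rank sum of x
    return ComparisonResult(
        test="wilcoxon",
        statistic=w,
        p_two_sided=float(res.pvalue),
        n=(int(x.size), int(y.size)),
        method="exact" if exact else "normal_approx",
    )


def spearman(x, y) -> ComparisonResult:
    """Spearman rank correlation with a t approximation on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("zero rank variance in one of the vectors")
    rho, p = stats.spearmanr(x, y)
    return ComparisonResult(
        test="spearman",
        statistic=float(rho),
        p_two_sided=float(p),
        n=int(x.size),
        method="t_approx",
    )


def genus_aggregate(
    fixation: pd.DataFrame,
    lineage_info: pd.DataFrame,
    richness: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-genus mean G_ST / N_ST over defined lineage results, per scale.

    ``fixation`` is the structure-scan table (lmdh_id, scale, GST, NST,
    defined); ``lineage_info`` maps lmdh_id to genus, order and dispersal;
    ``richness`` (optional) maps genus to endemic species count S.  Genera
    with no defined result at a scale are dropped.
    """
    info = lineage_info.set_index("lmdh_id") if "lmdh_id" in lineage_info.columns else lineage_info
    df = fixation[fixation["defined"]].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["genus", "scale", "order", "dispersal", "mean_GST", "mean_NST", "n_lineages"]
        )
    df = df.join(info[["genus", "order", "dispersal"]], on="lmdh_id")
    out = (
        df.groupby(["genus", "scale"])
        .agg(
            order=("order", "first"),
            dispersal=("dispersal", "first"),
            mean_GST=("GST", "mean"),
            mean_NST=("NST", "mean"),
            n_lineages=("lmdh_id", "nunique"),
        )
        .reset_index()
    )
    if richness is not None:
        rich = richness.set_index("genus_unit")["S"] if "genus_unit" in richness.columns else richness
        out["S"] = out["genus"].map(rich)
    return out
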