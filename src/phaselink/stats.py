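"""Two-group comparison of connectivity and topology features.

Mann-Whitney U (exact for small tie-free samples, normal approximation with
tie correction otherwise), Benjamini-Hochberg FDR within a stated family of
features, and the pre/post percentage change 100*(post - pre)/pre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "mann_whitney",
    "fdr_bh",
    "percent_change",
    "group_comparison_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    """One feature's two-group Mann-Whitney comparison."""

    feature: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    U: float
    p: float
    p_adjusted: float
    significant: bool


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the combined sample size is at most
    20 and there are no ties, the tie-corrected normal approximation
    otherwise.  Returns (U of the first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        # a constant feature: no evidence either way
        logger.info("mann_whitney: constant input, returning p = 1")
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection mask."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre."""
    if pre == 0:
        raise ValueError("percent change undefined for pre = 0")
    return 100.0 * (post - pre) / pre


def group_comparison_table(
    features: pd.DataFrame,
    labels: Sequence[str],
    q: float = 0.05,
    groups: tuple[str, str] | None = None,
    families: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mann-Whitney comparison of every feature column, FDR-corrected.

    Parameters
    ----------
    features
        Numeric per-subject feature table (rows = subjects).
    labels
        Group label per row; exactly two distinct labels.
    groups
        Order of the two groups for the (mean_a, mean_b) columns; defaults to
        sorted label order.
    families
        Optional mapping feature -> family id; BH correction is applied
        within each family separately (default: all features one family).
    """
    labels = np.asarray(labels)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    ga, gb = groups if groups is not None else (uniq[0], uniq[1])
    rows = []
    for col in features.columns:
        x = features.loc[labels == ga, col].to_numpy(dtype=float)
        y = features.loc[labels == gb, col].to_numpy(dtype=float)
        U, p = mann_whitney(x, y)
        rows.append(
            {
                "feature": col,
                "family": families.get(col, "all") if families else "all",
                f"mean_{ga}": x.mean(),
                f"sd_{ga}": x.std(ddof=1) if x.size > 1 else 0.0,
                f"mean_{gb}": y.mean(),
                f"sd_{gb}": y.std(ddof=1) if y.size > 1 else 0.0,
                "U": U,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    table["significant"] = False
    for fam, idx in table.groupby("family").groups.items():
        p_adj, reject = fdr_bh(table.loc[idx, "p"].to_numpy(), q)
        table.loc[idx, "p_adjusted"] = p_adj
        table.loc[idx, "significant"] = reject
    return table
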