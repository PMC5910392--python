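"""Group-wise differential analysis of dCq and ratio features.

Covers two-group t-tests (Welch by default), one-way ANOVA across two or
more groups, the paired Wilcoxon signed-rank test for matched samples,
Benjamini-Hochberg FDR adjustment, two-sample Kolmogorov-Smirnov tests,
and the downstream feature filters used in biomarker panel refinement:
an effect-magnitude filter, a cross-dataset consistency filter, a
distribution-match gate that decides whether two datasets may be pooled,
and the miRNA connection-degree summary of a significant-ratio set.

Features are analysed pairwise-complete: each feature uses whatever
samples observed it, so group sizes may differ across features.  Features
whose groups hold fewer than two observations are flagged (``tested =
False``) and excluded from the multiplicity correction rather than
silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import fold_change

__all__ = [
    "t_test",
    "anova_oneway",
    "paired_wilcoxon",
    "bh_adjust",
    "ks_two_sample",
    "differential_table",
    "magnitude_filter",
    "consistency_filter",
    "pooling_gate",
    "node_degree",
    "volcano_coordinates",
    "WilcoxonResult",
    "ConsistencySet",
    "PoolingDecision",
]


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def t_test(x, y, variant: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test; ``variant`` is ``"student"`` (pooled
    variance) or ``"welch"`` (unequal variances)."""
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observed values")
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    stat, p = float(res.statistic), float(res.pvalue)
    if math.isnan(p):  # zero variance in both groups and equal means
        stat, p = 0.0, 1.0
    return stat, p


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA over two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observed values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:  # all values identical: no variance at all
        return 0.0, 1.0
    res = stats.f_oneway(*arrays)
    f, p = float(res.statistic), float(res.pvalue)
    if math.isnan(f):
        f, p = 0.0, 1.0
    return f, p


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    median_log2_diff: float
    n_informative: int
    tested: bool


def paired_wilcoxon(
    x_tumour,
    x_normal,
    pseudo_count: float = 0.5,
    min_informative: int = 5,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on matched expression vectors.

    Values are shifted by ``pseudo_count`` before log2 (RPM tables contain
    zeros).  Pairs with zero log2 difference are uninformative; with fewer
    than ``min_informative`` informative pairs the test is flagged instead
    of producing a p-value.  The reported effect is the median per-pair
    log2(tumour/normal) over *all* pairs.
    """
    t = np.asarray(x_tumour, dtype=float)
    n = np.asarray(x_normal, dtype=float)
    if t.shape != n.shape:
        raise ValueError("matched vectors must have equal length")
    if np.any(t < 0) or np.any(n < 0):
        raise ValueError("expression values must be non-negative")
    l2d = np.log2(t + pseudo_count) - np.log2(n + pseudo_count)
    median = float(np.median(l2d)) if len(l2d) else math.nan
    informative = l2d[l2d != 0.0]
    if len(informative) < min_informative:
        return WilcoxonResult(math.nan, math.nan, median, len(informative), False)
    res = stats.wilcoxon(informative, alternative="two-sided")
    return WilcoxonResult(
        float(res.statistic), float(res.pvalue), median, len(informative), True
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def ks_two_sample(values_a, values_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("KS test needs at least 3 values per sample")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# feature-wise differential tables
# ---------------------------------------------------------------------------


def differential_table(
    values: pd.DataFrame,
    groups: pd.Series,
    group1,
    group2,
    test: str = "welch",
) -> pd.DataFrame:
    """Per-feature two-group comparison with BH correction.

    Parameters
    ----------
    values
        Samples x features matrix (dCq or ratio values; NaN allowed).
    groups
        Per-sample group labels aligned with ``values``.  ``group1`` and
        ``group2`` may be single labels or sets of labels (e.g. the
        combined lung-cancer group ``{"SCC", "AD"}``).
    test
        ``"welch"`` (default), ``"student"`` or ``"anova"`` (two-group
        one-way ANOVA; equivalent to the pooled-variance t-test).

    Returns a table with group means and SDs, the signed mean difference
    (dCq/log2 units), the signed linear fold change, raw and BH-adjusted
    p-values, and a ``tested`` flag.  Features failing the minimum group
    size (2 per group) carry NaN p-values and do not enter the BH family.
    """
    groups = groups.loc[values.index]
    set1 = {group1} if isinstance(group1, str) else set(group1)
    set2 = {group2} if isinstance(group2, str) else set(group2)
    mask1 = groups.isin(set1).to_numpy()
    mask2 = groups.isin(set2).to_numpy()
    if mask1.sum() == 0 or mask2.sum() == 0:
        raise ValueError("both groups must be present in the data")

    mat = values.to_numpy(dtype=float)
    rows = []
    for j, feat in enumerate(values.columns):
        x = mat[mask1, j]
        y = mat[mask2, j]
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        n1, n2 = len(x), len(y)
        tested = n1 >= 2 and n2 >= 2
        m1 = float(np.mean(x)) if n1 else math.nan
        m2 = float(np.mean(y)) if n2 else math.nan
        if tested:
            if test == "anova":
                stat, p = anova_oneway([x, y])
            else:
                stat, p = t_test(x, y, variant=test)
            fc = fold_change(m1, m2)
        else:
            stat, p, fc = math.nan, math.nan, math.nan
        rows.append(
            {
                "feature": feat,
                "mean1": m1,
                "mean2": m2,
                "sd1": float(np.std(x, ddof=1)) if n1 >= 2 else math.nan,
                "sd2": float(np.std(y, ddof=1)) if n2 >= 2 else math.nan,
                "n1": n1,
                "n2": n2,
                "mean_diff": m1 - m2,
                "fold_change": fc,
                "statistic": stat,
                "p_raw": p,
                "tested": tested,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adj"] = math.nan
    tested_mask = out["tested"].to_numpy()
    if tested_mask.any():
        out.loc[tested_mask, "p_adj"] = bh_adjust(out.loc[tested_mask, "p_raw"])
    return out


def magnitude_filter(diff: pd.DataFrame, min_abs_dcq: float = 1.0) -> list[str]:
    """Features whose absolute group mean difference is >= ``min_abs_dcq``
    cycles (inclusive boundary)."""
    keep = diff["mean_diff"].abs() >= min_abs_dcq
    return list(diff.index[keep.fillna(False)])


@dataclass
class ConsistencySet:
    """Features significant in both datasets with concordant direction."""

    features: list[str]
    table: pd.DataFrame  # per-dataset effect sizes and adjusted p-values


def consistency_filter(
    diff_discovery: pd.DataFrame,
    diff_verification: pd.DataFrame,
    alpha: float = 0.05,
) -> ConsistencySet:
    """Intersect two differential tables: keep features BH-significant in
    both datasets with the same sign of mean difference."""
    shared = diff_discovery.index.intersection(diff_verification.index)
    if len(shared) == 0:
        raise ValueError("differential tables share no features")
    d = diff_discovery.loc[shared]
    v = diff_verification.loc[shared]
    sig = (d["p_adj"] < alpha) & (v["p_adj"] < alpha)
    concordant = np.sign(d["mean_diff"]) == np.sign(v["mean_diff"])
    keep = (sig & concordant).fillna(False)
    feats = list(shared[keep])
    table = pd.DataFrame(
        {
            "mean_diff_discovery": d["mean_diff"],
            "p_adj_discovery": d["p_adj"],
            "mean_diff_verification": v["mean_diff"],
            "p_adj_verification": v["p_adj"],
            "consistent": keep,
        }
    )
    return ConsistencySet(features=feats, table=table)


@dataclass
class PoolingDecision:
    pool: bool
    table: pd.DataFrame  # feature x group KS results
    vacuous: bool = False


def pooling_gate(
    values_a: pd.DataFrame,
    groups_a: pd.Series,
    values_b: pd.DataFrame,
    groups_b: pd.Series,
    group_sets: Mapping[str, Iterable[str]] | None = None,
    alpha: float = 0.05,
) -> PoolingDecision:
    """Decide whether two datasets may be pooled.

    For every shared feature and every group set (default: HD alone and
    the combined LC = SCC+AD group) a two-sample KS test compares the two
    datasets' value distributions; p-values are BH-adjusted across the
    whole family.  Pooling is allowed when nothing rejects at ``alpha``.
    Features with fewer than 3 values on either side are flagged untested;
    an empty feature set pools vacuously.
    """
    if group_sets is None:
        group_sets = {"HD": {"HD"}, "LC": {"SCC", "AD"}}
    shared = values_a.columns.intersection(values_b.columns)
    rows = []
    for gname, gset in group_sets.items():
        gset = set(gset)
        ma = groups_a.loc[values_a.index].isin(gset).to_numpy()
        mb = groups_b.loc[values_b.index].isin(gset).to_numpy()
        for feat in shared:
            a = values_a.loc[ma, feat].to_numpy(dtype=float)
            b = values_b.loc[mb, feat].to_numpy(dtype=float)
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            if len(a) < 3 or len(b) < 3:
                rows.append(
                    {"feature": feat, "group": gname, "n_a": len(a), "n_b": len(b),
                     "D": math.nan, "p_raw": math.nan, "tested": False}
                )
                continue
            d_stat, p = ks_two_sample(a, b)
            rows.append(
                {"feature": feat, "group": gname, "n_a": len(a), "n_b": len(b),
                 "D": d_stat, "p_raw": p, "tested": True}
            )
    table = pd.DataFrame(
        rows, columns=["feature", "group", "n_a", "n_b", "D", "p_raw", "tested"]
    )
    if len(table) == 0 or not table["tested"].any():
        table["p_adj"] = math.nan
        return PoolingDecision(pool=True, table=table, vacuous=True)
    table["p_adj"] = math.nan
    tested = table["tested"].to_numpy()
    table.loc[tested, "p_adj"] = bh_adjust(table.loc[tested, "p_raw"])
    pool = not bool((table.loc[tested, "p_adj"] < alpha).any())
    return PoolingDecision(pool=pool, table=table, vacuous=False)


def volcano_coordinates(diff: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready coordinates for a differential table:
    x = mean difference (log2 units), y = -log10 BH-adjusted p."""
    out = pd.DataFrame(
        {
            "log2_diff": diff["mean_diff"],
            "p_adj": diff["p_adj"],
        },
        index=diff.index,
    )
    with np.errstate(divide="ignore"):
        out["neg_log10_p_adj"] = -np.log10(out["p_adj"])
    return out


def node_degree(significant_ratio_ids: Iterable[str]) -> pd.Series:
    """Count how many significant ratios each miRNA participates in.

    The degree sum equals twice the number of ratios (handshake lemma);
    high-degree miRNAs are the hubs of the deregulated-ratio network.
    """
    counts: dict[str, int] = {}
    for rid in significant_ratio_ids:
        parts = rid.split("/")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"malformed ratio id {rid!r}")
        for m in parts:
            counts[m] = counts.get(m, 0) + 1
    s = pd.Series(counts, dtype=int, name="degree")
    return s.sort_values(ascending=False)
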