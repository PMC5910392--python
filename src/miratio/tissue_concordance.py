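"""Matched tumour-vs-normal concordance of candidate plasma markers.

Plasma findings gain credibility when the same miRNAs are deregulated in
tumour tissue itself.  Given matched tumour/normal expression (RPM) for a
feature panel at the precursor ("hairpin") and/or mature level, each
feature is tested with the paired Wilcoxon signed-rank test; p-values are
BH-adjusted within the tested list and the effect size is the median
per-patient log2(tumour/normal) ratio (pseudo-count 0.5 RPM for zeros).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diff_expression import bh_adjust, paired_wilcoxon

LEVELS = ("hairpin", "mature")

_COLUMNS = ("feature_id", "level", "patient_id", "tumour_rpm", "normal_rpm")


@dataclass
class MatchedExpressionTable:
    """Long-format matched tumour/normal expression table.

    One row per (feature, level, patient); expression is non-negative RPM.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"matched table missing columns: {missing}")
        bad_levels = set(self.data["level"]) - set(LEVELS)
        if bad_levels:
            raise ValueError(f"unknown expression levels: {sorted(bad_levels)}")
        if (self.data[["tumour_rpm", "normal_rpm"]] < 0).any().any():
            raise ValueError("expression values must be non-negative")
        if self.data.duplicated(subset=["feature_id", "level", "patient_id"]).any():
            raise ValueError("duplicate (feature, level, patient) rows")

    @property
    def features(self) -> list[tuple[str, str]]:
        seen = self.data[["feature_id", "level"]].drop_duplicates()
        return list(seen.itertuples(index=False, name=None))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path: str | Path) -> "MatchedExpressionTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"feature_id": str, "level": str,
                                                      "patient_id": str}))


def concordance_test(
    table: MatchedExpressionTable,
    feature_list: Sequence[str] | None = None,
    alpha: float = 0.05,
    pseudo_count: float = 0.5,
    min_informative: int = 5,
) -> pd.DataFrame:
    """Paired tumour-vs-normal test for each feature in the table.

    ``feature_list`` restricts the analysis; requested features absent
    from the table are reported with status ``"missing"`` rather than
    dropped silently.  Direction is ``up``/``down`` for BH-significant
    features by the sign of the median log2 difference, else ``ns``.
    """
    present = table.features
    present_ids = {f for f, _ in present}
    wanted = list(feature_list) if feature_list is not None else sorted(present_ids)

    rows = []
    for fid in wanted:
        levels_here = [lvl for f, lvl in present if f == fid]
        if not levels_here:
            rows.append(
                {"feature_id": fid, "level": "", "n_pairs": 0, "n_informative": 0,
                 "median_log2_diff": math.nan, "p_raw": math.nan, "status": "missing"}
            )
            continue
        for lvl in levels_here:
            sub = table.data[(table.data["feature_id"] == fid) & (table.data["level"] == lvl)]
            sub = sub.sort_values("patient_id")
            res = paired_wilcoxon(
                sub["tumour_rpm"].to_numpy(),
                sub["normal_rpm"].to_numpy(),
                pseudo_count=pseudo_count,
                min_informative=min_informative,
            )
            rows.append(
                {
                    "feature_id": fid,
                    "level": lvl,
                    "n_pairs": len(sub),
                    "n_informative": res.n_informative,
                    "median_log2_diff": res.median_log2_diff,
                    "p_raw": res.p_value,
                    "status": "tested" if res.tested else "untested",
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = math.nan
    tested = (out["status"] == "tested").to_numpy()
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p_raw"])
    direction = []
    for _, r in out.iterrows():
        if r["status"] == "tested" and r["p_adj"] < alpha:
            direction.append("up" if r["median_log2_diff"] > 0 else "down")
        else:
            direction.append("ns" if r["status"] != "missing" else "missing")
    out["direction"] = direction
    return out


def volcano_coordinates(result: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready coordinates: x = median log2 difference, y = -log10 p_adj."""
    out = result[["feature_id", "level", "median_log2_diff", "p_adj", "direction"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p_adj"] = -np.log10(out["p_adj"])
    return out
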