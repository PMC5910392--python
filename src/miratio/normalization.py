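"""Global-mean dCq normalization and exhaustive pairwise ratio features.

Plasma has no validated housekeeping miRNA, so two reference-free
normalizations are used:

* **global mean**: ``dCq(s, i) = mean_j Cq(s, j) - Cq(s, i)`` with the
  mean over assays observed in sample *s*.  Higher dCq = more abundant.
* **ratios**: for every unordered assay pair {a, b} the per-sample Cq
  difference ``Cq(s, b) - Cq(s, a)`` (equivalently ``dcq(a) - dcq(b)``).
  Ratios cancel the per-sample offset exactly, so they are invariant to
  plasma input amount and extraction yield.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import PanelCqTable


def global_mean_dcq(table: PanelCqTable) -> pd.DataFrame:
    """Per-sample global-mean-normalized expression (samples x assays).

    Missing (undetected) entries propagate; the global mean of a sample is
    taken over its observed assays only.  A sample with no observed assay
    is an error (its reference is undefined).
    """
    cq = table.cq.to_numpy(dtype=float)
    n_obs = np.sum(np.isfinite(cq), axis=1)
    if np.any(n_obs == 0):
        bad = [s for s, n in zip(table.samples, n_obs) if n == 0]
        raise ValueError(f"samples with zero observed assays: {bad}")
    gmean = np.nanmean(cq, axis=1)
    dcq = gmean[:, None] - cq
    return pd.DataFrame(dcq, index=table.cq.index, columns=table.cq.columns)


@dataclass
class RatioMatrix:
    """Exhaustive pairwise-ratio feature matrix.

    ``pairs`` holds canonical unordered pairs (a, b) with a < b in
    lexicographic assay order; the feature named ``"a/b"`` has value
    ``Cq(s, b) - Cq(s, a)``, i.e. positive when a is more abundant than b.
    """

    values: pd.DataFrame  # samples x pair names
    pairs: list[tuple[str, str]]

    @property
    def pair_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6g", index_label="sample_id")


def ratio_matrix(table: PanelCqTable) -> RatioMatrix:
    """All k(k-1)/2 pairwise Cq differences (pairwise-complete).

    A sample contributes to a ratio only when both member assays are
    detected; otherwise the value is missing.
    """
    if table.n_assays < 2:
        raise ValueError("ratio features need at least 2 assays")
    assays = sorted(table.assays)
    cq = table.cq[assays].to_numpy(dtype=float)
    idx_pairs = list(combinations(range(len(assays)), 2))
    ii = np.array([i for i, _ in idx_pairs])
    jj = np.array([j for _, j in idx_pairs])
    values = cq[:, jj] - cq[:, ii]
    pairs = [(assays[i], assays[j]) for i, j in idx_pairs]
    names = [f"{a}/{b}" for a, b in pairs]
    return RatioMatrix(
        values=pd.DataFrame(values, index=table.cq.index, columns=names),
        pairs=pairs,
    )


def fold_change(mean1, mean2):
    """Signed linear fold change from two group mean dCq values.

    With ``d = mean1 - mean2`` (dCq units, i.e. log2 expression units),
    returns ``+2**d`` for d >= 0 and ``-2**(-d)`` for d < 0: the magnitude
    is always >= 1 and the sign encodes the direction of regulation.
    Accepts scalars or arrays.
    """
    m1 = np.asarray(mean1, dtype=float)
    m2 = np.asarray(mean2, dtype=float)
    if not (np.all(np.isfinite(m1)) and np.all(np.isfinite(m2))):
        raise ValueError("fold_change requires finite group means")
    d = m1 - m2
    out = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    if out.ndim == 0:
        return float(out)
    return out


def write_dcq(dcq: pd.DataFrame, path: str | Path) -> None:
    dcq.to_csv(path, sep="\t", float_format="%.6g", index_label="sample_id")
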