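"""Reading/writing qPCR Cq panel tables and sample/assay quality gates.

Plasma miRNA qPCR panels produce one quantification cycle (Cq) per sample
and assay; an assay that never crosses the fluorescence threshold is
*undetected* and carries no Cq.  Two quality gates are applied before any
statistics:

* a per-sample haemolysis gate based on the miR-23a/miR-451a ΔCq
  (miR-451a is highly abundant in erythrocytes, so red-blood-cell lysis
  inflates the ΔCq; samples with ΔCq >= 7.5 cycles are discarded), and
* a per-assay call-rate gate (assays detected in fewer than 80% of
  samples are too unreliable to analyse).

Both thresholds are configurable; the defaults are the conventional ones
for commercial serum/plasma miRNA qPCR panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("SCC", "AD", "HD", "EB")
DATASETS = ("discovery", "verification")
CANCER_GROUPS = frozenset({"SCC", "AD"})
NON_CANCER_GROUPS = frozenset({"HD", "EB"})

#: canonical haemolysis marker assays (numerator, denominator of the ΔCq)
HEMOLYSIS_MARKERS = ("hsa-miR-23a-3p", "hsa-miR-451a")

BLOCKLIST_TIERS = ("strong", "tentative")
BLOCKLIST_MODES = ("stringent", "semi_stringent")

#: literature-derived default haemolysis blocklist: miRNAs abundant in
#: erythrocytes ("strong") or repeatedly reported as haemolysis-sensitive
#: ("tentative").  User-supplied lists override this.
DEFAULT_HEMOLYSIS_BLOCKLIST: dict[str, str] = {
    "hsa-miR-451a": "strong",
    "hsa-miR-486-5p": "strong",
    "hsa-miR-92a-3p": "strong",
    "hsa-miR-16-5p": "tentative",
    "hsa-miR-25-3p": "tentative",
    "hsa-miR-106b-5p": "tentative",
}


class QcError(ValueError):
    """Raised when a quality gate cannot be applied or empties the data."""


@dataclass
class PanelCqTable:
    """Sample x assay Cq matrix with detection flags and sample metadata.

    Parameters
    ----------
    cq
        Float matrix of quantification cycles, samples in rows, assays in
        columns.  NaN wherever the assay is undetected.
    detected
        Boolean matrix parallel to ``cq``.
    meta
        Per-sample metadata indexed like ``cq``; must contain ``group``
        (one of SCC/AD/HD/EB) and ``dataset`` (discovery/verification).
    """

    cq: pd.DataFrame
    detected: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if not self.cq.index.is_unique:
            raise ValueError("duplicate sample identifiers")
        if not self.cq.columns.is_unique:
            raise ValueError("duplicate assay identifiers")
        if not self.cq.index.equals(self.detected.index) or not self.cq.columns.equals(
            self.detected.columns
        ):
            raise ValueError("cq and detected matrices are not aligned")
        if not self.cq.index.equals(self.meta.index):
            raise ValueError("metadata index does not match sample identifiers")
        for col in ("group", "dataset"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata is missing required column {col!r}")
        bad_groups = set(self.meta["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
        bad_ds = set(self.meta["dataset"]) - set(DATASETS)
        if bad_ds:
            raise ValueError(f"unknown dataset labels: {sorted(bad_ds)}")
        det = self.detected.to_numpy(dtype=bool)
        vals = self.cq.to_numpy(dtype=float)
        if np.any(det & ~np.isfinite(vals)):
            raise ValueError("detected entries must carry finite Cq values")
        if np.any(~det & ~np.isnan(vals)):
            raise ValueError("undetected entries must be stored as missing")

    # -- accessors ------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.cq.index)

    @property
    def assays(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def n_samples(self) -> int:
        return self.cq.shape[0]

    @property
    def n_assays(self) -> int:
        return self.cq.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.meta["group"]

    def subset(
        self,
        samples: Sequence[str] | None = None,
        assays: Sequence[str] | None = None,
    ) -> "PanelCqTable":
        """Return a copy restricted to the given samples and/or assays."""
        samples = list(samples) if samples is not None else self.samples
        assays = list(assays) if assays is not None else self.assays
        return PanelCqTable(
            cq=self.cq.loc[samples, assays].copy(),
            detected=self.detected.loc[samples, assays].copy(),
            meta=self.meta.loc[samples].copy(),
        )


@dataclass
class QcReport:
    """Outcome of the sample and assay quality gates.

    ``excluded_samples`` maps sample id -> reason code (``"hemolysis"`` or
    ``"qc_marker_missing"``); retained + excluded always partition the
    input sets exactly.
    """

    hemolysis_scores: pd.Series | None = None
    retained_samples: list[str] = field(default_factory=list)
    excluded_samples: dict[str, str] = field(default_factory=dict)
    assay_call_rates: pd.Series | None = None
    retained_assays: list[str] = field(default_factory=list)
    excluded_assays: list[str] = field(default_factory=list)

    def merge(self, other: "QcReport") -> "QcReport":
        """Combine a sample-gate report (self) with a subsequent
        assay-gate report (other): sample information comes from the
        first, assay information from the second."""
        return QcReport(
            hemolysis_scores=(
                self.hemolysis_scores
                if self.hemolysis_scores is not None
                else other.hemolysis_scores
            ),
            retained_samples=self.retained_samples or other.retained_samples,
            excluded_samples={**self.excluded_samples, **other.excluded_samples},
            assay_call_rates=(
                other.assay_call_rates
                if other.assay_call_rates is not None
                else self.assay_call_rates
            ),
            retained_assays=other.retained_assays or self.retained_assays,
            excluded_assays=other.excluded_assays or self.excluded_assays,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format summary (entity, kind, status, reason/score)."""
        rows: list[dict] = []
        for s in self.retained_samples:
            rows.append({"id": s, "kind": "sample", "status": "retained", "reason": ""})
        for s, reason in self.excluded_samples.items():
            rows.append({"id": s, "kind": "sample", "status": "excluded", "reason": reason})
        for a in self.retained_assays:
            rows.append({"id": a, "kind": "assay", "status": "retained", "reason": ""})
        for a in self.excluded_assays:
            rows.append({"id": a, "kind": "assay", "status": "excluded", "reason": "call_rate"})
        return pd.DataFrame(rows, columns=["id", "kind", "status", "reason"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_REQUIRED_CQ_COLUMNS = ("sample_id", "assay_id", "cq", "detected")
_REQUIRED_META_COLUMNS = ("sample_id", "group", "dataset")


def read_cq_table(path: str | Path, meta_path: str | Path) -> PanelCqTable:
    """Read a long-format Cq file plus its sample metadata file.

    The Cq file is tab-delimited with columns ``sample_id``, ``assay_id``,
    ``cq`` (empty where undetected) and ``detected`` (0/1); the metadata
    file carries ``sample_id``, ``group`` and ``dataset``.
    """
    long = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay_id": str})
    missing = [c for c in _REQUIRED_CQ_COLUMNS if c not in long.columns]
    if missing:
        raise ValueError(f"Cq file {path} is missing columns: {missing}")
    dup = long.duplicated(subset=["sample_id", "assay_id"])
    if dup.any():
        pairs = long.loc[dup, ["sample_id", "assay_id"]].iloc[0].tolist()
        raise ValueError(f"duplicate (sample, assay) rows in {path}, e.g. {tuple(pairs)}")

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    miss_m = [c for c in _REQUIRED_META_COLUMNS if c not in meta.columns]
    if miss_m:
        raise ValueError(f"metadata file {meta_path} is missing columns: {miss_m}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample_id rows in {meta_path}")
    meta = meta.set_index("sample_id")

    detected = (
        long.pivot(index="sample_id", columns="assay_id", values="detected")
        .astype(float)
        .fillna(0.0)
        .astype(bool)
    )
    cq = long.pivot(index="sample_id", columns="assay_id", values="cq").astype(float)
    cq = cq.where(detected)

    unknown = set(cq.index) - set(meta.index)
    if unknown:
        raise ValueError(f"samples without metadata: {sorted(unknown)}")
    meta = meta.loc[cq.index]
    # keep original assay order from the file rather than pivot's sort
    assay_order = list(dict.fromkeys(long["assay_id"]))
    sample_order = list(dict.fromkeys(long["sample_id"]))
    cq = cq.loc[sample_order, assay_order]
    detected = detected.loc[sample_order, assay_order]
    meta = meta.loc[sample_order]
    cq.columns.name = None
    detected.columns.name = None
    return PanelCqTable(cq=cq, detected=detected, meta=meta)


def write_cq_table(table: PanelCqTable, path: str | Path, meta_path: str | Path) -> None:
    """Write a table in the long format understood by :func:`read_cq_table`."""
    rows = []
    det = table.detected
    for s in table.samples:
        for a in table.assays:
            rows.append((s, a, table.cq.at[s, a], int(det.at[s, a])))
    long = pd.DataFrame(rows, columns=["sample_id", "assay_id", "cq", "detected"])
    long.to_csv(path, sep="\t", index=False, float_format="%.6g")
    table.meta.reset_index(names="sample_id").to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quality gates
# ---------------------------------------------------------------------------


def _resolve_marker(assays: Sequence[str], marker: str) -> str:
    """Resolve a marker assay name, allowing unique substring matches
    (panels label e.g. 'miR-23a' vs 'hsa-miR-23a-3p' inconsistently)."""
    if marker in assays:
        return marker
    hits = [a for a in assays if marker in a or a in marker]
    if len(hits) == 1:
        return hits[0]
    raise QcError(f"haemolysis marker {marker!r} not resolvable among assays")


def hemolysis_score(
    table: PanelCqTable,
    markers: tuple[str, str] = HEMOLYSIS_MARKERS,
) -> pd.Series:
    """Per-sample haemolysis ΔCq = Cq(miR-23a) − Cq(miR-451a).

    miR-451a is erythrocyte-derived, so haemolysed plasma shows a large
    ΔCq.  Samples where either marker is undetected get NaN — the gate is
    then uncomputable and the sample must be flagged, never passed.
    """
    m_hi = _resolve_marker(table.assays, markers[0])
    m_lo = _resolve_marker(table.assays, markers[1])
    score = table.cq[m_hi] - table.cq[m_lo]
    score.name = "hemolysis_dcq"
    return score


def filter_samples(
    table: PanelCqTable, threshold: float = 7.5
) -> tuple[PanelCqTable, QcReport]:
    """Drop haemolysed samples (ΔCq >= ``threshold``; the pass criterion is
    the strict ``ΔCq < threshold``) and samples whose markers are undetected."""
    scores = hemolysis_score(table)
    excluded: dict[str, str] = {}
    retained: list[str] = []
    for s in table.samples:
        v = scores.loc[s]
        if math.isnan(v):
            excluded[s] = "qc_marker_missing"
        elif v < threshold:
            retained.append(s)
        else:
            excluded[s] = "hemolysis"
    if not retained:
        raise QcError("haemolysis gate excluded every sample")
    report = QcReport(
        hemolysis_scores=scores,
        retained_samples=retained,
        excluded_samples=excluded,
        retained_assays=table.assays,
    )
    return table.subset(samples=retained), report


def filter_assays(
    table: PanelCqTable, min_call_rate: float = 0.8
) -> tuple[PanelCqTable, QcReport]:
    """Drop assays detected in less than ``min_call_rate`` of the samples.

    The boundary is inclusive: an assay detected in exactly 80% of samples
    is retained at the default threshold.
    """
    if table.n_samples == 0:
        raise QcError("cannot compute call rates on an empty table")
    rates = table.detected.mean(axis=0)
    rates.name = "call_rate"
    keep = [a for a in table.assays if rates.loc[a] >= min_call_rate]
    drop = [a for a in table.assays if a not in set(keep)]
    report = QcReport(
        assay_call_rates=rates,
        retained_samples=table.samples,
        retained_assays=keep,
        excluded_assays=drop,
    )
    return table.subset(assays=keep), report


def run_qc(
    table: PanelCqTable,
    hemolysis_threshold: float = 7.5,
    min_call_rate: float = 0.8,
) -> tuple[PanelCqTable, QcReport]:
    """Sample gate then assay gate (call rates computed over retained samples)."""
    t1, rep1 = filter_samples(table, threshold=hemolysis_threshold)
    t2, rep2 = filter_assays(t1, min_call_rate=min_call_rate)
    return t2, rep1.merge(rep2)


def apply_blocklist(
    features: Iterable[str],
    blocklist: Mapping[str, str],
    mode: str = "stringent",
) -> list[str]:
    """Remove features touching haemolysis-associated miRNAs.

    ``features`` may be plain assay ids or ratio names ``"a/b"``.  In
    ``stringent`` mode any blocklisted member disqualifies the feature; in
    ``semi_stringent`` mode only members with tier ``"strong"`` do.
    """
    if mode not in BLOCKLIST_MODES:
        raise ValueError(f"unknown blocklist mode {mode!r}; expected one of {BLOCKLIST_MODES}")
    bad_tiers = set(blocklist.values()) - set(BLOCKLIST_TIERS)
    if bad_tiers:
        raise ValueError(f"unknown blocklist tiers: {sorted(bad_tiers)}")
    if mode == "stringent":
        banned = set(blocklist)
    else:
        banned = {a for a, tier in blocklist.items() if tier == "strong"}
    kept = []
    for feat in features:
        members = feat.split("/") if "/" in feat else [feat]
        if not any(m in banned for m in members):
            kept.append(feat)
    return kept
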