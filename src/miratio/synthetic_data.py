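"""Synthetic qPCR cohort generator.

Emulates the statistical structure of plasma circulating-miRNA qPCR panel
data so that every downstream stage (QC, normalization, differential
testing, signature selection) is testable without external cohorts:

* a per-assay baseline mean Cq,
* planted group effects in dCq units (applied as Cq *decrements*, since
  lower Cq means more template),
* a per-sample global offset (variable plasma input / extraction yield),
* an additive batch shift between the discovery and verification runs,
* haemolysis contamination of a configurable fraction of samples that
  shifts a susceptible subset of assays (miR-451a above all), and
* detection-limit censoring: Cq values beyond the limit of detection are
  stored as missing with ``detected = False``, never as a sentinel value.

The generative model for sample *s*, assay *i* is::

    Cq(s, i) = mu(i) - effect(i, group(s)) + offset(s)
               + batch(dataset(s)) + h(s) * susceptibility(i) + eps(s, i)

with ``eps`` zero-mean Gaussian of SD ``within_sd`` and ``h(s)`` the
haemolysis level, drawn uniform on [5, 10] cycles for contaminated
samples (zero otherwise) so the 7.5-cycle ΔCq gate splits contaminated
samples realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io_qc import DATASETS, GROUPS, HEMOLYSIS_MARKERS, PanelCqTable

#: Cq shift per unit haemolysis level (cycles per cycle of h).  Negative
#: values mean the assay becomes *more* abundant (lower Cq) in haemolysed
#: plasma; miR-451a is the canonical erythrocyte marker.
DEFAULT_SUSCEPTIBILITY: dict[str, float] = {
    "hsa-miR-451a": -1.0,
    "hsa-miR-23a-3p": -0.1,
}

#: baseline Cq for the two QC marker assays; the clean-plasma ΔCq
#: (miR-23a − miR-451a) is therefore ~2 cycles, comfortably below the gate.
_MARKER_BASELINES = {"hsa-miR-23a-3p": 26.0, "hsa-miR-451a": 24.0}


@dataclass
class SimConfig:
    """Parameters of one simulated cohort (one dataset).

    All cycle-valued parameters are in Cq units.  ``effect_map`` maps
    assay id -> {group -> additive dCq shift}; positive effects mean the
    assay is *up-regulated* (lower Cq) in that group.
    """

    n_per_group: Mapping[str, int] = field(default_factory=lambda: {"SCC": 14, "AD": 6, "HD": 10})
    n_assays: int = 40
    baseline_mu: Mapping[str, float] | None = None
    effect_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    sample_offset_sd: float = 1.0
    within_sd: float = 0.8
    batch_shift: Mapping[str, float] = field(
        default_factory=lambda: {"discovery": 0.0, "verification": 0.0}
    )
    hemolysis_fraction: float = 0.0
    hemolysis_susceptibility: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUSCEPTIBILITY)
    )
    lod: float = 37.0
    dataset: str = "discovery"
    seed: int = 0
    #: baselines are assay-panel properties: two cohorts run on the same
    #: panel share them, so they get their own seed, independent of the
    #: cohort seed that drives sampling noise.
    baseline_seed: int = 12345

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_assays < 2:
            raise ValueError("n_assays must be at least 2")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if n <= 0:
                raise ValueError(f"group {g!r} has non-positive size {n}")
        if self.dataset not in DATASETS:
            raise ValueError(f"unknown dataset label {self.dataset!r}")
        if self.sample_offset_sd < 0 or self.within_sd < 0:
            raise ValueError("SD parameters must be non-negative")
        if not 0.0 <= self.hemolysis_fraction <= 1.0:
            raise ValueError("hemolysis_fraction must lie in [0, 1]")
        if not np.isfinite(self.lod):
            raise ValueError("lod must be finite")
        assays = set(self.assay_names())
        bad = set(self.effect_map) - assays
        if bad:
            raise ValueError(f"effect_map keys are not assays: {sorted(bad)}")
        for assay, shifts in self.effect_map.items():
            bad_g = set(shifts) - set(GROUPS)
            if bad_g:
                raise ValueError(f"effect_map[{assay!r}] has unknown groups {sorted(bad_g)}")

    def assay_names(self) -> list[str]:
        """QC markers first, then generic ``hsa-miR-<k>`` assays."""
        generic = [f"hsa-miR-{k}" for k in range(1, self.n_assays - 1)]
        return list(HEMOLYSIS_MARKERS) + generic

    # -- config file round-trip ----------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _baselines(config: SimConfig) -> np.ndarray:
    assays = config.assay_names()
    if config.baseline_mu is not None:
        missing = [a for a in assays if a not in config.baseline_mu]
        if missing:
            raise ValueError(f"baseline_mu missing assays: {missing[:3]}...")
        return np.array([float(config.baseline_mu[a]) for a in assays])
    rng = np.random.default_rng(config.baseline_seed)
    mu = rng.uniform(22.0, 33.0, size=len(assays))
    for a, v in _MARKER_BASELINES.items():
        mu[assays.index(a)] = v
    return mu


def generate_cohort(config: SimConfig) -> PanelCqTable:
    """Simulate one cohort; bit-identical for identical config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    assays = config.assay_names()
    n_assays = len(assays)

    sample_ids: list[str] = []
    groups: list[str] = []
    for g in GROUPS:  # fixed group order for determinism
        if g not in config.n_per_group:
            continue
        n = config.n_per_group[g]
        tag = config.dataset[:4]
        sample_ids.extend(f"{tag}-{g}-{i + 1:02d}" for i in range(n))
        groups.extend([g] * n)
    n_samples = len(sample_ids)

    mu = _baselines(config)

    effect = np.zeros((n_samples, n_assays))
    for assay, shifts in config.effect_map.items():
        j = assays.index(assay)
        for si, g in enumerate(groups):
            effect[si, j] = shifts.get(g, 0.0)

    offset = rng.normal(0.0, config.sample_offset_sd, size=n_samples)
    batch = float(config.batch_shift.get(config.dataset, 0.0))

    contaminated = rng.random(n_samples) < config.hemolysis_fraction
    h = np.where(contaminated, rng.uniform(5.0, 10.0, size=n_samples), 0.0)
    susc = np.array([config.hemolysis_susceptibility.get(a, 0.0) for a in assays])

    noise = rng.normal(0.0, config.within_sd, size=(n_samples, n_assays))

    cq = (
        mu[None, :]
        - effect
        + offset[:, None]
        + batch
        + h[:, None] * susc[None, :]
        + noise
    )
    detected = cq <= config.lod
    cq = np.where(detected, cq, np.nan)

    meta = pd.DataFrame(
        {
            "group": groups,
            "dataset": config.dataset,
            "hemolysis": h,
            "offset": offset,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return PanelCqTable(
        cq=pd.DataFrame(cq, index=meta.index, columns=assays),
        detected=pd.DataFrame(detected, index=meta.index, columns=assays),
        meta=meta,
    )


def generate_matched_tissue(
    n_pairs: int,
    effect_map: Mapping[str, float],
    seed: int,
    level: str = "mature",
    n_null_features: int = 0,
    pair_sd: float = 0.5,
    between_sd: float = 1.0,
) -> pd.DataFrame:
    """Simulate matched tumour/normal expression (RPM-like, log-normal).

    Each feature gets a patient-level baseline on the log2 scale; the
    planted log2 effect from ``effect_map`` is added to the tumour side
    only.  Returns the long-format table used by the tissue-concordance
    stage (columns feature_id, level, patient_id, tumour_rpm, normal_rpm).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    features = list(effect_map) + [f"sim-null-{k + 1}" for k in range(n_null_features)]
    rows = []
    for f in features:
        eff = float(effect_map.get(f, 0.0))
        base = rng.uniform(3.0, 10.0)
        patient_base = base + rng.normal(0.0, between_sd, size=n_pairs)
        normal_l2 = patient_base + rng.normal(0.0, pair_sd, size=n_pairs)
        tumour_l2 = patient_base + eff + rng.normal(0.0, pair_sd, size=n_pairs)
        for p in range(n_pairs):
            rows.append(
                {
                    "feature_id": f,
                    "level": level,
                    "patient_id": f"P{p + 1:03d}",
                    "tumour_rpm": float(2.0 ** tumour_l2[p]),
                    "normal_rpm": float(2.0 ** normal_l2[p]),
                }
            )
    return pd.DataFrame(rows)


def generate_ratio_features(
    n_cancer: int = 50,
    n_control: int = 30,
    n_features: int = 50,
    n_planted: int = 5,
    effect: float = 2.0,
    within_sd: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Cohort of miRNA *ratio* features with planted cancer effects.

    Built through the real pipeline: a cohort with ``2 * n_features``
    assays is simulated (cancer group SCC, control HD), the exhaustive
    ratio matrix is computed, and the ``n_features`` disjoint-pair ratios
    (assay 2k vs 2k+1) are kept.  The first ``n_planted`` of them carry a
    planted ``effect``-cycle group difference via a dCq effect on one
    member assay.  Returns ``(X, y, planted)`` with ``y = 1`` for cancer.
    """
    from .normalization import ratio_matrix  # local import avoids a cycle

    n_assays = 2 * n_features
    names = SimConfig(n_assays=n_assays).assay_names()
    eff_map = {names[2 * k]: {"SCC": effect} for k in range(n_planted)}
    cfg = SimConfig(
        n_per_group={"SCC": n_cancer, "HD": n_control},
        n_assays=n_assays,
        effect_map=eff_map,
        sample_offset_sd=1.0,
        within_sd=within_sd,
        hemolysis_fraction=0.0,
        lod=60.0,
        seed=seed,
    )
    table = generate_cohort(cfg)
    rm = ratio_matrix(table)
    wanted = []
    for k in range(n_features):
        a, b = sorted((names[2 * k], names[2 * k + 1]))
        wanted.append(f"{a}/{b}")
    X = rm.values[wanted]
    planted = []
    for k in range(n_planted):
        a, b = sorted((names[2 * k], names[2 * k + 1]))
        planted.append(f"{a}/{b}")
    y = (table.meta["group"].isin({"SCC", "AD"})).to_numpy().astype(int)
    return X, y, planted
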