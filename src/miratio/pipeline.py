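"""End-to-end orchestration: simulate -> qc -> normalize -> diff -> select.

``run_pipeline`` chains the stages on a pair of simulated cohorts
(discovery + verification), writes every intermediate table as delimited
text, and records a run manifest (config snapshot, seeds, gate counts and
SHA-256 digests of every output file) so a run is fully auditable.
All thresholds default to the conventional panel-analysis values:
haemolysis ΔCq < 7.5, call rate >= 0.8, alpha 0.05 with BH correction,
magnitude >= 1 cycle, AUC pre-filter > 0.7, 2000 bootstrap iterations.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .diff_expression import (
    consistency_filter,
    differential_table,
    magnitude_filter,
    node_degree,
    pooling_gate,
    volcano_coordinates,
)
from .io_qc import CANCER_GROUPS, PanelCqTable, run_qc, write_cq_table
from .normalization import global_mean_dcq, ratio_matrix, write_dcq
from .signature_selection import (
    auc_prefilter,
    bootstrap_lasso,
    final_model_and_roc,
    variable_importance,
)
from .synthetic_data import SimConfig, generate_cohort


class PipelineError(RuntimeError):
    """A stage failed or emptied the data; carries the stage name."""

    def __init__(self, stage: str, reason: str):
        self.stage = stage
        self.reason = reason
        super().__init__(f"[{stage}] {reason}")


def default_config() -> dict[str, Any]:
    """Study-scale default configuration with planted cancer effects.

    The planted effects (1-2.5 dCq cycles on six assays, consistent
    across both datasets) are sized like the differences the pipeline is
    designed to detect; haemolysis touches 10% of samples.
    """
    effects = {
        "hsa-miR-1": {"SCC": 2.4, "AD": 2.4},
        "hsa-miR-2": {"SCC": 2.0, "AD": 2.0},
        "hsa-miR-3": {"SCC": 1.6, "AD": 1.6},
        "hsa-miR-4": {"SCC": -1.5, "AD": -1.5},
        "hsa-miR-5": {"SCC": 1.2, "AD": 1.2},
        "hsa-miR-6": {"SCC": -1.0, "AD": -1.0},
    }
    return {
        "simulate": {
            "discovery": {
                "n_per_group": {"SCC": 14, "AD": 6, "HD": 10},
                "n_assays": 40,
                "effect_map": effects,
                "sample_offset_sd": 1.0,
                "within_sd": 0.8,
                "hemolysis_fraction": 0.1,
                "dataset": "discovery",
            },
            "verification": {
                "n_per_group": {"SCC": 28, "AD": 2, "HD": 20, "EB": 10},
                "n_assays": 40,
                "effect_map": effects,
                "sample_offset_sd": 1.0,
                "within_sd": 0.8,
                "hemolysis_fraction": 0.1,
                "batch_shift": {"discovery": 0.0, "verification": 0.3},
                "dataset": "verification",
            },
        },
        "qc": {"hemolysis_threshold": 7.5, "min_call_rate": 0.8},
        "diff": {"alpha": 0.05, "test": "welch", "min_abs_dcq": 1.0},
        "select": {
            "min_auc": 0.7,
            "n_iter": 2000,
            "test_fraction": 1.0 / 3.0,
            "n_folds": 5,
            "n_lambda": 100,
            "top_k": 10,
        },
    }


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict[str, Any]
    seed: int
    version: str = __version__
    timestamp: str = ""
    stages: list[dict[str, Any]] = field(default_factory=list)

    def add_stage(self, name: str, counts: dict[str, Any], outputs: dict[str, str]) -> None:
        self.stages.append({"name": name, "counts": counts, "outputs": outputs})

    def counts(self, stage: str) -> dict[str, Any]:
        for st in self.stages:
            if st["name"] == stage:
                return st["counts"]
        raise KeyError(stage)

    def write(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "config": self.config,
            "stages": self.stages,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def _register(outdir: Path, *names: str) -> dict[str, str]:
    return {n: _sha256(outdir / n) for n in names}


def run_pipeline(
    config: dict[str, Any],
    outdir: str | Path,
    seed: int = 0,
) -> RunManifest:
    """Execute the full pipeline on simulated cohorts; see module docstring."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = copy.deepcopy(config)
    manifest = RunManifest(
        config=config, seed=int(seed), timestamp=time.strftime("%Y-%m-%dT%H:%M:%S")
    )

    # --- stage 1: simulate -------------------------------------------------
    tables: dict[str, PanelCqTable] = {}
    for i, ds in enumerate(("discovery", "verification")):
        sim_cfg = dict(config["simulate"][ds])
        sim_cfg["dataset"] = ds
        sim_cfg["seed"] = int(seed) + i
        cfg = SimConfig(**sim_cfg)
        tables[ds] = generate_cohort(cfg)
        write_cq_table(tables[ds], outdir / f"{ds}_cq.tsv", outdir / f"{ds}_meta.tsv")
    manifest.add_stage(
        "simulate",
        {ds: {"samples": t.n_samples, "assays": t.n_assays} for ds, t in tables.items()},
        _register(outdir, *(f"{ds}_{k}.tsv" for ds in tables for k in ("cq", "meta"))),
    )

    # --- stage 2: qc -------------------------------------------------------
    qc_cfg = config["qc"]
    clean: dict[str, PanelCqTable] = {}
    counts: dict[str, Any] = {}
    for ds, t in tables.items():
        try:
            clean[ds], report = run_qc(
                t,
                hemolysis_threshold=qc_cfg["hemolysis_threshold"],
                min_call_rate=qc_cfg["min_call_rate"],
            )
        except Exception as exc:
            raise PipelineError("qc", str(exc)) from exc
        report.write(outdir / f"{ds}_qc_report.tsv")
        counts[ds] = {
            "samples_retained": clean[ds].n_samples,
            "samples_excluded": len(report.excluded_samples),
            "assays_retained": clean[ds].n_assays,
            "assays_excluded": len(report.excluded_assays),
        }
    common = [a for a in clean["discovery"].assays if a in set(clean["verification"].assays)]
    if len(common) < 2:
        raise PipelineError("qc", "fewer than 2 assays shared between datasets")
    clean = {ds: t.subset(assays=common) for ds, t in clean.items()}
    counts["assays_common"] = len(common)
    manifest.add_stage(
        "qc", counts, _register(outdir, *(f"{ds}_qc_report.tsv" for ds in clean))
    )

    # --- stage 3: normalize -------------------------------------------------
    ratios = {}
    for ds, t in clean.items():
        try:
            dcq = global_mean_dcq(t)
            rm = ratio_matrix(t)
        except Exception as exc:
            raise PipelineError("normalize", str(exc)) from exc
        write_dcq(dcq, outdir / f"{ds}_dcq.tsv")
        rm.write(outdir / f"{ds}_ratios.tsv")
        ratios[ds] = rm
    manifest.add_stage(
        "normalize",
        {ds: {"ratio_features": r.n_pairs} for ds, r in ratios.items()},
        _register(outdir, *(f"{ds}_{k}.tsv" for ds in ratios for k in ("dcq", "ratios"))),
    )

    # --- stage 4: differential analysis --------------------------------------
    diff_cfg = config["diff"]
    lc = sorted(CANCER_GROUPS)
    diffs = {}
    for ds in ("discovery", "verification"):
        diffs[ds] = differential_table(
            ratios[ds].values,
            clean[ds].groups,
            group1=lc,
            group2="HD",
            test=diff_cfg["test"],
        )
        diffs[ds].to_csv(outdir / f"{ds}_diff_ratios.tsv", sep="\t", float_format="%.6g")
        volcano_coordinates(diffs[ds]).to_csv(
            outdir / f"{ds}_volcano.tsv", sep="\t", float_format="%.6g"
        )
    sig_disc = list(
        diffs["discovery"].index[(diffs["discovery"]["p_adj"] < diff_cfg["alpha"]).fillna(False)]
    )
    big_disc = set(magnitude_filter(diffs["discovery"], diff_cfg["min_abs_dcq"]))
    sig_big = [f for f in sig_disc if f in big_disc]
    degrees = node_degree(sig_disc) if sig_disc else pd.Series(dtype=int, name="degree")
    degrees.rename_axis("mirna").reset_index().to_csv(
        outdir / "node_degrees.tsv", sep="\t", index=False
    )
    try:
        consistent = consistency_filter(
            diffs["discovery"], diffs["verification"], alpha=diff_cfg["alpha"]
        )
    except Exception as exc:
        raise PipelineError("diff", str(exc)) from exc
    consistent.table.to_csv(outdir / "consistency.tsv", sep="\t", float_format="%.6g")
    candidates = [f for f in consistent.features if f in big_disc]
    if not candidates:
        raise PipelineError("diff", "no consistent features survived the filters")
    gate = pooling_gate(
        ratios["discovery"].values[candidates],
        clean["discovery"].groups,
        ratios["verification"].values[candidates],
        clean["verification"].groups,
        alpha=diff_cfg["alpha"],
    )
    gate.table.to_csv(outdir / "pooling_gate.tsv", sep="\t", index=False, float_format="%.6g")
    manifest.add_stage(
        "diff",
        {
            "significant_discovery": len(sig_disc),
            "significant_and_magnitude": len(sig_big),
            "consistent": len(consistent.features),
            "candidates": len(candidates),
            "pooled": bool(gate.pool),
        },
        _register(
            outdir,
            "discovery_diff_ratios.tsv",
            "verification_diff_ratios.tsv",
            "discovery_volcano.tsv",
            "verification_volcano.tsv",
            "node_degrees.tsv",
            "consistency.tsv",
            "pooling_gate.tsv",
        ),
    )
    if not gate.pool:
        raise PipelineError("diff", "pooling gate rejected: datasets differ in distribution")

    # --- stage 5: signature selection ----------------------------------------
    sel_cfg = config["select"]
    pooled_values = pd.concat(
        [ratios["discovery"].values[candidates], ratios["verification"].values[candidates]]
    )
    pooled_groups = pd.concat([clean["discovery"].groups, clean["verification"].groups])
    complete = pooled_values.dropna(axis=0)
    y = pooled_groups.loc[complete.index].isin(CANCER_GROUPS).astype(int).to_numpy()
    keep, auc_table = auc_prefilter(complete, y, min_auc=sel_cfg["min_auc"])
    auc_table.rename_axis("feature").reset_index().to_csv(
        outdir / "feature_auc.tsv", sep="\t", index=False, float_format="%.6g"
    )
    if not keep:
        raise PipelineError("select", "no feature passed the AUC pre-filter")
    X = complete[keep]
    try:
        summary = bootstrap_lasso(
            X,
            y,
            n_iter=sel_cfg["n_iter"],
            test_fraction=sel_cfg["test_fraction"],
            n_folds=sel_cfg["n_folds"],
            n_lambda=sel_cfg["n_lambda"],
            seed=int(seed) + 1000,
        )
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc
    importance = variable_importance(summary, top_k=min(sel_cfg["top_k"], len(keep)))
    importance.rename_axis("feature").reset_index().to_csv(
        outdir / "variable_importance.tsv", sep="\t", index=False, float_format="%.6g"
    )
    model, roc, final_auc = final_model_and_roc(
        X, y, n_folds=sel_cfg["n_folds"], n_lambda=sel_cfg["n_lambda"], seed=int(seed) + 2000
    )
    model.to_json(outdir / "signature_model.json")
    roc.to_csv(outdir / "roc.tsv", sep="\t", index=False, float_format="%.6g")
    lo, hi = summary.auc_ci
    q1, q3 = summary.auc_quartiles
    manifest.add_stage(
        "select",
        {
            "features_prefiltered": len(keep),
            "bootstrap_iterations": summary.n_iter,
            "mean_test_auc": summary.mean_auc,
            "auc_ci": [lo, hi],
            "auc_quartiles": [q1, q3],
            "signature_size": len(model.nonzero_features()),
            "resubstitution_auc": final_auc,
        },
        _register(
            outdir, "feature_auc.tsv", "variable_importance.tsv",
            "signature_model.json", "roc.tsv",
        ),
    )

    manifest.write(outdir / "manifest.json")
    return manifest
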