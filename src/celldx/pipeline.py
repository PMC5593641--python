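"""End-to-end orchestration: simulate/ingest -> transform -> score -> diagnose.

One pipeline run reproduces the study design at configurable scale:

1. generate a synthetic cohort (or ingest a cell-table CSV);
2. natural-log transform the channel intensities;
3. optionally restrict the analysis to selected tissue compartments (the
   epithelial-only model variant vs the all-cells variant);
4. split by patient into development and validation sets;
5. fit the aberrant-vs-normal logistic model on the development patients,
   scan cutoffs, pick (or preset) an operating point, band the AUC;
6. build the Mahalanobis k-NN stager on the development patients and classify
   the validation cells;
7. aggregate per-cell labels into specimen compositions and majority
   diagnoses, and emit every intermediate as CSV/JSON under the output
   directory.

Reruns with the same config and seed are bit-identical. The single global
seed is expanded into per-stage seeds by a fixed counter scheme
(stage_seed(i) = (seed * 1000 + i) mod 2^31), so stages can be rerun in
isolation. Structured log lines record rows in/out per stage as the audit
trail for the conservation invariants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import knn as knn_mod
from . import logistic as logit
from .cohort import CohortConfig, default_cohort_config, generate_cohort
from .io import (
    CellTable,
    DefinitionError,
    filter_compartment,
    log_transform,
    read_cell_table,
    split_development_validation,
    write_cell_table,
)

__all__ = ["PipelineConfig", "EvaluationReport", "run_pipeline", "compare_models", "stage_seed"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "logistic", "knn")


def stage_seed(base_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed: (base * 1000 + index) mod 2^31."""
    return (int(base_seed) * 1000 + stage_index) % (2**31)


@dataclass
class PipelineConfig:
    """Everything one run needs; hashable to a provenance digest."""

    cohort: CohortConfig | None = None
    input_path: str | None = None
    markers: tuple[str, ...] | None = None
    compartments: tuple[str, ...] | None = None  # logistic-stage filter
    dev_patients: tuple[str, ...] = ()
    val_patients: tuple[str, ...] = ()
    log_floor: float = 1.0
    cutoff: float | str = "youden"  # numeric preset or scan rule
    knn_label_scheme: str = "path_category"
    knn_k: int = 5
    knn_subsample: int = 30_000
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_path is None):
            raise DefinitionError("exactly one of cohort / input_path must be set")
        if not self.dev_patients:
            raise DefinitionError("dev_patients must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            if isinstance(cohort, dict) and set(cohort) <= {
                "panel", "n_patients", "phases", "cells_per_specimen", "seed", "effect_scale",
            }:
                cohort = default_cohort_config(**cohort)
            else:
                raise DefinitionError("cohort config must use the default_cohort_config keys")
        for key in ("markers", "compartments", "dev_patients", "val_patients"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = dataclasses.asdict(self.cohort)
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class EvaluationReport:
    """Every stage output of one pipeline run, plus provenance."""

    config_hash: str
    seeds: dict[str, int]
    n_dev: int
    n_val: int
    coefficient_report: pd.DataFrame
    cutoff_scan: pd.DataFrame
    cutoff: float
    dev_auc: float
    dev_band: str
    val_auc: float | None
    val_band: str | None
    val_sensitivity: float | None
    val_specificity: float | None
    val_percent_correct: float | None
    roc_points: pd.DataFrame
    logistic_compositions: list[agg.TissueComposition]
    logistic_composition_table: pd.DataFrame
    knn_confusion: knn_mod.ConfusionReport | None
    knn_compositions: list[agg.TissueComposition]
    knn_composition_table: pd.DataFrame
    majority_table: pd.DataFrame

    def digest(self) -> str:
        """Hash of the run's numeric artifacts (determinism check)."""
        h = hashlib.sha256()
        h.update(self.config_hash.encode())
        for df in (
            self.coefficient_report,
            self.cutoff_scan,
            self.roc_points,
            self.logistic_composition_table,
            self.knn_composition_table,
            self.majority_table,
        ):
            h.update(df.round(12).to_csv().encode())
        for v in (self.cutoff, self.dev_auc, self.val_auc):
            h.update(repr(v).encode())
        return h.hexdigest()


def _specimen_ids(table: CellTable) -> np.ndarray:
    d = table.data
    return (d["patient_id"] + ":" + d["phase"]).to_numpy(dtype=object)


def _subset(table: CellTable, mask: np.ndarray) -> CellTable:
    return CellTable(
        table.data[mask].reset_index(drop=True), table.marker_names, dict(table.provenance)
    )


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Execute the full analysis; see the module docstring for the stages."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = {name: stage_seed(config.seed, i) for i, name in enumerate(_STAGES)}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # stage 1: simulate or ingest
    if config.cohort is not None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["simulate"])
        raw = generate_cohort(cohort_cfg)
    else:
        raw = read_cell_table(config.input_path, markers=config.markers)
    logger.info("stage=ingest seed=%s rows_out=%d", seeds["simulate"], raw.n_cells)
    if outdir:
        write_cell_table(raw, outdir / "cohort.csv")

    # stage 2: log transform
    table = log_transform(raw, floor=config.log_floor)
    markers = config.markers or table.marker_names

    # stage 3: optional compartment restriction (e.g. the epithelial-only
    # model variant), applied to development and validation alike
    if config.compartments:
        table = filter_compartment(table, config.compartments)
        logger.info("stage=filter compartments=%s rows_out=%d",
                    config.compartments, table.n_cells)

    # stage 4: development / validation split
    dev, val = split_development_validation(table, config.dev_patients, config.val_patients)
    logger.info("stage=split rows_in=%d dev=%d val=%d", table.n_cells, dev.n_cells, val.n_cells)
    have_val = val.n_cells > 0
    eval_table = val if have_val else dev

    # stage 5: logistic model
    logger.info("stage=logistic seed=%s rows_in=%d", seeds["logistic"], dev.n_cells)
    fit = logit.fit_logistic(dev, markers=markers)
    coef = logit.coefficient_report(fit)
    dev_truth = logit.aberrant_by_pathology(dev)
    dev_probs = logit.predict_prob(fit, dev)
    scan = logit.cutoff_scan(dev_probs, dev_truth)
    cutoff = (
        float(config.cutoff)
        if isinstance(config.cutoff, (int, float))
        else logit.select_cutoff(scan, rule=str(config.cutoff))
    )
    dev_roc = logit.roc_auc(dev_probs, dev_truth)

    eval_probs = logit.predict_prob(fit, eval_table, cutoff=cutoff)
    eval_truth = logit.aberrant_by_pathology(eval_table)
    both_classes = 0 < eval_truth.sum() < len(eval_truth)
    if both_classes:
        eval_roc = logit.roc_auc(eval_probs, eval_truth)
        pred = eval_probs.prob >= cutoff
        tp = int((pred & eval_truth).sum())
        tn = int((~pred & ~eval_truth).sum())
        val_sens = tp / int(eval_truth.sum())
        val_spec = tn / int((~eval_truth).sum())
        val_pct = (tp + tn) / len(eval_truth)
        val_auc: float | None = eval_roc.auc
        val_band: str | None = logit.discrimination_band(eval_roc.auc)
        roc_points = eval_roc.frame()
    else:
        val_auc = val_band = None
        val_sens = val_spec = val_pct = None
        roc_points = dev_roc.frame()

    cell_calls = eval_probs.labels(cutoff)
    logistic_comps = agg.compositions_by_specimen(
        cell_calls, _specimen_ids(eval_table), severity=("normal", "aberrant")
    )
    logistic_comp_table = agg.composition_table(logistic_comps, ["normal", "aberrant"])

    # stage 6: k-NN staging/grading
    knn_confusion = None
    knn_comps: list[agg.TissueComposition] = []
    class_order = (
        list(agg.SEVERITY_PATHOLOGY)
        if config.knn_label_scheme == "path_category"
        else list(agg.SEVERITY_GLEASON)
    )
    try:
        model = knn_mod.build_knn(
            dev,
            label_scheme=config.knn_label_scheme,
            k=config.knn_k,
            subsample_size=config.knn_subsample,
            seed=seeds["knn"],
            markers=markers,
        )
        knn_result = knn_mod.classify_cells(model, eval_table)
        knn_truth = eval_table.data[config.knn_label_scheme].to_numpy()
        present = sorted(set(knn_truth) | set(model.labels))
        order = [c for c in class_order + ["unknown"] if c in present]
        knn_confusion = knn_mod.knn_accuracy_heatmap(knn_result, knn_truth, class_order=order)
        knn_comps = agg.compositions_by_specimen(
            knn_result.assigned, _specimen_ids(eval_table), severity=order
        )
        knn_comp_table = agg.composition_table(knn_comps, order)
        logger.info(
            "stage=knn seed=%s refs=%d queries=%d abstain=%.4f",
            seeds["knn"], model.n_ref, eval_table.n_cells, knn_result.abstain_rate,
        )
    except (DefinitionError, knn_mod.ConfigurationError) as exc:
        raise RuntimeError(f"stage=knn failed: {exc}") from exc

    # stage 7: majority diagnoses vs truth
    majority_rows = []
    truth_by_spec = (
        eval_table.data.assign(spec=_specimen_ids(eval_table))
        .groupby("spec")[config.knn_label_scheme]
        .agg(lambda s: s.mode().iloc[0])
    )
    for comp in knn_comps:
        majority_rows.append(
            {
                "specimen": comp.specimen_id,
                "majority_label": comp.majority_label,
                "majority_probability": comp.majority_fraction,
                "tie": comp.tie,
                "n_cells": comp.n_cells,
                "n_abstained": comp.n_abstained,
                "truth_majority": truth_by_spec.get(comp.specimen_id),
            }
        )
    majority_table = pd.DataFrame(majority_rows)

    report = EvaluationReport(
        config_hash=config.config_hash(),
        seeds=seeds,
        n_dev=dev.n_cells,
        n_val=val.n_cells,
        coefficient_report=coef,
        cutoff_scan=scan,
        cutoff=cutoff,
        dev_auc=dev_roc.auc,
        dev_band=logit.discrimination_band(dev_roc.auc),
        val_auc=val_auc,
        val_band=val_band,
        val_sensitivity=val_sens,
        val_specificity=val_spec,
        val_percent_correct=val_pct,
        roc_points=roc_points,
        logistic_compositions=logistic_comps,
        logistic_composition_table=logistic_comp_table,
        knn_confusion=knn_confusion,
        knn_compositions=knn_comps,
        knn_composition_table=knn_comp_table,
        majority_table=majority_table,
    )

    if outdir:
        coef.to_csv(outdir / "coefficients.csv")
        scan.to_csv(outdir / "cutoff_scan.csv", index=False)
        roc_points.to_csv(outdir / "roc_points.csv", index=False)
        logistic_comp_table.to_csv(outdir / "logistic_compositions.csv")
        knn_comp_table.to_csv(outdir / "knn_compositions.csv")
        majority_table.to_csv(outdir / "majority_diagnoses.csv", index=False)
        if knn_confusion is not None:
            knn_confusion.counts.to_csv(outdir / "knn_confusion_counts.csv")
            knn_confusion.row_normalized.to_csv(outdir / "knn_confusion_rownorm.csv")
        fit.to_json(outdir / "logistic_model.json", cutoff=cutoff)
        summary = {
            "config_hash": report.config_hash,
            "seeds": seeds,
            "n_dev": report.n_dev,
            "n_val": report.n_val,
            "cutoff": report.cutoff,
            "dev_auc": report.dev_auc,
            "dev_band": report.dev_band,
            "val_auc": report.val_auc,
            "val_band": report.val_band,
            "val_sensitivity": report.val_sensitivity,
            "val_specificity": report.val_specificity,
            "val_percent_correct": report.val_percent_correct,
            "knn_accuracy": knn_confusion.accuracy if knn_confusion else None,
            "knn_abstain_rate": knn_confusion.abstain_rate if knn_confusion else None,
            "report_digest": report.digest(),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return report


def compare_models(
    report_a: EvaluationReport,
    report_b: EvaluationReport,
    names: Sequence[str] = ("epithelial_only", "all_cells"),
) -> pd.DataFrame:
    """Side-by-side sensitivity/specificity/AUC/accuracy of two runs.

    Both runs must come from the same cohort (same simulate-stage seed and
    cohort sizes); only the compartment filter is expected to differ.
    """
    if report_a.seeds.get("simulate") != report_b.seeds.get("simulate"):
        raise DefinitionError("reports come from different cohorts")
    rows = {}
    for name, rep in zip(names, (report_a, report_b)):
        rows[name] = {
            "cutoff": rep.cutoff,
            "sensitivity": rep.val_sensitivity,
            "specificity": rep.val_specificity,
            "percent_correct": rep.val_percent_correct,
            "dev_auc": rep.dev_auc,
            "val_auc": rep.val_auc,
            "knn_accuracy": rep.knn_confusion.accuracy if rep.knn_confusion else None,
            "knn_abstain_rate": rep.knn_confusion.abstain_rate if rep.knn_confusion else None,
        }
    return pd.DataFrame(rows).T
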