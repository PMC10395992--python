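"""One-command orchestration of the full dual-task analysis.

Stages: generate (or load) the cohort -> weighted dual-task costs ->
five pooled indices -> descriptive group statistics -> LOOCV logistic
battery. Every run writes its artifacts plus a manifest carrying the
configuration hash, package version, per-stage timings, and record
counts (subjects dropped, cells flagged), so the data-handling choices
of a run are auditable afterwards.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classification import MetricsReport, ModelSpec, battery_specs, compute_metrics, design_matrix, loocv, run_model_battery
from .data_io import config_hash, read_feature_table, read_subject_records, write_feature_table, write_report, write_subject_records
from .dtc import RescaleBounds, compute_dtc_star
from .group_stats import summarize_cohort
from .pooled_index import (
    PI_NAMES,
    SelectionConfig,
    assemble_candidates,
    candidate_signs,
    fit_normalization,
    score_pi,
    select_components,
)
from .synthetic import CohortSpec, cohort_to_tables, generate_cohort

_KNOWN_KEYS = {
    "source",
    "features_path",
    "subjects_path",
    "cohort",
    "bounds",
    "selection",
    "alpha",
    "out_dir",
    "seed",
    "fold_safe",
}


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one analysis run."""

    source: str = "synthetic"  # or "files"
    features_path: str | None = None
    subjects_path: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    bounds: RescaleBounds = field(default_factory=RescaleBounds)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    alpha: float = 0.05
    out_dir: str = "mcdt_run"
    seed: int | None = None
    fold_safe: bool = False

    def __post_init__(self) -> None:
        if self.source not in ("synthetic", "files"):
            raise ValueError(f"source must be 'synthetic' or 'files', got {self.source!r}")
        if self.source == "files" and not (self.features_path and self.subjects_path):
            raise ValueError("source='files' requires features_path and subjects_path")
        if self.seed is not None:
            self.cohort.seed = int(self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "n_per_class" in c:
                c["n_per_class"] = {k: int(v) for k, v in c["n_per_class"].items()}
            d["cohort"] = CohortSpec(**c)
        if "bounds" in d and isinstance(d["bounds"], dict):
            d["bounds"] = RescaleBounds(**d["bounds"])
        if "selection" in d and isinstance(d["selection"], dict):
            s = dict(d["selection"])
            if "tie_break_manual" in s:
                s["tie_break_manual"] = tuple(s["tie_break_manual"])
            d["selection"] = SelectionConfig(**s)
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def fold_safe_battery(dtc, labels, subjects, selection, orientation, specs) -> MetricsReport:
    """Battery with PI selection + normalization refitted inside each fold.

    The held-out subject contributes neither to the elimination
    procedure nor to the normalization statistics of the fold that
    predicts it. (The per-condition rescaling of response counts inside
    DTC* remains cohort-wide; see the methods note.)
    """
    import numpy as np

    report = MetricsReport()
    sub = pd.DataFrame([dataclasses.asdict(s) for s in subjects]).set_index("subject_id")
    for spec in specs:
        cand = assemble_candidates(dtc, PI_NAMES[spec.pi_name], selection)
        signs = candidate_signs(cand.columns, orientation) if orientation else None
        keep = [
            s
            for s in cand.index
            if sub.loc[s, "diagnosis"] in spec.classes and not cand.loc[s].isna().any()
        ]
        cand_k = cand.loc[keep]
        lab_k = labels.loc[keep]
        covars = []
        if "AGE" in spec.regressors:
            covars.append(sub.loc[keep, "age"].to_numpy(dtype=float))
        if "FAB" in spec.regressors:
            covars.append(sub.loc[keep, "fab"].to_numpy(dtype=float))

        def refit(mask, cand_k=cand_k, lab_k=lab_k, covars=covars, signs=signs):
            train = cand_k.iloc[mask.nonzero()[0]] if hasattr(mask, "nonzero") else cand_k[mask]
            model = select_components(train, lab_k[mask], selection, name=spec.pi_name, signs=signs)
            fit_normalization(model, train)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pi = score_pi(model, cand_k).scores.iloc[:, 0].to_numpy(dtype=float)
            return np.column_stack([pi, *covars])

        X0 = refit(np.ones(len(keep), dtype=bool))
        y = lab_k.to_numpy()
        confusion, flagged = loocv(X0, y, spec, refit=refit)
        metrics = compute_metrics(confusion, spec.problem)
        report.entries.append(
            {
                "pi_name": spec.pi_name,
                "regressors": "+".join(spec.regressors),
                "label": spec.label(),
                "problem": spec.problem,
                "n": len(y),
                "flagged_folds": flagged,
                "confusion": confusion.values.tolist(),
                "confusion_labels": list(confusion.index),
                "metrics": metrics,
            }
        )
    return report


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the run directory."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())
    prov = {"config_hash": chash, "seed": config.cohort.seed}
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": chash,
        "version": __version__,
        "stages": {},
    }

    def stage(name):
        class _T:
            def __enter__(self):
                manifest["stages"].setdefault(name, {})
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest["stages"].setdefault(name, {})["seconds"] = round(
                    time.perf_counter() - self.t0, 3
                )

        return _T()

    try:
        with stage("input"):
            if config.source == "synthetic":
                cohort = generate_cohort(config.cohort)
                features, subjects = cohort_to_tables(cohort)
            else:
                features = read_feature_table(config.features_path)
                subjects = read_subject_records(config.subjects_path)
            write_feature_table(features, out / "features.csv")
            write_subject_records(subjects, out / "subjects.csv")
            manifest["stages"]["input"]["n_subjects"] = features.n_subjects

        labels = pd.Series({s.subject_id: s.diagnosis for s in subjects})

        with stage("descriptives"):
            desc = summarize_cohort(subjects, alpha=config.alpha)
            write_report(desc, out / "descriptives.csv", provenance=prov)

        with stage("dtc"):
            dtc = compute_dtc_star(features, config.bounds)
            dtc.table.to_csv(out / "dtc.csv", index=False)
            manifest["stages"]["dtc"]["n_flagged_cells"] = len(dtc.flagged)

        with stage("pooled_index"):
            models = {}
            scores_cols = []
            for name, exercises in PI_NAMES.items():
                cand = assemble_candidates(dtc, exercises, config.selection)
                signs = candidate_signs(cand.columns, dtc.effective_orientation)
                model = select_components(cand, labels, config.selection, name=name, signs=signs)
                models[name] = model
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scores_cols.append(score_pi(model, cand).scores)
            scores = pd.concat(scores_cols, axis=1)
            (out / "pi_models").mkdir(exist_ok=True)
            for name, model in models.items():
                (out / "pi_models" / f"{name}.json").write_text(model.to_json())
            scores.rename_axis("subject").reset_index().to_csv(out / "pi_scores.csv", index=False)
            manifest["stages"]["pooled_index"]["components"] = {
                n: m.components for n, m in models.items()
            }

        with stage("battery"):
            specs = battery_specs(list(PI_NAMES))
            if config.fold_safe:
                report = fold_safe_battery(
                    dtc, labels, subjects, config.selection, dtc.effective_orientation, specs
                )
            else:
                report = run_model_battery(scores, subjects, specs)
            write_report(report.to_frame(), out / "battery.csv", provenance=prov)
            write_report(report.per_class_frame(), out / "battery_per_class.csv", provenance=prov)
            (out / "battery_full.json").write_text(json.dumps(report.entries, indent=1))
            manifest["stages"]["battery"]["n_evaluations"] = len(report.entries)
    except Exception as exc:  # annotate which stage died, keep artifacts
        failed = [s for s in ("input", "descriptives", "dtc", "pooled_index", "battery") if s not in manifest["stages"] or "seconds" not in manifest["stages"][s]]
        manifest["error"] = {"stage": failed[0] if failed else "unknown", "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
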