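"""End-to-end study orchestration at desk scale.

``run_all`` drives the full analysis from one config: simulate a synthetic
cohort, split it temporally, fit every (base family x meta family) stacking
combination per outcome, evaluate with program metrics / accuracy / macro
AUROC, rank models by correct predictions then identified users, run the
economic simulation on the top models for inpatient bed days, pick the
dominant model by median benefit, and sweep its reach x benefit sensitivity
grid per predicted tier.  Every stage seed fans out from one master seed; the
manifest written at the end records seeds, library versions, record counts
after each filter, and the path of every artifact, so a run is reproducible
bit-for-bit from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .base_learners import BASE_FAMILIES, BinaryThresholdScorer
from .economics import (
    EconomicScenario,
    eligible_patients,
    fixed_effects_benefit,
    intervention_burden,
    monte_carlo_benefit,
    select_dominant,
)
from .ensemble import META_FAMILIES, build_meta_features, fit_meta, split_train_test, upsample_balance
from .errors import EmptyInputError, StageError
from .metrics import accuracy_with_ci, confusion, multiclass_auroc, per_class_metrics, program_metrics
from .registry import FEATURE_COLUMNS, CohortSpec, generate_cohort, temporal_split, write_cohort
from .sensitivity import GridSpec, run_grid, write_plot_data
from .tiers import assign_class, scheme_by_name
from ._seeds import derive_seed

__all__ = ["RunConfig", "run_all", "rank_models", "evaluate_predictions", "RUN_CONFIG_SCHEMA"]

logger = logging.getLogger(__name__)

_OUTCOME_COLS = {"LOS": ("current_los_days", "next_los_days"), "ED": ("current_ed_visits", "next_ed_visits")}


@dataclass
class RunConfig:
    """One reproducible run: cohort, model sweep, evaluation, economics, grid."""

    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(n_patients=2000, n_years=2, seed=0))
    outcomes: tuple = ("LOS",)
    base_families: tuple = BASE_FAMILIES
    meta_families: tuple = META_FAMILIES
    train_year: int = 0
    validate_year: int = 1
    split_fraction: float = 0.75
    stratify: bool = True
    upsample: bool = True
    refit_base: bool = False
    scenario: EconomicScenario = field(default_factory=EconomicScenario)
    grid: GridSpec = field(default_factory=GridSpec)
    grid_tiers: tuple = (1, 2, 3)
    top_k: int = 5
    master_seed: int = 0
    outdir: str = "tierstack_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["scenario"] = self.scenario.to_dict()
        d["grid"] = self.grid.to_dict()
        for k in ("outcomes", "base_families", "meta_families", "grid_tiers"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortSpec.from_dict(d["cohort"])
        if "scenario" in d:
            sc = dict(d["scenario"])
            if "reach_means" in sc:
                sc["reach_means"] = {int(k): float(v) for k, v in sc["reach_means"].items()}
            d["scenario"] = EconomicScenario(**sc)
        if "grid" in d:
            g = dict(d["grid"])
            for k in ("reach_levels", "benefit_levels"):
                if k in g:
                    g[k] = tuple(g[k])
            d["grid"] = GridSpec(**g)
        for k in ("outcomes", "base_families", "meta_families", "grid_tiers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


#: JSON Schema of the YAML/JSON run configuration.
RUN_CONFIG_SCHEMA = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "tierstack run configuration",
    "type": "object",
    "properties": {
        "cohort": {
            "type": "object",
            "properties": {
                "n_patients": {"type": "integer", "minimum": 1},
                "n_years": {"type": "integer", "minimum": 2},
                "seed": {"type": "integer"},
                "usage_prevalence": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
                "tier_prevalences": {"type": "array", "items": {"type": "number"}, "minItems": 4, "maxItems": 4},
                "missingness_rate": {"type": "number", "minimum": 0, "exclusiveMaximum": 1},
            },
            "required": ["n_patients"],
        },
        "outcomes": {"type": "array", "items": {"enum": ["LOS", "ED"]}},
        "base_families": {"type": "array", "items": {"enum": list(BASE_FAMILIES)}},
        "meta_families": {"type": "array", "items": {"enum": list(META_FAMILIES)}},
        "train_year": {"type": "integer"},
        "validate_year": {"type": "integer"},
        "split_fraction": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
        "stratify": {"type": "boolean"},
        "upsample": {"type": "boolean"},
        "refit_base": {"type": "boolean"},
        "scenario": {"type": "object"},
        "grid": {"type": "object"},
        "grid_tiers": {"type": "array", "items": {"enum": [1, 2, 3]}},
        "top_k": {"type": "integer", "minimum": 1},
        "master_seed": {"type": "integer"},
        "outdir": {"type": "string"},
    },
}


def model_id(outcome: str, meta_family: str, base_family: str) -> str:
    """Canonical model identifier: outcome, meta-learner, base-learner."""
    return f"{outcome.lower()}_{meta_family}__{base_family}"


def evaluate_predictions(actual_tiers, predicted_tiers, tier_scores=None) -> dict:
    """Full metric report for one model on one dataset."""
    cm = confusion(actual_tiers, predicted_tiers)
    pm = program_metrics(cm)
    acc, acc_lo, acc_hi = accuracy_with_ci(cm)
    report = {
        "n": cm.total,
        **pm.rounded(1).to_dict(),
        "accuracy": acc,
        "accuracy_ci": [acc_lo, acc_hi],
        "confusion": cm.counts.tolist(),
        "per_class": per_class_metrics(cm).to_dict(orient="index"),
    }
    if tier_scores is not None:
        auroc, lo, hi = multiclass_auroc(tier_scores, actual_tiers)
        report["auroc"] = auroc
        report["auroc_ci"] = [lo, hi]
    return report


def rank_models(metric_reports: dict) -> list:
    """Order model ids by correct predictions, then identified users, then id.

    ``metric_reports`` maps model id -> report containing ``correct_pct`` and
    ``identified_pct``.  Returns the full ordering (slice for a top-k).
    """
    if not metric_reports:
        raise EmptyInputError("no metric reports to rank")
    return sorted(
        metric_reports,
        key=lambda mid: (-metric_reports[mid]["correct_pct"], -metric_reports[mid]["identified_pct"], mid),
    )


def _tidy_metrics(reports: dict) -> pd.DataFrame:
    """Long-format (model id x metric x value x CI bounds) metrics table."""
    rows = []
    for mid, by_split in reports.items():
        for split, rep in by_split.items():
            for metric in ("correct_pct", "under_pct", "over_pct", "missed_pct", "identified_pct", "unnecessary_pct"):
                rows.append({"model_id": mid, "split": split, "metric": metric, "value": rep[metric]})
            rows.append(
                {
                    "model_id": mid,
                    "split": split,
                    "metric": "accuracy",
                    "value": rep["accuracy"],
                    "ci_low": rep["accuracy_ci"][0],
                    "ci_high": rep["accuracy_ci"][1],
                }
            )
            if "auroc" in rep:
                rows.append(
                    {
                        "model_id": mid,
                        "split": split,
                        "metric": "auroc",
                        "value": rep["auroc"],
                        "ci_low": rep["auroc_ci"][0],
                        "ci_high": rep["auroc_ci"][1],
                    }
                )
    return pd.DataFrame(rows)


def _fit_outcome_models(config: RunConfig, train_records: pd.DataFrame, valid_records: pd.DataFrame, outcome: str, outdir: Path):
    """Fit all (base x meta) combinations for one outcome; return reports and predictions."""
    scheme = scheme_by_name(outcome)
    usage_col, next_col = _OUTCOME_COLS[outcome.upper()]
    base_X_cols = FEATURE_COLUMNS + [usage_col]

    tiers_all = assign_class(train_records[next_col].to_numpy(), scheme)
    rows_tr, rows_te, tiers_tr, tiers_te = split_train_test(
        train_records,
        tiers_all,
        fraction=config.split_fraction,
        seed=derive_seed(config.master_seed, "split", outcome),
        stratify=config.stratify,
    )
    tiers_val = assign_class(valid_records[next_col].to_numpy(), scheme)
    logger.info(
        "[%s] train %d / test %d / validation %d records", outcome, len(rows_tr), len(rows_te), len(tiers_val)
    )

    reports: dict = {}
    predictions: dict = {}
    for base_family in config.base_families:
        scorers = []
        for j in (1, 2, 3):
            scorer = BinaryThresholdScorer(
                family=base_family,
                threshold_index=j,
                outcome=scheme.name,
                seed=derive_seed(config.master_seed, "base", outcome, base_family),
            )
            scorer.fit(rows_tr[base_X_cols], (tiers_tr >= j).astype(int))
            scorers.append(scorer)

        meta_tr = build_meta_features(scorers, rows_tr[base_X_cols], rows_tr[usage_col].to_numpy())
        meta_te = build_meta_features(scorers, rows_te[base_X_cols], rows_te[usage_col].to_numpy())
        if config.refit_base:
            # refit flag: base learners re-estimated on the validation-year
            # records before scoring them (frozen scorers are the default)
            val_scorers = []
            for j, s in enumerate(scorers, start=1):
                rs = BinaryThresholdScorer(
                    family=base_family,
                    threshold_index=j,
                    outcome=scheme.name,
                    seed=derive_seed(config.master_seed, "base-refit", outcome, base_family),
                )
                rs.fit(valid_records[base_X_cols], (tiers_val >= j).astype(int))
                val_scorers.append(rs)
        else:
            val_scorers = scorers
        meta_val = build_meta_features(val_scorers, valid_records[base_X_cols], valid_records[usage_col].to_numpy())

        fit_rows, fit_labels = meta_tr, tiers_tr
        if config.upsample:
            fit_rows, fit_labels = upsample_balance(
                meta_tr, tiers_tr, seed=derive_seed(config.master_seed, "upsample", outcome, base_family)
            )

        for meta_family in config.meta_families:
            mid = model_id(outcome, meta_family, base_family)
            meta = fit_meta(
                meta_family,
                fit_rows,
                fit_labels,
                seed=derive_seed(config.master_seed, "meta", outcome, base_family, meta_family),
                require_balanced=config.upsample,
            )
            reports[mid] = {}
            predictions[mid] = {}
            for split, rows, meta_rows, actual in (
                ("test", rows_te, meta_te, tiers_te),
                ("validation", valid_records, meta_val, tiers_val),
            ):
                pred = meta.predict(meta_rows)
                scores = meta.predict_scores(meta_rows)
                reports[mid][split] = evaluate_predictions(actual, pred, scores)
                out = pd.DataFrame(
                    {
                        "patient_id": rows["patient_id"].to_numpy(),
                        "year_index": rows["year_index"].to_numpy(),
                        "actual_tier": actual,
                        "predicted_tier": pred,
                    }
                )
                for t in range(4):
                    out[f"score_tier{t}"] = scores[:, t]
                path = outdir / f"predictions_{mid}_{split}.csv"
                out.to_csv(path, index=False)
                predictions[mid][split] = {"path": str(path), "predicted": pred}
    return reports, predictions, tiers_val


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tierstack_version": __version__,
        "versions": _library_versions(),
        "master_seed": config.master_seed,
        "config": config.to_dict(),
        "stages": {},
        "files": {},
    }
    stage = "simulate"
    try:
        cohort = generate_cohort(config.cohort)
        cohort_path = outdir / "cohort.csv"
        write_cohort(cohort, cohort_path)
        config.cohort.to_yaml(outdir / "cohort_spec.yaml")
        manifest["files"]["cohort"] = str(cohort_path)
        manifest["stages"]["simulate"] = {"records": len(cohort), "patients": config.cohort.n_patients}

        stage = "temporal_split"
        train_records, valid_records = temporal_split(cohort, config.train_year, config.validate_year)
        manifest["stages"]["temporal_split"] = {"train_records": len(train_records), "validation_records": len(valid_records)}

        all_reports: dict = {}
        rankings: dict = {}
        los_predictions = None
        manifest["files"]["predictions"] = {}
        for outcome in config.outcomes:
            stage = f"models[{outcome}]"
            reports, predictions, tiers_val = _fit_outcome_models(config, train_records, valid_records, outcome, outdir)
            all_reports.update(reports)
            for mid, by_split in predictions.items():
                manifest["files"]["predictions"][mid] = {s: d["path"] for s, d in by_split.items()}
            stage = f"rank[{outcome}]"
            test_reports = {mid: r["test"] for mid, r in reports.items()}
            order = rank_models(test_reports)
            rankings[outcome] = {"order": order, "top": order[: config.top_k]}
            if outcome.upper() == "LOS":
                los_predictions = predictions
            manifest["stages"][f"models[{outcome}]"] = {
                "n_models": len(reports),
                "expected_models": len(config.base_families) * len(config.meta_families),
            }

        stage = "metrics_report"
        (outdir / "metrics.json").write_text(json.dumps(all_reports, indent=1))
        _tidy_metrics(all_reports).to_csv(outdir / "metrics.csv", index=False)
        manifest["files"]["metrics_json"] = str(outdir / "metrics.json")
        manifest["files"]["metrics_csv"] = str(outdir / "metrics.csv")
        manifest["rankings"] = rankings

        if los_predictions is not None:
            stage = "economics"
            top = rankings["LOS"]["top"]
            summaries, econ_report = {}, {}
            for mid in top:
                pred = los_predictions[mid]["validation"]["predicted"]
                eligible = eligible_patients(valid_records, pred, mode=config.scenario.eligibility_mode)
                scenario = config.scenario.replace(seed=derive_seed(config.master_seed, "econ", mid))
                _, summary = monte_carlo_benefit(eligible, scenario)
                summaries[mid] = summary
                econ_report[mid] = {
                    "n_eligible": len(eligible),
                    "intervention_burden": intervention_burden(valid_records, pred),
                    "fixed_effects_benefit_50pct": fixed_effects_benefit(eligible, 0.50),
                    "monte_carlo": summary.to_dict(),
                }
            dominant = select_dominant(summaries)
            econ_report["dominant_model"] = dominant
            (outdir / "economics.json").write_text(json.dumps(econ_report, indent=1))
            manifest["files"]["economics"] = str(outdir / "economics.json")
            manifest["dominant_model"] = dominant
            manifest["stages"]["economics"] = {"models": list(top), "dominant": dominant}

            stage = "sensitivity_grid"
            pred = los_predictions[dominant]["validation"]["predicted"]
            eligible = eligible_patients(valid_records, pred, mode=config.scenario.eligibility_mode)
            grid_files = {}
            for tier in config.grid_tiers:
                grid_spec = GridSpec(
                    reach_levels=config.grid.reach_levels,
                    benefit_levels=config.grid.benefit_levels,
                    runs_per_cell=config.grid.runs_per_cell,
                    target_tier=tier,
                    benefit_sd=config.grid.benefit_sd,
                    per_patient_denominator=config.grid.per_patient_denominator,
                    seed=derive_seed(config.master_seed, "grid", tier),
                )
                table = run_grid(eligible, grid_spec)
                csv_path = outdir / f"grid_tier{tier}.csv"
                table.to_csv(csv_path, index=False)
                write_plot_data(table, json_path=outdir / f"grid_tier{tier}_plot.json")
                grid_files[tier] = str(csv_path)
            manifest["files"]["grids"] = grid_files
            manifest["stages"]["sensitivity_grid"] = {"tiers": list(config.grid_tiers), "cells_per_tier": len(config.grid.reach_levels) * len(config.grid.benefit_levels)}

    except Exception as exc:  # noqa: BLE001 - stage-tagged abort with partial outputs retained
        manifest["FAILED"] = {"stage": stage, "error": repr(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        (outdir / "FAILED").write_text(f"{stage}: {exc!r}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    manifest["files"]["manifest"] = str(outdir / "manifest.json")
    return manifest


def _library_versions() -> dict:
    import sklearn
    import scipy
    import xgboost

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }
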