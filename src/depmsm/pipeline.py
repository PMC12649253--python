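"""End-to-end pipeline: simulate -> score/classify -> preprocess -> design ->
penalized fit -> report.

Every stage logs its inputs, seed and row counts; re-running with the same
config writes byte-identical artifacts.  The YAML config covers the cohort
size, seed, wave schedule, missingness, the penalty-tuning criterion and the
output precision-relevant choices; unset fields fall back to the study-like
defaults.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError
from .adalasso import fit_adaptive_lasso, fit_initial, post_selection_inference, tune_lambda
from .cesd import classify_panel, events_to_frame, sequences_to_frame, tabulate_events
from .cohort import default_cohort_spec, emit_cesd_scores, generate_covariates, simulate_state_paths, write_cohort
from .design import TransitionStructure, build_transition_records, write_stacked
from .prep import PreprocessConfig, chained_impute, mad_outliers, screen_interactions
from .published import MODEL_TERMS
from .report import effect_table, onset_age_summary, write_effect_table

log = logging.getLogger("depmsm")


@dataclass
class PipelineConfig:
    n_subjects: int = 2000
    seed: int = 0
    wave_times: tuple[float, ...] = (0.0, 2.0, 4.0, 7.0)
    missing_item_rate: float = 0.0
    emit_items: bool = True
    criterion: str = "bic"
    n_grid: int = 50
    mad_k: float = 3.0
    onset_age_cutoff: float = 60.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        if "wave_times" in raw:
            raw["wave_times"] = tuple(float(t) for t in raw["wave_times"])
        return cls(**raw)


def _stage(name: str):
    log.info("stage %s", name)


def run_pipeline(config: PipelineConfig, seed: int | None = None, out_dir="results/pipeline") -> dict:
    """Execute the full analysis and write its artifacts under ``out_dir``.

    Returns a dict of the in-memory artifacts (cohort, sequences, design,
    fits, tables).  ``seed`` overrides the config seed when given.
    """
    seed = config.seed if seed is None else int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = default_cohort_spec(
        n_subjects=config.n_subjects,
        seed=seed,
        wave_times=config.wave_times,
        missing_item_rate=config.missing_item_rate,
        emit_items=config.emit_items,
    )

    _stage("simulate")
    covariates = generate_covariates(spec)
    sim = simulate_state_paths(covariates, spec)
    panel = emit_cesd_scores(sim)
    write_cohort(sim, panel, out)
    log.info("simulate: n=%d subjects, %d panel rows, seed=%d", spec.n_subjects, len(panel), seed)

    _stage("states")
    sequences = classify_panel(panel)
    sequences_to_frame(sequences).to_csv(out / "states.csv", index=False, float_format="%.10g")
    events_to_frame(sequences).to_csv(out / "events.csv", index=False, float_format="%.10g")
    event_counts = tabulate_events(sequences)
    log.info("states: %d sequences, events %s", len(sequences), event_counts)

    _stage("prep")
    prep_cfg = PreprocessConfig(mad_k=config.mad_k, seed=seed)
    completed = chained_impute(covariates.set_index("subject_id"), prep_cfg).reset_index()
    mad_flags = {
        col: int(mad_outliers(completed[col].to_numpy(), prep_cfg)[0].sum())
        for col in prep_cfg.normalize_columns
        if col in completed.columns
    }
    ranked = screen_interactions(
        prep_cfg.interaction_candidates, completed, sequences
    )
    log.info("prep: MAD flags %s; screened interaction order %s", mad_flags, ranked)
    from .cohort import model_matrix

    mm = model_matrix(spec, completed)

    _stage("design")
    structure = TransitionStructure()
    design = build_transition_records(sequences, mm.reset_index(), structure)
    write_stacked(design, out / "stacked.csv")
    log.info("design: %d records, n=%d, p=%d", len(design.table), design.n, design.p)

    _stage("fit")
    initial = fit_initial(design)
    penalty = tune_lambda(design, criterion=config.criterion, initial=initial, n_grid=config.n_grid)
    fit = fit_adaptive_lasso(design, penalty, initial)
    inference = post_selection_inference(design, fit.active_set)
    fit_payload = {
        "seed": seed,
        "lambda_by_group": {g: float(v) for g, v in fit.lambda_by_group.items()},
        "kkt_max_violation": float(fit.kkt_max_violation),
        "beta_hat": {g: [float(b) for b in v] for g, v in fit.beta_hat.items()},
        "active_terms": {
            g: [MODEL_TERMS[i] for i in idx] for g, idx in fit.active_set.items()
        },
        "se": {g: [float(s) for s in v] for g, v in inference.se.items()},
        "wald_p": {g: [float(p) for p in v] for g, v in inference.wald_p.items()},
        "tuning_path": {
            g: penalty.tuning_path[g].to_dict(orient="list") for g in penalty.tuning_path
        },
    }
    (out / "fit.json").write_text(json.dumps(fit_payload, indent=1, sort_keys=True))
    log.info("fit: lambda %s, kkt %.2e", fit.lambda_by_group, fit.kkt_max_violation)

    _stage("report")
    table = effect_table(MODEL_TERMS, fit, inference, group_order=design.structure.group_labels)
    write_effect_table(table, out / "effects.csv")
    ages = dict(zip(covariates["subject_id"], covariates["age"]))
    onset_summary, _ = onset_age_summary(sequences, ages, cutoff=config.onset_age_cutoff)
    onset_summary.to_csv(out / "onset_age.csv", index=False, float_format="%.4f")
    log.info("report: %d effect rows", len(table))

    return {
        "spec": spec,
        "covariates": covariates,
        "panel": panel,
        "sequences": sequences,
        "event_counts": event_counts,
        "design": design,
        "initial": initial,
        "penalty": penalty,
        "fit": fit,
        "inference": inference,
        "effects": table,
        "onset_age": onset_summary,
    }
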