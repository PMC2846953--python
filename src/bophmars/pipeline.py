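"""End-to-end orchestration of the modeling workflow for one response:

BLLOQ substitution -> 80/20 analysis/validation split -> drop rows with a
missing response -> stratified median imputation (imputed copy; the
unimputed copy is kept for final refits) -> categorical encoding ->
forest screening (ranking, nested sets, large/medium/small choice, BOE +
smoking-status augmentation) -> spline grid search -> preferred-model
selection -> threshold-basis reparametrization -> complete-case OLS refit
on unimputed data -> validation apply/refit -> group importance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .basis import ThresholdModel, hinge_to_threshold
from .inference import (
    ImportanceRecord,
    RegressionFit,
    fit_summary,
    group_importance,
    refit_ols,
    validate,
)
from .mars import GridResult, grid_search, select_preferred
from .metadata import SMOKING_COLUMN, Cohort
from .preprocess import (
    EncodedTable,
    apply_blloq_rule,
    drop_missing_response,
    encode_categoricals,
    impute_continuous_medians,
    split_analysis_validation,
)
from .screening import (
    PredictorSet,
    augment_predictor_set,
    build_nested_sets,
    choose_set_sizes,
    rank_variables,
)

__all__ = ["ResponseRun", "run_response", "run_all"]


@dataclass
class ResponseRun:
    """All artifacts of one response's modeling run."""

    response: str
    blloq_counts: dict[str, int]
    n_dropped_response: int
    imputation_counts: dict[str, int]
    ranking: list[tuple[str, float]]
    nested_sets: list[PredictorSet]
    sets: dict[str, tuple[str, ...]]
    grid_results: list[GridResult]
    preferred: GridResult
    threshold_model: ThresholdModel
    analysis_fit: RegressionFit
    applied_r2: float
    validation_fit: RegressionFit
    stability: pd.DataFrame
    importance: list[ImportanceRecord]
    summary_row: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "response": self.response,
            "blloq_substitutions": self.blloq_counts,
            "dropped_missing_response": self.n_dropped_response,
            "imputed_cells": self.imputation_counts,
            "chosen_sets": {k: list(v) for k, v in self.sets.items()},
            "preferred": {
                "set": self.preferred.set_name,
                "model_type": self.preferred.config.model_type,
                "max_basis": self.preferred.config.max_basis,
                "entry_penalty": self.preferred.config.entry_penalty,
                "gcv_r2": self.preferred.gcv_r2,
                "n_params": self.preferred.n_params,
                "n_vars": self.preferred.n_vars,
            },
            "analysis": {
                "r2": self.analysis_fit.r2,
                "n_used": self.analysis_fit.n_used,
                "n_dropped": self.analysis_fit.n_dropped,
            },
            "validation": {
                "applied_r2": self.applied_r2,
                "refit_r2": self.validation_fit.r2,
                "n_used": self.validation_fit.n_used,
            },
        }


def run_response(
    cohort: Cohort,
    response: str,
    split_seed: int = 0,
    split_fraction: float = 0.8,
    screen_trees: int = 1000,
    screen_cv_trees: int = 200,
    screen_folds: int = 10,
    max_set_size: int = 30,
    model_types: Sequence[int] = (0, 1, 2),
    max_basis_values: Sequence[int] = (10, 20, 30, 60),
    entry_penalties: Sequence[float] = (0.0, 0.01),
    min_span: int = 3,
    select_tolerance: float = 0.01,
    seed: int = 0,
    exclude: Sequence[str] = (),
) -> ResponseRun:
    """Run the full workflow for one response biomarker."""
    working, blloq_counts = apply_blloq_rule(cohort)
    working = split_analysis_validation(working, split_fraction, split_seed)
    working, n_dropped = drop_missing_response(working, response)

    imputed, imp_counts = impute_continuous_medians(working)
    encoded = encode_categoricals(imputed)
    analysis = encoded.subset("analysis")

    exclude = set(exclude) | set(encoded.response_columns) - {response}
    if (working.data[SMOKING_COLUMN] == 0).all():
        exclude.add("SMKYRS")  # years smoked is undefined for nonsmokers
    screen_table = analysis.data.drop(
        columns=[c for c in encoded.response_columns if c != response]
    )
    ranking = rank_variables(
        screen_table,
        response,
        n_trees=screen_trees,
        seed=seed,
        exclude=[v for v in exclude if v in screen_table.columns],
    )
    max_size = min(max_set_size, len(ranking))
    nested = build_nested_sets(
        ranking,
        screen_table,
        response,
        max_size=max_size,
        folds=screen_folds,
        seed=seed,
        n_trees=screen_cv_trees,
    )
    large, medium, small = choose_set_sizes(nested)

    boe = [b for b in cohort.boe if b in screen_table.columns]
    sets = {
        name: augment_predictor_set(
            ps.variables, boe, SMOKING_COLUMN, available=screen_table.columns
        )
        for name, ps in (("large", large), ("medium", medium), ("small", small))
    }
    results = grid_search(
        analysis.data,
        response,
        sets,
        model_types=model_types,
        max_basis_values=max_basis_values,
        entry_penalties=entry_penalties,
        min_span=min_span,
        seed=seed,
    )
    preferred = select_preferred(results, tolerance=select_tolerance)
    tmodel = hinge_to_threshold(preferred.model, provenance=encoded.provenance)

    analysis_raw = working.partition("analysis")
    validation_raw = working.partition("validation")
    analysis_fit = refit_ols(
        tmodel, analysis_raw, response, meta=working.meta, on_collinear="drop"
    )
    applied_r2, validation_fit, stability = validate(
        tmodel,
        analysis_fit,
        validation_raw,
        response,
        meta=working.meta,
        on_collinear="drop",
    )
    importance = group_importance(
        tmodel, analysis_raw, response, meta=working.meta
    )
    summary_row = {
        "response": response,
        "rf_cv_r2": large.cv_r2,
        "mars_gcv_r2": preferred.gcv_r2,
        "ols_r2_analysis": analysis_fit.r2,
        "ols_r2_validation_applied": applied_r2,
        "ols_r2_validation_refit": validation_fit.r2,
    }
    return ResponseRun(
        response=response,
        blloq_counts=blloq_counts,
        n_dropped_response=n_dropped,
        imputation_counts=imp_counts,
        ranking=ranking,
        nested_sets=nested,
        sets=sets,
        grid_results=results,
        preferred=preferred,
        threshold_model=tmodel,
        analysis_fit=analysis_fit,
        applied_r2=applied_r2,
        validation_fit=validation_fit,
        stability=stability,
        importance=importance,
        summary_row=summary_row,
    )


def run_all(
    cohort: Cohort, responses: Sequence[str] | None = None, **kwargs
) -> tuple[dict[str, ResponseRun], pd.DataFrame]:
    """Run every response and assemble the cross-method fit summary."""
    responses = list(responses) if responses is not None else cohort.responses
    runs = {r: run_response(cohort, r, **kwargs) for r in responses}
    summary = fit_summary([run.summary_row for run in runs.values()])
    return runs, summary
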