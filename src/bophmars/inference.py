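"""Final-model inference: complete-case OLS refit of a threshold-basis
model, application/refit on the validation partition, group-wise marginal
and delta R-squared importance, and the cross-method fit-statistic summary.

Final refits deliberately use *unimputed* data: rows with a missing
response or a missing continuous predictor are dropped and the count
reported.  Missing categorical values are their own level and therefore do
not drop rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import ThresholdModel, ThresholdTerm
from .metadata import VariableMeta

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "ImportanceRecord",
    "CollinearityError",
    "refit_ols",
    "validate",
    "group_importance",
    "fit_summary",
]

SIGNIFICANCE_ALPHA = 0.05


class CollinearityError(ValueError):
    """Raised when the refit design is rank deficient; names the terms."""


@dataclass
class RegressionFit:
    """OLS refit results in the printed coefficient-table layout."""

    params: pd.DataFrame  # Parameters / Value / Std Error / t value / P value
    r2: float
    n_used: int
    n_dropped: int
    fitted_model: ThresholdModel = field(repr=False, default=None)

    def coefficient(self, name: str) -> float:
        row = self.params.loc[self.params["Parameters"] == name]
        if row.empty:
            raise KeyError(f"no term named {name!r}")
        return float(row["Value"].iloc[0])

    def std_error(self, name: str) -> float:
        row = self.params.loc[self.params["Parameters"] == name]
        if row.empty:
            raise KeyError(f"no term named {name!r}")
        return float(row["Std Error"].iloc[0])


@dataclass(frozen=True)
class ImportanceRecord:
    group: str
    marginal_r2: float
    delta_r2: float


def _complete_case_design(
    model: ThresholdModel,
    table: pd.DataFrame,
    response: str,
    meta: Mapping[str, VariableMeta] | None,
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Design matrix restricted to complete cases.

    A row is dropped when the response or any raw model variable is
    missing — categorical included (the explicit missing category applies
    to the screening/spline stage, not the final refits).  A variable that
    enters only through an explicit EQ.MISSING indicator keeps its missing
    rows, since missingness is the quantity being modeled there.
    """
    y = table[response].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    missing_ok = {
        t.basis.variable
        for t in model.terms
        if t.basis.form == "EQ" and t.basis.cutoff == "MISSING"
    }
    for var in model.source_variables():
        if var in missing_ok or var not in table.columns:
            continue
        keep &= table[var].notna().to_numpy()
    D = model.design_matrix(table.loc[keep], meta=meta)
    bad = D.isna().any(axis=1).to_numpy()
    if bad.any():
        D, y_out = D.loc[~bad], y[keep][~bad]
    else:
        y_out = y[keep]
    return D, y_out, int(len(table) - len(D))


def _collinear_columns(D: pd.DataFrame) -> list[str]:
    """Columns whose QR diagonal collapses (in entry order, the later of
    any dependent pair is flagged); empty when the design has full rank."""
    X = D.to_numpy(dtype=float)
    Xc = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Xc) == Xc.shape[1]:
        return []
    _, R = np.linalg.qr(Xc, mode="reduced")
    rdiag = np.abs(np.diag(R))
    scale = rdiag.max() if rdiag.size else 1.0
    bad = [
        name
        for name, v in zip(["Intercept", *D.columns], rdiag)
        if v < 1e-10 * scale and name != "Intercept"
    ]
    return bad or list(D.columns[-1:])


def refit_ols(
    model: ThresholdModel,
    table: pd.DataFrame,
    response: str,
    meta: Mapping[str, VariableMeta] | None = None,
    on_collinear: str = "error",
) -> RegressionFit:
    """Complete-case OLS on the model's basis functions.

    Reports estimates, classical standard errors, t statistics and
    two-sided p values from the t distribution with n - p - 1 degrees of
    freedom, plus the number of dropped incomplete cases.  A rank-deficient
    design raises :class:`CollinearityError` naming the collinear terms;
    with ``on_collinear="drop"`` the offending basis functions (e.g. an
    interaction unsupported in a small partition) are removed with a
    warning instead.
    """
    D, y, n_dropped = _complete_case_design(model, table, response, meta)
    if len(D) <= D.shape[1] + 1:
        raise ValueError("too few complete cases to refit")
    for _ in range(D.shape[1]):
        bad = _collinear_columns(D)
        if not bad:
            break
        if on_collinear == "error":
            raise CollinearityError(
                f"rank-deficient design; collinear terms: {bad}"
            )
        logger.warning("dropping collinear basis function(s): %s", bad)
        D = D.drop(columns=bad)
        model = ThresholdModel(
            intercept=model.intercept,
            terms=[t for t in model.terms if t.basis.name not in bad],
            passthrough=[
                (term, c) for term, c in model.passthrough if term.name not in bad
            ],
        )
    X = sm.add_constant(D.to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(y, X).fit()
    names = ["Intercept", *D.columns]
    params = pd.DataFrame(
        {
            "Parameters": names,
            "Value": res.params,
            "Std Error": res.bse,
            "t value": res.tvalues,
            "P value": res.pvalues,
        }
    )
    refit = ThresholdModel(
        intercept=float(res.params[0]),
        terms=[
            ThresholdTerm(t.basis, float(c))
            for t, c in zip(model.terms, res.params[1: 1 + len(model.terms)])
        ],
        passthrough=[
            (term, float(c))
            for (term, _), c in zip(
                model.passthrough, res.params[1 + len(model.terms):]
            )
        ],
    )
    return RegressionFit(
        params=params,
        r2=float(res.rsquared),
        n_used=int(res.nobs),
        n_dropped=n_dropped,
        fitted_model=refit,
    )


def validate(
    model: ThresholdModel,
    analysis_fit: RegressionFit,
    validation_table: pd.DataFrame,
    response: str,
    meta: Mapping[str, VariableMeta] | None = None,
    on_collinear: str = "error",
) -> tuple[float, RegressionFit, pd.DataFrame]:
    """Apply analysis-set coefficients to the validation partition and
    refit the same basis there.

    Returns ``(applied_r2, refit, stability)``: the applied R-squared uses
    the validation-set mean in its denominator (so a non-transferable
    model shows up as applied_r2 <= 0); ``stability`` compares per-term
    significance at alpha = 0.05 between partitions.
    """
    if len(validation_table) == 0:
        raise ValueError("validation partition is empty")
    fitted = analysis_fit.fitted_model
    D, y, _ = _complete_case_design(fitted, validation_table, response, meta)
    if len(D) == 0:
        raise ValueError("no complete validation cases")
    pred = fitted.intercept + D.to_numpy(dtype=float) @ np.array(
        [t.coefficient for t in fitted.terms]
        + [c for _, c in fitted.passthrough]
    )
    sst = float(np.sum((y - y.mean()) ** 2))
    applied_r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst
    refit = refit_ols(
        model, validation_table, response, meta=meta, on_collinear=on_collinear
    )
    stability = (
        analysis_fit.params[["Parameters", "P value"]]
        .rename(columns={"P value": "p_analysis"})
        .merge(
            refit.params[["Parameters", "P value"]].rename(
                columns={"P value": "p_validation"}
            ),
            on="Parameters",
            how="outer",
        )
    )
    stability["significant_analysis"] = stability["p_analysis"] < SIGNIFICANCE_ALPHA
    stability["significant_validation"] = (
        stability["p_validation"] < SIGNIFICANCE_ALPHA
    )
    lost = stability.loc[
        stability.significant_analysis & ~stability.significant_validation,
        "Parameters",
    ].tolist()
    if lost:
        logger.info("terms losing significance in validation: %s", lost)
    return applied_r2, refit, stability


def group_importance(
    model: ThresholdModel,
    table: pd.DataFrame,
    response: str,
    meta: Mapping[str, VariableMeta] | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> list[ImportanceRecord]:
    """Marginal and delta R-squared per predictor group.

    By default every basis transformation of one source variable forms one
    group (multiple knot transforms of e.g. AST count as a single group);
    an explicit ``groups`` mapping of label -> term names overrides this.
    The marginal R-squared fits the group's terms alone; the delta
    R-squared is the drop in full-model R-squared when the group is
    removed.  Records are sorted by delta R-squared, descending.
    """
    term_names = model.term_names
    if groups is None:
        groups_map: dict[str, list[str]] = {}
        for t in model.terms:
            label = (
                meta[t.basis.variable].group
                if meta is not None and t.basis.variable in meta
                else t.basis.variable
            )
            groups_map.setdefault(label, []).append(t.basis.name)
    else:
        groups_map = {k: list(v) for k, v in groups.items()}
        for label, names in groups_map.items():
            missing = set(names) - set(term_names)
            if missing:
                raise KeyError(
                    f"group {label!r} references absent terms {sorted(missing)}"
                )

    D, y, _ = _complete_case_design(model, table, response, meta)
    X = D.to_numpy(dtype=float)
    all_names = list(D.columns)

    def ols_r2(cols: list[str]) -> float:
        idx = [all_names.index(c) for c in cols]
        Xc = sm.add_constant(X[:, idx], has_constant="add")
        return float(sm.OLS(y, Xc).fit().rsquared)

    full_r2 = ols_r2(all_names)
    records = []
    for label, names in groups_map.items():
        marginal = ols_r2(names)
        rest = [c for c in all_names if c not in names]
        delta = full_r2 - (ols_r2(rest) if rest else 0.0)
        records.append(
            ImportanceRecord(label, marginal_r2=marginal, delta_r2=max(delta, 0.0))
        )
    records.sort(key=lambda rec: -rec.delta_r2)
    return records


def fit_summary(rows: Sequence[Mapping], agreement_tol: float = 0.05) -> pd.DataFrame:
    """Cross-method fit-statistic table, one row per response.

    Expects per-response dicts with keys ``response``, ``rf_cv_r2``,
    ``mars_gcv_r2``, ``ols_r2_analysis``, ``ols_r2_validation_applied``,
    ``ols_r2_validation_refit``; adds a reproducibility flag marking any
    response where analysis and validation-refit R-squared disagree by
    more than ``agreement_tol``.
    """
    cols = [
        "response",
        "rf_cv_r2",
        "mars_gcv_r2",
        "ols_r2_analysis",
        "ols_r2_validation_applied",
        "ols_r2_validation_refit",
    ]
    frame = pd.DataFrame(list(rows))[cols]
    frame["agreement_flag"] = (
        (frame["ols_r2_analysis"] - frame["ols_r2_validation_refit"]).abs()
        > agreement_tol
    )
    return frame
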