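"""Data-preparation rules: BLLOQ substitution, stratified median imputation,
categorical encoding with an explicit missing category, derived variables,
and the analysis/validation split.

The fixed order of operations for a modeling run is: BLLOQ rule ->
80/20 split -> drop rows with a missing response (per target) ->
stratified median imputation (imputed copy only) -> encoding.  The split
precedes imputation because medians are computed separately for the
analysis and validation partitions (and separately for smokers and
nonsmokers).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metadata import (
    ID_COLUMN,
    PARTITION_COLUMN,
    SMOKING_COLUMN,
    Cohort,
    VariableMeta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EncodedTable",
    "apply_blloq_rule",
    "blloq_value",
    "derive_crcl",
    "split_analysis_validation",
    "drop_missing_response",
    "impute_continuous_medians",
    "encode_categoricals",
    "decode_categorical",
]

MISSING_LEVEL = "MISSING"


@dataclass
class EncodedTable:
    """Numeric design table plus provenance of every derived column.

    ``provenance`` maps an encoded column name to ``(source variable,
    form, level)`` where form is ``LINEAR``, ``EQ`` or ``GT``.
    """

    data: pd.DataFrame
    provenance: dict[str, tuple[str, str, str | None]]
    partition: pd.Series
    response_columns: tuple[str, ...] = ()

    def predictor_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.response_columns]

    def subset(self, label: str) -> "EncodedTable":
        mask = (self.partition == label).to_numpy()
        return EncodedTable(
            self.data.loc[mask].reset_index(drop=True),
            self.provenance,
            self.partition.loc[mask].reset_index(drop=True),
            self.response_columns,
        )


# ---------------------------------------------------------------------------
# BLLOQ substitution
# ---------------------------------------------------------------------------


def blloq_value(value: float, flag: int) -> float:
    """Elementwise BLLOQ rule: a flagged *missing* value becomes 0; a
    flagged value that was measured anyway is left unchanged; unflagged
    values (missing or not) are untouched."""
    if flag and (value is None or (isinstance(value, float) and math.isnan(value))):
        return 0.0
    return value


def apply_blloq_rule(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Apply the BLLOQ substitution to every flagged exposure biomarker.

    Returns the updated cohort and a per-variable count of substituted
    cells.  Idempotent: substituted zeros are non-missing, so a second
    application changes nothing.
    """
    data = cohort.data.copy()
    counts: dict[str, int] = {}
    for name, m in cohort.meta.items():
        if not m.blloq_flag_column or m.blloq_flag_column not in data:
            continue
        flagged = data[m.blloq_flag_column].astype(bool) & data[name].isna()
        data.loc[flagged, name] = 0.0
        counts[name] = int(flagged.sum())
    return Cohort(data, dict(cohort.meta)), counts


# ---------------------------------------------------------------------------
# derived variables
# ---------------------------------------------------------------------------


def derive_crcl(urine_creatinine_24h, serum_creatinine):
    """Creatinine clearance: 24 h urine creatinine / serum creatinine
    (mg/24h over mg/dL gives dL/day).  Nonpositive serum creatinine is
    invalid: the result is missing and a warning is logged.  Missing
    inputs propagate."""
    u = np.asarray(urine_creatinine_24h, dtype=float)
    s = np.asarray(serum_creatinine, dtype=float)
    invalid = ~np.isnan(s) & (s <= 0)
    if invalid.any():
        logger.warning(
            "derive_crcl: %d nonpositive serum creatinine values set to missing",
            int(invalid.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = u / np.where(invalid, np.nan, s)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# split / drop / impute
# ---------------------------------------------------------------------------


def split_analysis_validation(
    cohort: Cohort,
    fraction: float = 0.8,
    seed: int = 0,
    stratify_smoking: bool = False,
) -> Cohort:
    """Assign ``round(fraction * n)`` rows to the analysis partition and
    the rest to validation, uniformly at random (optionally within each
    smoking stratum)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("split fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    data = cohort.data.copy()
    n = len(data)
    labels = np.full(n, "validation", dtype=object)

    def assign(idx: np.ndarray) -> None:
        k = round(fraction * len(idx))
        chosen = rng.choice(idx, size=k, replace=False)
        labels[chosen] = "analysis"

    if stratify_smoking:
        for val in (1, 0):
            assign(np.flatnonzero(data[SMOKING_COLUMN].to_numpy() == val))
    else:
        assign(np.arange(n))
    data[PARTITION_COLUMN] = labels
    return Cohort(data, dict(cohort.meta))


def drop_missing_response(cohort: Cohort, response: str) -> tuple[Cohort, int]:
    """Remove rows with a missing value of the target response."""
    if cohort.meta[response].role != "response":
        raise ValueError(f"{response} is not a response variable")
    missing = cohort.data[response].isna()
    n_dropped = int(missing.sum())
    if n_dropped == len(cohort.data):
        logger.error("all %d rows have missing %s", n_dropped, response)
    data = cohort.data.loc[~missing].reset_index(drop=True)
    return Cohort(data, dict(cohort.meta)), n_dropped


def impute_continuous_medians(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Replace missing continuous predictor values with the stratum median.

    Strata are smoking status x partition; responses are never imputed.
    A stratum with no observed values for a variable falls back to the
    global median with a warning.
    """
    data = cohort.data.copy()
    counts: dict[str, int] = {}
    strata = list(
        data.groupby([SMOKING_COLUMN, PARTITION_COLUMN], observed=True).groups.items()
    )
    for name in cohort.continuous_predictors():
        if name not in data:
            continue
        col = data[name]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            counts[name] = 0
            continue
        filled = col.copy()
        for key, idx in strata:
            sub = col.loc[idx]
            med = sub.median()
            if pd.isna(med):
                med = col.median()
                logger.warning(
                    "stratum %s fully missing for %s; global median used",
                    key,
                    name,
                )
            filled.loc[idx] = sub.fillna(med)
        data[name] = filled
        counts[name] = n_missing
    return Cohort(data, dict(cohort.meta)), counts


# ---------------------------------------------------------------------------
# categorical encoding
# ---------------------------------------------------------------------------


def _declared_levels(data: pd.DataFrame, m: VariableMeta) -> list[str]:
    levels = list(m.levels or ())
    observed = {str(v) for v in data[m.name].dropna().unique()}
    unseen = observed - set(levels)
    if unseen:
        raise ValueError(
            f"variable {m.name} has undeclared level(s) {sorted(unseen)}"
        )
    return levels


def encode_categoricals(
    cohort: Cohort, variables: Sequence[str] | None = None
) -> EncodedTable:
    """Encode the cohort into an all-numeric design table.

    Continuous variables pass through unchanged.  Nominal variables emit
    the *full* indicator set ``VAR.EQ.LEVEL`` (downstream fitting selects
    among individual indicators).  Ordinal variables emit cumulative
    indicators ``VAR.GT.LEVEL_j`` (1 when the value lies strictly above
    level j); the drinks-per-week variable additionally emits the
    collapsed ``DRINK.EQ.Y`` any-vs-NO indicator so both codings are
    available.  Missing categorical values become their own ``MISSING``
    level before encoding.
    """
    data = cohort.data
    names = list(variables) if variables is not None else [
        n for n in cohort.meta if n in data.columns
    ]
    cols: dict[str, np.ndarray] = {}
    provenance: dict[str, tuple[str, str, str | None]] = {}
    responses: list[str] = []

    for name in names:
        m = cohort.meta[name]
        if m.role == "response":
            cols[name] = data[name].to_numpy(dtype=float)
            provenance[name] = (name, "LINEAR", None)
            responses.append(name)
            continue
        if m.vtype == "continuous":
            cols[name] = data[name].to_numpy(dtype=float)
            provenance[name] = (name, "LINEAR", None)
            continue
        levels = _declared_levels(data, m)
        raw = data[name]
        has_missing = bool(raw.isna().any())
        str_vals = raw.astype("object").where(raw.notna(), MISSING_LEVEL).astype(str)
        if m.vtype == "nominal":
            emit_levels = levels + ([MISSING_LEVEL] if has_missing else [])
            for lev in emit_levels:
                col = f"{name}.EQ.{lev}"
                cols[col] = (str_vals == lev).to_numpy(dtype=float)
                provenance[col] = (name, "EQ", lev)
        else:  # ordinal: cumulative indicators; missing rows are 0 throughout
            order = {lev: i for i, lev in enumerate(levels)}
            idx = str_vals.map(lambda v: order.get(v, np.nan))
            for lev in levels[:-1]:
                col = f"{name}.GT.{lev}"
                cols[col] = (idx > order[lev]).fillna(False).to_numpy(dtype=float)
                provenance[col] = (name, "GT", lev)
            if has_missing:
                col = f"{name}.EQ.{MISSING_LEVEL}"
                cols[col] = (str_vals == MISSING_LEVEL).to_numpy(dtype=float)
                provenance[col] = (name, "EQ", MISSING_LEVEL)
            if name == "DRINK" and "NO" in levels:
                col = f"{name}.EQ.Y"
                cols[col] = (
                    raw.notna() & (str_vals != "NO") & (str_vals != MISSING_LEVEL)
                ).to_numpy(dtype=float)
                provenance[col] = (name, "EQ", "Y")

    frame = pd.DataFrame(cols, index=data.index).reset_index(drop=True)
    partition = data[PARTITION_COLUMN].reset_index(drop=True)
    # smoking status is part of the design (binary, passes through above
    # only if declared in meta); include it explicitly
    if SMOKING_COLUMN not in frame and SMOKING_COLUMN in data:
        frame[SMOKING_COLUMN] = data[SMOKING_COLUMN].to_numpy(dtype=float)
        provenance[SMOKING_COLUMN] = (SMOKING_COLUMN, "LINEAR", None)
    return EncodedTable(frame, provenance, partition, tuple(responses))


def decode_categorical(
    encoded: EncodedTable, variable: str, levels: Sequence[str]
) -> pd.Series:
    """Recover original categorical values from their indicator columns
    (round-trip check for the encoding)."""
    prov = encoded.provenance
    eq_cols = {
        lev: c
        for c, (src, form, lev) in prov.items()
        if src == variable and form == "EQ" and lev != "Y"
    }
    gt_cols = [
        (lev, c)
        for c, (src, form, lev) in prov.items()
        if src == variable and form == "GT"
    ]
    n = len(encoded.data)
    if gt_cols:  # ordinal: level index = number of GT indicators equal to 1
        order = list(levels)
        count = sum(encoded.data[c].to_numpy() for _, c in gt_cols)
        out = pd.Series([order[int(k)] for k in count], dtype="object")
        if MISSING_LEVEL in eq_cols:
            out[encoded.data[eq_cols[MISSING_LEVEL]] == 1] = np.nan
        return out
    out = pd.Series([np.nan] * n, dtype="object")
    for lev, c in eq_cols.items():
        out[encoded.data[c] == 1] = lev
    out[out == MISSING_LEVEL] = np.nan
    return out
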