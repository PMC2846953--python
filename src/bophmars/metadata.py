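"""Shared containers: per-variable metadata and the subject-level cohort table.

A cohort is a plain pandas DataFrame (one row per subject) plus a metadata
record per variable.  Missing values are encoded as NaN for continuous
variables and NaN/None for categoricals; below-limit-of-quantification
(BLLOQ) status for exposure biomarkers lives in companion 0/1 columns named
``<var>_BLLOQ``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

ROLES = ("response", "boe", "covariate")
VTYPES = ("continuous", "nominal", "ordinal")

#: partition labels for the analysis/validation split
PARTITIONS = ("analysis", "validation", "unassigned")

ID_COLUMN = "SUBJID"
SMOKING_COLUMN = "SMOKE"
PARTITION_COLUMN = "PARTITION"


@dataclass(frozen=True)
class VariableMeta:
    """Role, measurement type, units and grouping of one cohort variable."""

    name: str
    role: str  # response / boe / covariate
    vtype: str  # continuous / nominal / ordinal
    units: str = ""
    group: str = ""  # importance-group label; defaults to the variable name
    levels: tuple[str, ...] | None = None  # declared levels, ordered if ordinal
    blloq_flag_column: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name}")
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown vtype {self.vtype!r} for {self.name}")
        if self.vtype in ("nominal", "ordinal") and not self.levels:
            raise ValueError(f"categorical variable {self.name} needs levels")
        if not self.group:
            object.__setattr__(self, "group", self.name)


@dataclass
class Cohort:
    """Subjects x variables table with metadata sidecar.

    ``data`` holds one row per subject with at least ``SUBJID``, ``SMOKE``
    (1 = smoker) and ``PARTITION`` columns; ``meta`` maps variable name to
    its :class:`VariableMeta`.
    """

    data: pd.DataFrame
    meta: dict[str, VariableMeta]

    def __post_init__(self) -> None:
        if self.data[ID_COLUMN].duplicated().any():
            raise ValueError("duplicate subject ids in cohort")
        for name, m in self.meta.items():
            if m.blloq_flag_column and m.role != "boe":
                raise ValueError(
                    f"BLLOQ flag declared for non-BOE variable {name}"
                )
        if PARTITION_COLUMN not in self.data.columns:
            self.data[PARTITION_COLUMN] = "unassigned"

    # -- convenience selectors -------------------------------------------
    def variables(self, role: str | None = None) -> list[str]:
        return [
            n for n, m in self.meta.items() if role is None or m.role == role
        ]

    @property
    def responses(self) -> list[str]:
        return self.variables("response")

    @property
    def boe(self) -> list[str]:
        return self.variables("boe")

    def continuous_predictors(self) -> list[str]:
        return [
            n
            for n, m in self.meta.items()
            if m.role != "response" and m.vtype == "continuous"
        ]

    def partition(self, label: str) -> pd.DataFrame:
        return self.data[self.data[PARTITION_COLUMN] == label]

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), dict(self.meta))

    # -- I/O --------------------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        """Write ``cohort.csv`` and ``variables.csv`` (metadata sidecar)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(outdir / "cohort.csv", index=False)
        rows = []
        for m in self.meta.values():
            rows.append(
                {
                    "name": m.name,
                    "role": m.role,
                    "type": m.vtype,
                    "units": m.units,
                    "group": m.group,
                    "levels": "|".join(m.levels) if m.levels else "",
                    "blloq_flag_column": m.blloq_flag_column or "",
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "variables.csv", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "Cohort":
        indir = Path(indir)
        side = pd.read_csv(indir / "variables.csv", keep_default_na=False)
        meta: dict[str, VariableMeta] = {}
        cat_cols: dict[str, tuple[str, ...]] = {}
        for _, r in side.iterrows():
            levels = tuple(r["levels"].split("|")) if r["levels"] else None
            meta[r["name"]] = VariableMeta(
                name=r["name"],
                role=r["role"],
                vtype=r["type"],
                units=r["units"],
                group=r["group"],
                levels=levels,
                blloq_flag_column=r["blloq_flag_column"] or None,
            )
            if levels:
                cat_cols[r["name"]] = levels
        dtypes = {name: "object" for name in cat_cols}
        data = pd.read_csv(indir / "cohort.csv", dtype=dtypes)
        return cls(data, meta)
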