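"""Hinge and threshold basis functions for adaptive spline regression models.

Two equivalent parametrizations of the same piecewise-linear model space are
supported:

* **hinge** terms ``max(0, x - c)`` / ``max(0, c - x)`` (the reflected pair
  used during spline fitting), optionally multiplied pairwise for two-way
  interactions;
* **threshold** terms in the interpretable naming convention used for the
  final coefficient tables: ``X.IFGT.c`` evaluates to ``x`` when ``x > c``
  and to ``c`` otherwise (i.e. ``max(x, c)``), ``X.IFLT.c`` to ``min(x, c)``,
  ``X.EQ.L`` / ``X.GT.L`` to categorical and cumulative-ordinal indicators.

Because ``max(0, x - c) = max(x, c) - c`` the two spaces are related by an
exact linear reparametrization; :func:`hinge_to_threshold` performs it while
preserving fitted values bit-for-bit up to float rounding.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metadata import VariableMeta

__all__ = [
    "HingeFactor",
    "HingeTerm",
    "SplineModel",
    "ThresholdBasis",
    "ThresholdTerm",
    "ThresholdModel",
    "basis_name",
    "format_cutoff",
    "eval_threshold_basis",
    "hinge_to_threshold",
    "threshold_to_hinge",
]

_INDICATOR_RE = re.compile(r"^(?P<var>.+)\.(?P<form>EQ|GT)\.(?P<level>.+)$")


def format_cutoff(cutoff: float | str) -> str:
    """Render a knot/level for use in a basis name, without trailing zeros."""
    if isinstance(cutoff, str):
        return cutoff
    f = float(cutoff)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return np.format_float_positional(f, trim="-")


# ---------------------------------------------------------------------------
# hinge representation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HingeFactor:
    """One factor of a spline term: a hinge ``max(0, +/-(x - c))`` or plain x.

    ``knot=None`` marks a linear factor (model type 0 entries and encoded
    0/1 indicator columns).  ``direction`` is ``'+'`` for ``max(0, x - c)``
    and ``'-'`` for ``max(0, c - x)``.
    """

    variable: str
    knot: float | None = None
    direction: str = "+"

    def __post_init__(self) -> None:
        if self.direction not in ("+", "-"):
            raise ValueError("direction must be '+' or '-'")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.knot is None:
            return x
        if self.direction == "+":
            return np.maximum(0.0, x - self.knot)
        return np.maximum(0.0, self.knot - x)

    @property
    def name(self) -> str:
        if self.knot is None:
            return self.variable
        c = format_cutoff(self.knot)
        if self.direction == "+":
            return f"h({self.variable}-{c})"
        return f"h({c}-{self.variable})"


@dataclass(frozen=True)
class HingeTerm:
    """Product of one or two hinge/linear factors."""

    factors: tuple[HingeFactor, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.factors) <= 2:
            raise ValueError("terms are single factors or two-way products")
        vars_ = [f.variable for f in self.factors]
        if len(set(vars_)) != len(vars_):
            raise ValueError("interaction factors must use distinct variables")

    def evaluate(self, table: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        out = None
        for f in self.factors:
            if f.variable not in table:
                raise KeyError(f"model references absent variable {f.variable!r}")
            col = f.evaluate(np.asarray(table[f.variable], dtype=float))
            out = col if out is None else out * col
        return out

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(f.variable for f in self.factors)

    @property
    def is_interaction(self) -> bool:
        return len(self.factors) == 2

    @property
    def name(self) -> str:
        return "*".join(f.name for f in self.factors)


@dataclass
class SplineModel:
    """Fitted spline model: intercept plus weighted hinge terms."""

    intercept: float
    terms: list[tuple[HingeTerm, float]]
    rss: float = float("nan")
    n: int = 0
    complexity: float = float("nan")
    gcv: float = float("nan")
    gcv_r2: float = float("nan")
    model_type: int = 1

    def predict(self, table) -> np.ndarray:
        nrow = len(next(iter(table.values()))) if isinstance(table, dict) else len(table)
        out = np.full(nrow, self.intercept, dtype=float)
        for term, coef in self.terms:
            out += coef * term.evaluate(table)
        return out

    @property
    def n_params(self) -> int:
        return len(self.terms) + 1

    @property
    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for term, _ in self.terms:
            for v in term.variables:
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    def distinct_knots(self) -> int:
        return len(
            {
                (f.variable, f.knot)
                for term, _ in self.terms
                for f in term.factors
                if f.knot is not None
            }
        )

    def to_json(self) -> str:
        payload = {
            "intercept": self.intercept,
            "model_type": self.model_type,
            "stats": {
                "rss": self.rss,
                "n": self.n,
                "complexity": self.complexity,
                "gcv": self.gcv,
                "gcv_r2": self.gcv_r2,
            },
            "terms": [
                {
                    "coefficient": coef,
                    "factors": [
                        {
                            "variable": f.variable,
                            "knot": f.knot,
                            "direction": f.direction,
                        }
                        for f in term.factors
                    ],
                }
                for term, coef in self.terms
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SplineModel":
        payload = json.loads(text)
        terms = [
            (
                HingeTerm(
                    tuple(
                        HingeFactor(f["variable"], f["knot"], f["direction"])
                        for f in t["factors"]
                    )
                ),
                t["coefficient"],
            )
            for t in payload["terms"]
        ]
        stats = payload.get("stats", {})
        return cls(
            intercept=payload["intercept"],
            terms=terms,
            model_type=payload.get("model_type", 1),
            **{k: stats.get(k, float("nan")) for k in ("rss", "complexity", "gcv", "gcv_r2")},
            n=int(stats.get("n", 0)),
        )


# ---------------------------------------------------------------------------
# threshold representation
# ---------------------------------------------------------------------------

_FORMS = ("LINEAR", "EQ", "GT", "IFGT", "IFLT")


@dataclass(frozen=True)
class ThresholdBasis:
    """One interpretable basis function (Form 1, 2 or 3 naming convention)."""

    variable: str
    form: str
    cutoff: float | str | None = None

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown basis form {self.form!r}")
        if self.form in ("IFGT", "IFLT") and not isinstance(
            self.cutoff, (int, float)
        ):
            raise TypeError(f"{self.form} basis requires a numeric cutoff")
        if self.form in ("EQ", "GT") and self.cutoff is None:
            raise ValueError(f"{self.form} basis requires a level cutoff")

    @property
    def name(self) -> str:
        return basis_name(self)

    def evaluate(
        self, values, levels: Sequence[str] | None = None
    ) -> np.ndarray:
        """Evaluate on a vector of raw variable values.

        ``levels`` supplies the declared (ordered, for ordinals) level list;
        it is required for GT indicators and consulted for the collapsed
        any-vs-NO indicator (cutoff ``Y`` on a variable with no literal
        ``Y`` level).
        """
        if self.form == "LINEAR":
            return np.asarray(values, dtype=float)
        if self.form == "IFGT":
            return np.maximum(np.asarray(values, dtype=float), float(self.cutoff))
        if self.form == "IFLT":
            return np.minimum(np.asarray(values, dtype=float), float(self.cutoff))
        s = pd.Series(values, dtype="object")
        if self.form == "EQ":
            if self.cutoff == "MISSING":
                return s.isna().to_numpy(dtype=float)
            if (
                self.cutoff == "Y"
                and levels is not None
                and "Y" not in levels
            ):
                # drinks-at-all style collapse: any declared level except NO
                out = s.notna() & (s.astype(str) != "NO")
            else:
                out = s.notna() & (s.astype(str) == str(self.cutoff))
            return out.to_numpy(dtype=float)
        # GT: cumulative ordinal indicator, value strictly above the cutoff
        if levels is None:
            raise ValueError(
                f"ordered levels required to evaluate {self.name}"
            )
        order = {lev: i for i, lev in enumerate(levels)}
        if str(self.cutoff) not in order:
            raise KeyError(
                f"level {self.cutoff!r} not declared for {self.variable}"
            )
        cut = order[str(self.cutoff)]
        idx = s.map(lambda v: order.get(v if v is None else str(v), np.nan) if not pd.isna(v) else np.nan)
        return (idx > cut).fillna(False).to_numpy(dtype=float)


def eval_threshold_basis(
    x, basis: ThresholdBasis, levels: Sequence[str] | None = None
):
    """Evaluate ``basis`` at scalar or vector ``x`` (functional front door)."""
    scalar = np.isscalar(x) or isinstance(x, str) or x is None
    out = basis.evaluate([x] if scalar else x, levels=levels)
    return float(out[0]) if scalar else out


def basis_name(basis: ThresholdBasis) -> str:
    if basis.form == "LINEAR":
        return basis.variable
    return f"{basis.variable}.{basis.form}.{format_cutoff(basis.cutoff)}"


@dataclass(frozen=True)
class ThresholdTerm:
    basis: ThresholdBasis
    coefficient: float


@dataclass
class ThresholdModel:
    """Intercept plus weighted threshold basis functions.

    ``passthrough`` carries interaction hinge terms that have no threshold
    equivalent (only relevant for two-way spline models).
    """

    intercept: float
    terms: list[ThresholdTerm]
    passthrough: list[tuple[HingeTerm, float]] = field(default_factory=list)

    @property
    def term_names(self) -> list[str]:
        return [t.basis.name for t in self.terms]

    def _levels(self, var: str, meta: Mapping[str, VariableMeta] | None):
        if meta is not None and var in meta:
            return meta[var].levels
        return None

    def _passthrough_inputs(
        self, table: pd.DataFrame, meta: Mapping[str, VariableMeta] | None
    ) -> dict[str, np.ndarray]:
        """Columns needed by passthrough interaction factors, resolving
        encoded indicator names (``VAR.EQ.LEVEL`` / ``VAR.GT.LEVEL``)
        against the raw table when the encoded column is absent."""
        out: dict[str, np.ndarray] = {}
        for term, _ in self.passthrough:
            for f in term.factors:
                if f.variable in out:
                    continue
                if f.variable in table:
                    out[f.variable] = np.asarray(table[f.variable], dtype=float)
                    continue
                m = _INDICATOR_RE.match(f.variable)
                if m and m.group("var") in table:
                    src = m.group("var")
                    b = ThresholdBasis(src, m.group("form"), m.group("level"))
                    out[f.variable] = b.evaluate(
                        table[src], levels=self._levels(src, meta)
                    )
                else:
                    raise KeyError(
                        f"model references absent variable {f.variable!r}"
                    )
        return out

    def design_matrix(
        self, table: pd.DataFrame, meta: Mapping[str, VariableMeta] | None = None
    ) -> pd.DataFrame:
        """Evaluate every basis function; columns named per the convention."""
        cols = {}
        for t in self.terms:
            var = t.basis.variable
            if var not in table:
                raise KeyError(f"model references absent variable {var!r}")
            cols[t.basis.name] = t.basis.evaluate(
                table[var], levels=self._levels(var, meta)
            )
        if self.passthrough:
            inputs = self._passthrough_inputs(table, meta)
            for term, _ in self.passthrough:
                cols[term.name] = term.evaluate(inputs)
        return pd.DataFrame(cols, index=table.index)

    def source_variables(self) -> tuple[str, ...]:
        """Raw cohort variables the model depends on (encoded indicator
        factor names are mapped back to their source variable)."""
        seen: list[str] = []
        for t in self.terms:
            if t.basis.variable not in seen:
                seen.append(t.basis.variable)
        for term, _ in self.passthrough:
            for v in term.variables:
                m = _INDICATOR_RE.match(v)
                src = m.group("var") if m else v
                if src not in seen:
                    seen.append(src)
        return tuple(seen)

    def evaluate(
        self, table: pd.DataFrame, meta: Mapping[str, VariableMeta] | None = None
    ) -> np.ndarray:
        out = np.full(len(table), float(self.intercept))
        for t in self.terms:
            var = t.basis.variable
            if var not in table:
                raise KeyError(f"model references absent variable {var!r}")
            out += t.coefficient * np.asarray(
                t.basis.evaluate(table[var], levels=self._levels(var, meta)),
                dtype=float,
            )
        if self.passthrough:
            inputs = self._passthrough_inputs(table, meta)
            for term, coef in self.passthrough:
                out += coef * term.evaluate(inputs)
        return out

    @property
    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.terms:
            if t.basis.variable not in seen:
                seen.append(t.basis.variable)
        for term, _ in self.passthrough:
            for v in term.variables:
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "terms": [
                    {
                        "variable": t.basis.variable,
                        "form": t.basis.form,
                        "cutoff": t.basis.cutoff,
                        "coefficient": t.coefficient,
                        "name": t.basis.name,
                    }
                    for t in self.terms
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdModel":
        payload = json.loads(text)
        return cls(
            intercept=payload["intercept"],
            terms=[
                ThresholdTerm(
                    ThresholdBasis(t["variable"], t["form"], t.get("cutoff")),
                    t["coefficient"],
                )
                for t in payload["terms"]
            ],
        )

    def coefficient_table(self) -> pd.DataFrame:
        """Skeleton of the printed coefficient-table layout (values only;
        standard errors / t / p are filled in by the inference refit)."""
        rows = [{"Parameters": "Intercept", "Value": self.intercept}]
        rows += [
            {"Parameters": t.basis.name, "Value": t.coefficient}
            for t in self.terms
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reparametrization
# ---------------------------------------------------------------------------


def _indicator_basis(column: str, provenance: Mapping | None) -> ThresholdBasis | None:
    """Map an encoded indicator column back to its EQ/GT threshold basis."""
    if provenance is not None and column in provenance:
        source, form, level = provenance[column]
        if form in ("EQ", "GT"):
            return ThresholdBasis(source, form, level)
        return None
    m = _INDICATOR_RE.match(column)
    if m:
        return ThresholdBasis(m.group("var"), m.group("form"), m.group("level"))
    return None


def hinge_to_threshold(
    model: SplineModel, provenance: Mapping | None = None
) -> ThresholdModel:
    """Convert a hinge-basis spline model to the threshold parametrization.

    Uses ``max(0, x - c) = IFGT(x, c) - c`` and ``max(0, c - x) =
    c - IFLT(x, c)``, folding the constants into the intercept so fitted
    values are preserved exactly.  Linear terms on encoded indicator columns
    become EQ/GT bases (via ``provenance`` or by parsing the column name);
    two-way interaction terms pass through untransformed with a warning.
    """
    intercept = float(model.intercept)
    terms: list[ThresholdTerm] = []
    passthrough: list[tuple[HingeTerm, float]] = []
    for term, coef in model.terms:
        if term.is_interaction:
            warnings.warn(
                f"interaction term {term.name} has no threshold form; "
                "passed through unchanged",
                stacklevel=2,
            )
            passthrough.append((term, coef))
            continue
        (factor,) = term.factors
        if factor.knot is None:
            ind = _indicator_basis(factor.variable, provenance)
            basis = ind or ThresholdBasis(factor.variable, "LINEAR")
            terms.append(ThresholdTerm(basis, float(coef)))
        elif factor.direction == "+":
            terms.append(
                ThresholdTerm(
                    ThresholdBasis(factor.variable, "IFGT", float(factor.knot)),
                    float(coef),
                )
            )
            intercept -= coef * factor.knot
        else:
            terms.append(
                ThresholdTerm(
                    ThresholdBasis(factor.variable, "IFLT", float(factor.knot)),
                    -float(coef),
                )
            )
            intercept += coef * factor.knot
    return ThresholdModel(intercept=intercept, terms=terms, passthrough=passthrough)


def threshold_to_hinge(model: ThresholdModel) -> SplineModel:
    """Inverse reparametrization (round-trip check; EQ/GT become linear
    terms on the correspondingly named indicator columns)."""
    intercept = float(model.intercept)
    terms: list[tuple[HingeTerm, float]] = []
    for t in model.terms:
        b = t.basis
        if b.form == "LINEAR":
            terms.append((HingeTerm((HingeFactor(b.variable),)), t.coefficient))
        elif b.form in ("EQ", "GT"):
            terms.append((HingeTerm((HingeFactor(b.name),)), t.coefficient))
        elif b.form == "IFGT":
            terms.append(
                (
                    HingeTerm((HingeFactor(b.variable, float(b.cutoff), "+"),)),
                    t.coefficient,
                )
            )
            intercept += t.coefficient * float(b.cutoff)
        else:  # IFLT: min(x, c) = c - max(0, c - x)
            terms.append(
                (
                    HingeTerm((HingeFactor(b.variable, float(b.cutoff), "-"),)),
                    -t.coefficient,
                )
            )
            intercept += t.coefficient * float(b.cutoff)
    terms.extend(model.passthrough)
    return SplineModel(intercept=intercept, terms=terms)
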