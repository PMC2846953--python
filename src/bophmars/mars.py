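"""Adaptive regression spline engine.

Implements the classic two-stage procedure: a greedy *forward pass* that
adds reflected pairs of hinge functions ``max(0, x - c)`` / ``max(0, c - x)``
(exact search over all observed-value knots, subject to a minimum span), and
a *backward pass* that deletes terms one at a time and selects the subset
minimizing the generalized cross-validation (GCV) criterion

    GCV = (RSS / n) / (1 - C(M) / n)^2 ,

where the complexity ``C(M) = (#terms + 1) + d * (#distinct knots)`` charges
``d`` effective parameters per knot (d = 2 for linear/additive models, 3
when two-way interactions are searched).  Three model types are supported:
0 = linear entries only, 1 = additive hinge transformations, 2 = two-way
hinge interaction products.  A configurable entry penalty charges the
forward-pass lack-of-fit score for each *new* variable entering the model,
favoring re-use of variables already selected.

The forward knot search is exact but evaluated in vectorized form: given
the current fitted subspace (tracked as an orthonormal basis Q), the RSS
after adding the reflected pair at knot c equals the RSS after adding
``{x, max(0, x - c)}``, because the two spans coincide once an intercept is
present.  Projecting the whole knot-column matrix against Q in one BLAS
call then reduces each knot's score to a 2x2 solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .basis import HingeFactor, HingeTerm, SplineModel

__all__ = [
    "FitConfig",
    "ForwardResult",
    "GridResult",
    "gcv",
    "gcv_r2",
    "gcv_r2_from_stats",
    "candidate_knots",
    "forward_pass",
    "backward_pass",
    "fit",
    "cv_r2",
    "grid_search",
    "select_preferred",
]

_DEFAULT_MAX_BASIS = (10, 20, 30, 60)
_DEFAULT_PENALTIES = (0.0, 0.01)


@dataclass(frozen=True)
class FitConfig:
    """Control parameters for one spline fit."""

    model_type: int = 1  # 0 linear, 1 additive, 2 two-way interactions
    max_basis: int = 30  # number of initial basis functions (forward cap)
    entry_penalty: float = 0.0  # lack-of-fit charge per newly entered variable
    folds: int = 10
    seed: int = 0
    min_span: int = 3  # minimum observations between candidate knots
    d_additive: float = 2.0  # GCV cost per knot, model types 0/1
    d_interaction: float = 3.0  # GCV cost per knot, model type 2

    def __post_init__(self) -> None:
        if self.model_type not in (0, 1, 2):
            raise ValueError("model_type must be 0, 1 or 2")
        if self.max_basis < 2:
            raise ValueError("max_basis must be at least 2")
        if self.entry_penalty < 0:
            raise ValueError("entry_penalty must be nonnegative")
        if self.min_span < 1:
            raise ValueError("min_span must be at least 1")

    @property
    def knot_cost(self) -> float:
        return self.d_interaction if self.model_type == 2 else self.d_additive


# ---------------------------------------------------------------------------
# GCV statistics
# ---------------------------------------------------------------------------


def gcv(rss: float, n: int, complexity: float) -> float:
    """Generalized cross-validation: mean squared residual inflated by the
    squared complexity penalty.  ``complexity >= n`` signals an infinitely
    penalized (rejected) model."""
    if complexity < 0:
        raise ValueError("complexity must be nonnegative")
    if n <= 0:
        raise ValueError("n must be positive")
    if complexity >= n:
        return math.inf
    return (rss / n) / (1.0 - complexity / n) ** 2


def gcv_r2_from_stats(gcv_value: float, mean_total_ss: float) -> float:
    """Ordinary R-squared with the error variance replaced by GCV."""
    if mean_total_ss <= 0:
        raise ValueError("response has zero variance; GCV R2 undefined")
    return 1.0 - gcv_value / mean_total_ss


def gcv_r2(model: SplineModel, response: np.ndarray) -> float:
    y = np.asarray(response, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    return gcv_r2_from_stats(model.gcv, sst / len(y))


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def candidate_knots(x: np.ndarray, min_span: int = 3) -> np.ndarray:
    """Candidate knots: every ``min_span``-th order statistic, keeping at
    least ``min_span`` observations on each side of any knot.  Knots are
    always observed data values (exact search; no approximation)."""
    xs = np.sort(np.asarray(x, dtype=float))
    xs = xs[np.isfinite(xs)]
    n = xs.size
    if n < 2 * min_span + 1:
        return np.empty(0)
    vals = xs[min_span: n - min_span: min_span]
    return np.unique(vals)


@dataclass
class ForwardResult:
    terms: list[HingeTerm]
    rss_path: np.ndarray  # RSS after 0, 1, 2, ... forward additions
    columns: list[np.ndarray] = field(default_factory=list, repr=False)


def _best_knot_scores(Hp, wp, w2, r, tol):
    """Vectorized exact RSS decrease for the 2-D candidate span
    {h_perp(c), w_perp} at every knot c; falls back to the 1-D span when
    the pair is (numerically) collinear."""
    a = np.einsum("ij,ij->j", Hp, Hp)
    u = Hp.T @ r
    with np.errstate(divide="ignore", invalid="ignore"):
        dec1 = np.where(a > tol, u * u / np.where(a > tol, a, 1.0), -np.inf)
        if w2 > tol:
            b = Hp.T @ wp
            v = float(wp @ r)
            det = a * w2 - b * b
            dec2 = (u * u * w2 - 2.0 * u * v * b + v * v * a) / np.where(
                det > tol * w2, det, np.inf
            )
            dec = np.where(det > tol * w2, dec2, dec1)
        else:
            dec = dec1
    return dec


def forward_pass(
    table: pd.DataFrame, response: str, config: FitConfig
) -> ForwardResult:
    """Greedy forward selection of basis functions.

    Returns the ordered list of hinge terms (reflected pairs are added
    together; singletons may later survive the backward pass) and the RSS
    trajectory.  Deterministic given column order and config.
    """
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    cols = [c for c in table.columns if c != response]
    if len(cols) < 2:
        raise ValueError("need at least 2 candidate variables")
    arrays = {c: table[c].to_numpy(dtype=float) for c in cols}
    # drop constant columns up front
    cols = [c for c in cols if np.ptp(arrays[c]) > 0]

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        return ForwardResult([], np.array([0.0]))

    binary = {c: np.unique(arrays[c]).size <= 2 for c in cols}
    knots = {
        c: candidate_knots(arrays[c], config.min_span)
        for c in cols
        if not binary[c] and config.model_type >= 1
    }

    Q = np.ones((n, 1)) / math.sqrt(n)
    r = y - y.mean()
    rss = float(r @ r)
    tol = 1e-10 * max(sst, 1.0)
    col_tol = 1e-12

    terms: list[HingeTerm] = []
    columns: list[np.ndarray] = []
    model_vars: set[str] = set()
    rss_path = [rss]
    pen = config.entry_penalty

    def orth(v: np.ndarray) -> np.ndarray:
        w = v - Q @ (Q.T @ v)
        return w - Q @ (Q.T @ w)  # re-orthogonalize for stability

    while len(terms) < config.max_basis:
        room_for_pair = len(terms) + 2 <= config.max_basis
        best_score = rss / sst - 1e-12
        best = None  # (kind, payload, rss_new)
        for c in cols:
            x = arrays[c]
            xp = orth(x)
            x2 = float(xp @ xp)
            newvar = 0.0 if c in model_vars else 1.0
            if x2 > col_tol * float(x @ x):
                dec = float(xp @ r) ** 2 / x2
                score = (rss - dec) / sst + pen * newvar
                if score < best_score:
                    best_score, best = score, ("linear", (c,), rss - dec)
            if config.model_type >= 1 and not binary[c] and room_for_pair:
                K = knots.get(c, np.empty(0))
                if K.size:
                    H = np.maximum(0.0, x[:, None] - K[None, :])
                    Hp = H - Q @ (Q.T @ H)
                    dec = _best_knot_scores(Hp, xp, x2, r, tol)
                    j = int(np.argmax(dec))
                    if dec[j] > 0:
                        score = (rss - dec[j]) / sst + pen * newvar
                        if score < best_score:
                            best_score = score
                            best = ("pair", (c, float(K[j]), None), rss - dec[j])
                    if config.model_type == 2:
                        for pi, pterm in enumerate(terms):
                            if pterm.is_interaction or c in pterm.variables:
                                continue
                            pcol = columns[pi]
                            Hb = pcol[:, None] * H
                            Hbp = Hb - Q @ (Q.T @ Hb)
                            bx = pcol * x
                            bxp = orth(bx)
                            bx2 = float(bxp @ bxp)
                            deci = _best_knot_scores(Hbp, bxp, bx2, r, tol)
                            ji = int(np.argmax(deci))
                            if deci[ji] > 0:
                                score = (rss - deci[ji]) / sst + pen * newvar
                                if score < best_score:
                                    best_score = score
                                    best = (
                                        "pair",
                                        (c, float(K[ji]), pi),
                                        rss - deci[ji],
                                    )
            elif config.model_type == 2 and binary[c]:
                # binary child: interaction enters linearly in the child
                for pi, pterm in enumerate(terms):
                    if pterm.is_interaction or c in pterm.variables:
                        continue
                    bx = columns[pi] * x
                    bxp = orth(bx)
                    bx2 = float(bxp @ bxp)
                    if bx2 > col_tol * max(float(bx @ bx), 1.0):
                        dec = float(bxp @ r) ** 2 / bx2
                        score = (rss - dec) / sst + pen * newvar
                        if score < best_score:
                            best_score = score
                            best = ("ilinear", (c, pi), rss - dec)
        if best is None:
            break
        kind, payload, rss_target = best
        if rss - rss_target <= tol:
            break

        new_terms: list[HingeTerm]
        if kind == "linear":
            (c,) = payload
            new_terms = [HingeTerm((HingeFactor(c),))]
        elif kind == "ilinear":
            c, pi = payload
            new_terms = [HingeTerm(terms[pi].factors + (HingeFactor(c),))]
        else:
            c, knot, pi = payload
            parent = terms[pi].factors if pi is not None else ()
            new_terms = [
                HingeTerm(parent + (HingeFactor(c, knot, "+"),)),
                HingeTerm(parent + (HingeFactor(c, knot, "-"),)),
            ]
        for t in new_terms:
            col = t.evaluate(arrays)
            terms.append(t)
            columns.append(col)
            model_vars.update(t.variables)
            q = orth(col)
            nq = float(np.linalg.norm(q))
            if nq > 1e-9 * (np.linalg.norm(col) + 1.0):
                q = q / nq
                Q = np.hstack([Q, q[:, None]])
                r = r - q * float(q @ r)
        rss = float(r @ r)
        rss_path.append(rss)
    return ForwardResult(terms, np.asarray(rss_path), columns)


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------


def _lstsq(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def _distinct_knots(terms: Sequence[HingeTerm]) -> int:
    return len(
        {
            (f.variable, f.knot)
            for t in terms
            for f in t.factors
            if f.knot is not None
        }
    )


def backward_pass(
    terms: Sequence[HingeTerm],
    table: pd.DataFrame,
    response: str,
    config: FitConfig,
) -> SplineModel:
    """Prune forward-pass terms one at a time (least RSS increase first)
    and return the subset with minimal GCV."""
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))
    arrays = {c: table[c].to_numpy(dtype=float) for c in table.columns}
    terms = list(terms)
    cols = [t.evaluate(arrays) for t in terms]
    B = np.column_stack([np.ones(n)] + cols) if terms else np.ones((n, 1))
    d = config.knot_cost

    active = list(range(len(terms)))
    best: tuple[float, list[int], np.ndarray, float] | None = None
    while True:
        Bc = B[:, [0] + [i + 1 for i in active]]
        coef, rss = _lstsq(Bc, y)
        complexity = (len(active) + 1) + d * _distinct_knots([terms[i] for i in active])
        g = gcv(rss, n, complexity)
        if best is None or g < best[0]:
            best = (g, active.copy(), coef, rss)
        if not active:
            break
        gram_inv = np.linalg.pinv(Bc.T @ Bc)
        diag = np.diag(gram_inv)[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(diag > 1e-12, coef[1:] ** 2 / np.where(diag > 1e-12, diag, 1.0), 0.0)
        active.pop(int(np.argmin(inc)))

    g, sel, coef, rss = best
    chosen = [terms[i] for i in sel]
    complexity = (len(chosen) + 1) + d * _distinct_knots(chosen)
    model = SplineModel(
        intercept=float(coef[0]),
        terms=[(t, float(c)) for t, c in zip(chosen, coef[1:])],
        rss=rss,
        n=n,
        complexity=complexity,
        gcv=g,
        gcv_r2=gcv_r2_from_stats(g, sst / n) if sst > 0 else float("nan"),
        model_type=config.model_type,
    )
    return model


def fit(table: pd.DataFrame, response: str, config: FitConfig) -> SplineModel:
    """Forward pass followed by GCV-pruning backward pass."""
    fwd = forward_pass(table, response, config)
    return backward_pass(fwd.terms, table, response, config)


# ---------------------------------------------------------------------------
# cross-validation and grid search
# ---------------------------------------------------------------------------


def cv_r2(table: pd.DataFrame, response: str, config: FitConfig) -> float:
    """Pooled k-fold cross-validated R-squared of the full fit procedure."""
    n = len(table)
    if n < config.folds:
        raise ValueError(f"n={n} is smaller than folds={config.folds}")
    y = table[response].to_numpy(dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    press = 0.0
    for tr, te in kf.split(y):
        model = fit(table.iloc[tr].reset_index(drop=True), response, config)
        pred = model.predict(table.iloc[te])
        press += float(np.sum((y[te] - pred) ** 2))
    return 1.0 - press / sst


@dataclass
class GridResult:
    set_name: str
    config: FitConfig
    model: SplineModel
    gcv_r2: float
    n_params: int
    n_vars: int
    order: int = 0  # insertion index; stable tie-break


def grid_search(
    table: pd.DataFrame,
    response: str,
    predictor_sets: Mapping[str, Sequence[str]],
    model_types: Sequence[int] = (0, 1, 2),
    max_basis_values: Sequence[int] = _DEFAULT_MAX_BASIS,
    entry_penalties: Sequence[float] = _DEFAULT_PENALTIES,
    min_span: int = 3,
    seed: int = 0,
) -> list[GridResult]:
    """Fit one spline model per (predictor set x model type x max basis x
    entry penalty) grid cell; the default grid has 3x3x4x2 = 72 cells."""
    out: list[GridResult] = []
    for set_name, variables in predictor_sets.items():
        sub = table[[*variables, response]]
        for mt in model_types:
            for mb in max_basis_values:
                for pen in entry_penalties:
                    cfg = FitConfig(
                        model_type=mt,
                        max_basis=mb,
                        entry_penalty=pen,
                        min_span=min_span,
                        seed=seed,
                    )
                    model = fit(sub, response, cfg)
                    out.append(
                        GridResult(
                            set_name=set_name,
                            config=cfg,
                            model=model,
                            gcv_r2=model.gcv_r2,
                            n_params=model.n_params,
                            n_vars=len(model.variables),
                            order=len(out),
                        )
                    )
    return out


def select_preferred(
    results: Sequence[GridResult], tolerance: float = 0.01
) -> GridResult:
    """Goodness-of-fit/parsimony rule: among models whose GCV R-squared is
    within ``tolerance`` of the best, prefer fewest distinct variables,
    then fewest parameters, then the simplest model type."""
    if not results:
        raise ValueError("empty grid results")
    best_r2 = max(r.gcv_r2 for r in results)
    candidates = [r for r in results if r.gcv_r2 >= best_r2 - tolerance]
    return min(
        candidates,
        key=lambda r: (r.n_vars, r.n_params, r.config.model_type, r.order),
    )


def grid_results_frame(results: Sequence[GridResult]) -> pd.DataFrame:
    """Grid records as a table (one row per cell), sortable by GCV R2."""
    return pd.DataFrame(
        {
            "set": r.set_name,
            "model_type": r.config.model_type,
            "max_basis": r.config.max_basis,
            "entry_penalty": r.config.entry_penalty,
            "gcv_r2": r.gcv_r2,
            "n_params": r.n_params,
            "n_vars": r.n_vars,
        }
        for r in results
    )
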