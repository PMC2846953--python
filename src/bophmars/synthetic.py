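"""Seeded synthetic cohort generator for the biomarker modeling pipeline.

The generator emulates a cross-sectional exposure study of adult cigarette
smokers and nonsmokers: exposure biomarkers (BOE) that are stochastically
larger in smokers and frequently below the limit of quantification (BLLOQ)
in nonsmokers, correlated clinical-laboratory covariates, categorical
demographics/lifestyle variables, sparse completely-at-random missingness,
and four response biomarkers of potential harm (DEH11, EPI8, WBC, HDL)
generated from the reference threshold-basis models with Gaussian noise
calibrated so that each model's population R-squared matches its nominal
value.

Joint predictor structure is a Gaussian copula: a latent multivariate
normal vector is mapped through per-variable marginal quantile transforms
(log-normal for biomarkers and urine outputs, normal for most labs and
anthropometrics, probability-threshold coding for categoricals).  This
preserves rank correlations, keeps generation deterministic for a given
seed, and is simple to document; it makes no claim of fidelity to any real
study's marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .basis import ThresholdModel
from .metadata import (
    ID_COLUMN,
    PARTITION_COLUMN,
    SMOKING_COLUMN,
    Cohort,
    VariableMeta,
)
from .reference_models import REFERENCE_MODELS, REFERENCE_R2

__all__ = [
    "PredictorSpec",
    "GeneratorConfig",
    "calibrate_noise_variance",
    "apply_generating_model",
    "generate_cohort",
    "inject_missingness_and_blloq",
    "default_predictor_specs",
    "small_predictor_specs",
    "default_config",
    "small_config",
]

RESPONSES = ("DEH11", "EPI8", "WBC", "HDL")

#: labs given a default latent correlation with the exposure biomarkers
_SMOKING_LABS = ("CRP", "TRIG", "HGB")


@dataclass(frozen=True)
class PredictorSpec:
    """Marginal distribution and metadata for one generated variable.

    Distribution parameters may be scalars (shared) or ``(nonsmoker,
    smoker)`` pairs.  Kinds:

    ``lognormal``
        params ``median`` and ``sigma`` (log-scale SD).
    ``normal``
        params ``mean`` and ``sd``; optional ``clip=(lo, hi)``.
    ``mixture_lognormal``
        param ``components``: sequence of ``(weight, median, sigma)`` —
        used for labs with a heavy pathological tail (AST, ALKPH).
    ``categorical``
        params ``levels`` and ``probs``; ``vtype`` distinguishes nominal
        from ordinal (ordinal levels are ordered).
    """

    name: str
    kind: str
    vtype: str = "continuous"
    role: str = "covariate"
    units: str = ""
    group: str = ""
    blloq: bool = False
    params: Mapping = field(default_factory=dict)

    def per_group(self, key: str, smoker: bool):
        val = self.params[key]
        if isinstance(val, tuple) and len(val) == 2 and self.kind != "categorical":
            return val[1] if smoker else val[0]
        return val


def _ln(name, median, sigma, *, units="", role="covariate", blloq=False, group=""):
    return PredictorSpec(
        name, "lognormal", role=role, units=units, blloq=blloq, group=group,
        params={"median": median, "sigma": sigma},
    )


def _nm(name, mean, sd, *, units="", clip=None, group=""):
    return PredictorSpec(
        name, "normal", units=units, group=group,
        params={"mean": mean, "sd": sd, "clip": clip},
    )


def _cat(name, levels, probs, *, vtype="nominal", units="", group=""):
    return PredictorSpec(
        name, "categorical", vtype=vtype, units=units, group=group,
        params={"levels": tuple(levels), "probs": tuple(probs)},
    )


def _boe_specs() -> list[PredictorSpec]:
    """Nine exposure biomarkers, log-normal, elevated in smokers."""
    rows = [
        # name, nonsmoker median, smoker median, (ns sigma, sm sigma), units
        ("HPMA3", 320.0, 1600.0, (0.6, 0.6), "ug/24 hr urine"),
        ("DHBMA", 350.0, 620.0, (0.5, 0.5), "ug/24 hr urine"),
        ("MHBMA", 2.2, 30.0, (0.8, 0.8), "ug/24 hr urine"),
        ("NICEQ", 0.06, 12.0, (0.9, 0.6), "mg/24 hr urine"),
        ("COTIN", 1.2, 210.0, (0.8, 0.6), "ng/mL"),
        ("OHP", 90.0, 260.0, (0.6, 0.6), "ng/24 hr urine"),
        ("TOTNN", 16.0, 300.0, (0.8, 0.7), "ng/24 hr urine"),
        ("ABP", 28.0, 85.0, (0.5, 0.5), "pg/g Hb"),
        ("COHB", 0.9, 5.2, (0.5, 0.5), "%"),
    ]
    return [
        _ln(n, (m0, m1), s, units=u, role="boe", blloq=True)
        for n, m0, m1, s, u in rows
    ]


def _core_lab_specs() -> list[PredictorSpec]:
    """Labs referenced by at least one reference model, plus serum
    creatinine (needed for the creatinine-clearance quotient)."""
    return [
        _ln("UCRCAL", 1400.0, 0.35, units="mg/24 hr urine"),
        _ln("SCREAT", 0.95, 0.18, units="mg/dL"),
        PredictorSpec(
            "AST", "mixture_lognormal", units="U/L",
            params={"components": ((0.97, 24.0, 0.30), (0.03, 80.0, 0.50))},
        ),
        PredictorSpec(
            "ALKPH", "mixture_lognormal", units="U/L",
            params={"components": ((0.97, 75.0, 0.22), (0.03, 160.0, 0.40))},
        ),
        _ln("TRIG", 115.0, 0.55, units="mg/dL"),
        _ln("CRP", 1.8, 1.0, units="mg/L"),
        _nm("PLATE", 250.0, 60.0, units="x10^3/uL", clip=(80.0, 600.0)),
        _nm("HGB", 14.5, 1.4, units="g/dL", clip=(8.0, 20.0)),
    ]


def _demo_lifestyle_specs() -> list[PredictorSpec]:
    return [
        _nm("AGE", 43.0, 12.0, units="Yrs", clip=(21.0, 75.0)),
        _nm("WEIGHTK", 80.0, 16.0, units="kg", clip=(45.0, 160.0)),
        _cat("SEX", ("F", "M"), (0.45, 0.55)),
        _cat(
            "RACE",
            ("CAUCASIAN", "BLACK", "ASIAN", "NATIVE.AMER", "MULTI.RACIAL", "OTHER"),
            (0.66, 0.20, 0.04, 0.02, 0.03, 0.05),
        ),
        _cat(
            "DRINK",
            ("NO", "LT.1.PER.WK", "1.PER.WK", "GT.1.PER.WK", "DAILY"),
            (0.30, 0.25, 0.15, 0.20, 0.10),
            vtype="ordinal",
        ),
        _cat("VITAMIN", ("NO", "YES"), (0.65, 0.35)),
        _cat("NSAID", ("NO", "YES"), (0.75, 0.25)),
    ]


def small_predictor_specs() -> list[PredictorSpec]:
    """Compact 25-predictor schema (plus derived CRCL counted within the
    25) for fast end-to-end pipeline runs."""
    return _boe_specs() + _core_lab_specs() + _demo_lifestyle_specs()


def default_predictor_specs() -> list[PredictorSpec]:
    """Full default schema (~60 variables including responses): the compact
    core plus decoy labs, vitals, respiratory measures and questionnaire
    items that never enter a generating model."""
    decoy_labs = [
        _ln("ALT", 25.0, 0.4, units="U/L"),
        _ln("GGT", 25.0, 0.5, units="U/L"),
        _nm("BUN", 14.0, 4.0, units="mg/dL", clip=(4.0, 40.0)),
        _nm("GLUC", 95.0, 15.0, units="mg/dL", clip=(55.0, 300.0)),
        _nm("CHOL", 195.0, 35.0, units="mg/dL", clip=(90.0, 400.0)),
        _nm("RBC", 4.8, 0.45, units="x10^6/uL", clip=(3.0, 7.0)),
        _ln("BILI", 0.6, 0.4, units="mg/dL"),
        _nm("ALB", 4.4, 0.3, units="g/dL", clip=(2.5, 6.0)),
        _nm("SODIUM", 140.0, 2.5, units="mmol/L"),
        _nm("POTAS", 4.2, 0.35, units="mmol/L"),
        _nm("CALC", 9.4, 0.4, units="mg/dL"),
    ]
    vitals = [
        _nm("RESP", 16.0, 2.0, units="breaths/min", clip=(8.0, 30.0)),
        _nm("TEMP", 36.7, 0.3, units="degC"),
        _nm("SYSBP", 122.0, 14.0, units="mmHg", clip=(85.0, 220.0)),
        _nm("DIABP", 76.0, 9.0, units="mmHg", clip=(45.0, 130.0)),
        _nm("PULSE", 72.0, 10.0, units="bpm", clip=(40.0, 140.0)),
        _nm("FVC", 4.1, 0.9, units="L", clip=(1.5, 7.5)),
        _nm("FEV1", 3.2, 0.8, units="L", clip=(1.0, 6.0)),
        _nm("HEIGHT", 170.0, 10.0, units="cm", clip=(140.0, 210.0)),
    ]
    questionnaire = [
        _cat("EXHAUST.EXP", ("NONE", "SOME", "HIGH"), (0.6, 0.3, 0.1), vtype="ordinal"),
        _cat("CHEM.EXP", ("NONE", "SOME", "HIGH"), (0.7, 0.2, 0.1), vtype="ordinal"),
        _cat(
            "GENHEALTH", ("POOR", "FAIR", "GOOD", "EXCELLENT"),
            (0.05, 0.25, 0.5, 0.2), vtype="ordinal",
        ),
        _cat(
            "INCOME", ("LT25K", "25.50K", "50.75K", "GT75K"),
            (0.3, 0.35, 0.2, 0.15), vtype="ordinal",
        ),
        _cat(
            "EDUC", ("HS.OR.LESS", "SOME.COLLEGE", "COLLEGE", "GRADUATE"),
            (0.35, 0.3, 0.25, 0.1), vtype="ordinal",
        ),
        _cat("EXERCISE", ("NONE", "OCCASIONAL", "REGULAR"), (0.4, 0.4, 0.2), vtype="ordinal"),
    ]
    return small_predictor_specs() + decoy_labs + vitals + questionnaire


def default_latent_correlations(
    specs: Sequence[PredictorSpec],
) -> list[tuple[str, str, float]]:
    """0.5 among the exposure biomarkers, 0.3 between each BOE and the
    smoking-related labs, 0 elsewhere: realistic collinearity for the
    screening stage without claiming fidelity to any real study."""
    names = {s.name for s in specs}
    boe = [s.name for s in specs if s.role == "boe"]
    out: list[tuple[str, str, float]] = []
    for i, a in enumerate(boe):
        for b in boe[i + 1:]:
            out.append((a, b, 0.5))
    for a in boe:
        for lab in _SMOKING_LABS:
            if lab in names:
                out.append((a, lab, 0.3))
    return out


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    n_smokers: int = 3585
    n_nonsmokers: int = 1077
    predictor_specs: list[PredictorSpec] = field(default_factory=default_predictor_specs)
    generating_models: Mapping[str, ThresholdModel] = field(
        default_factory=lambda: dict(REFERENCE_MODELS)
    )
    target_r2: Mapping[str, float] = field(default_factory=lambda: dict(REFERENCE_R2))
    missing_rate: float = 0.02
    blloq_rate_nonsmokers: float = 0.6
    blloq_drop_prob: float = 0.5
    #: empirical calibration: the drawn noise vector is centered, made
    #: exactly orthogonal to the linear predictor and rescaled to exactly
    #: its calibrated SD, so the cohort-level R2 equals the target by
    #: construction (the mvrnorm empirical=TRUE convention)
    empirical_noise: bool = True
    latent_correlations: list[tuple[str, str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_smokers < 0 or self.n_nonsmokers < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_smokers + self.n_nonsmokers <= 0:
            raise ValueError("cohort must contain at least one subject")
        if not 0.0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if not 0.0 <= self.blloq_rate_nonsmokers < 1.0:
            raise ValueError("blloq_rate_nonsmokers must lie in [0, 1)")
        if not 0.0 <= self.blloq_drop_prob <= 1.0:
            raise ValueError("blloq_drop_prob must lie in [0, 1]")
        for resp, r2 in self.target_r2.items():
            if not 0.0 < r2 <= 1.0:
                raise ValueError(f"target_r2[{resp}] must lie in (0, 1]")
        names = {s.name for s in self.predictor_specs}
        names |= {"CRCL", "SMKYRS", SMOKING_COLUMN}
        for resp, model in self.generating_models.items():
            for var in model.variables:
                if var not in names:
                    raise ValueError(
                        f"generating model for {resp} references unknown "
                        f"variable {var!r}"
                    )
        if self.latent_correlations is None:
            self.latent_correlations = default_latent_correlations(
                self.predictor_specs
            )


def default_config(seed: int = 0, **kw) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, **kw)


def small_config(seed: int = 0, n_smokers: int = 615, n_nonsmokers: int = 185, **kw) -> GeneratorConfig:
    """800-subject, 25-predictor cohort for fast pipeline runs (group sizes
    keep the default smoker:nonsmoker ratio)."""
    return GeneratorConfig(
        n_smokers=n_smokers,
        n_nonsmokers=n_nonsmokers,
        predictor_specs=small_predictor_specs(),
        seed=seed,
        **kw,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def calibrate_noise_variance(linear_predictor_variance: float, target_r2: float) -> float:
    """Noise variance that makes ``target_r2`` the population R-squared.

    With V = Var(linear predictor) and independent Gaussian noise of
    variance s2, the population R-squared is V / (V + s2); solving gives
    s2 = V (1 - R2) / R2.
    """
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError("target_r2 must lie in (0, 1]")
    if linear_predictor_variance < 0:
        raise ValueError("variance must be nonnegative")
    return linear_predictor_variance * (1.0 - target_r2) / target_r2


def apply_generating_model(
    model: ThresholdModel,
    table: pd.DataFrame,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    meta: Mapping[str, VariableMeta] | None = None,
) -> np.ndarray:
    """Evaluate a generating model and add Gaussian noise.

    With ``noise_sd = 0`` the output is an exact deterministic function of
    the predictors.  Raises ``KeyError`` if the model references a variable
    absent from ``table``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lp = model.evaluate(table, meta=meta)
    if noise_sd == 0:
        return lp
    return lp + rng.normal(0.0, noise_sd, size=len(lp))


def _build_meta(specs: Sequence[PredictorSpec]) -> dict[str, VariableMeta]:
    meta: dict[str, VariableMeta] = {}
    for s in specs:
        meta[s.name] = VariableMeta(
            name=s.name,
            role=s.role,
            vtype=s.vtype,
            units=s.units,
            group=s.group or s.name,
            levels=tuple(s.params["levels"]) if s.kind == "categorical" else None,
            blloq_flag_column=f"{s.name}_BLLOQ" if s.blloq else None,
        )
    meta["CRCL"] = VariableMeta(
        "CRCL", "covariate", "continuous", units="dL/day",
        group="UCRCAL/CRCL",
    )
    meta["UCRCAL"] = replace(meta["UCRCAL"], group="UCRCAL/CRCL")
    meta["SMKYRS"] = VariableMeta("SMKYRS", "covariate", "continuous", units="Yrs")
    units = {"DEH11": "ng/24 hr urine", "EPI8": "ng/24 hr urine",
             "WBC": "x10^3/uL", "HDL": "ng/dL"}
    for resp in RESPONSES:
        meta[resp] = VariableMeta(resp, "response", "continuous", units=units[resp])
    return meta


def _latent_matrix(
    specs: Sequence[PredictorSpec],
    entries: Sequence[tuple[str, str, float]],
) -> np.ndarray:
    names = [s.name for s in specs]
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for a, b, rho in entries:
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-8:
        raise ValueError("latent correlation matrix is not positive semi-definite")
    return corr


def _sample_group(
    specs: Sequence[PredictorSpec],
    chol: np.ndarray,
    n: int,
    smoker: bool,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    z = rng.standard_normal((n, len(specs))) @ chol.T
    u = None
    cols: dict[str, np.ndarray] = {}
    for j, s in enumerate(specs):
        zj = z[:, j]
        if s.kind == "lognormal":
            med = s.per_group("median", smoker)
            sig = s.per_group("sigma", smoker)
            cols[s.name] = np.exp(math.log(med) + sig * zj)
        elif s.kind == "normal":
            mean = s.per_group("mean", smoker)
            sd = s.per_group("sd", smoker)
            x = mean + sd * zj
            clip = s.params.get("clip")
            if clip:
                x = np.clip(x, clip[0], clip[1])
            cols[s.name] = x
        elif s.kind == "mixture_lognormal":
            comps = s.params["components"]
            w = np.array([c[0] for c in comps])
            pick = rng.choice(len(comps), size=n, p=w / w.sum())
            med = np.array([c[1] for c in comps])[pick]
            sig = np.array([c[2] for c in comps])[pick]
            cols[s.name] = np.exp(np.log(med) + sig * zj)
        elif s.kind == "categorical":
            from scipy.stats import norm

            if u is None:
                u = norm.cdf(z)
            probs = np.asarray(s.per_group("probs", smoker), dtype=float)
            cum = np.cumsum(probs / probs.sum())
            k = np.searchsorted(cum, u[:, j], side="right")
            k = np.clip(k, 0, len(probs) - 1)
            levels = np.asarray(s.params["levels"], dtype=object)
            cols[s.name] = levels[k]
        else:
            raise ValueError(f"unknown marginal kind {s.kind!r}")
    return cols


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate the full seeded cohort (responses populated, missingness
    and BLLOQ flags injected per the config rates)."""
    rng = np.random.default_rng(config.seed)
    specs = config.predictor_specs
    corr = _latent_matrix(specs, config.latent_correlations or [])
    # tiny jitter guards Cholesky against exactly-singular PSD inputs
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))

    frames = []
    for smoker, n in ((True, config.n_smokers), (False, config.n_nonsmokers)):
        if n == 0:
            continue
        cols = _sample_group(specs, chol, n, smoker, rng)
        df = pd.DataFrame(cols)
        df.insert(0, SMOKING_COLUMN, int(smoker))
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    n_total = len(data)
    data.insert(0, ID_COLUMN, [f"S{i + 1:05d}" for i in range(n_total)])

    # derived variables
    data["CRCL"] = data["UCRCAL"] / data["SCREAT"]
    smkyrs = np.where(
        data[SMOKING_COLUMN] == 1,
        np.clip(
            0.72 * (data["AGE"] - 18.0) + rng.normal(0.0, 4.0, n_total), 0.5, None
        ),
        0.0,
    )
    data["SMKYRS"] = np.round(smkyrs, 1)

    meta = _build_meta(specs)
    # responses from the generating models, noise calibrated to target R2
    for resp in RESPONSES:
        if resp not in config.generating_models:
            continue
        model = config.generating_models[resp]
        lp = model.evaluate(data, meta=meta)
        v = float(np.var(lp))
        sigma2 = calibrate_noise_variance(v, config.target_r2[resp])
        if config.empirical_noise and sigma2 > 0 and n_total > 2:
            eps = rng.standard_normal(n_total)
            lpc = lp - lp.mean()
            eps = eps - eps.mean()
            eps -= (lpc @ eps) / (lpc @ lpc) * lpc
            eps *= math.sqrt(sigma2) / eps.std()
            data[resp] = lp + eps
        else:
            data[resp] = apply_generating_model(
                model, data, math.sqrt(sigma2), seed=rng, meta=meta
            )

    data[PARTITION_COLUMN] = "unassigned"
    cohort = Cohort(data, meta)
    return inject_missingness_and_blloq(cohort, config, rng=rng)


def inject_missingness_and_blloq(
    cohort: Cohort,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Set BLLOQ flags for exposure biomarkers and mask predictors MCAR.

    Values below the per-variable quantification threshold (the nonsmoker
    ``blloq_rate_nonsmokers`` quantile) are flagged; flagged values are
    removed with probability ``blloq_drop_prob`` and retained otherwise,
    so both branches of the downstream BLLOQ substitution rule occur.
    Responses are never masked.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    data = cohort.data.copy()
    meta = dict(cohort.meta)
    n = len(data)

    nonsmoker = data[SMOKING_COLUMN] == 0
    for name, m in cohort.meta.items():
        if not m.blloq_flag_column:
            continue
        vals = data[name].to_numpy(dtype=float)
        ref = vals[nonsmoker.to_numpy()] if nonsmoker.any() else vals
        if config.blloq_rate_nonsmokers > 0 and len(ref):
            thr = np.quantile(ref, config.blloq_rate_nonsmokers)
            flag = vals < thr
        else:
            flag = np.zeros(n, dtype=bool)
        drop = flag & (rng.random(n) < config.blloq_drop_prob)
        vals[drop] = np.nan
        data[name] = vals
        data[m.blloq_flag_column] = flag.astype(int)

    if config.missing_rate > 0:
        for name, m in cohort.meta.items():
            if m.role == "response":
                continue
            mask = rng.random(n) < config.missing_rate
            if mask.any():
                if m.vtype == "continuous":
                    col = data[name].to_numpy(dtype=float)
                    col[mask] = np.nan
                    data[name] = col
                else:
                    col = data[name].astype("object")
                    col[mask] = np.nan
                    data[name] = col
    return Cohort(data, meta)
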