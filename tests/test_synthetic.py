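"""Generator: noise calibration, generating-model evaluation, cohort
structure, determinism, and missingness/BLLOQ injection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bophmars.basis import ThresholdBasis, ThresholdModel, ThresholdTerm
from bophmars.reference_models import REFERENCE_MODELS, REFERENCE_R2
from bophmars.synthetic import (
    GeneratorConfig,
    apply_generating_model,
    calibrate_noise_variance,
    default_config,
    generate_cohort,
    small_config,
    _build_meta,
    small_predictor_specs,
)


@pytest.mark.parametrize(
    "v, r2, expected",
    [(4.0, 1.0, 0.0), (4.0, 0.5, 4.0), (9.0, 0.9, 1.0)],
)
def test_calibrate_noise_variance(v, r2, expected):
    # oracle: solve V / (V + s2) = R2  =>  s2 = V (1 - R2) / R2
    assert calibrate_noise_variance(v, r2) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
def test_calibrate_noise_variance_rejects_bad_r2(bad):
    with pytest.raises(ValueError):
        calibrate_noise_variance(4.0, bad)


def test_hdl_model_hand_evaluation():
    """One subject evaluated against the HDL generating model by hand
    under threshold semantics (IFGT = max, IFLT = min):

    55.4292 - 0.0291*31 + 0.0258*193 - 0.5819*100 + 0.483*100
    + 0.0753*177 - 0.267*76 - 0.0834*76 + 0.3119*40 + 6.72 = 55.5102
    """
    meta = _build_meta(small_predictor_specs())
    row = pd.DataFrame(
        {
            "COTIN": [0.0],
            "TRIG": [100.0],
            "WEIGHTK": [76.0],
            "AGE": [40.0],
            "SEX": ["F"],
            "DRINK": ["NO"],
        }
    )
    out = apply_generating_model(REFERENCE_MODELS["HDL"], row, 0.0, meta=meta)
    assert out[0] == pytest.approx(55.5102, abs=1e-6)


def test_all_zero_bases_return_intercept():
    model = ThresholdModel(
        7.25, [ThresholdTerm(ThresholdBasis("SEX", "EQ", "F"), 3.0)]
    )
    out = apply_generating_model(model, pd.DataFrame({"SEX": ["M"]}), 0.0)
    assert out[0] == 7.25


def test_missing_model_variable_is_schema_error():
    with pytest.raises(KeyError, match="absent variable"):
        apply_generating_model(
            REFERENCE_MODELS["WBC"], pd.DataFrame({"TOTNN": [10.0]}), 0.0
        )


def test_r2_calibration_monte_carlo(rng):
    """At n = 1e5 the sample R2 of the response on its true linear
    predictor is within 0.01 of the target (iid-noise path)."""
    n = 100_000
    meta = _build_meta(small_predictor_specs())
    tab = pd.DataFrame(
        {
            "COTIN": np.exp(rng.normal(np.log(50), 1.2, n)),
            "TRIG": np.exp(rng.normal(np.log(115), 0.55, n)),
            "WEIGHTK": rng.normal(80, 16, n),
            "AGE": rng.uniform(21, 75, n),
            "SEX": np.where(rng.random(n) < 0.45, "F", "M"),
            "DRINK": rng.choice(
                ["NO", "LT.1.PER.WK", "1.PER.WK", "GT.1.PER.WK", "DAILY"], n
            ),
        }
    )
    model = REFERENCE_MODELS["HDL"]
    lp = model.evaluate(tab, meta=meta)
    target = 0.39
    s2 = calibrate_noise_variance(float(np.var(lp)), target)
    y = apply_generating_model(model, tab, np.sqrt(s2), seed=7, meta=meta)
    resid = y - lp - (y - lp).mean()
    r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    assert r2 == pytest.approx(target, abs=0.01)


def test_default_cohort_counts(default_cohort):
    data = default_cohort.data
    assert len(data) == 4662
    assert int((data["SMOKE"] == 1).sum()) == 3585
    for resp in ("DEH11", "EPI8", "WBC", "HDL"):
        assert data[resp].notna().all()
    assert data["PARTITION"].eq("unassigned").all()


def test_generation_is_deterministic():
    a = generate_cohort(small_config(seed=5))
    b = generate_cohort(small_config(seed=5))
    pd.testing.assert_frame_equal(a.data, b.data)
    c = generate_cohort(small_config(seed=6))
    assert not a.data["HDL"].equals(c.data["HDL"])


def test_boe_stochastically_larger_in_smokers(default_cohort):
    data = default_cohort.data
    smoker = data["SMOKE"] == 1
    for b in default_cohort.boe:
        x = data.loc[smoker, b].dropna()
        y = data.loc[~smoker, b].dropna()
        p = stats.mannwhitneyu(x, y, alternative="greater").pvalue
        assert p < 1e-3, f"{b} not elevated in smokers (p={p:.2g})"


def test_zero_rates_leave_cohort_complete():
    c = generate_cohort(
        small_config(seed=2, missing_rate=0.0, blloq_rate_nonsmokers=0.0)
    )
    pred = [n for n, m in c.meta.items() if m.role != "response"]
    assert not c.data[pred].isna().any().any()
    flags = [m.blloq_flag_column for m in c.meta.values() if m.blloq_flag_column]
    assert c.data[flags].to_numpy().sum() == 0


def test_mcar_rate_within_binomial_ci():
    rate = 0.05
    c = generate_cohort(
        small_config(
            seed=3, n_smokers=800, n_nonsmokers=200,
            missing_rate=rate, blloq_rate_nonsmokers=0.0,
        )
    )
    cont = [
        n for n, m in c.meta.items()
        if m.role != "response" and m.vtype == "continuous"
        and n not in ("CRCL", "SMKYRS")  # derived, not independently masked
    ]
    cells = c.data[cont].size
    observed = int(c.data[cont].isna().sum().sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], cells, rate)
    assert lo <= observed <= hi


def test_blloq_injection_exercises_both_branches(default_cohort):
    data = default_cohort.data
    for name, m in default_cohort.meta.items():
        if not m.blloq_flag_column:
            continue
        flagged = data[m.blloq_flag_column] == 1
        assert (flagged & data[name].isna()).any(), f"{name}: no dropped branch"
        assert (flagged & data[name].notna()).any(), f"{name}: no retained branch"
        # unflagged exposure values are never masked by the BLLOQ mechanism
        assert flagged.mean() > 0.05


def test_noiseless_responses_match_independent_evaluator():
    """With target R2 = 1 (zero noise) the stored responses equal an
    independent re-evaluation of the generating models."""
    cfg = small_config(
        seed=4, missing_rate=0.0, blloq_rate_nonsmokers=0.0,
        target_r2={k: 1.0 for k in REFERENCE_R2},
    )
    c = generate_cohort(cfg)
    d = c.data

    def ind(v):  # independent indicator helper
        return v.astype(float)

    # hand-coded evaluation, written independently of ThresholdModel
    deh11 = (
        -4045.3022
        + 1.4494 * np.maximum(d.COTIN, 11)
        + 0.3531 * np.minimum(d.UCRCAL, 3036)
        + 0.3698 * np.minimum(d.CRCL, 4325)
        + 17.9064 * np.maximum(d.AST, 25)
        - 18.2428 * np.maximum(d.AST, 126)
        + 3.1360 * np.minimum(d.ALKPH, 184)
        + 30.7979 * np.maximum(d.ALKPH, 184)
        - 346.0560 * ind(d.NSAID == "YES")
        - 211.7183 * ind(d.VITAMIN == "YES")
    )
    np.testing.assert_allclose(d.DEH11, deh11, atol=1e-8)
    hdl = (
        55.4292
        - 0.0291 * np.maximum(d.COTIN, 31)
        + 0.0258 * np.maximum(d.COTIN, 193)
        - 0.5819 * np.maximum(d.TRIG, 52)
        + 0.483 * np.maximum(d.TRIG, 64)
        + 0.0753 * np.maximum(d.TRIG, 177)
        - 0.267 * np.minimum(d.WEIGHTK, 76)
        - 0.0834 * np.maximum(d.WEIGHTK, 76)
        + 0.3119 * np.minimum(d.AGE, 55)
        + 6.72 * ind(d.SEX == "F")
        + 2.0567 * ind(d.DRINK != "NO")
        + 7.875 * ind(d.DRINK.isin(["GT.1.PER.WK", "DAILY"]))
    )
    np.testing.assert_allclose(d.HDL, hdl, atol=1e-8)


def test_config_validation_errors():
    with pytest.raises(ValueError, match="positive semi-definite"):
        generate_cohort(
            small_config(seed=0, latent_correlations=[("COTIN", "TOTNN", 2.0)])
        )
    bad_model = {
        "HDL": ThresholdModel(
            0.0, [ThresholdTerm(ThresholdBasis("NOPE", "LINEAR", None), 1.0)]
        )
    }
    with pytest.raises(ValueError, match="unknown variable"):
        GeneratorConfig(generating_models=bad_model, target_r2={"HDL": 0.5})
    with pytest.raises(ValueError, match="missing_rate"):
        GeneratorConfig(missing_rate=0.5)
    with pytest.raises(ValueError, match="at least one subject"):
        GeneratorConfig(n_smokers=0, n_nonsmokers=0)


def test_nonsmoker_only_cohort_is_mostly_censored():
    c = generate_cohort(small_config(seed=9, n_smokers=0, n_nonsmokers=400))
    flags = [m.blloq_flag_column for m in c.meta.values() if m.blloq_flag_column]
    # threshold at the 60th percentile flags roughly 60% of each biomarker
    frac = c.data[flags].mean()
    assert (frac > 0.5).all()
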