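"""Reference threshold-basis regression models for the four biomarkers.

These are the published final all-subjects regression models relating
serum cotinine, total NNAL, 1-hydroxypyrene and clinical covariates to
DEH11, EPI8, WBC and HDL in a large smoker/nonsmoker exposure study.
The raw study data are proprietary, so these coefficient sets serve
as the *generating truth* of the synthetic cohort generator: every
downstream stage (screening, spline fitting, refitting, validation) can be
exercised and checked against them.

Nominal population R-squared values reported alongside each model are used
to calibrate the generator's noise variance.
"""

from __future__ import annotations

from .basis import ThresholdBasis, ThresholdModel, ThresholdTerm

__all__ = ["REFERENCE_MODELS", "REFERENCE_R2", "reference_model"]


def _model(intercept: float, rows: list[tuple[str, str, float | str | None, float]]) -> ThresholdModel:
    return ThresholdModel(
        intercept=intercept,
        terms=[
            ThresholdTerm(ThresholdBasis(var, form, cutoff), coef)
            for var, form, cutoff, coef in rows
        ],
    )


# 24 h urine 11-dehydro-thromboxane B2 (platelet activation), ng/24 hr urine
DEH11_MODEL = _model(
    -4045.3022,
    [
        ("COTIN", "IFGT", 11, 1.4494),
        ("UCRCAL", "IFLT", 3036, 0.3531),
        ("CRCL", "IFLT", 4325, 0.3698),
        ("AST", "IFGT", 25, 17.9064),
        ("AST", "IFGT", 126, -18.2428),
        ("ALKPH", "IFLT", 184, 3.1360),
        ("ALKPH", "IFGT", 184, 30.7979),
        ("NSAID", "EQ", "YES", -346.0560),
        ("VITAMIN", "EQ", "YES", -211.7183),
    ],
)

# 24 h urine 8-epi-prostaglandin F2alpha (oxidative stress), ng/24 hr urine
EPI8_MODEL = _model(
    1383.0200,
    [
        ("TOTNN", "IFLT", 57, 5.1813),
        ("TOTNN", "IFGT", 57, 0.5548),
        ("TOTNN", "IFGT", 1452, -1.4595),
        ("OHP", "IFLT", 473, 0.8552),
        ("CRCL", "LINEAR", None, 0.6268),
        ("AST", "IFGT", 22, -135.4800),
        ("AST", "IFGT", 24, 247.4960),
        ("AST", "IFGT", 26, -108.4000),
        ("AST", "IFLT", 106, 12.2512),
        ("WEIGHTK", "LINEAR", None, 6.2845),
        ("VITAMIN", "EQ", "YES", -250.7700),
    ],
)

# white blood cell count (inflammation), x10^3 cells/uL
WBC_MODEL = _model(
    -6.4951,
    [
        ("TOTNN", "IFGT", 51, -0.0055),
        ("TOTNN", "IFLT", 471, 0.0078),
        ("TOTNN", "IFGT", 471, 0.0065),
        ("CRP", "IFLT", 2, 0.3426),
        ("CRP", "IFGT", 2, 0.0715),
        ("CRP", "IFGT", 20, -0.0477),
        ("PLATE", "IFLT", 245, 0.0106),
        ("PLATE", "IFGT", 245, 0.007),
        ("HGB", "IFLT", 14, 0.3242),
        ("TRIG", "IFLT", 171, 0.0051),
        ("TRIG", "IFGT", 503, 0.0025),
        ("RACE", "EQ", "BLACK", -0.679),
    ],
)

# high-density lipoprotein cholesterol (lipid metabolism), mg/dL
HDL_MODEL = _model(
    55.4292,
    [
        ("COTIN", "IFGT", 31, -0.0291),
        ("COTIN", "IFGT", 193, 0.0258),
        ("TRIG", "IFGT", 52, -0.5819),
        ("TRIG", "IFGT", 64, 0.483),
        ("TRIG", "IFGT", 177, 0.0753),
        ("WEIGHTK", "IFLT", 76, -0.267),
        ("WEIGHTK", "IFGT", 76, -0.0834),
        ("AGE", "IFLT", 55, 0.3119),
        ("SEX", "EQ", "F", 6.72),
        ("DRINK", "EQ", "Y", 2.0567),
        ("DRINK", "GT", "1.PER.WK", 7.875),
    ],
)

REFERENCE_MODELS: dict[str, ThresholdModel] = {
    "DEH11": DEH11_MODEL,
    "EPI8": EPI8_MODEL,
    "WBC": WBC_MODEL,
    "HDL": HDL_MODEL,
}

#: nominal population R-squared of each reference model
REFERENCE_R2: dict[str, float] = {
    "DEH11": 0.29,
    "EPI8": 0.41,
    "WBC": 0.29,
    "HDL": 0.39,
}


def reference_model(response: str) -> ThresholdModel:
    try:
        return REFERENCE_MODELS[response]
    except KeyError:
        raise KeyError(
            f"no reference model for {response!r}; "
            f"choose from {sorted(REFERENCE_MODELS)}"
        ) from None
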