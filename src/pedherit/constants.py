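"""Reference constants for the Dutch primary-school census analysis.

Category frequencies of the environmental covariates in the national sample
(sex, SES funding weight, migrant status, school denomination) and the
posterior-mean covariate effects reported for the full model. The synthetic
census generator samples covariates at these frequencies and applies these
effects by default, so simulated data mirror the published study conditions;
tests and the simulator cite this single source of truth.
"""

from __future__ import annotations

#: valid bounds of the standardized achievement score scale (points)
SCORE_MIN = 500.0
SCORE_MAX = 550.0

#: empty-model posterior-mean intercept (score points)
MEAN_SCORE = 535.03

#: posterior-mean variance components (score points squared)
EMPTY_MODEL_VC = {"sigma2_A": 89.10, "sigma2_E": 5.59}
FULL_MODEL_VC = {"sigma2_A": 75.83, "sigma2_E": 13.21}

#: MZ twinning rate: roughly one in every 200 births
MZ_TWIN_RATE = 0.005

#: sex frequencies in the analysis sample
SEX_FREQS = {"Female": 0.5011, "Male": 0.4989}

#: SES funding-weight frequencies (weight value -> proportion)
WEIGHT_FREQS = {
    0.00: 0.8684,
    0.25: 0.0041,
    0.30: 0.0715,
    0.40: 0.0001,
    0.70: 0.0001,
    0.90: 0.0050,
    1.20: 0.0508,
}

#: migrant-status frequencies (0 = none, 1 = first, 2 = second generation)
MIGRANT_FREQS = {0: 0.7811, 1: 0.0231, 2: 0.1958}

#: school-denomination frequencies; ABZ is the reference category downstream
DENOMINATION_FREQS = {
    "ABZ": 0.0449,
    "ASF": 0.0011,
    "EVA": 0.0005,
    "EVB": 0.0002,
    "GEV": 0.0097,
    "HIN": 0.0014,
    "IC": 0.0003,
    "ISL": 0.0058,
    "JOO": 0.0002,
    "OPB": 0.3020,
    "PC": 0.2383,
    "REF": 0.0225,
    "RK": 0.3635,
    "SCA": 0.0001,
    "SOC": 0.00005,
    "SOP": 0.0002,
    "SOR": 0.0006,
    "SPR": 0.0088,
}

#: reference categories (carry no design column)
REFERENCE_SEX = "Female"
REFERENCE_MIGRANT = 0
REFERENCE_DENOMINATION = "ABZ"

#: full-model posterior-mean regression coefficients (score points per unit)
FULL_MODEL_INTERCEPT = 537.24
BETA_MALE = 0.35
BETA_WEIGHT = -6.26
BETA_GROUP_SIZE = 0.03
BETA_MIGRANT = {1: -1.97, 2: -1.50}
BETA_DENOMINATION = {
    "ASF": -1.88,
    "EVA": -3.22,
    "EVB": -3.84,
    "GEV": -1.82,
    "HIN": -0.47,
    "IC": -4.88,
    "ISL": -0.76,
    "JOO": 0.01,
    "OPB": -2.07,
    "PC": -1.93,
    "REF": -1.81,
    "RK": -1.58,
    "SCA": -4.61,
    "SOC": -1.35,
    "SOP": -3.44,
    "SOR": -1.12,
    "SPR": -2.65,
}

#: classroom group size: mean and SD used by the generator (pupils)
GROUP_SIZE_MEAN = 25.0
GROUP_SIZE_SD = 5.0

#: fraction of pupils in special primary education (missing SES weight)
SPECIAL_ED_RATE = 1_623 / 894_750
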