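"""Reference fixtures from the original three-year school survey study.

These constants serve two purposes: they calibrate the synthetic cohort
generator (demographic distributions, default planted effect sizes) and they
provide regression fixtures for the multiple-comparison machinery (the 75
p-values of the published battery and its survey-count ledger).

Effect and measure identifiers used as keys here match the registries in
:mod:`psybattery.battery` and :mod:`psybattery.inference`.
"""

from __future__ import annotations

MEASURES = (
    "cpss",
    "phqa",
    "hads",
    "crafft",
    "rosenberg",
    "kidscreen",
    "cyrm",
    "ptsd",
    "depression",
    "mod_severe_depression",
    "suicidal",
    "anxiety",
    "substance",
    "tobacco",
    "any4",
)

EFFECTS = ("time", "age", "female_vs_male", "other_vs_fm", "pnts_vs_fm")

# The 75 p-values of the published default battery, keyed (measure, effect).
# Used as an FDR regression fixture: joint step-up correction at alpha=0.05
# rejects every test except (cyrm, time) and (tobacco, time).
REFERENCE_PVALUES: dict[tuple[str, str], float] = {
    # time effect
    ("cpss", "time"): 0.0025,
    ("phqa", "time"): 0.00001,
    ("hads", "time"): 0.019,
    ("crafft", "time"): 0.014,
    ("rosenberg", "time"): 0.00011,
    ("kidscreen", "time"): 0.0028,
    ("cyrm", "time"): 0.32,
    ("ptsd", "time"): 0.00070,
    ("depression", "time"): 0.00033,
    ("mod_severe_depression", "time"): 0.0011,
    ("suicidal", "time"): 0.018,
    ("anxiety", "time"): 0.00020,
    ("substance", "time"): 0.012,
    ("tobacco", "time"): 0.71,
    ("any4", "time"): 0.00004,
    # age effect
    ("cpss", "age"): 0.00001,
    ("phqa", "age"): 0.00001,
    ("hads", "age"): 0.00001,
    ("crafft", "age"): 0.00001,
    ("rosenberg", "age"): 0.00001,
    ("kidscreen", "age"): 0.00001,
    ("cyrm", "age"): 0.00002,
    ("ptsd", "age"): 0.00001,
    ("depression", "age"): 0.00001,
    ("mod_severe_depression", "age"): 0.00001,
    ("suicidal", "age"): 0.0088,
    ("anxiety", "age"): 0.00001,
    ("substance", "age"): 0.00001,
    ("tobacco", "age"): 0.00001,
    ("any4", "age"): 0.00001,
    # female vs male
    ("cpss", "female_vs_male"): 0.00001,
    ("phqa", "female_vs_male"): 0.00001,
    ("hads", "female_vs_male"): 0.00001,
    ("crafft", "female_vs_male"): 0.00002,
    ("rosenberg", "female_vs_male"): 0.00001,
    ("kidscreen", "female_vs_male"): 0.00001,
    ("cyrm", "female_vs_male"): 0.0014,
    ("ptsd", "female_vs_male"): 0.00001,
    ("depression", "female_vs_male"): 0.00001,
    ("mod_severe_depression", "female_vs_male"): 0.00001,
    ("suicidal", "female_vs_male"): 0.00001,
    ("anxiety", "female_vs_male"): 0.00001,
    ("substance", "female_vs_male"): 0.00001,
    ("tobacco", "female_vs_male"): 0.0040,
    ("any4", "female_vs_male"): 0.00001,
    # other vs female/male
    ("cpss", "other_vs_fm"): 0.00001,
    ("phqa", "other_vs_fm"): 0.00001,
    ("hads", "other_vs_fm"): 0.00001,
    ("crafft", "other_vs_fm"): 0.00001,
    ("rosenberg", "other_vs_fm"): 0.00001,
    ("kidscreen", "other_vs_fm"): 0.00001,
    ("cyrm", "other_vs_fm"): 0.00001,
    ("ptsd", "other_vs_fm"): 0.00003,
    ("depression", "other_vs_fm"): 0.00001,
    ("mod_severe_depression", "other_vs_fm"): 0.00001,
    ("suicidal", "other_vs_fm"): 0.00001,
    ("anxiety", "other_vs_fm"): 0.00006,
    ("substance", "other_vs_fm"): 0.00024,
    ("tobacco", "other_vs_fm"): 0.00027,
    ("any4", "other_vs_fm"): 0.00002,
    # prefer-not-to-say vs female/male
    ("cpss", "pnts_vs_fm"): 0.00001,
    ("phqa", "pnts_vs_fm"): 0.00001,
    ("hads", "pnts_vs_fm"): 0.00004,
    ("crafft", "pnts_vs_fm"): 0.00001,
    ("rosenberg", "pnts_vs_fm"): 0.00001,
    ("kidscreen", "pnts_vs_fm"): 0.00001,
    ("cyrm", "pnts_vs_fm"): 0.00001,
    ("ptsd", "pnts_vs_fm"): 0.00022,
    ("depression", "pnts_vs_fm"): 0.00024,
    ("mod_severe_depression", "pnts_vs_fm"): 0.00003,
    ("suicidal", "pnts_vs_fm"): 0.00018,
    ("anxiety", "pnts_vs_fm"): 0.00001,
    ("substance", "pnts_vs_fm"): 0.00006,
    ("tobacco", "pnts_vs_fm"): 0.0012,
    ("any4", "pnts_vs_fm"): 0.00003,
}

# Tests that did NOT survive the published joint FDR correction.
REFERENCE_NONSIGNIFICANT: frozenset[tuple[str, str]] = frozenset(
    {("cyrm", "time"), ("tobacco", "time")}
)

# Survey-count ledger: collected, retained after exclusion, enrolled students.
SURVEY_COUNTS = {
    "all": {"collected": 9920, "included": 9376, "enrolled": 13848},
    2017: {"collected": 3252, "included": 3070, "enrolled": 4407},
    2018: {"collected": 3451, "included": 3265, "enrolled": 4592},
    2019: {"collected": 3217, "included": 3041, "enrolled": 4849},
}

EXCLUDED_TOTAL = 544

# Gender-identity shares (percent) of the retained cohort.
GENDER_SHARES = {
    "all": {"female": 47.3, "male": 48.6, "other": 1.7, "prefer_not_say": 2.4},
    2017: {"female": 48.3, "male": 47.8, "other": 1.6, "prefer_not_say": 2.4},
    2018: {"female": 46.6, "male": 49.9, "other": 1.6, "prefer_not_say": 2.0},
    2019: {"female": 47.0, "male": 48.0, "other": 1.9, "prefer_not_say": 3.0},
}

# Age shares (percent, ages 11..19) of the retained cohort.
AGE_SHARES = {
    "all": [2.7, 18.1, 17.7, 17.2, 16.4, 14.5, 11.0, 1.9, 0.6],
    2017: [2.4, 17.9, 17.2, 17.7, 15.5, 14.4, 12.2, 2.0, 0.7],
    2018: [2.6, 17.7, 17.2, 16.3, 17.9, 15.4, 10.2, 2.2, 0.6],
    2019: [3.0, 18.7, 18.8, 17.7, 15.7, 13.7, 10.6, 1.5, 0.4],
}

AGES = tuple(range(11, 20))

# Default planted effect sizes for the synthetic cohort, per continuous
# measure: baseline latent level (male, first year, at the mean age),
# per-year time slope, per-year-of-age slope, additive gender-identity
# offsets, and the residual SD of the latent severity.
DEFAULT_PLANTS = {
    "cpss": {
        "baseline": 10.61, "sd": 10.30,
        "time": 0.47, "age": 0.42,
        "female": 4.79, "other": 6.30, "pnts": 4.11,
    },
    "phqa": {
        "baseline": 6.76, "sd": 5.88,
        "time": 0.36, "age": 0.60,
        "female": 2.90, "other": 4.18, "pnts": 2.14,
    },
    "hads": {
        "baseline": 6.52, "sd": 4.27,
        "time": 0.14, "age": 0.27,
        "female": 2.50, "other": 2.13, "pnts": 1.40,
    },
    "crafft": {
        "baseline": 0.52, "sd": 1.20,
        "time": 0.04, "age": 0.22,
        "female": 0.12, "other": 0.52, "pnts": 0.41,
    },
    "rosenberg": {
        "baseline": 19.55, "sd": 6.15,
        "time": -0.33, "age": -0.33,
        "female": -3.02, "other": -3.74, "pnts": -2.56,
    },
    "kidscreen": {
        "baseline": 28.91, "sd": 7.72,
        "time": -0.33, "age": -0.97,
        "female": -4.20, "other": -3.64, "pnts": -2.70,
    },
    "cyrm": {
        "baseline": 47.25, "sd": 9.05,
        "time": 0.12, "age": -0.25,
        "female": -0.62, "other": -6.64, "pnts": -5.40,
    },
    # Latent propensities on a 0-100 axis; positive above the threshold.
    "tobacco": {
        "baseline": 14.8, "sd": 30.0,
        "time": -0.3, "age": 6.0,
        "female": 3.1, "other": 15.2, "pnts": 11.2,
    },
}

TOBACCO_LATENT_THRESHOLD = 50.0
SUICIDAL_LATENT_THRESHOLD = 14.0
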