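"""Published-cohort default parameters for the synthetic generator.

The defaults describe the activity-profile structure estimated for UK
10-11-year-olds measured before the COVID-19 lockdowns (the "pre-COVID"
preset) and after them (the "post-lockdown" preset, observed in two survey
waves, W1 in 2021 and W2 in 2022).  Each preset carries, per profile:

* mean weekday/weekend proportions of wear time in MVPA and sedentary
  behaviour (light activity is the simplex remainder),
* the mixing proportion (share of children),
* profile-conditional covariate distributions: probability female,
  probability of no degree-level education in the household, and mean days
  per week of structured (clubs) and unstructured (free play) activity.

Within-profile variances are not published; they are derived here by moment
matching so that the mixture's overall weekday SDs reproduce the published
cohort SDs (see :func:`matched_within_variance`).
"""

from __future__ import annotations

import numpy as np

# Profile labels, ordered most active -> least active (by estimated share
# meeting the 60-min/day MVPA guideline).
PRE_COVID_LABELS = [
    "Highly Active", "Active", "Moderate",
    "Sedentary", "Inactive", "Sedentary & Inactive",
]
POST_LOCKDOWN_LABELS = [
    "Highly Active", "Active/Light", "Moderate",
    "Sedentary", "Inactive", "Sedentary & Inactive",
]

# Mean proportions per profile, columns (MVPA_wd, SED_wd, MVPA_we, SED_we).
PRE_COVID_MEANS = np.array([
    [0.12, 0.56, 0.16, 0.48],   # Highly Active
    [0.10, 0.64, 0.12, 0.63],   # Active
    [0.09, 0.62, 0.09, 0.59],   # Moderate
    [0.08, 0.67, 0.06, 0.70],   # Sedentary
    [0.07, 0.63, 0.05, 0.62],   # Inactive
    [0.06, 0.68, 0.04, 0.71],   # Sedentary & Inactive
])
PRE_COVID_MIXING = np.array([0.10, 0.13, 0.20, 0.23, 0.15, 0.19])

POST_LOCKDOWN_MEANS = np.array([
    [0.11, 0.62, 0.16, 0.56],   # Highly Active
    [0.10, 0.58, 0.13, 0.51],   # Active/Light
    [0.09, 0.64, 0.09, 0.61],   # Moderate
    [0.08, 0.69, 0.07, 0.71],   # Sedentary
    [0.07, 0.62, 0.05, 0.61],   # Inactive
    [0.06, 0.69, 0.04, 0.73],   # Sedentary & Inactive
])
W1_MIXING = np.array([0.05, 0.07, 0.20, 0.16, 0.14, 0.38])
# Printed W2 shares sum to 0.99; renormalised at use.
W2_MIXING = np.array([0.12, 0.07, 0.20, 0.20, 0.13, 0.27])

# Overall (mixture) weekday SD targets for (MVPA, SED) proportions.
PRE_COVID_SD_TARGETS = (0.03, 0.07)
POST_LOCKDOWN_SD_TARGETS = (0.03, 0.06)   # W2 column

# Within-profile SDs scale with a profile's activity level:
# sd_k^2 = s_k * v_bar with s_k ~ exp(gamma * z_k), z_k the standardised
# guideline-weighted MVPA mean, normalised so the mixing-weighted mean
# variance (and hence the overall mixture SD) is unchanged.  This keeps the
# MVPA coefficient of variation roughly constant across profiles, and
# gamma is set so the model-implied classification entropy under the
# default cohort conditions matches the published 6-profile value (0.547).
SD_ACTIVITY_SCALING_GAMMA = 0.7
K6_ENTROPY_TARGET = 0.547

# Profile-conditional covariates, rows aligned with the label order above.
FEMALE_PROB = {
    "Y6":    np.array([0.30, 0.24, 0.49, 0.48, 0.85, 0.69]),
    "Y6-W1": np.array([0.04, 0.16, 0.36, 0.41, 0.59, 0.67]),
    "Y6-W2": np.array([0.08, 0.86, 0.39, 0.42, 0.73, 0.74]),
}
NO_DEGREE_PROB = {
    "Y6":    np.array([0.50, 0.42, 0.46, 0.35, 0.63, 0.46]),
    "Y6-W1": np.array([0.27, 0.36, 0.29, 0.23, 0.43, 0.35]),
    "Y6-W2": np.array([0.31, 0.65, 0.33, 0.21, 0.84, 0.35]),
}
STRUCTURED_MEAN = {
    "Y6":    np.array([2.7, 2.4, 2.1, 1.7, 1.6, 1.5]),
    "Y6-W1": np.array([1.5, 1.9, 1.6, 1.5, 1.5, 1.4]),
    "Y6-W2": np.array([2.5, 1.3, 2.0, 1.3, 1.2, 1.4]),
}
UNSTRUCTURED_MEAN = {
    "Y6":    np.array([2.9, 3.3, 3.3, 2.7, 3.1, 2.7]),
    "Y6-W1": np.array([2.3, 3.3, 2.9, 2.6, 2.3, 2.6]),
    "Y6-W2": np.array([2.9, 2.5, 2.5, 2.1, 1.9, 2.6]),
}
# Overall SD targets for the two activity-day scores.
STRUCTURED_SD = {"Y6": 1.4, "Y6-W1": 1.1, "Y6-W2": 1.3}
UNSTRUCTURED_SD = {"Y6": 1.6, "Y6-W1": 1.5, "Y6-W2": 1.5}

# Daily wear-time model (minutes within the 06:00-24:00 window).
WEAR_MEAN_MIN = 780.0
WEAR_SD_MIN = 60.0

# Default weekend-block missingness (missing at random).
WEEKEND_MISSING_RATE = 0.15

GUIDELINE_MIN_PER_DAY = 60.0


def matched_within_variance(means_1d: np.ndarray, mixing: np.ndarray,
                            target_sd: float) -> float:
    """Shared within-profile variance that reproduces an overall mixture SD.

    By the law of total variance, ``total = within + between`` when the
    within-profile variance is common across profiles; ``between`` is the
    mixing-weighted variance of the profile means.  Returns
    ``target_sd**2 - between`` (floored at 10% of the target variance so a
    preset with widely spread means still yields a proper distribution).
    """
    w = np.asarray(mixing, dtype=float)
    w = w / w.sum()
    m = np.asarray(means_1d, dtype=float)
    between = float(w @ m**2 - (w @ m) ** 2)
    return max(target_sd**2 - between, 0.1 * target_sd**2)
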