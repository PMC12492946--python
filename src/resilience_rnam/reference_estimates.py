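"""Reference REML estimates for DFI paired with each production trait.

These are published variance-component estimates from a large Piétrain
sire-line evaluation fitting the exact bivariate reaction-norm model this
package implements (DFI with a reaction norm on the challenge-probability
gradient, paired one at a time with a single-record production trait).
They serve three purposes here: generator defaults at realistic magnitudes,
worked-example inputs for the gradient-correlation formulas, and the model
comparison arithmetic of the restricted likelihood-ratio test.

Per trait pair the entries are, in order:
``var_a10, var_a11, var_a2`` (genetic variances of the DFI intercept, DFI
slope and trait 2), ``cov_a10_a11, cov_a10_a2, cov_a11_a2`` (genetic
covariances), the analogous permanent-environmental block
``var_pe10, var_pe11, var_pe2, cov_pe10_pe11, cov_pe10_pe2, cov_pe11_pe2``
and the residual variances ``var_e1, var_e2``. ``r_a10_a2`` and
``r_a11_a2`` are the correlations reported alongside them.
"""

from __future__ import annotations

import numpy as np

from .gradient_correlations import GeneticCovK

__all__ = [
    "TRAIT_PAIRS",
    "VARIANCE_COMPONENTS",
    "REPORTED_CORRELATIONS",
    "MINUS2_LOGLIK",
    "genetic_cov",
    "pe_cov",
    "residual_variances",
]

TRAIT_PAIRS = ("AGE", "BFT", "LMT", "FCR", "LMP", "PH24", "DLP", "BHW")

# trait2: (va10, va11, va2, c_a10a11, c_a10a2, c_a11a2,
#          vpe10, vpe11, vpe2, c_pe10pe11, c_pe10pe2, c_pe11pe2, ve1, ve2)
VARIANCE_COMPONENTS = {
    "AGE": (0.036, 0.087, 34.773, -0.021, -0.918, 0.254,
            0.030, 0.122, 30.422, -0.004, -0.836, -0.776, 0.175, 12.420),
    "BFT": (0.037, 0.089, 0.483, -0.013, 0.063, 0.007,
            0.024, 0.125, 0.127, -0.016, 0.009, 0.003, 0.175, 0.381),
    "LMT": (0.033, 0.093, 10.389, -0.018, 0.048, -0.282,
            0.026, 0.123, 5.662, -0.014, -0.027, 0.206, 0.175, 7.708),
    "FCR": (0.043, 0.088, 0.018, -0.013, 0.025, 0.002,
            0.023, 0.122, 0.004, -0.015, 0.009, 0.002, 0.175, 0.009),
    "LMP": (0.034, 0.089, 1.329, -0.016, -0.068, -0.024,
            0.025, 0.124, 0.945, -0.014, -0.064, 0.081, 0.175, 1.878),
    "PH24": (0.033, 0.089, 0.006, -0.017, 0.003, -0.003,
             0.026, 0.125, 0.006, -0.014, 0.001, 0.003, 0.175, 0.012),
    "DLP": (0.033, 0.089, 1.143, -0.017, -0.042, 0.019,
            0.026, 0.125, 1.846, -0.014, -0.012, 0.002, 0.175, 0.0003),
    "BHW": (0.034, 0.089, 0.040, -0.017, -0.012, 0.009,
            0.026, 0.124, 0.017, -0.014, 0.006, -0.007, 0.175, 0.097),
}

# Correlations reported alongside the estimates: r(a10, a2) and r(a11, a2).
REPORTED_CORRELATIONS = {
    "AGE": (-0.817, 0.146),
    "BFT": (0.470, 0.035),
    "LMT": (0.081, -0.286),
    "FCR": (0.901, 0.052),
    "LMP": (-0.318, -0.069),
    "PH24": (0.177, -0.130),
    "DLP": (-0.214, 0.059),
    "BHW": (-0.315, 0.149),
}

# Reported -2 log-likelihood of the plain animal model (AM) and the
# reaction-norm model (RNAM) per trait pair, inputs to the REML ratio test.
MINUS2_LOGLIK = {
    "AGE": (881941.77, 868811.53),
    "BFT": (559758.28, 546479.09),
    "LMT": (796114.77, 782843.03),
    "FCR": (356623.06, 343434.96),
    "LMP": (524503.18, 511215.86),
    "PH24": (346118.14, 332845.72),
    "DLP": (455067.78, 441798.60),
    "BHW": (384808.03, 371538.62),
}


# Population mean (SD) of each trait in the reference population; units:
# days, mm, mm, ratio, %, pH, %, kg.
TRAIT_MEANS = {
    "AGE": (135.10, 9.03),
    "BFT": (27.63, 1.12),
    "LMT": (71.50, 6.19),
    "FCR": (2.28, 0.20),
    "LMP": (63.20, 2.04),
    "PH24": (5.68, 0.17),
    "DLP": (0.03, 0.02),
    "BHW": (9.98, 0.67),
}


def genetic_cov(trait: str) -> GeneticCovK:
    """The 3x3 genetic (co)variance K for one DFI-trait pair."""
    v = VARIANCE_COMPONENTS[trait]
    return GeneticCovK(
        var_a10=v[0], var_a11=v[1], var_a2=v[2],
        cov_a10_a11=v[3], cov_a10_a2=v[4], cov_a11_a2=v[5],
    )


def pe_cov(trait: str) -> np.ndarray:
    """The 3x3 permanent-environmental (co)variance T for one pair."""
    v = VARIANCE_COMPONENTS[trait]
    return np.array(
        [
            [v[6], v[9], v[10]],
            [v[9], v[7], v[11]],
            [v[10], v[11], v[8]],
        ]
    )


def residual_variances(trait: str) -> tuple[float, float]:
    v = VARIANCE_COMPONENTS[trait]
    return v[12], v[13]
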