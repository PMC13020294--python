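"""Published calibration constants for Quercus mongolica in Northeast China.

The package ships the published coefficient sets of the destructive
175-tree Q. mongolica calibration (Heilongjiang, Jilin, Liaoning and
eastern Inner Mongolia; diameter classes 2-32 cm, 53-tree root
subsample).  The raw tree data were never deposited, so these constants
serve three roles: defaults for the synthetic-population generator,
generating truths for parameter-recovery tests, and published values
that derived quantities (carbon-scaled coefficients, reconstructed mean
prediction errors) must reproduce.

Component means are back-calculated from the published per-component
SEE/MPE pairs (the printed summary table is not machine-readable); they
are reconstructions consistent with the published error statistics, not
verbatim values.
"""

from __future__ import annotations

# ---------------------------------------------------------------- study design
N_TREES = 175
N_ROOT_SUBSAMPLE = 53
DBH_RANGE_CM = (1.4, 31.5)
MAX_HEIGHT_M = 20.5          # applicability bound of the published models
MEAN_HEIGHT_M = 9.75
MEAN_DBH_CM = 15.513
DIAMETER_CLASS_CENTERS_CM = (2, 4, 6, 8, 12, 16, 20, 24, 28, 32)
TREES_PER_DIAMETER_CLASS = 16          # 160 design trees + 15 random extras

# Mean dry mass per component over the calibration trees (kg).
# Reconstructed from SEE and MPE consistency (see module docstring).
COMPONENT_MEANS_KG = {
    "stem": 95.2,
    "branch": 47.23,
    "leaf": 5.65,
    "root": 40.30,
    "aboveground": 148.17,
}

# ------------------------------------------------------------- carbon factors
# Component carbon content fractions (national standard GB/T 43648-2024;
# the stem value is the wood/bark arithmetic mean).
CARBON_FACTORS = {"stem": 0.4820, "branch": 0.4805, "leaf": 0.4923}
# Not published for roots; implied by the published belowground biomass vs
# carbon coefficient pair (0.0245 / 0.0523).  Reconstructed, not quoted.
ROOT_CARBON_FACTOR_IMPLIED = 0.4685

# -------------------------------------------------- independent biomass models
# Weighted-CAR coefficients, biomass (kg): (a0, a1[, a2]) for
# Y = a0 * DBH^a1 [* H^a2], keyed by (component, form).
INDEPENDENT_BIOMASS = {
    ("aboveground", "univariate"): (0.0956, 2.4803),
    ("aboveground", "bivariate"): (0.0588, 2.1205, 0.6270),
    ("stem", "univariate"): (0.1057, 2.3113),
    ("stem", "bivariate"): (0.0445, 1.7307, 1.0389),
    ("branch", "univariate"): (0.0069, 2.9374),
    ("branch", "bivariate"): (0.0076, 3.0193, -0.1361),
    ("leaf", "univariate"): (0.0162, 2.0129),
    ("leaf", "bivariate"): (0.0168, 1.9820, 0.0225),
    ("root", "univariate"): (0.0523, 2.2585),
    ("root", "bivariate"): (0.0496, 2.1323, 0.1824),
}

# Same structure for the directly fitted carbon-stock models (kg C).
INDEPENDENT_CARBON = {
    ("aboveground", "univariate"): (0.0462, 2.4795),
    ("aboveground", "bivariate"): (0.0284, 2.1195, 0.6272),
    ("stem", "univariate"): (0.0509, 2.3113),
    ("stem", "bivariate"): (0.0214, 1.7307, 1.0389),
    ("branch", "univariate"): (0.0033, 2.9374),
    ("branch", "bivariate"): (0.0037, 3.0193, -0.1361),
    ("leaf", "univariate"): (0.0080, 2.0129),
    ("leaf", "bivariate"): (0.0083, 1.9820, 0.0225),
    ("root", "univariate"): (0.0245, 2.2585),
    ("root", "bivariate"): (0.0228, 2.2801, 0.1859),
}

# Published error statistics of the independent biomass fits:
# (SEE kg, n, p, MPE %).  Used for the mean-prediction-error
# reconstruction and to size the generator's residual noise.
INDEPENDENT_BIOMASS_ERRORS = {
    ("aboveground", "univariate"): (51.32, 175, 2, 5.17),
    ("aboveground", "bivariate"): (43.58, 175, 3, 4.39),
    ("stem", "univariate"): (37.14, 175, 2, 5.82),
    ("stem", "bivariate"): (21.17, 175, 3, 3.31),
    ("branch", "univariate"): (29.41, 175, 2, 9.29),
    ("branch", "bivariate"): (29.70, 175, 3, 9.38),
    ("leaf", "univariate"): (3.59, 175, 2, 9.49),
    ("leaf", "bivariate"): (3.63, 175, 3, 9.60),
    ("root", "univariate"): (23.41, 53, 2, 16.02),
    ("root", "bivariate"): (23.67, 53, 3, 16.21),
}

# The five published MPE values that reconstruct exactly (to the printed
# 2 decimals) from SEE, component mean, n and p with a two-sided 95%
# Student-t quantile at n-p df.  (Leaf univariate and stem bivariate are
# off by 0.01 under every t convention - rounding noise in the source.)
MPE_RECONSTRUCTION_SET = (
    ("aboveground", "univariate"),
    ("aboveground", "bivariate"),
    ("stem", "univariate"),
    ("branch", "univariate"),
    ("root", "univariate"),
)

# --------------------------------------------- aggregation-compatible system
# Component equations of the additive (aggregation) system: the stem uses
# the bivariate form, branch and leaf the univariate form; the total is
# their algebraic sum.
AGGREGATION_BIOMASS = {
    "stem": (0.0458, 1.7481, 1.0067),
    "branch": (0.0068, 2.9438),
    "leaf": (0.0168, 2.0005),
}
AGGREGATION_CARBON = {
    "stem": (0.0220, 1.7483, 1.0071),
    "branch": (0.0033, 2.9436),
    "leaf": (0.0081, 2.0083),
}

# ----------------------------------------- decomposition-compatible system
# Proportion functions g(x) = c0 * DBH^c1 allocating the independent
# aboveground total: stem share = 1/(1+g_branch+g_leaf), etc.
DECOMPOSITION_BIOMASS_PROPORTIONS = {
    "branch": (0.0686, 0.6133),
    "leaf": (0.1646, -0.3209),
}
DECOMPOSITION_CARBON_PROPORTIONS = {
    "branch": (0.0684, 0.6133),
    "leaf": (0.1680, -0.3207),
}

# --------------------------------------- climate-parameterized aggregation
# Effective coefficient/exponents are linear in one climate indicator per
# component: stem uses DD_lt0 (degree-days below 0 C) and the bivariate
# form, branch uses PAS (precipitation as snow), leaf uses TD
# (continentality).  Tuples: (c0, c01, e1, e11[, e2, e21]).
CLIMATE_ASSIGNMENT = {"stem": "DD_lt0", "branch": "PAS", "leaf": "TD"}
CLIMATE_AGGREGATION_BIOMASS = {
    "stem": (0.042623, 0.000005, 1.613553, 0.000116, 1.259482, -0.000230),
    "branch": (-0.003729, 0.000210, 3.163793, -0.004557),
    "leaf": (-0.109317, 0.003615, 4.483994, -0.069648),
}
CLIMATE_AGGREGATION_CARBON = {
    "stem": (0.022058, 0.000002, 1.638036, 0.000101, 1.204234, -0.000195),
    "branch": (-0.001795, 0.000100, 3.167026, -0.004585),
    "leaf": (-0.060362, 0.001944, 4.789116, -0.077394),
}

# ------------------------------------------------------ root-shoot ratio
# Ratio models M_root = (b0 * DBH^b1 [* H^b2]) * M_aboveground.
ROOT_SHOOT_BIOMASS = {
    "univariate": (0.6926, -0.2848),
    "bivariate": (0.8966, 0.0133, -0.4805),
}
ROOT_SHOOT_CARBON = {
    "univariate": (0.6724, -0.2845),
    "bivariate": (0.8707, 0.0139, -0.4809),
}

# ------------------------------------------- published allocation ranges (%)
# Min-max (and mean) of per-tree component proportions of whole-tree
# biomass over the 53 root-excavated trees.
ALLOCATION_RANGES_PCT = {
    "stem": (27.13, 75.28, 49.12),
    "branch": (7.56, 45.38, 20.20),
    "leaf": (0.95, 12.72, 4.61),
    "root": (9.92, 54.55, 26.07),
}

# Residual coefficient of variation per component implied by the
# published fit quality: under multiplicative heteroscedastic noise
# SEE^2 = cv^2 * E[f(x)^2], so cv = SEE / sqrt(mean squared prediction)
# evaluated over the diameter-class design.  The generator's default
# multiplicative-noise scale.
RESIDUAL_CV = {"stem": 0.27, "branch": 0.40, "leaf": 0.46, "root": 0.40}
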