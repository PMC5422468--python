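"""Bundled data from a published two-stage optimization of glutathione
(GSH) fermentation by a *Lactobacillus plantarum* isolate.

Stage 1 is a 16-run Plackett-Burman screen of 14 culture variables; stage 2
is a 13-run Box-Behnken response-surface design over the three variables
the screen selected (precursor amino acids, temperature, urea).  The tables
are transcribed exactly as printed, including the screening matrix's known
non-orthogonality (several column pairs have inner product +-4): the matrix
is deliberately never "repaired", and all analyses of these data run on the
verbatim matrix.

The response is intracellular reduced glutathione in uM per gram.
"""

from __future__ import annotations

# --- Stage 1: Plackett-Burman screen (16 runs x 14 two-level factors) ---

PB_FACTOR_NAMES = [
    "sodium_chloride",
    "bile_salt",
    "hydrogen_peroxide",
    "sds",
    "ethanol",
    "potassium_chloride",
    "urea",
    "butanol",
    "aerobic_incubation",
    "amino_acids",
    "ph",
    "temperature",
    "incubation_time",
    "cooling",
]

# Coded +-1 levels, trial order as printed.
PB_MATRIX = [
    [1, 1, -1, 1, -1, -1, -1, 1, 1, 1, -1, -1, 1, -1],
    [-1, 1, 1, -1, 1, 1, 1, -1, 1, 1, -1, -1, -1, 1],
    [1, -1, 1, 1, -1, -1, -1, 1, -1, 1, 1, -1, -1, -1],
    [-1, 1, -1, 1, 1, 1, 1, -1, 1, -1, 1, 1, -1, -1],
    [-1, -1, 1, -1, 1, 1, -1, 1, -1, 1, 1, 1, 1, -1],
    [-1, -1, -1, 1, -1, -1, 1, -1, 1, -1, -1, 1, 1, 1],
    [1, -1, -1, -1, 1, 1, 1, 1, -1, 1, 1, -1, 1, 1],
    [1, 1, -1, -1, -1, -1, -1, 1, 1, -1, -1, 1, -1, 1],
    [1, 1, 1, -1, -1, -1, 1, -1, 1, 1, 1, -1, 1, -1],
    [-1, 1, 1, 1, -1, -1, -1, 1, -1, 1, -1, 1, -1, 1],
    [1, -1, 1, 1, 1, 1, -1, -1, 1, -1, 1, -1, 1, -1],
    [-1, 1, -1, 1, 1, 1, -1, -1, -1, 1, 1, 1, -1, 1],
    [1, -1, 1, -1, 1, 1, 1, -1, -1, -1, -1, 1, 1, -1],
    [-1, 1, -1, 1, -1, -1, 1, 1, -1, -1, 1, -1, 1, 1],
    [1, -1, 1, -1, 1, 1, 1, 1, 1, -1, -1, 1, -1, 1],
    [-1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1],
]

PB_RESPONSES = [
    260, 245, 1147, 917, 956, 1147, 260, 275,
    860, 443, 199, 153, 1338, 122, 153, 122,
]

# Natural-unit levels of the 14 screening factors (low at coded -1, high at
# coded +1).  Supplements absent at the low level are coded low=0; the
# on/off conditions (aerobic incubation, post-incubation cooling) are 0/1
# indicators.
PB_FACTOR_LEVELS = {
    "sodium_chloride": (1.0, 5.0, "%"),
    "bile_salt": (0.0, 0.5, "%"),
    "hydrogen_peroxide": (0.0, 0.05, "%"),
    "sds": (0.0, 0.05, "%"),
    "ethanol": (0.0, 2.0, "%"),
    "potassium_chloride": (0.0, 0.5, "%"),
    "urea": (0.0, 0.1, "%"),
    "butanol": (0.0, 1.0, "%"),
    "aerobic_incubation": (0.0, 1.0, "indicator"),
    "amino_acids": (0.0, 0.05, "%"),
    "ph": (6.0, 8.0, "pH"),
    "temperature": (30.0, 40.0, "degC"),
    "incubation_time": (18.0, 24.0, "h"),
    "cooling": (0.0, 1.0, "indicator (24 h at 4 degC)"),
}

# --- Stage 2: Box-Behnken design (13 runs x 3 three-level factors) ---

BBD_FACTOR_NAMES = ["amino_acids", "temperature", "urea"]

BBD_MATRIX = [
    [0, -1, -1],
    [0, 1, -1],
    [0, -1, 1],
    [0, 1, 1],
    [-1, -1, 0],
    [-1, 1, 0],
    [1, -1, 0],
    [1, 1, 0],
    [-1, 0, -1],
    [-1, 0, 1],
    [1, 0, -1],
    [1, 0, 1],
    [0, 0, 0],
]

BBD_RESPONSES = [
    82.34, 129.01, 156.77, 194.51, 239.01, 305.76, 550.02,
    389.93, 426.33, 512.0, 661.35, 683.24, 1599.06,
]

# Predicted column as printed alongside the experimental responses; kept
# only for comparison reporting, never used in any fit.
BBD_PREDICTED_PRINTED = [
    108.61, 110.84, 174.94, 168.25, 215.41, 326.59, 529.19,
    413.53, 423.67, 517.43, 655.92, 685.90, 1599.06,
]

# Natural-unit levels at coded -1 / 0 / +1.  Spacing is non-uniform for
# amino acids and urea (roughly geometric), which is why decoding uses a
# piecewise-linear (or log) map rather than a single linear rescale.
BBD_FACTOR_LEVELS = {
    "amino_acids": (0.0125, 0.025, 0.05, "%"),
    "temperature": (35.0, 40.0, 45.0, "degC"),
    "urea": (0.02, 0.1, 0.5, "%"),
}

# --- Printed analysis results, for side-by-side comparison only ---

# First-order screening model as printed.  The intercept equals the grand
# mean of the 16 responses and is reproducible, and the printed R-squared
# coincides with the R-squared of the saturated first-order fit on the
# printed matrix (which is rank-deficient: its ethanol and KCl columns are
# identical, so a minimum-norm solve is needed).  The three printed slopes
# are NOT reproducible by least squares on the printed matrix (a
# documented discrepancy of the source analysis) and must never be used as
# expected values for any fit.
PRINTED_SCREEN_INTERCEPT = 537.3125
PRINTED_SCREEN_SLOPES = {
    "amino_acids": 169.650611210532,
    "temperature": 310.851847691976,
    "urea": 254.802687529275,
}
PRINTED_SCREEN_R2 = 0.8353

# Reported optimum of the fitted surface (natural units) and its predicted
# response.
PRINTED_OPTIMUM_NATURAL = {"amino_acids": 0.0281, "urea": 0.1916, "temperature": 40.0}
PRINTED_OPTIMUM_RESPONSE = 1599.06

# Quantities measured in the laboratory, not derivable from any model fit;
# excluded from reproduction by construction.
MEASURED_ONLY = {
    "verification_yield_uM_per_g": 1610.22,
    "baseline_isolate_yield_uM_per_g": 152.61,
}
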