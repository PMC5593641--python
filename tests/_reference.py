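"""Published worked-example values used as test inputs.

Two multivariate logistic coefficient tables (odds ratio, delta-method SE,
Wald z, 95% CI) for the Panel I markers — one fitted on epithelial cells
only, one on all imaged cells — plus validation composition counts with
their printed percentage rows. These are *inputs* for consistency checks of
the reporting arithmetic: the package re-derives z and the CI bounds from
the (OR, SE) pairs and the percentage rows from the counts.
"""

# term -> (odds_ratio, se_or, z_printed, ci_low, ci_high)
EPITHELIAL_MODEL = {
    "lnDAPI": (7.224606, 0.2921743, 48.9, 6.674063, 7.820565),
    "lnAMACR": (0.199478, 0.0132372, -24.29, 0.1751499, 0.2271852),
    "ln5mC": (0.0199724, 0.0017131, -45.63, 0.0168818, 0.0236286),
    "ln5hmC": (2.95159, 0.2216339, 14.41, 2.547649, 3.419578),
    "_cons": (490131.5, 201505.3, 31.87, 218958.8, 1097142.0),
}

ALL_CELLS_MODEL = {
    "lnDAPI": (6.459606, 0.1339882, 89.94, 6.20226, 6.727629),
    "lnAMACR": (0.4555956, 0.0120028, -29.84, 0.4326676, 0.4797386),
    "ln5mC": (0.0290629, 0.0009604, -107.08, 0.0272403, 0.0310075),
    "ln5hmC": (3.055547, 0.0929042, 36.74, 2.878778, 3.243171),
    "_cons": (3845.418, 650.8334, 48.77, 2759.806, 5358.073),
}

# binary (normal, aberrant) cell counts with printed percentage rows
BINARY_COMPOSITIONS = {
    "HPrEpiC": ((1800, 266), (87.12, 12.88)),
    "LNCaP": ((148, 17289), (0.85, 99.15)),
}

# six-class staging counts (B, ASAP, AC, StageII, StageIII, LAC) with
# printed percentage rows, from the 30,000-cell-reference k-NN validation
SIX_CLASS_ORDER = ("B", "ASAP", "AC", "StageII", "StageIII", "LAC")
SIX_CLASS_COMPOSITIONS = {
    "HPrEpiC": ((1613, 20, 221, 35, 16, 106), (80.21, 0.99, 10.99, 1.74, 0.8, 5.27)),
    "LNCaP": ((78, 262, 430, 14681, 264, 1220), (0.46, 1.55, 2.54, 86.69, 1.56, 7.2)),
}

# fuzzy-rule worked example: 80 normal / 20 aberrant cells
FUZZY_EXAMPLE = {"normal": 80, "aberrant": 20}
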