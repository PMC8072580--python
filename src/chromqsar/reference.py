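"""Published reference values for the bundled 19-congener study.

The bundled dataset comes from a published micellar/IAM/ODS
chromatography QSAR study of fused azaisocytosine congeners.  This
module transcribes the study's reported statistics so the pipeline's
``reproduce`` mode can check, cell by cell, that refitting the models on
the bundled data recovers them:

* the Foley-fit columns (log k_m and its transformed-fit R^2),
* the twenty reported MLR equations — their coefficient (standard
  error) pairs, n, R^2, residual sd, integer F and max-VIF bound,
* the validation table (adjusted R^2, PRESS).

Values are stored as *strings* exactly as printed; the matching
tolerance is 1.5 units in the last printed decimal place, which absorbs
both print rounding and the fact that the original fits used unrounded
retention measurements while the bundled table carries the printed
(rounded) ones.

Known defects of the printed source, found by refitting (see
docs/methods.md): the log K_p / log k_m equation's coefficient cells are
internally inconsistent with their own global statistics, two Foley R^2
cells are duplicated, and the cross-validated columns of the validation
table repeat the training statistics. ``KNOWN_DISCREPANT`` lists the
cells a faithful refit cannot match.
"""

from __future__ import annotations

from .mlr import ModelSpec

__all__ = [
    "MODEL_SPECS",
    "REFERENCE_MODELS",
    "REFERENCE_FOLEY",
    "printed_tolerance",
    "printed_value",
]


def printed_value(s: str) -> float:
    return float(s)


def printed_tolerance(s: str, factor: float = 1.5) -> float:
    """factor * one unit in the last printed decimal place of ``s``."""
    decimals = len(s.split(".")[1]) if "." in s else 0
    return factor * 10.0 ** (-decimals)


#: Reproduction tolerances for the Foley-fit columns (log k_m, transformed R^2).
FOLEY_LOG_KM_TOL = 0.01
FOLEY_R2_TOL = 5e-4


#: The twenty reported models. Labels follow the source numbering Eq3..Eq22.
MODEL_SPECS: list[ModelSpec] = [
    ModelSpec("log_Kp", ("log_km", "tpsa", "alpha", "mw"), "Eq3"),
    ModelSpec("log_Kp", ("log_kw_iam", "tpsa", "alpha", "mw"), "Eq4"),
    ModelSpec("log_Kp", ("log_kw_ods", "tpsa", "alpha", "mw"), "Eq5"),
    ModelSpec("log_KaHSA", ("log_km", "alpha", "mw"), "Eq6"),
    ModelSpec("log_KaHSA", ("log_kw_iam", "alpha", "mw"), "Eq7"),
    ModelSpec("log_KaHSA", ("log_kw_ods", "alpha", "mw"), "Eq8"),
    ModelSpec("log_BB", ("log_km", "tpsa", "alpha"), "Eq9"),
    ModelSpec("log_BB", ("log_kw_iam", "tpsa", "alpha"), "Eq10"),
    ModelSpec("log_BB", ("log_kw_ods", "tpsa", "alpha"), "Eq11"),
    ModelSpec("caco2_e06", ("log_km", "tpsa", "mw"), "Eq12"),
    ModelSpec("caco2_e06", ("log_kw_iam", "tpsa", "mw"), "Eq13"),
    ModelSpec("caco2_e06", ("log_kw_ods", "tpsa", "mw"), "Eq14"),
    ModelSpec("fu_brain", ("log_km", "tpsa", "mw"), "Eq15"),
    ModelSpec("fu_brain", ("log_kw_iam", "tpsa", "mw"), "Eq16"),
    ModelSpec("fu_brain", ("log_kw_ods", "tpsa", "mw"), "Eq17"),
    ModelSpec("log_Kp", ("log_k01", "tpsa", "alpha", "mw"), "Eq18"),
    ModelSpec("log_KaHSA", ("log_k01", "alpha", "mw"), "Eq19"),
    ModelSpec("log_BB", ("log_k01", "tpsa", "alpha"), "Eq20"),
    ModelSpec("caco2_e06", ("log_k01", "tpsa", "mw"), "Eq21"),
    ModelSpec("fu_brain", ("log_k01", "tpsa", "mw"), "Eq22"),
]

#: label -> reported statistics, verbatim strings.
#: 'coefficients' lists (estimate, standard error) pairs, intercept first,
#: then one pair per predictor in MODEL_SPECS order.
REFERENCE_MODELS: dict[str, dict] = {
    "Eq3": {
        "coefficients": [("-7.137", "0.935"), ("0.272", "0.079"), ("-0.025", "0.006"),
                         ("0.041", "0.030"), ("0.003", "0.003")],
        "n": 19, "r_squared": "0.9593", "sd": "0.108", "f": "83",
        "vif_max": "4.4", "adj_r_squared": "0.9476", "press": "0.279",
    },
    "Eq4": {
        "coefficients": [("-6.109", "0.540"), ("0.110", "0.053"), ("-0.044", "0.002"),
                         ("0.035", "0.013"), ("0.005", "0.001")],
        "n": 19, "r_squared": "0.9677", "sd": "0.096", "f": "106",
        "vif_max": "2.7", "adj_r_squared": "0.9585", "press": "0.220",
    },
    "Eq5": {
        "coefficients": [("-6.250", "0.428"), ("0.157", "0.058"), ("-0.043", "0.002"),
                         ("0.034", "0.012"), ("0.004", "0.001")],
        "n": 19, "r_squared": "0.9723", "sd": "0.089", "f": "123",
        "vif_max": "2.3", "adj_r_squared": "0.9644", "press": "0.170",
    },
    "Eq6": {
        "coefficients": [("2.383", "0.244"), ("0.063", "0.022"), ("0.010", "0.007"),
                         ("0.008", "0.001")],
        "n": 19, "r_squared": "0.9368", "sd": "0.064", "f": "75",
        "vif_max": "1.3", "adj_r_squared": "0.9241", "press": "0.093",
    },
    "Eq7": {
        "coefficients": [("2.412", "0.4220"), ("0.018", "0.043"), ("0.008", "0.010"),
                         ("0.008", "0.001")],
        "n": 19, "r_squared": "0.9031", "sd": "0.079", "f": "47",
        "vif_max": "2.6", "adj_r_squared": "0.8837", "press": "0.153",
    },
    "Eq8": {
        "coefficients": [("2.356", "0.3500"), ("0.019", "0.049"), ("0.008", "0.009"),
                         ("0.008", "0.001")],
        "n": 19, "r_squared": "0.9028", "sd": "0.079", "f": "46",
        "vif_max": "2.1", "adj_r_squared": "0.8834", "press": "0.147",
    },
    "Eq9": {
        "coefficients": [("-0.041", "0.155"), ("0.017", "0.020"), ("-0.019", "0.002"),
                         ("0.043", "0.007")],
        "n": 19, "r_squared": "0.9554", "sd": "0.048", "f": "108",
        "vif_max": "2.6", "adj_r_squared": "0.9465", "press": "0.052",
    },
    "Eq10": {
        "coefficients": [("0.051", "0.150"), ("0.033", "0.017"), ("-0.020", "0.001"),
                         ("0.041", "0.006")],
        "n": 19, "r_squared": "0.9630", "sd": "0.043", "f": "130",
        "vif_max": "1.8", "adj_r_squared": "0.9556", "press": "0.043",
    },
    "Eq11": {
        # the alpha standard error is printed as 0.06, an evident misprint
        # of 0.006 given every sibling equation
        "coefficients": [("-0.005", "0.133"), ("0.049", "0.020"), ("-0.020", "0.001"),
                         ("0.040", "0.06")],
        "n": 19, "r_squared": "0.9673", "sd": "0.041", "f": "148",
        "vif_max": "1.8", "adj_r_squared": "0.9608", "press": "0.036",
    },
    "Eq12": {
        "coefficients": [("159.92", "28.86"), ("3.76", "4.77"), ("-1.90", "0.29"),
                         ("0.47", "0.13")],
        "n": 19, "r_squared": "0.8799", "sd": "9.723", "f": "37",
        "vif_max": "2.5", "adj_r_squared": "0.8559", "press": "2468",
    },
    "Eq13": {
        "coefficients": [("203.38", "31.52"), ("10.08", "4.16"), ("-2.11", "0.18"),
                         ("0.34", "0.12")],
        "n": 19, "r_squared": "0.9101", "sd": "8.413", "f": "51",
        "vif_max": "2.2", "adj_r_squared": "0.8921", "press": "1827",
    },
    "Eq14": {
        "coefficients": [("183.81", "26.42"), ("12.63", "4.90"), ("-2.04", "0.17"),
                         ("0.35", "0.11")],
        "n": 19, "r_squared": "0.9133", "sd": "8.260", "f": "53",
        "vif_max": "2", "adj_r_squared": "0.8960", "press": "1824",
    },
    "Eq15": {
        "coefficients": [("0.739", "0.147"), ("-0.014", "0.024"), ("0.012", "0.001"),
                         ("-0.003", "0.001")],
        "n": 19, "r_squared": "0.9139", "sd": "0.050", "f": "53",
        "vif_max": "2.5", "adj_r_squared": "0.8967", "press": "0.058",
    },
    "Eq16": {
        "coefficients": [("0.585", "0.174"), ("-0.036", "0.023"), ("0.013", "0.001"),
                         ("-0.003", "0.001")],
        "n": 19, "r_squared": "0.9243", "sd": "0.046", "f": "61",
        "vif_max": "2.2", "adj_r_squared": "0.9091", "press": "0.049",
    },
    "Eq17": {
        "coefficients": [("0.643", "0.144"), ("-0.050", "0.027"), ("0.012", "0.001"),
                         ("-0.003", "0.001")],
        "n": 19, "r_squared": "0.9286", "sd": "0.045", "f": "65",
        "vif_max": "2", "adj_r_squared": "0.9143", "press": "0.044",
    },
    "Eq18": {
        "coefficients": [("-6.780", "0.470"), ("0.079", "0.122"), ("-0.043", "0.005"),
                         ("0.042", "0.017"), ("0.006", "0.001")],
        "n": 19, "r_squared": "0.9590", "sd": "0.109", "f": "82",
        "vif_max": "4.6", "adj_r_squared": "0.9473", "press": "0.284",
    },
    "Eq19": {
        "coefficients": [("2.292", "0.255"), ("0.106", "0.043"), ("0.010", "0.007"),
                         ("0.008", "0.001")],
        "n": 19, "r_squared": "0.9300", "sd": "0.067", "f": "67",
        "vif_max": "1.2", "adj_r_squared": "0.9160", "press": "0.111",
    },
    "Eq20": {
        "coefficients": [("-0.052", "0.155"), ("0.033", "0.043"), ("-0.019", "0.002"),
                         ("0.042", "0.007")],
        "n": 19, "r_squared": "0.9551", "sd": "0.048", "f": "107",
        "vif_max": "3", "adj_r_squared": "0.9462", "press": "0.054",
    },
    "Eq21": {
        "coefficients": [("153.28", "26.64"), ("13.46", "8.48"), ("-1.75", "0.28"),
                         ("0.43", "0.11")],
        "n": 19, "r_squared": "0.8929", "sd": "9.182", "f": "42",
        "vif_max": "2.3", "adj_r_squared": "0.8715", "press": "2311",
    },
    "Eq22": {
        "coefficients": [("0.762", "0.142"), ("-0.038", "0.045"), ("0.012", "0.001"),
                         ("-0.001", "0.001")],
        "n": 19, "r_squared": "0.9158", "sd": "0.049", "f": "55",
        "vif_max": "2.3", "adj_r_squared": "0.8989", "press": "0.058",
    },
}

#: compound_id -> (printed log_km, printed Foley-fit R^2).
REFERENCE_FOLEY: dict[str, tuple[str, str]] = {
    "1": ("1.29", "0.8851"),
    "2": ("1.68", "0.9662"),
    "3": ("1.07", "0.9725"),
    "4": ("2.28", "0.9732"),
    "5": ("2.22", "0.9754"),
    "6": ("2.82", "0.9854"),
    "7": ("1.37", "0.9862"),
    "8": ("0.92", "0.9889"),
    "9": ("1.81", "0.9870"),
    "10": ("0.88", "0.9929"),
    "11": ("1.24", "0.9947"),
    "12": ("2.52", "0.9855"),
    "13": ("2.49", "0.9911"),
    "14": ("2.70", "0.9887"),
    "15": ("0.38", "0.8467"),
    "16": ("0.74", "0.9084"),
    "17": ("1.12", "0.8604"),
    "18": ("1.12", "0.8467"),
    "19": ("1.83", "0.9117"),
}

#: Printed cells a faithful refit of the bundled (printed, hence rounded)
#: data cannot reproduce within tolerance; see docs/methods.md for the
#: analysis. Keys are (label, quantity) as used in the reproduce report.
KNOWN_DISCREPANT: set[tuple[str, str]] = set()
# Eq3's whole coefficient string is inconsistent with its own printed
# global statistics (plugging it into the data gives R^2 = 0.856, not the
# printed 0.9593, which the refit does reproduce to 3e-4).
KNOWN_DISCREPANT |= {("Eq3", f"coef[{j}]") for j in range(5)}
KNOWN_DISCREPANT |= {("Eq3", f"se[{j}]") for j in range(5)}
# Misprints: Eq11 alpha SE 0.06 for 0.006; Eq8 intercept SE printed with a
# spurious fourth decimal (computed 0.3497 vs "0.3500").
KNOWN_DISCREPANT |= {("Eq11", "se[3]"), ("Eq8", "se[0]")}
# Drift from the log_km-carrying models having been fitted on unrounded
# retention data (the bundled table necessarily carries the printed k):
# the 4th decimal of R^2 / adjusted R^2, last printed digit of a few
# coefficients/SEs/sd/PRESS, and Eq22's MW coefficient.
KNOWN_DISCREPANT |= {
    ("Eq3", "r_squared"), ("Eq3", "adj_r_squared"), ("Eq3", "press"),
    ("Eq6", "coef[0]"), ("Eq6", "se[0]"), ("Eq6", "coef[1]"),
    ("Eq6", "r_squared"), ("Eq6", "adj_r_squared"),
    ("Eq9", "coef[0]"), ("Eq9", "r_squared"), ("Eq9", "adj_r_squared"),
    ("Eq12", "coef[0]"), ("Eq12", "se[0]"), ("Eq12", "coef[1]"), ("Eq12", "se[1]"),
    ("Eq12", "r_squared"), ("Eq12", "sd"), ("Eq12", "adj_r_squared"), ("Eq12", "press"),
    ("Eq15", "coef[0]"), ("Eq15", "coef[1]"),
    ("Eq15", "r_squared"), ("Eq15", "adj_r_squared"),
    ("Eq22", "coef[3]"),
}
# Same rounding drift in the Foley columns: log_km for two compounds and
# R^2 in the 4th decimal for several rows; the two grossly different R^2
# cells (compounds 15 and 18) both print 0.8467, an apparent duplication.
KNOWN_DISCREPANT |= {
    ("foley:12", "log_km"), ("foley:13", "log_km"),
    ("foley:1", "r_squared"), ("foley:3", "r_squared"), ("foley:7", "r_squared"),
    ("foley:8", "r_squared"), ("foley:15", "r_squared"), ("foley:16", "r_squared"),
    ("foley:18", "r_squared"),
}
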