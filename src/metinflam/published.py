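"""Published reference values from the appendicitis index study.

These are *inputs* to the package, not results it claims to compute: the
fixed cutoffs let a user classify new patients with the published decision
thresholds, the printed odds ratios and group sizes feed the post-hoc power
table, and the sensitivity/specificity/Youden columns support internal
consistency checks (J = Se + Sp - 100).

All cutoffs are labelled "as published, units convention unverified": the
source does not state whether they were derived from absolute counts
(10^3/uL) or percent differentials.
"""

from __future__ import annotations

INDEX_NAMES = ("nlr", "plr", "sii", "imi", "glr", "nlcr", "clr", "gcnli", "misi")

#: Outcome classifications: histopathological (perforated vs non-perforated)
#: and surgical (complicated, stages III-IV, vs uncomplicated, stages I-II).
CLASSIFICATIONS = ("histopathological", "surgical")

#: Study group sizes (disease-positive, disease-negative) per classification.
GROUP_SIZES = {
    "histopathological": (21, 225),
    "surgical": (76, 170),
}

#: Published decision thresholds per index and classification ("fixed cutoffs").
PUBLISHED_CUTOFFS = {
    "histopathological": {
        "nlr": 5.015, "plr": 147.42, "sii": 1463.02,
        "imi": 658.71, "glr": 117.46, "nlcr": 9.66,
        "clr": 0.64, "gcnli": 905.51, "misi": 83.82,
    },
    "surgical": {
        "nlr": 10.76, "plr": 235.355, "sii": 3718.42,
        "imi": 987.83, "glr": 71.74, "nlcr": 8.04,
        "clr": 0.47, "gcnli": 1267.7, "misi": 54.81,
    },
}

#: Published diagnostic performance at the fixed cutoffs:
#: auc, sensitivity, specificity, ppv, npv, youden (percent scale), odds_ratio.
#: ``float("inf")`` marks an odds ratio reported as +inf (a zero cell).
PUBLISHED_PERFORMANCE = {
    "histopathological": {
        "nlr":   {"auc": 0.662, "sensitivity": 95.45, "specificity": 26.76,
                  "ppv": 11.86, "npv": 98.28, "youden": 22.21, "odds_ratio": 7.7},
        "plr":   {"auc": 0.648, "sensitivity": 95.24, "specificity": 32.26,
                  "ppv": 11.98, "npv": 98.59, "youden": 27.5, "odds_ratio": 9.5},
        "sii":   {"auc": 0.600, "sensitivity": 100.0, "specificity": 31.13,
                  "ppv": 12.57, "npv": 100.0, "youden": 31.13,
                  "odds_ratio": float("inf")},
        "imi":   {"auc": 0.688, "sensitivity": 94.74, "specificity": 36.72,
                  "ppv": 13.84, "npv": 98.48, "youden": 31.46, "odds_ratio": 10.45},
        "glr":   {"auc": 0.721, "sensitivity": 68.42, "specificity": 73.48,
                  "ppv": 21.31, "npv": 95.68, "youden": 41.9, "odds_ratio": 6.01},
        "nlcr":  {"auc": 0.699, "sensitivity": 57.89, "specificity": 75.14,
                  "ppv": 20.0, "npv": 94.3, "youden": 33.04, "odds_ratio": 4.2},
        "clr":   {"auc": 0.720, "sensitivity": 73.68, "specificity": 62.98,
                  "ppv": 17.28, "npv": 95.8, "youden": 36.67, "odds_ratio": 4.76},
        "gcnli": {"auc": 0.597, "sensitivity": 89.47, "specificity": 33.9,
                  "ppv": 12.69, "npv": 96.77, "youden": 23.37, "odds_ratio": 4.36},
        "misi":  {"auc": 0.742, "sensitivity": 68.42, "specificity": 72.38,
                  "ppv": 20.63, "npv": 95.62, "youden": 40.8, "odds_ratio": 5.68},
    },
    "surgical": {
        "nlr":   {"auc": 0.679, "sensitivity": 45.96, "specificity": 82.19,
                  "ppv": 85.06, "npv": 40.82, "youden": 28.15, "odds_ratio": 3.9},
        "plr":   {"auc": 0.677, "sensitivity": 46.34, "specificity": 83.78,
                  "ppv": 86.36, "npv": 41.33, "youden": 30.12, "odds_ratio": 4.5},
        "sii":   {"auc": 0.667, "sensitivity": 33.75, "specificity": 91.78,
                  "ppv": 90.0, "npv": 38.73, "youden": 25.53, "odds_ratio": 5.7},
        "imi":   {"auc": 0.753, "sensitivity": 58.52, "specificity": 78.69,
                  "ppv": 85.87, "npv": 46.15, "youden": 37.21, "odds_ratio": 5.21},
        "glr":   {"auc": 0.743, "sensitivity": 65.94, "specificity": 75.81,
                  "ppv": 85.85, "npv": 50.0, "youden": 41.75, "odds_ratio": 6.1},
        "nlcr":  {"auc": 0.677, "sensitivity": 46.67, "specificity": 83.61,
                  "ppv": 86.3, "npv": 41.46, "youden": 30.27, "odds_ratio": 4.46},
        "clr":   {"auc": 0.632, "sensitivity": 64.49, "specificity": 64.52,
                  "ppv": 80.18, "npv": 44.94, "youden": 29.01, "odds_ratio": 3.3},
        "gcnli": {"auc": 0.762, "sensitivity": 68.15, "specificity": 73.77,
                  "ppv": 85.18, "npv": 51.14, "youden": 41.92, "odds_ratio": 6.02},
        "misi":  {"auc": 0.676, "sensitivity": 60.15, "specificity": 72.58,
                  "ppv": 83.0, "npv": 45.0, "youden": 32.73, "odds_ratio": 3.99},
    },
}

#: Published post-hoc power table rows: (index, odds_ratio, n1, n2,
#: effect_size, power, power_rounded). n1 = disease-positive group.
PUBLISHED_POWER_TABLE = {
    "histopathological": [
        ("imi",   10.45, 21, 225, 1.29375, 0.99990, 1.000),
        ("glr",    6.01, 21, 225, 0.98877, 0.99119, 0.991),
        ("nlcr",   4.2,  21, 225, 0.79120, 0.93416, 0.934),
        ("clr",    4.76, 21, 225, 0.86021, 0.96485, 0.965),
        ("gcnli",  4.36, 21, 225, 0.81182, 0.94497, 0.945),
        ("misi",   5.68, 21, 225, 0.95763, 0.98735, 0.987),
    ],
    "surgical": [
        ("imi",   5.21, 76, 170, 0.91001, 1.00000, 1.000),
        ("glr",   6.1,  76, 170, 0.99696, 1.00000, 1.000),
        ("nlcr",  4.46, 76, 170, 0.82432, 0.99997, 1.000),
        ("clr",   3.3,  76, 170, 0.65824, 0.99753, 0.998),
        ("gcnli", 6.02, 76, 170, 0.98968, 1.00000, 1.000),
        ("misi",  3.99, 76, 170, 0.76292, 0.99982, 1.000),
    ],
}
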