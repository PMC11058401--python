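"""Published summary statistics of the smartphone-app intervention trial.

These are the printed inputs from which every closed-form statistic of the
study can be recomputed (baseline group comparisons, interaction effect
sizes, paired-test effect sizes, correlation tests and their between-group
Fisher comparisons).  They double as the calibration target the synthetic
cohort generator emulates.

Group sample sizes were 35/35 after screening 89 recruits (18 excluded by a
CES-D score of 16 or higher, 1 by missing imaging).
"""

from __future__ import annotations

N_PER_GROUP = 35

DESIGN = {
    "recruited": 89,
    "excluded_cesd": 18,
    "excluded_imaging": 1,
    "retained": 70,
    "retained_women": 39,
    "retained_men": 31,
    "power_effect_size_d": 0.5,
    "power_alpha": 0.05,
    "power_target": 0.80,
    "power_required_n": 34,
}

BRAIN_MEASURES = (
    "fa_bhq",
    "gm_bhq",
    "corpus_callosum",
    "internal_capsule",
    "corona_radiata",
    "posterior_thalamic_radiation",
    "external_capsule",
    "cingulum",
    "superior_longitudinal_fasciculus",
    "uncinate_fasciculus",
)

# measure: (mean_int, sd_int, mean_ctl, sd_ctl, t, p); t printed as magnitude
TABLE1 = {
    "fa_bhq": (95.445, 4.254, 97.476, 3.507, 2.179, 0.033),
    "gm_bhq": (96.276, 7.614, 96.983, 7.120, 0.401, 0.690),
    "corpus_callosum": (94.737, 6.367, 97.283, 5.213, 1.831, 0.071),
    "internal_capsule": (94.156, 4.628, 96.118, 4.581, 1.783, 0.079),
    "corona_radiata": (94.770, 6.435, 96.784, 5.217, 1.439, 0.155),
    "posterior_thalamic_radiation": (96.142, 6.408, 99.217, 5.330, 2.182, 0.033),
    "external_capsule": (96.164, 5.701, 98.301, 4.248, 1.778, 0.080),
    "cingulum": (95.574, 4.452, 98.038, 3.986, 2.439, 0.017),
    "superior_longitudinal_fasciculus": (96.795, 5.024, 99.521, 3.918, 2.532, 0.014),
    "uncinate_fasciculus": (92.886, 6.462, 96.352, 5.236, 2.465, 0.016),
    "poms_ah": (2.890, 2.529, 2.690, 2.349, 0.343, 0.733),
    "poms_cb": (2.400, 2.172, 1.630, 1.784, 1.624, 0.109),
    "poms_dd": (1.940, 2.338, 1.140, 1.801, 1.604, 0.114),
    "poms_fi": (2.830, 2.269, 3.140, 3.040, 0.490, 0.626),
    "poms_ta": (3.510, 2.801, 3.110, 2.676, 0.611, 0.543),
    "poms_va": (10.690, 4.745, 12.460, 3.936, 1.700, 0.094),
    "poms_f": (11.570, 4.111, 12.830, 2.925, 1.474, 0.146),
    "tmt_a": (22.640, 5.880, 22.060, 4.795, 0.452, 0.653),
    "tmt_b": (51.867, 23.570, 46.091, 11.599, 1.301, 0.199),
    "tmt_b_a": (31.641, 17.726, 24.031, 10.244, 2.199, 0.032),
    "age": (53.660, 8.731, 52.260, 6.599, 0.757, 0.452),
    "bmi": (22.143, 3.366, 23.240, 3.551, 1.327, 0.189),
}

# male_int, female_int, male_ctl, female_ctl, chi2, p
TABLE1_SEX = (14, 21, 17, 18, 0.521, 0.470)

# measure: F, p, partial eta^2, then per group (pre_mean, pre_sd, post_mean,
# post_sd, paired t, p, Cohen's d); paired differences are pre - post
LONGITUDINAL = {
    "fa_bhq": (
        5.292, 0.024, 0.072,
        (95.445, 4.254, 95.970, 4.010, -2.078, 0.045, -0.351),
        (97.476, 3.507, 97.074, 3.419, 1.281, 0.209, 0.217),
    ),
    "gm_bhq": (
        0.387, 0.536, 0.006,
        (96.276, 7.614, 96.612, 7.608, -1.218, 0.232, -0.206),
        (96.983, 7.120, 97.098, 7.122, -0.520, 0.607, -0.088),
    ),
    "corpus_callosum": (
        6.605, 0.012, 0.089,
        (94.737, 6.367, 95.301, 5.994, -1.926, 0.062, -0.326),
        (97.283, 5.213, 96.705, 5.293, 1.729, 0.093, 0.292),
    ),
    "internal_capsule": (
        6.358, 0.014, 0.086,
        (94.156, 4.628, 94.980, 4.492, -2.278, 0.029, -0.385),
        (96.118, 4.581, 95.530, 4.200, 1.376, 0.178, 0.233),
    ),
    "corona_radiata": (
        5.323, 0.024, 0.073,
        (94.770, 6.435, 95.275, 6.470, -1.836, 0.075, -0.310),
        (96.784, 5.217, 96.317, 5.021, 1.463, 0.153, 0.247),
    ),
    "posterior_thalamic_radiation": (
        5.091, 0.027, 0.070,
        (96.142, 6.408, 96.718, 6.295, -2.020, 0.051, -0.341),
        (99.217, 5.330, 98.836, 5.451, 1.213, 0.234, 0.205),
    ),
    "external_capsule": (
        4.929, 0.030, 0.068,
        (96.164, 5.701, 96.918, 5.383, -2.556, 0.015, -0.432),
        (98.301, 4.248, 97.990, 3.898, 0.823, 0.416, 0.139),
    ),
    "cingulum": (
        3.796, 0.056, 0.053,
        (95.574, 4.452, 95.976, 4.130, -1.440, 0.159, -0.243),
        (98.038, 3.986, 97.635, 3.826, 1.323, 0.195, 0.224),
    ),
    "superior_longitudinal_fasciculus": (
        5.963, 0.017, 0.081,
        (96.795, 5.024, 97.179, 4.755, -1.674, 0.103, -0.283),
        (99.521, 3.918, 98.970, 3.519, 1.797, 0.081, 0.304),
    ),
    "uncinate_fasciculus": (
        2.905, 0.093, 0.041,
        (92.886, 6.462, 93.577, 6.531, -1.455, 0.155, -0.246),
        (96.352, 5.236, 95.946, 5.445, 0.935, 0.357, 0.158),
    ),
    "poms_ah": (
        0.108, 0.743, 0.002,
        (2.890, 2.529, 2.830, 1.871, 0.132, 0.896, 0.022),
        (2.690, 2.349, 2.800, 2.506, -0.391, 0.698, -0.066),
    ),
    "poms_cb": (
        0.000, 1.000, 0.000,
        (2.400, 2.172, 2.400, 1.850, 0.000, 1.000, 0.000),
        (1.630, 1.784, 1.630, 1.784, 0.000, 1.000, 0.000),
    ),
    "poms_dd": (
        0.063, 0.803, 0.001,
        (1.940, 2.338, 1.800, 1.762, 0.380, 0.706, 0.064),
        (1.140, 1.801, 1.110, 1.659, 0.111, 0.912, 0.019),
    ),
    "poms_fi": (
        3.396, 0.070, 0.048,
        (2.830, 2.269, 3.660, 2.689, -1.996, 0.054, -0.337),
        (3.140, 3.040, 3.090, 2.716, 0.236, 0.815, 0.040),
    ),
    "poms_ta": (
        0.002, 0.962, 0.000,
        (3.510, 2.801, 3.340, 1.846, 0.340, 0.736, 0.057),
        (3.110, 2.676, 2.910, 2.188, 0.647, 0.522, 0.109),
    ),
    "poms_va": (
        0.920, 0.341, 0.013,
        (10.690, 4.745, 11.140, 4.930, -0.826, 0.415, -0.140),
        (12.460, 3.936, 12.260, 3.995, 0.496, 0.623, 0.084),
    ),
    "poms_f": (
        0.422, 0.518, 0.006,
        (11.570, 4.111, 11.770, 3.557, -0.486, 0.630, -0.082),
        (12.830, 2.925, 12.660, 2.910, 0.432, 0.668, 0.073),
    ),
    "tmt_a": (
        0.099, 0.754, 0.001,
        (22.640, 5.880, 19.957, 4.550, 3.343, 0.002, 0.565),
        (22.060, 4.795, 19.757, 5.531, 2.553, 0.015, 0.432),
    ),
    "tmt_b": (
        0.380, 0.540, 0.006,
        (51.867, 23.570, 52.689, 24.301, -0.137, 0.892, -0.023),
        (46.091, 11.599, 43.131, 13.973, 2.325, 0.026, 0.393),
    ),
    "tmt_b_a": (
        0.107, 0.744, 0.002,
        (31.641, 17.726, 32.731, 24.381, -0.226, 0.822, -0.038),
        (24.031, 10.244, 23.460, 13.855, 0.359, 0.722, 0.061),
    ),
}

#: measures whose interaction p-values form the multiple-comparison family
REGIONAL_FAMILY = (
    "corpus_callosum",
    "internal_capsule",
    "corona_radiata",
    "posterior_thalamic_radiation",
    "external_capsule",
    "cingulum",
    "superior_longitudinal_fasciculus",
    "uncinate_fasciculus",
)

#: regions reported significant at the 5% level after BH adjustment
REGIONS_SIGNIFICANT_BH = (
    "corpus_callosum",
    "internal_capsule",
    "corona_radiata",
    "posterior_thalamic_radiation",
    "external_capsule",
    "superior_longitudinal_fasciculus",
)

CORRELATION_COLUMNS = (
    "fa_bhq",
    "corpus_callosum",
    "internal_capsule",
    "corona_radiata",
    "posterior_thalamic_radiation",
    "external_capsule",
    "superior_longitudinal_fasciculus",
)

CORRELATION_ROWS = (
    "poms_ah", "poms_cb", "poms_dd", "poms_fi", "poms_ta", "poms_va", "poms_f",
    "tmt_a", "tmt_b", "tmt_b_a",
)

# change-score correlations (r, p) per behavior row x brain column, n = 35
CHANGE_CORRELATIONS_INTERVENTION = {
    "poms_ah": ((-0.027, 0.875), (-0.044, 0.801), (0.002, 0.992), (-0.111, 0.527), (0.055, 0.754), (0.014, 0.935), (-0.070, 0.689)),
    "poms_cb": ((-0.187, 0.283), (-0.198, 0.255), (-0.171, 0.327), (-0.254, 0.141), (-0.241, 0.163), (-0.122, 0.485), (-0.022, 0.900)),
    "poms_dd": ((0.134, 0.443), (0.088, 0.617), (0.103, 0.555), (0.042, 0.812), (0.128, 0.463), (0.207, 0.232), (0.180, 0.301)),
    "poms_fi": ((-0.177, 0.308), (-0.261, 0.130), (-0.130, 0.455), (-0.250, 0.147), (-0.186, 0.284), (-0.234, 0.177), (-0.282, 0.101)),
    "poms_ta": ((-0.002, 0.992), (-0.022, 0.898), (0.013, 0.942), (-0.082, 0.639), (-0.006, 0.974), (0.076, 0.664), (0.079, 0.653)),
    "poms_va": ((0.359, 0.034), (0.268, 0.120), (0.372, 0.028), (0.280, 0.103), (0.292, 0.089), (0.367, 0.030), (0.313, 0.067)),
    "poms_f": ((0.066, 0.706), (0.008, 0.964), (0.128, 0.465), (0.067, 0.701), (-0.082, 0.639), (0.090, 0.607), (0.133, 0.448)),
    "tmt_a": ((0.101, 0.565), (0.122, 0.484), (0.156, 0.370), (0.099, 0.573), (0.093, 0.597), (0.131, 0.454), (-0.060, 0.732)),
    "tmt_b": ((-0.304, 0.076), (-0.335, 0.049), (-0.353, 0.038), (-0.376, 0.026), (-0.277, 0.108), (-0.403, 0.016), (-0.230, 0.183)),
    "tmt_b_a": ((-0.343, 0.044), (-0.366, 0.031), (-0.399, 0.018), (-0.392, 0.020), (-0.299, 0.081), (-0.438, 0.009), (-0.225, 0.195)),
}

CHANGE_CORRELATIONS_CONTROL = {
    "poms_ah": ((-0.009, 0.961), (-0.061, 0.729), (0.032, 0.854), (0.006, 0.973), (-0.026, 0.884), (-0.139, 0.424), (0.006, 0.971)),
    "poms_cb": ((-0.081, 0.643), (0.000, 1.000), (-0.116, 0.508), (-0.110, 0.528), (-0.103, 0.557), (0.019, 0.913), (0.035, 0.842)),
    "poms_dd": ((-0.094, 0.590), (0.006, 0.971), (-0.124, 0.479), (-0.131, 0.453), (-0.145, 0.406), (-0.093, 0.596), (-0.136, 0.437)),
    "poms_fi": ((0.008, 0.962), (0.079, 0.653), (0.024, 0.893), (0.021, 0.904), (-0.067, 0.703), (-0.075, 0.670), (0.010, 0.955)),
    "poms_ta": ((-0.050, 0.777), (0.039, 0.825), (-0.107, 0.541), (-0.047, 0.787), (-0.176, 0.312), (-0.158, 0.366), (-0.140, 0.423)),
    "poms_va": ((-0.286, 0.096), (-0.327, 0.055), (-0.269, 0.118), (-0.272, 0.114), (-0.129, 0.461), (-0.230, 0.184), (0.015, 0.933)),
    "poms_f": ((-0.168, 0.335), (-0.208, 0.231), (-0.180, 0.300), (-0.160, 0.359), (-0.067, 0.702), (-0.178, 0.307), (-0.019, 0.912)),
    "tmt_a": ((0.239, 0.166), (0.219, 0.207), (0.232, 0.180), (0.284, 0.099), (0.109, 0.535), (0.181, 0.299), (0.268, 0.120)),
    "tmt_b": ((0.064, 0.716), (0.062, 0.722), (0.058, 0.741), (0.142, 0.416), (-0.063, 0.719), (-0.046, 0.794), (0.021, 0.906)),
    "tmt_b_a": ((-0.089, 0.613), (-0.080, 0.647), (-0.087, 0.618), (-0.048, 0.784), (-0.114, 0.516), (-0.144, 0.410), (-0.137, 0.432)),
}

# printed Fisher r-to-z comparisons: (behavior, brain, z, p)
FISHER_COMPARISONS = (
    ("poms_va", "fa_bhq", 2.680, 0.004),
    ("poms_va", "internal_capsule", 2.666, 0.004),
    ("poms_va", "external_capsule", 2.477, 0.007),
    ("tmt_b", "corpus_callosum", -1.642, 0.050),
    ("tmt_b", "internal_capsule", -1.708, 0.044),
    ("tmt_b", "corona_radiata", -2.153, 0.016),
    ("tmt_b", "external_capsule", -1.525, 0.064),
    ("tmt_b_a", "fa_bhq", -1.073, 0.142),
    ("tmt_b_a", "corpus_callosum", -1.215, 0.112),
    ("tmt_b_a", "internal_capsule", -1.341, 0.090),
    ("tmt_b_a", "corona_radiata", -1.464, 0.072),
    ("tmt_b_a", "external_capsule", -1.299, 0.097),
)
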