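"""Published descriptive statistics of the reference cohort.

Group means and standard deviations of the adult DXA reference cohort
(10,894 participants, ages 18-81, Lunar Prodigy scanner), stratified by sex
and decade-style age group.  These printed values serve two purposes in this
package: they calibrate the synthetic cohort generator's true L/M/S curves,
and they feed the index-formula consistency checks (applying the index
definitions to the printed group means must reproduce the printed index
values).

All masses in kg except VAT mass (g) and VAT volume (cm^3); heights in cm;
indices in kg/m^2; ratios dimensionless.
"""

from __future__ import annotations

AGE_GROUPS: list[tuple[float, float]] = [
    (18.0, 30.0),
    (30.0, 40.0),
    (40.0, 50.0),
    (50.0, 60.0),
    (60.0, 70.0),
    (70.0, 82.0),
]

AGE_GROUP_LABELS: list[str] = [
    "18 to <30",
    "30 to <40",
    "40 to <50",
    "50 to <60",
    "60 to <70",
    "70 to <82",
]

AGE_GROUP_MIDPOINTS: list[float] = [(a + b) / 2.0 for a, b in AGE_GROUPS]

#: per-sex sample sizes by age group
GROUP_N = {
    "male": [1233, 885, 830, 839, 784, 576],
    "female": [1324, 861, 1040, 1010, 925, 587],
}

#: (mean, sd) per age group, in AGE_GROUPS order
GROUP_STATS = {
    "male": {
        "height": [(178.6, 7.1), (178.8, 6.9), (179.2, 6.9), (178.1, 6.7), (175.0, 6.5), (173.7, 6.7)],
        "weight": [(77.4, 13.3), (82.6, 13.2), (86.9, 14.7), (88.2, 14.1), (86.3, 12.9), (84.7, 12.7)],
        "bmi": [(24.2, 3.8), (25.9, 4.0), (27.0, 4.2), (27.8, 4.1), (28.2, 4.0), (28.1, 3.7)],
        "fm_total": [(19.0, 8.8), (22.6, 8.8), (25.6, 9.5), (27.2, 9.1), (27.7, 8.4), (27.9, 8.4)],
        "lm_total": [(55.2, 7.2), (56.9, 6.9), (58.1, 7.0), (57.8, 6.7), (55.5, 6.2), (53.6, 5.9)],
        "fmi": [(6.0, 2.7), (7.1, 2.8), (8.0, 2.9), (8.6, 2.8), (9.0, 2.7), (9.3, 2.7)],
        "lmi": [(17.3, 1.9), (17.8, 1.9), (18.1, 1.8), (18.2, 1.8), (18.1, 1.7), (17.8, 1.5)],
        "appendicular_fmi": [(2.8, 1.1), (3.0, 1.1), (3.1, 1.0), (3.2, 1.0), (3.2, 0.9), (3.3, 0.9)],
        "appendicular_lmi": [(8.3, 1.1), (8.5, 1.1), (8.5, 1.0), (8.5, 1.0), (8.2, 1.0), (7.9, 0.8)],
        "fm_android_gynoid": [(0.4, 0.1), (0.5, 0.2), (0.7, 0.2), (0.8, 0.2), (0.8, 0.2), (0.9, 0.2)],
        "fm_trunk_limbs": [(1.0, 0.3), (1.2, 0.3), (1.4, 0.3), (1.6, 0.4), (1.7, 0.4), (1.7, 0.4)],
        "vat_mass": [(424.6, 385.4), (767.2, 543.2), (1243.3, 755.2), (1612.5, 894.8), (1904.0, 914.0), (2037.7, 888.0)],
    },
    "female": {
        "height": [(165.8, 6.4), (165.8, 6.5), (165.5, 6.4), (164.4, 6.3), (161.7, 6.0), (160.4, 6.2)],
        "weight": [(62.1, 11.7), (64.8, 12.8), (68.5, 13.5), (70.2, 13.7), (71.4, 13.4), (71.2, 13.0)],
        "bmi": [(22.6, 4.1), (23.6, 4.6), (25.0, 4.9), (26.0, 5.1), (27.3, 5.1), (27.7, 4.9)],
        "fm_total": [(21.5, 8.2), (23.0, 9.3), (25.6, 9.9), (28.0, 10.1), (30.1, 9.8), (30.5, 9.4)],
        "lm_total": [(38.7, 5.0), (39.8, 5.1), (40.9, 5.2), (40.3, 5.0), (39.5, 4.7), (39.0, 4.8)],
        "fmi": [(7.8, 3.0), (8.4, 3.4), (9.4, 3.7), (10.4, 3.8), (11.6, 3.8), (11.9, 3.7)],
        "lmi": [(14.1, 1.5), (14.5, 1.6), (14.9, 1.7), (14.9, 1.6), (15.1, 1.6), (15.2, 1.6)],
        "appendicular_fmi": [(4.1, 1.4), (4.3, 1.5), (4.6, 1.6), (4.8, 1.6), (5.1, 1.6), (5.2, 1.6)],
        "appendicular_lmi": [(6.4, 0.9), (6.5, 0.9), (6.7, 1.0), (6.6, 0.9), (6.6, 0.9), (6.7, 0.9)],
        "fm_android_gynoid": [(0.3, 0.1), (0.3, 0.1), (0.4, 0.1), (0.5, 0.2), (0.6, 0.2), (0.6, 0.2)],
        "fm_trunk_limbs": [(0.8, 0.2), (0.9, 0.2), (0.9, 0.3), (1.1, 0.3), (1.2, 0.3), (1.2, 0.4)],
        "vat_mass": [(235.6, 241.8), (340.2, 312.6), (522.8, 432.4), (759.9, 528.4), (1053.0, 628.1), (1146.7, 631.3)],
    },
}

#: whole-sample (18 to <82) means and SDs, used by the index consistency checks
OVERALL_STATS = {
    "male": {
        "height": (177.6, 7.1),
        "weight": (83.8, 14.1),
        "bmi": (26.6, 4.3),
        "fm_total": (24.3, 9.5),
        "lm_total": (56.3, 6.9),
        "pct_fm": (29.3, 7.3),
        "fmi": (7.7, 3.0),
        "lmi": (17.8, 1.8),
        "appendicular_fmi": (3.1, 1.0),
        "appendicular_lmi": (8.3, 1.0),
        "fm_android_gynoid": (0.7, 0.2),
        "fm_trunk_limbs": (1.4, 0.4),
        "vat_mass": (1218.1, 939.2),
    },
    "female": {
        "height": (164.3, 6.6),
        "weight": (67.5, 13.4),
        "bmi": (25.1, 5.1),
        "fm_total": (25.9, 10.0),
        "lm_total": (39.7, 5.1),
        "pct_fm": (38.3, 7.5),
        "fmi": (9.7, 3.8),
        "lmi": (14.7, 1.7),
        "appendicular_fmi": (4.6, 1.6),
        "appendicular_lmi": (6.6, 0.9),
        "fm_android_gynoid": (0.4, 0.2),
        "fm_trunk_limbs": (1.0, 0.3),
        "vat_mass": (635.1, 574.3),
    },
}

#: parameters modelled with age-specific reference distributions
REFERENCE_PARAMETERS = (
    "fmi",
    "lmi",
    "appendicular_lmi",
    "appendicular_fmi",
    "fm_android_gynoid",
    "fm_trunk_limbs",
    "vat_mass",
)
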