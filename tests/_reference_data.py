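"""Reference values for a seven-rung island-area ladder (0.36..2.52 m²).

Per abundance class: observed richness and the random-placement expectation
at each area, plus the paired statistics they imply (differences taken as
expectation - observation, sample SD with n-1, two-sided t with 6 df).
These are fixed external inputs for the comparison machinery.
"""

AREAS_M2 = [0.36, 0.72, 1.08, 1.44, 1.80, 2.16, 2.52]

OBSERVED = {
    "abundant": [117, 126, 132, 142, 144, 144, 145],
    "moderate": [428, 550, 589, 838, 920, 1075, 1181],
    "rare": [1071, 1317, 1736, 2924, 3752, 4532, 4924],
}

EXPECTED = {
    "abundant": [116.99, 126.0, 132.0, 142.0, 144.0, 144.0, 145.0],
    "moderate": [408.81, 547.52, 588.82, 837.99, 919.99, 1074.99, 1180.99],
    "rare": [344.64, 845.93, 1318.16, 2419.99, 3375.47, 4253.83, 4808.07],
}

# published paired statistics (rounding as printed)
PUBLISHED_STATS = {
    "abundant": {"mean": -0.00143, "sd": 0.00378, "abs_t": 1.0},
    "moderate": {"mean": -3.127, "sd": 7.141, "abs_t": 1.159},
    "rare": {"mean": -412.8, "sd": 190.5, "abs_t": 5.735},
}

# total observed richness per rung (abundant + moderate + rare)
TOTAL_OBSERVED = [1616, 1993, 2457, 3904, 4816, 5751, 6250]
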