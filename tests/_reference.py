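"""Reference values from a published 10-patient clinical cohort.

Used to pin down the package's aggregation and percentage conventions:
per-patient normal/abnormal/ST beat counts for the night-window summary, and
per-tumor delivered energies whose per-patient sums are known.
"""

# patient id -> (N, A, ST) beat counts, before and after treatment
BEAT_COUNTS_BEFORE = {
    "4": (14317, 12, 0),
    "5": (15722, 3, 15692),
    "6": (13975, 309, 0),
    "7": (16873, 20, 0),
    "9": (18321, 18, 6915),
    "10": (14785, 70, 0),
    "12": (18825, 42, 0),
    "13": (13864, 6, 0),
    "14": (13857, 135, 10111),
    "15": (17461, 25, 696),
}
BEAT_COUNTS_AFTER = {
    "4": (14216, 17, 0),
    "5": (18112, 1, 14001),
    "6": (18271, 8, 0),
    "7": (18820, 15, 2321),
    "9": (26047, 9, 0),
    "10": (15202, 23, 763),
    "12": (17764, 6, 4395),
    "13": (19405, 8, 3209),
    "14": (16620, 0, 7078),
    "15": (26450, 39, 25188),
}

# printed per-patient abnormal-beat percentages (3 decimals) before treatment
PCT_ABNORMAL_BEFORE = {
    "4": 0.084, "5": 0.019, "6": 2.163, "7": 0.118, "9": 0.098,
    "10": 0.471, "12": 0.223, "13": 0.043, "14": 0.965, "15": 0.143,
}
PCT_ABNORMAL_AFTER = {
    "4": 0.119, "5": 0.006, "6": 0.044, "7": 0.080, "9": 0.035,
    "10": 0.151, "12": 0.034, "13": 0.044, "14": 0.0, "15": 0.147,
}
# printed ST percentages (1 decimal unless < 10)
PCT_ST_BEFORE = {
    "4": 0.0, "5": 99.8, "6": 0.0, "7": 0.0, "9": 37.7,
    "10": 0.0, "12": 0.0, "13": 0.0, "14": 73.0, "15": 3.99,
}

# column sums of the before/after summary row
SUM_N_BEFORE = 158000
SUM_A_BEFORE = 640
SUM_PCT_A_BEFORE = 0.403
SUM_N_AFTER = 190907

# patient id -> list of per-tumor delivered energies (J) and the printed total
TUMOR_ENERGIES = {
    "4": ([196.1, 275.1], 471.2),
    "5": ([867.2, 314.4, 386.3], 1567.9),
    "6": ([321.8, 47.4], 369.2),
    "7": ([75.7, 89.6], 165.3),
    "9": ([312.1, 266.4], 578.5),
    "10": ([304.7, 177.7], 482.4),
    "12": ([184.4, 222.0], 406.4),
    "13": ([5976.0], 5976.0),
    "14": ([32.0, 81.5], 113.5),
}
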