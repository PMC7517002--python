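"""Published per-repetition hold-out accuracies for the two benchmark
protocols this method was reported on.

These series are *inputs*: worked examples for the mean/std summary
statistics of :mod:`emosig.evaluate`.  ``MUSIC_FUSED_RUNS`` holds the ten
per-experiment accuracies (percent) of each classifier on the four-emotion
music-induction protocol with all four channels fused.
``VIDEO_SUBJECT_RUNS`` holds the same for five subjects of the
video-induction valence-arousal quadrant protocol.
"""

MUSIC_FUSED_RUNS = {
    "svm": (96, 96, 95, 95, 94, 95, 95, 96, 96, 97),
    "dt": (91, 91, 92, 89, 90, 90, 93, 89, 90, 90),
    "elm": (86, 89, 89, 91, 88, 90, 92, 90, 88, 91),
    "team": (98, 98, 98, 99, 98, 98, 99, 100, 99, 99),
}

VIDEO_SUBJECT_RUNS = {
    "s01": {
        "dt": (64, 61, 58, 60, 58, 59, 59, 60, 62, 62),
        "elm": (62, 60, 64, 58, 62, 58, 64, 60, 64, 63),
        "svm": (75, 72, 72, 76, 75, 77, 72, 73, 71, 72),
        "team": (80, 80, 80, 81, 80, 82, 79, 79, 76, 78),
    },
    "s02": {
        "dt": (55, 51, 53, 53, 50, 56, 51, 57, 52, 55),
        "elm": (58, 54, 59, 52, 53, 56, 53, 57, 57, 55),
        "svm": (68, 66, 71, 63, 63, 64, 64, 66, 63, 63),
        "team": (72, 70, 76, 70, 69, 70, 68, 70, 68, 70),
    },
    "s03": {
        "dt": (62, 58, 59, 63, 62, 61, 57, 59, 60, 62),
        "elm": (65, 63, 61, 63, 62, 62, 63, 63, 65, 62),
        "svm": (84, 82, 80, 82, 83, 81, 80, 81, 80, 82),
        "team": (88, 88, 87, 89, 86, 86, 87, 86, 87, 86),
    },
    "s04": {
        "dt": (58, 62, 60, 57, 61, 58, 59, 58, 63, 58),
        "elm": (48, 51, 49, 47, 53, 50, 47, 52, 53, 51),
        "svm": (63, 66, 65, 64, 65, 60, 61, 60, 62, 61),
        "team": (70, 70, 72, 72, 73, 68, 70, 70, 68, 67),
    },
    "s05": {
        "dt": (50, 52, 52, 55, 50, 51, 59, 51, 52, 55),
        "elm": (57, 58, 52, 50, 56, 53, 54, 51, 52, 56),
        "svm": (69, 67, 68, 66, 76, 69, 70, 70, 69, 68),
        "team": (75, 73, 78, 73, 82, 75, 75, 74, 75, 75),
    },
}

#: Published "mean +/- std" summaries (percent) for the series above,
#: at printed precision.
MUSIC_FUSED_SUMMARY = {
    "svm": (95.5, 0.85),
    "dt": (90.5, 1.27),
    "elm": (89.4, 1.78),
    "team": (98.6, 0.70),
}

VIDEO_SUBJECT_SUMMARY = {
    "s01": {"dt": (60.3, 1.95), "elm": (61.5, 2.37), "svm": (73.5, 2.07), "team": (79.5, 1.65)},
    "s02": {"dt": (53.3, 2.36), "elm": (55.4, 2.37), "svm": (65.1, 2.69), "team": (70.3, 2.31)},
    "s03": {"dt": (60.3, 2.00), "elm": (62.9, 1.29), "svm": (81.5, 1.35), "team": (87.0, 1.05)},
    "s04": {"dt": (59.4, 2.01), "elm": (50.1, 2.28), "svm": (62.7, 2.21), "team": (70.0, 1.94)},
    "s05": {"dt": (52.7, 2.83), "elm": (53.9, 2.73), "svm": (69.2, 2.70), "team": (75.5, 2.68)},
}

#: Published overall five-subject average for the team strategy (percent).
VIDEO_OVERALL_TEAM_MEAN = 76.46
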