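"""Published benchmark figures for the cascaded U-Net + DCNN system.

These are the printed per-fold percentages of the reference 10-fold
evaluation on the BRATS 2015 glioma cohorts (high-grade and low-grade),
and the image counts of its fixed 70/15/15 split.  They serve as
worked-example inputs: feeding the fold columns through
:func:`gliocascade.metrics.aggregate_percent` reproduces the printed
average row, and :func:`gliocascade.metrics.make_split` on the
high-grade image count reproduces the printed split sizes.
"""

#: Per-fold percentages, high-grade glioma cohort (complete tumor region).
TENFOLD_HGG = {
    "dice": [87.16, 89.1, 87.98, 88.74, 88.95, 88.97, 88.47, 88.62, 89.68, 89.83],
    "sensitivity": [88.61, 88.92, 89.8, 89.53, 88.76, 88.81, 89.5, 90.14, 89.94, 89.97],
    "accuracy": [85.54, 88.76, 89.03, 89.2, 88.12, 89.98, 88.73, 88.91, 87.66, 90.22],
}

#: Per-fold percentages, low-grade glioma cohort (complete tumor region).
TENFOLD_LGG = {
    "dice": [80.5, 85.3, 83.6, 82.1, 85.84, 86.23, 86.41, 85.33, 85.98, 85.96],
    "sensitivity": [77.02, 79.5, 80.64, 81.2, 79.14, 80.65, 80.12, 80.79, 80.2, 80.74],
    "accuracy": [80.04, 79.96, 80.2, 81.4, 83.5, 84.6, 86.73, 84.1, 85.9, 85.3],
}

#: Printed average row (one decimal of percent).
TENFOLD_AVG = {
    "hgg": {"dice": 88.8, "sensitivity": 89.4, "accuracy": 88.6},
    "lgg": {"dice": 84.7, "sensitivity": 80.0, "accuracy": 83.1},
}

#: High-grade cohort: 220 scans x 4 sequences = 880 images, split 70/15/15.
HGG_N_IMAGES = 880
HGG_SPLIT_COUNTS = (616, 132, 132)

#: Low-grade cohort counts as printed (not derivable from 70/15/15 of the
#: stated cohort size; retained for reference only, never asserted).
LGG_SPLIT_COUNTS = (120, 28, 28)
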