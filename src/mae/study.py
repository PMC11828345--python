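"""Design constants of the clinical HREM study this package re-implements.

The reference experiment collected 2,315 swallow images over the six motility
categories, split them 6:2:2 (train/val/test) per class, expanded the training
split eightfold by augmentation, and reported its ensemble's held-out test
errors: one Achalasia II swallow predicted Normal, one IEM predicted DES and
five IEM predicted Normal, out of 461 test images.  These constants let the
split rule, the augmentation arithmetic and the published metrics be
reconstructed and checked without access to the clinical images themselves.
"""

from __future__ import annotations

import numpy as np

from mae.classes import CLASS_NAMES, class_index
from mae.metrics import ConfusionMatrix

__all__ = [
    "CLASS_TOTALS",
    "REFERENCE_SPLITS",
    "TEST_COUNTS",
    "REPORTED_TEST_ERRORS",
    "reference_confusion",
]

# Per-class image totals of the source dataset (sum: 2,315).
CLASS_TOTALS: dict[str, int] = {
    "Achalasia II": 178,
    "DES": 339,
    "EGJOO": 240,
    "IEM": 483,
    "Jackhammer": 100,
    "Normal": 975,
}

# Published (train, val, test) sizes per class under the 6:2:2 floor rule.
REFERENCE_SPLITS: dict[str, tuple[int, int, int]] = {
    "Achalasia II": (108, 35, 35),
    "DES": (205, 67, 67),
    "EGJOO": (144, 48, 48),
    "IEM": (291, 96, 96),
    "Jackhammer": (60, 20, 20),
    "Normal": (585, 195, 195),
}

TEST_COUNTS: tuple[int, ...] = tuple(v[2] for v in REFERENCE_SPLITS.values())

# The ensemble's reported test misclassifications: (true, predicted, count).
REPORTED_TEST_ERRORS: tuple[tuple[str, str, int], ...] = (
    ("Achalasia II", "Normal", 1),
    ("IEM", "DES", 1),
    ("IEM", "Normal", 5),
)


def reference_confusion() -> ConfusionMatrix:
    """The 6x6 test confusion matrix implied by the reported errors.

    Every test image sits on the diagonal except the seven reported
    misclassifications.
    """
    k = len(CLASS_NAMES)
    counts = np.zeros((k, k), dtype=np.int64)
    for label, n_test in zip(CLASS_NAMES, TEST_COUNTS):
        counts[class_index(label), class_index(label)] = n_test
    for true, pred, n in REPORTED_TEST_ERRORS:
        t, p = class_index(true), class_index(pred)
        counts[t, t] -= n
        counts[t, p] += n
    return ConfusionMatrix(counts)
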