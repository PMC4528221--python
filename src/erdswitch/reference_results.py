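"""Published per-subject results of the original four-volunteer study.

These printed numbers are inputs, not outputs: the group-level summary
statistics can be recomputed exactly from the per-subject accuracies, and
the EMG percentages parameterize realistic synthetic condition profiles.
All accuracies are single-trial classification percentages.
"""

from __future__ import annotations

__all__ = [
    "WITHIN_CONDITION_ACCURACIES",
    "WITHIN_CONDITION_MEAN_CI",
    "TRANSFER_ACCURACIES",
    "TRANSFER_MEAN_CI",
    "EMG_PERCENT_OF_ACTUAL",
]

#: Ten-fold cross-validated accuracy per subject (S1..S4), keyed by
#: (channel_set, condition); each condition was classified against the
#: no-movement baseline of its phase.
WITHIN_CONDITION_ACCURACIES: dict[tuple[str, str], tuple[float, ...]] = {
    ("all30", "actual"): (81, 83, 93, 79),
    ("all30", "isometric"): (83, 68, 89, 81),
    ("all30", "imagined"): (73, 55, 73, 75),
    ("all30", "attempted"): (78, 73, 92, 81),
    ("motor9", "actual"): (78, 81, 96, 92),
    ("motor9", "isometric"): (80, 68, 88, 77),
    ("motor9", "imagined"): (69, 56, 78, 80),
    ("motor9", "attempted"): (81, 82, 92, 79),
}

#: Printed group mean (lower, upper) rows for the same table.
WITHIN_CONDITION_MEAN_CI: dict[tuple[str, str], tuple[float, float, float]] = {
    ("all30", "actual"): (84, 74, 94),
    ("all30", "isometric"): (80, 66, 94),
    ("all30", "imagined"): (69, 54, 84),
    ("all30", "attempted"): (81, 68, 94),
    ("motor9", "actual"): (87, 73, 100),
    ("motor9", "isometric"): (78, 65, 91),
    ("motor9", "imagined"): (71, 53, 88),
    ("motor9", "attempted"): (84, 74, 93),
}

#: Accuracy on attempted movement when the classifier was trained on each
#: phase-1 movement condition, keyed by (channel_set, training_condition).
TRANSFER_ACCURACIES: dict[tuple[str, str], tuple[float, ...]] = {
    ("all30", "actual"): (71, 76, 89, 80),
    ("all30", "isometric"): (70, 81, 84, 70),
    ("all30", "imagined"): (68, 67, 67, 73),
    ("motor9", "actual"): (71, 69, 91, 78),
    ("motor9", "isometric"): (66, 83, 90, 70),
    ("motor9", "imagined"): (59, 58, 73, 77),
}

TRANSFER_MEAN_CI: dict[tuple[str, str], tuple[float, float, float]] = {
    ("all30", "actual"): (79, 67, 91),
    ("all30", "isometric"): (76, 65, 88),
    ("all30", "imagined"): (69, 64, 73),
    ("motor9", "actual"): (77, 61, 93),
    ("motor9", "isometric"): (77, 59, 95),
    ("motor9", "imagined"): (67, 51, 82),
}

#: EMG squared-envelope power per condition, percent of actual movement,
#: per subject S1..S4.
EMG_PERCENT_OF_ACTUAL: dict[str, tuple[float, ...]] = {
    "actual": (100, 100, 100, 100),
    "none": (0.6, 0.2, 0.4, 0.8),
    "isometric": (1.8, 0.8, 1.4, 0.7),
    "imagined": (0.7, 0.2, 0.5, 0.9),
    "attempted": (0.8, 3.0, 0.6, 0.2),
}
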