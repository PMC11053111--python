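"""Polar-map augmentation for CNN training.

Two small transforms emulate the uncertainty of the left-ventricle
segmentation that produced the polar map: (1) cyclic column shifts of one
column (+/- 10 degrees of rotation), and (2) a radial stretch that erases
the 3 outermost (basal) rows and linearly re-interpolates the remaining 13
rows back onto 16.  The training set is exactly quadrupled: originals,
right-shifted, left-shifted and stretched copies, with labels replicated.
Test partitions are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .polar import MeasurementMatrix, N_ROWS

PROVENANCE_TAGS = ("original", "shift_right", "shift_left", "stretch")
AUGMENTATION_FACTOR = 4

_STRETCH_KEEP = 13  # rows kept after erasing the outer 3


def shift_columns(matrix: MeasurementMatrix, direction: str) -> MeasurementMatrix:
    """Cyclic shift of the angular axis by one column (10 degrees).

    Right: S'[i, j] = S[i, j-1] with wrap S'[i, 1] = S[i, 36].
    Left:  S''[i, j] = S[i, j+1] with wrap S''[i, 36] = S[i, 1].
    """
    if direction not in ("right", "left"):
        raise ValidationError(f"direction must be 'right' or 'left', got {direction!r}")
    step = 1 if direction == "right" else -1
    return MeasurementMatrix(np.roll(matrix.values, step, axis=1))


def radial_stretch(matrix: MeasurementMatrix) -> MeasurementMatrix:
    """Erase the outer 3 rows and stretch rows 1-13 back to 16 rows.

    Each column is resampled independently by piecewise-linear interpolation
    with endpoints mapped to endpoints, so constant and linear radial
    profiles are preserved exactly.
    """
    kept = matrix.values[:_STRETCH_KEEP, :]
    src = np.arange(_STRETCH_KEEP, dtype=float)
    dst = np.linspace(0.0, _STRETCH_KEEP - 1, N_ROWS)
    out = np.empty((N_ROWS, matrix.values.shape[1]))
    for c in range(matrix.values.shape[1]):
        out[:, c] = np.interp(dst, src, kept[:, c])
    return MeasurementMatrix(out)


@dataclass
class AugmentedSet:
    """Quadrupled training set with per-copy provenance tags."""

    matrices: list
    labels: np.ndarray
    tags: list

    def __len__(self) -> int:
        return len(self.matrices)


def augment_training_set(matrices, labels, *, is_test: bool = False) -> AugmentedSet:
    """Quadruple a training set: originals + right shift + left shift + stretch.

    Labels are copied to each transformed copy.  Calling this on a test
    partition is a usage error: evaluation data must stay untouched.
    """
    if is_test:
        raise ValidationError("test partitions must never be augmented")
    matrices = list(matrices)
    labels = np.asarray(labels)
    if len(matrices) != len(labels):
        raise ValidationError("matrices and labels must have equal length")

    out_matrices: list = []
    out_tags: list = []
    for tag, fn in (
        ("original", lambda m: m),
        ("shift_right", lambda m: shift_columns(m, "right")),
        ("shift_left", lambda m: shift_columns(m, "left")),
        ("stretch", radial_stretch),
    ):
        out_matrices.extend(fn(m) for m in matrices)
        out_tags.extend([tag] * len(matrices))
    out_labels = np.concatenate([labels] * AUGMENTATION_FACTOR) if len(labels) else labels
    return AugmentedSet(matrices=out_matrices, labels=out_labels, tags=out_tags)
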