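"""Polar-pixelized perfusion matrices, the AHA 17-segment parcellation and cohort I/O.

A quantified perfusion study is stored as a 16x36 matrix ``S[m, n]`` of
nonnegative flow values: row ``m`` indexes the radial position on the polar
map (row 1 innermost, adjacent to the apex/pole; row 16 outermost, basal) and
column ``n`` the angular position in 10-degree steps.  Columns 1 and 36 are
spatial neighbours -- the angular axis is periodic.  Upstream quantification
software exports 24x36 matrices; the last 8 rows fall outside the standard
polar-map display and are discarded on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortLoadError, ConfigurationError, ShapeError, ValidationError

N_ROWS = 16
N_COLS = 36
N_PIXELS = N_ROWS * N_COLS
RAW_ROWS = 24  # rows in the raw export; the last 8 are cut off

#: manifest columns that are not clinical covariates
MANIFEST_CORE_COLUMNS = (
    "patient_id",
    "stress_file",
    "rest_file",
    "rest_hr",
    "rest_sbp",
    "event",
    "time_days",
)


def validate_matrix_values(values, *, context: str = "matrix") -> np.ndarray:
    """Validate and return a (16, 36) float array of finite nonnegative values.

    A 24x36 array is truncated to its first 16 rows before validation.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_COLS or arr.shape[0] not in (N_ROWS, RAW_ROWS):
        raise ShapeError(
            f"{context}: expected shape ({N_ROWS}, {N_COLS}) or ({RAW_ROWS}, {N_COLS}), "
            f"got {arr.shape}"
        )
    if arr.shape[0] == RAW_ROWS:
        arr = arr[:N_ROWS]
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{context}: non-finite entries present")
    if np.any(arr < 0):
        raise ValidationError(f"{context}: negative entries present")
    return arr.copy()


class MeasurementMatrix:
    """One patient's 16x36 polar-pixel perfusion signal.

    Parameters
    ----------
    values : array-like
        16x36 (or raw 24x36, truncated) nonnegative finite values.
        Units are mL/min/g for blood-flow signals, unitless for flow reserve.
    """

    __slots__ = ("values",)

    def __init__(self, values, *, context: str = "matrix"):
        self.values = validate_matrix_values(values, context=context)

    @classmethod
    def from_csv(cls, path: str | os.PathLike, *, context: str | None = None) -> "MeasurementMatrix":
        """Read a headerless per-patient matrix CSV (16 or 24 rows x 36 columns)."""
        name = context or str(path)
        try:
            frame = pd.read_csv(path, header=None)
        except FileNotFoundError:
            raise
        except Exception as exc:  # malformed CSV
            raise CohortLoadError(f"{name}: cannot parse matrix CSV ({exc})") from exc
        return cls(frame.to_numpy(), context=name)

    def to_csv(self, path: str | os.PathLike) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.10g")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, MeasurementMatrix) and np.array_equal(self.values, other.values)

    def __repr__(self) -> str:
        return f"MeasurementMatrix(mean={self.values.mean():.4g})"


@dataclass
class PerfusionStudy:
    """Paired stress/rest matrices with resting hemodynamics.

    ``rest_hr`` (beats/min) and ``rest_sbp`` (mmHg) feed the rate-pressure
    product adjustment of rest flow; derived signals are cached in
    ``derived``.
    """

    patient_id: str
    s_mbf: MeasurementMatrix
    r_mbf: MeasurementMatrix
    rest_hr: float = float("nan")
    rest_sbp: float = float("nan")
    derived: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.s_mbf.shape != self.r_mbf.shape:
            raise ShapeError(f"patient {self.patient_id}: stress/rest shape mismatch")


@dataclass(frozen=True)
class OutcomeRecord:
    """MACE outcome: event indicator and days to first event or last news."""

    patient_id: str
    event: int
    time_days: float

    def __post_init__(self):
        if self.event not in (0, 1):
            raise ValidationError(f"patient {self.patient_id}: event must be 0 or 1")
        if not np.isfinite(self.time_days) or self.time_days < 0:
            raise ValidationError(f"patient {self.patient_id}: time_days must be >= 0")

    @property
    def censored(self) -> bool:
        return self.event == 0


class Parcellation17:
    """Assignment of the 576 polar pixels to the 17 AHA segments.

    Segments 1-6 are basal (outer ring), 7-12 mid, 13-16 apical, 17 the apex
    (all columns of the innermost rows).  Within a ring the angular blocks
    are contiguous under the periodic wrap of the 36 columns.
    """

    def __init__(self, segment_of_pixel: np.ndarray, angular_offset: int, ring_rows: tuple):
        seg = np.asarray(segment_of_pixel, dtype=int)
        if seg.shape != (N_ROWS, N_COLS):
            raise ShapeError("segment map must be 16x36")
        counts = np.bincount(seg.ravel(), minlength=18)[1:]
        if counts.sum() != N_PIXELS or np.any(counts <= 0) or seg.min() < 1 or seg.max() > 17:
            raise ValidationError("segment map must assign every pixel to one of segments 1..17")
        self.segment_of_pixel = seg
        self.pixel_count_per_segment = counts
        self.angular_offset = int(angular_offset)
        self.ring_rows = tuple(ring_rows)

    def mask(self, segment: int) -> np.ndarray:
        """Boolean pixel mask of one segment (1..17)."""
        return self.segment_of_pixel == segment

    def segment_means(self, matrix: MeasurementMatrix | np.ndarray) -> np.ndarray:
        """Mean signal per segment, ordered by segment label 1..17."""
        values = matrix.values if isinstance(matrix, MeasurementMatrix) else np.asarray(matrix, float)
        flat = values.ravel()
        seg = self.segment_of_pixel.ravel()
        sums = np.bincount(seg, weights=flat, minlength=18)[1:]
        return sums / self.pixel_count_per_segment


def make_parcellation17(
    rows_apex: int = 4,
    rows_apical: int = 4,
    rows_mid: int = 4,
    rows_basal: int = 4,
    angular_offset: int = 0,
) -> Parcellation17:
    """Build the 17-segment parcellation of the 16x36 grid.

    The four ring depths count rows from the pole outward and must sum to 16.
    The apex (segment 17) takes all 36 columns of the innermost ``rows_apex``
    rows; the apical ring is split into 4 contiguous 9-column blocks
    (segments 13-16); the mid and basal rings into 6 contiguous 6-column
    blocks each (segments 7-12 and 1-6).  Blocks start at ``angular_offset``
    columns and wrap periodically.
    """
    depths = (rows_apex, rows_apical, rows_mid, rows_basal)
    if any(int(d) != d or d <= 0 for d in depths):
        raise ConfigurationError("ring depths must be positive integers")
    if sum(depths) != N_ROWS:
        raise ConfigurationError(f"ring depths must sum to {N_ROWS}, got {sum(depths)}")
    if not (0 <= angular_offset < N_COLS):
        raise ConfigurationError("angular_offset must be in 0..35")

    seg = np.zeros((N_ROWS, N_COLS), dtype=int)
    cols = (np.arange(N_COLS) - angular_offset) % N_COLS

    r0 = 0
    # apex: innermost rows, one segment
    seg[r0 : r0 + rows_apex, :] = 17
    r0 += rows_apex
    # apical ring: 4 blocks of 9 columns -> segments 13..16
    seg[r0 : r0 + rows_apical, :] = 13 + cols // 9
    r0 += rows_apical
    # mid ring: 6 blocks of 6 columns -> segments 7..12
    seg[r0 : r0 + rows_mid, :] = 7 + cols // 6
    r0 += rows_mid
    # basal ring: 6 blocks of 6 columns -> segments 1..6
    seg[r0 : r0 + rows_basal, :] = 1 + cols // 6

    return Parcellation17(seg, angular_offset, depths)


@dataclass
class CohortRecord:
    """One manifest row: imaging study, outcome and raw clinical covariates."""

    study: PerfusionStudy
    outcome: OutcomeRecord
    clinical: dict


def load_cohort(manifest_path: str | os.PathLike, matrix_dir: str | os.PathLike | None = None) -> list[CohortRecord]:
    """Load a cohort from a manifest CSV plus per-patient matrix CSVs.

    The manifest has one row per patient with columns
    ``patient_id, stress_file, rest_file, rest_hr, rest_sbp, event,
    time_days`` followed by the clinical covariates.  Matrix paths are
    resolved relative to ``matrix_dir`` (default: the manifest's directory).
    """
    manifest_path = os.fspath(manifest_path)
    base = os.fspath(matrix_dir) if matrix_dir is not None else os.path.dirname(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise CohortLoadError(f"cannot parse manifest {manifest_path}: {exc}") from exc

    missing = [c for c in MANIFEST_CORE_COLUMNS if c not in manifest.columns]
    if missing:
        raise CohortLoadError(f"manifest missing required columns: {missing}")
    clinical_cols = [c for c in manifest.columns if c not in MANIFEST_CORE_COLUMNS]

    records = []
    for _, row in manifest.iterrows():
        pid = str(row["patient_id"])
        matrices = {}
        for kind, col in (("stress", "stress_file"), ("rest", "rest_file")):
            path = os.path.join(base, str(row[col]))
            if not os.path.exists(path):
                raise CohortLoadError(f"patient {pid}: missing {kind} matrix file {path}")
            matrices[kind] = MeasurementMatrix.from_csv(path, context=f"patient {pid} {kind} ({path})")
        study = PerfusionStudy(
            patient_id=pid,
            s_mbf=matrices["stress"],
            r_mbf=matrices["rest"],
            rest_hr=float(row["rest_hr"]),
            rest_sbp=float(row["rest_sbp"]),
        )
        outcome = OutcomeRecord(patient_id=pid, event=int(row["event"]), time_days=float(row["time_days"]))
        clinical = {c: row[c] for c in clinical_cols}
        records.append(CohortRecord(study=study, outcome=outcome, clinical=clinical))
    return records
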