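"""Derivation of the three candidate perfusion signals: sMBF, MFR, MFC radius.

Rest flow depends on the resting workload, so it is normalised to a
reference rate-pressure product (RPP = heart rate x systolic blood pressure)
of 8500 mmHg/min before the flow reserve is formed.  The myocardial flow
capacity (MFC) radius combines stress flow and flow reserve at each pixel as
the Euclidean norm sqrt(sMBF^2 + MFR^2).
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .errors import DomainError, ShapeError
from .polar import MeasurementMatrix, PerfusionStudy

REFERENCE_RPP = 8500.0  # mmHg/min


class SignalKind(str, Enum):
    """The three candidate perfusion signals used for MACE prediction."""

    SMBF = "smbf"
    MFR = "mfr"
    MFC_RADIUS = "mfc_radius"


def rpp_adjust_rest(r_mbf: MeasurementMatrix, rest_hr: float, rest_sbp: float) -> MeasurementMatrix:
    """Normalise rest flow to the reference rate-pressure product.

    Every entry is scaled by ``8500 / (rest_hr * rest_sbp)``.
    """
    if not (rest_hr > 0):
        raise DomainError(f"rest heart rate must be > 0, got {rest_hr}")
    if not (rest_sbp > 0):
        raise DomainError(f"rest systolic blood pressure must be > 0, got {rest_sbp}")
    factor = REFERENCE_RPP / (rest_hr * rest_sbp)
    return MeasurementMatrix(r_mbf.values * factor)


def compute_mfr(s_mbf: MeasurementMatrix, r_mbf_adjusted: MeasurementMatrix) -> MeasurementMatrix:
    """Pixelwise myocardial flow reserve: stress flow over (adjusted) rest flow."""
    if s_mbf.shape != r_mbf_adjusted.shape:
        raise ShapeError("stress and rest matrices must share shape")
    rest = r_mbf_adjusted.values
    bad = np.argwhere(rest <= 0)
    if bad.size:
        m, n = bad[0] + 1
        raise DomainError(f"rest flow must be strictly positive; pixel (m={m}, n={n}) is {rest[bad[0][0], bad[0][1]]}")
    return MeasurementMatrix(s_mbf.values / rest)


def compute_mfc_radius(s_mbf: MeasurementMatrix, mfr: MeasurementMatrix) -> MeasurementMatrix:
    """Pixelwise flow-capacity radius: Euclidean norm of (sMBF, MFR)."""
    if s_mbf.shape != mfr.shape:
        raise ShapeError("sMBF and MFR matrices must share shape")
    return MeasurementMatrix(np.hypot(s_mbf.values, mfr.values))


def derive_signal(study: PerfusionStudy, kind: SignalKind | str, rpp_adjust: bool = True) -> MeasurementMatrix:
    """Return the requested signal for a study, caching derived matrices.

    ``rpp_adjust`` applies the rate-pressure-product normalisation to rest
    flow before the reserve is computed; stress flow is never adjusted.
    """
    kind = SignalKind(kind)
    if kind is SignalKind.SMBF:
        return study.s_mbf
    key = (kind.value, bool(rpp_adjust))
    if key in study.derived:
        return study.derived[key]
    rest = rpp_adjust_rest(study.r_mbf, study.rest_hr, study.rest_sbp) if rpp_adjust else study.r_mbf
    mfr = compute_mfr(study.s_mbf, rest)
    if kind is SignalKind.MFR:
        result = mfr
    else:
        result = compute_mfc_radius(study.s_mbf, mfr)
    study.derived[key] = result
    return result
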