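"""Gray-level texture features on the flat 16x36 perfusion grid.

Implements the five standard 2D texture-matrix families with IBSI-compatible
feature definitions and the conventional default settings: co-occurrence
(GLCM, 24 features, distance 1, 4 symmetric directions, per-angle features
averaged), run length (GLRLM, 16, 4 directions averaged), size zone (GLSZM,
16, 8-connected zones), neighbouring gray tone difference (NGTDM, 5,
8-neighbourhood) and gray level dependence (GLDM, 14, alpha = 0).

Intensities are discretized with a fixed bin width anchored at the pooled
cohort minimum; the matrix is treated as a flat image (the periodic
adjacency of columns 1 and 36 is deliberately ignored, as standard texture
toolkits do).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .polar import MeasurementMatrix

_EPS = np.spacing(1.0)

# (dr, dc) offsets covering the 4 unique 2D directions at distance 1
_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))

GLCM_FEATURES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
GLDM_FEATURES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

N_TEXTURE_FEATURES = (
    len(GLCM_FEATURES) + len(GLRLM_FEATURES) + len(GLSZM_FEATURES)
    + len(NGTDM_FEATURES) + len(GLDM_FEATURES)
)  # 24 + 16 + 16 + 5 + 14 = 75

TEXTURE_FEATURE_NAMES = tuple(
    [f"glcm_{n}" for n in GLCM_FEATURES]
    + [f"glrlm_{n}" for n in GLRLM_FEATURES]
    + [f"glszm_{n}" for n in GLSZM_FEATURES]
    + [f"ngtdm_{n}" for n in NGTDM_FEATURES]
    + [f"gldm_{n}" for n in GLDM_FEATURES]
)


@dataclass(frozen=True)
class DiscretizationRule:
    """Fixed-bin-width intensity discretization anchored at ``origin``."""

    bin_width: float
    origin: float = 0.0

    def __post_init__(self):
        if not (self.bin_width > 0):
            raise ConfigurationError(f"bin_width must be > 0, got {self.bin_width}")


def cohort_bin_width(matrices, n_bins: int = 16) -> DiscretizationRule:
    """Bin width = pooled value range over the whole cohort divided by ``n_bins``.

    The anchor (``origin``) is the pooled minimum.
    """
    matrices = list(matrices)
    if not matrices:
        raise ConfigurationError("cohort_bin_width requires a nonempty cohort")
    lo = min(float(np.min(_values(m))) for m in matrices)
    hi = max(float(np.max(_values(m))) for m in matrices)
    if hi <= lo:
        raise ConfigurationError("degenerate cohort: pooled value range is zero")
    return DiscretizationRule(bin_width=(hi - lo) / n_bins, origin=lo)


def _values(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, MeasurementMatrix) else np.asarray(matrix, float)


def discretize(matrix, rule: DiscretizationRule) -> np.ndarray:
    """Map intensities to positive integer gray levels.

    Level = floor((x - origin) / bin_width) + 1, floored at 1 so values below
    the anchor (possible in strict train-only mode) collapse into the first bin.
    """
    x = _values(matrix)
    g = np.floor((x - rule.origin) / rule.bin_width).astype(int) + 1
    return np.maximum(g, 1)


# --------------------------------------------------------------------------
# texture matrices

def glcm_matrices(gray: np.ndarray):
    """Per-direction symmetric, normalised co-occurrence matrices.

    Returns (list of Ng x Ng arrays, present gray values).
    """
    levels = np.unique(gray)
    index = {g: i for i, g in enumerate(levels)}
    ng = len(levels)
    idx = np.vectorize(index.get)(gray)
    out = []
    rows, cols = gray.shape
    for dr, dc in _DIRECTIONS:
        p = np.zeros((ng, ng))
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        a = idx[r0:r1, c0:c1].ravel()
        b = idx[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        np.add.at(p, (a, b), 1.0)
        p = p + p.T  # symmetric co-occurrence
        out.append(p / p.sum())
    return out, levels.astype(float)


def _glcm_features_single(p: np.ndarray, gv: np.ndarray) -> dict:
    ng = len(gv)
    i = gv[:, None] * np.ones((1, ng))
    j = gv[None, :] * np.ones((ng, 1))
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((px * gv).sum())
    uy = float((py * gv).sum())
    sx = float(np.sqrt((px * (gv - ux) ** 2).sum()))
    sy = float(np.sqrt((py * (gv - uy) ** 2).sum()))

    ksum = np.arange(int(2 * gv.min()), int(2 * gv.max()) + 1)
    pxy_sum = np.array([p[(i + j) == k].sum() for k in ksum])
    kdiff = np.arange(0, int(gv.max() - gv.min()) + 1)
    pxy_diff = np.array([p[np.abs(i - j) == k].sum() for k in kdiff])

    feats = {}
    feats["Autocorrelation"] = float((p * i * j).sum())
    mu = ux + uy
    feats["ClusterProminence"] = float((p * (i + j - mu) ** 4).sum())
    feats["ClusterShade"] = float((p * (i + j - mu) ** 3).sum())
    feats["ClusterTendency"] = float((p * (i + j - mu) ** 2).sum())
    feats["Contrast"] = float((p * (i - j) ** 2).sum())
    if sx * sy > 0:
        feats["Correlation"] = float(((p * i * j).sum() - ux * uy) / (sx * sy))
    else:
        feats["Correlation"] = 1.0
    da = float((kdiff * pxy_diff).sum())
    feats["DifferenceAverage"] = da
    feats["DifferenceEntropy"] = float(-(pxy_diff * np.log2(pxy_diff + _EPS)).sum())
    feats["DifferenceVariance"] = float((pxy_diff * (kdiff - da) ** 2).sum())
    absdiff = np.abs(i - j)
    feats["Id"] = float((p / (1.0 + absdiff)).sum())
    feats["Idm"] = float((p / (1.0 + absdiff**2)).sum())
    feats["Idmn"] = float((p / (1.0 + absdiff**2 / ng**2)).sum())
    feats["Idn"] = float((p / (1.0 + absdiff / ng)).sum())
    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    hxy = float(-(p * np.log2(p + _EPS)).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())
    div = max(hx, hy)
    feats["Imc1"] = float((hxy - hxy1) / div) if div != 0 else 0.0
    feats["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = absdiff != 0
    feats["InverseVariance"] = float((p[off] / absdiff[off] ** 2).sum())
    feats["JointAverage"] = ux
    feats["JointEnergy"] = float((p**2).sum())
    feats["JointEntropy"] = hxy
    feats["MCC"] = _glcm_mcc(p, px, py)
    feats["MaximumProbability"] = float(p.max())
    feats["SumAverage"] = float((ksum * pxy_sum).sum())
    feats["SumEntropy"] = float(-(pxy_sum * np.log2(pxy_sum + _EPS)).sum())
    feats["SumSquares"] = float((p * (i - ux) ** 2).sum())
    return feats


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    # Q[i, j] = sum_k p(i, k) p(j, k) / (px(i) py(k)); MCC = sqrt of the
    # second-largest eigenvalue of Q
    ng = p.shape[0]
    if ng == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = p / py[None, :]  # p(j, k) / py(k) with j rows, k cols
        w[~np.isfinite(w)] = 0.0
        q = (p @ w.T) / px[:, None]
        q[~np.isfinite(q)] = 0.0
    eig = np.linalg.eigvals(q)
    eig = np.sort(np.abs(eig.real))
    return float(np.sqrt(max(0.0, eig[-2])))


def glcm_features(gray: np.ndarray) -> dict:
    """24 GLCM features, averaged over the 4 directions."""
    mats, gv = glcm_matrices(gray)
    per_angle = [_glcm_features_single(p, gv) for p in mats]
    return {n: float(np.mean([f[n] for f in per_angle])) for n in GLCM_FEATURES}


def glrlm_matrices(gray: np.ndarray):
    """Per-direction run-length matrices P(gray level, run length)."""
    levels = np.unique(gray)
    index = {g: i for i, g in enumerate(levels)}
    ng = len(levels)
    rows, cols = gray.shape
    max_len = max(rows, cols)
    out = []
    for dr, dc in _DIRECTIONS:
        p = np.zeros((ng, max_len))
        for line in _lines(gray, dr, dc):
            for g, length in _runs(line):
                p[index[g], length - 1] += 1
        out.append(p)
    return out, levels.astype(float)


def _lines(gray: np.ndarray, dr: int, dc: int):
    rows, cols = gray.shape
    if (dr, dc) == (0, 1):
        yield from (gray[r, :] for r in range(rows))
    elif (dr, dc) == (1, 0):
        yield from (gray[:, c] for c in range(cols))
    elif (dr, dc) == (1, 1):
        yield from (np.diagonal(gray, offset=o) for o in range(-(rows - 1), cols))
    else:  # (1, -1): anti-diagonals
        flipped = gray[:, ::-1]
        yield from (np.diagonal(flipped, offset=o) for o in range(-(rows - 1), cols))


def _runs(line: np.ndarray):
    start = 0
    for k in range(1, len(line) + 1):
        if k == len(line) or line[k] != line[start]:
            yield int(line[start]), k - start
            start = k


def _rlm_features_single(p: np.ndarray, gv: np.ndarray, n_pixels: int) -> dict:
    nr = p.sum()
    jv = np.arange(1, p.shape[1] + 1, dtype=float)
    pg = p.sum(axis=1)  # per gray level
    pr = p.sum(axis=0)  # per run length
    pnorm = p / nr
    iv = gv
    i2 = iv[:, None] ** 2
    j2 = jv[None, :] ** 2

    feats = {}
    feats["GrayLevelNonUniformity"] = float((pg**2).sum() / nr)
    feats["GrayLevelNonUniformityNormalized"] = float((pg**2).sum() / nr**2)
    mu_i = float((pnorm * iv[:, None]).sum())
    feats["GrayLevelVariance"] = float((pnorm * (iv[:, None] - mu_i) ** 2).sum())
    feats["HighGrayLevelRunEmphasis"] = float((p * i2).sum() / nr)
    feats["LongRunEmphasis"] = float((p * j2).sum() / nr)
    feats["LongRunHighGrayLevelEmphasis"] = float((p * i2 * j2).sum() / nr)
    feats["LongRunLowGrayLevelEmphasis"] = float((p * j2 / i2).sum() / nr)
    feats["LowGrayLevelRunEmphasis"] = float((p / i2).sum() / nr)
    feats["RunEntropy"] = float(-(pnorm * np.log2(pnorm + _EPS)).sum())
    feats["RunLengthNonUniformity"] = float((pr**2).sum() / nr)
    feats["RunLengthNonUniformityNormalized"] = float((pr**2).sum() / nr**2)
    feats["RunPercentage"] = float(nr / n_pixels)
    mu_j = float((pnorm * jv[None, :]).sum())
    feats["RunVariance"] = float((pnorm * (jv[None, :] - mu_j) ** 2).sum())
    feats["ShortRunEmphasis"] = float((p / j2).sum() / nr)
    feats["ShortRunHighGrayLevelEmphasis"] = float((p * i2 / j2).sum() / nr)
    feats["ShortRunLowGrayLevelEmphasis"] = float((p / (i2 * j2)).sum() / nr)
    return feats


def glrlm_features(gray: np.ndarray) -> dict:
    """16 GLRLM features, averaged over the 4 directions."""
    mats, gv = glrlm_matrices(gray)
    per_angle = [_rlm_features_single(p, gv, gray.size) for p in mats]
    return {n: float(np.mean([f[n] for f in per_angle])) for n in GLRLM_FEATURES}


def glszm_matrix(gray: np.ndarray):
    """Size-zone matrix P(gray level, zone size), 8-connected zones."""
    levels = np.unique(gray)
    structure = np.ones((3, 3), dtype=int)
    zones = []  # (level index, size)
    for li, g in enumerate(levels):
        labelled, n = ndimage.label(gray == g, structure=structure)
        if n:
            sizes = np.bincount(labelled.ravel())[1:]
            zones.extend((li, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    p = np.zeros((len(levels), max_size))
    for li, s in zones:
        p[li, s - 1] += 1
    return p, levels.astype(float)


def glszm_features(gray: np.ndarray) -> dict:
    """16 GLSZM features (zone analogue of the run-length family)."""
    p, gv = glszm_matrix(gray)
    f = _rlm_features_single(p, gv, gray.size)
    rename = {
        "HighGrayLevelRunEmphasis": "HighGrayLevelZoneEmphasis",
        "LongRunEmphasis": "LargeAreaEmphasis",
        "LongRunHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis": "LowGrayLevelZoneEmphasis",
        "RunEntropy": "ZoneEntropy",
        "RunLengthNonUniformity": "SizeZoneNonUniformity",
        "RunLengthNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
        "RunPercentage": "ZonePercentage",
        "RunVariance": "ZoneVariance",
        "ShortRunEmphasis": "SmallAreaEmphasis",
        "ShortRunHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    }
    return {rename.get(k, k): v for k, v in f.items()}


def _neighbor_stacks(gray: np.ndarray):
    """Yield, per pixel, arrays of the 8 in-image neighbour values."""
    rows, cols = gray.shape
    padded = np.full((rows + 2, cols + 2), np.nan)
    padded[1:-1, 1:-1] = gray
    stack = np.stack([
        padded[1 + dr : rows + 1 + dr, 1 + dc : cols + 1 + dc]
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ])
    return stack  # shape (8, rows, cols), NaN outside the image


def ngtdm_features(gray: np.ndarray) -> dict:
    """5 NGTDM features from the neighbourhood gray-tone difference matrix."""
    stack = _neighbor_stacks(gray)
    nbr_mean = np.nanmean(stack, axis=0)
    levels = np.unique(gray)
    n_pix = gray.size
    n_i = np.array([(gray == g).sum() for g in levels], dtype=float)
    s_i = np.array([np.abs(g - nbr_mean[gray == g]).sum() for g in levels])
    p_i = n_i / n_pix
    gv = levels.astype(float)
    ngp = len(levels)

    feats = {}
    denom = float((p_i * s_i).sum())
    feats["Coarseness"] = 1.0 / denom if denom != 0 else 1e6
    if ngp == 1:
        feats["Contrast"] = 0.0
    else:
        pair = (p_i[:, None] * p_i[None, :] * (gv[:, None] - gv[None, :]) ** 2).sum()
        feats["Contrast"] = float(pair / (ngp * (ngp - 1)) * s_i.sum() / n_pix)
    ipi = gv * p_i
    busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    feats["Busyness"] = denom / busy_den if busy_den != 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.abs(gv[:, None] - gv[None, :]) * (
            p_i[:, None] * s_i[:, None] + p_i[None, :] * s_i[None, :]
        ) / (p_i[:, None] + p_i[None, :])
    feats["Complexity"] = float(np.nansum(num) / n_pix)
    s_sum = float(s_i.sum())
    strength_num = float(((p_i[:, None] + p_i[None, :]) * (gv[:, None] - gv[None, :]) ** 2).sum())
    feats["Strength"] = strength_num / s_sum if s_sum != 0 else 0.0
    return feats


def gldm_matrix(gray: np.ndarray, alpha: float = 0.0):
    """Dependence matrix P(gray level, dependence size).

    A neighbour is dependent when its gray level differs from the centre by
    at most ``alpha``; the dependence size counts the centre plus its
    dependent 8-neighbours.
    """
    stack = _neighbor_stacks(gray)
    with np.errstate(invalid="ignore"):
        # NaN (outside-image) neighbours never compare <= alpha, so edge
        # pixels simply have fewer candidate neighbours
        dep = 1 + (np.abs(stack - gray[None]) <= alpha).sum(axis=0).astype(int)
    levels = np.unique(gray)
    index = {g: i for i, g in enumerate(levels)}
    p = np.zeros((len(levels), int(dep.max())))
    for g, d in zip(gray.ravel(), dep.ravel()):
        p[index[g], d - 1] += 1
    return p, levels.astype(float)


def gldm_features(gray: np.ndarray, alpha: float = 0.0) -> dict:
    """14 GLDM features (dependence analogue of the run-length family)."""
    p, gv = gldm_matrix(gray, alpha)
    f = _rlm_features_single(p, gv, gray.size)
    rename = {
        "RunEntropy": "DependenceEntropy",
        "RunLengthNonUniformity": "DependenceNonUniformity",
        "RunLengthNonUniformityNormalized": "DependenceNonUniformityNormalized",
        "RunVariance": "DependenceVariance",
        "HighGrayLevelRunEmphasis": "HighGrayLevelEmphasis",
        "LongRunEmphasis": "LargeDependenceEmphasis",
        "LongRunHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis": "LowGrayLevelEmphasis",
        "ShortRunEmphasis": "SmallDependenceEmphasis",
        "ShortRunHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
    }
    out = {rename.get(k, k): v for k, v in f.items()}
    for dropped in ("GrayLevelNonUniformityNormalized", "RunPercentage"):
        out.pop(rename.get(dropped, dropped), None)
    return {k: out[k] for k in GLDM_FEATURES}


def texture_features(matrix, rule: DiscretizationRule) -> dict:
    """All 75 texture features of a discretized matrix, in documented order."""
    gray = discretize(matrix, rule)
    out = {}
    out.update({f"glcm_{k}": v for k, v in glcm_features(gray).items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(gray).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_features(gray).items()})
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(gray).items()})
    out.update({f"gldm_{k}": v for k, v in gldm_features(gray).items()})
    return {k: out[k] for k in TEXTURE_FEATURE_NAMES}
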