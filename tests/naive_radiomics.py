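"""Independent, deliberately naive radiomics oracle for conformance tests.

Every function here recomputes a feature family directly from its textbook
definition with plain Python loops and dictionaries — no code shared with
the package implementation — so agreement between the two routes checks the
vectorized implementation against the written definitions.
"""

import math
from collections import Counter, defaultdict

import numpy as np

EPS = np.spacing(1.0)

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def naive_discretize(x, bin_width, origin):
    g = np.zeros(x.shape, dtype=int)
    for r in range(x.shape[0]):
        for c in range(x.shape[1]):
            g[r, c] = max(1, int(math.floor((x[r, c] - origin) / bin_width)) + 1)
    return g


# -- first order -----------------------------------------------------------


def naive_first_order(x, bin_width, origin):
    from scipy import stats

    v = sorted(x.ravel().tolist())
    arr = np.array(v)
    n = len(v)
    mean = sum(v) / n
    p10, p25, p50, p75, p90 = (np.percentile(arr, q) for q in (10, 25, 50, 75, 90))
    robust = arr[(arr >= p10) & (arr <= p90)]
    var = sum((t - mean) ** 2 for t in v) / n

    levels = Counter(naive_discretize(x, bin_width, origin).ravel().tolist())
    probs = [k / n for k in levels.values()]

    return {
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_Energy": float(sum(t**2 for t in v)),
        "firstorder_Entropy": float(-sum(p * math.log2(p) for p in probs)),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_Kurtosis": float(stats.kurtosis(arr, fisher=False, bias=True)) if var > 0 else 0.0,
        "firstorder_Maximum": float(max(v)),
        "firstorder_Mean": float(mean),
        "firstorder_MeanAbsoluteDeviation": float(sum(abs(t - mean) for t in v) / n),
        "firstorder_Median": float(p50),
        "firstorder_Minimum": float(min(v)),
        "firstorder_Range": float(max(v) - min(v)),
        "firstorder_RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "firstorder_RootMeanSquared": float(math.sqrt(sum(t**2 for t in v) / n)),
        "firstorder_Skewness": float(stats.skew(arr, bias=True)) if var > 0 else 0.0,
        "firstorder_TotalEnergy": float(sum(t**2 for t in v)),
        "firstorder_Uniformity": float(sum(p**2 for p in probs)),
        "firstorder_Variance": float(var),
    }


# -- GLCM ------------------------------------------------------------------


def naive_glcm_features(gray):
    levels = sorted(set(gray.ravel().tolist()))
    rows, cols = gray.shape
    per_angle = []
    for dr, dc in DIRECTIONS:
        counts = defaultdict(float)
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[(gray[r, c], gray[r2, c2])] += 1
                    counts[(gray[r2, c2], gray[r, c])] += 1
        total = sum(counts.values())
        p = {k: v / total for k, v in counts.items()}
        per_angle.append(_glcm_one(p, levels))
    return {k: float(np.mean([f[k] for f in per_angle])) for k in per_angle[0]}


def _glcm_one(p, levels):
    ng = len(levels)
    px = {i: sum(p.get((i, j), 0.0) for j in levels) for i in levels}
    py = {j: sum(p.get((i, j), 0.0) for i in levels) for i2, j in [(0, j) for j in levels]}
    ux = sum(i * v for i, v in px.items())
    uy = sum(j * v for j, v in py.items())
    sx = math.sqrt(sum(v * (i - ux) ** 2 for i, v in px.items()))
    sy = math.sqrt(sum(v * (j - uy) ** 2 for j, v in py.items()))

    psum = defaultdict(float)
    pdiff = defaultdict(float)
    for (i, j), v in p.items():
        psum[i + j] += v
        pdiff[abs(i - j)] += v

    f = {}
    f["Autocorrelation"] = sum(v * i * j for (i, j), v in p.items())
    mu = ux + uy
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
        f[name] = sum(v * (i + j - mu) ** power for (i, j), v in p.items())
    f["Contrast"] = sum(v * (i - j) ** 2 for (i, j), v in p.items())
    f["Correlation"] = (
        (f["Autocorrelation"] - ux * uy) / (sx * sy) if sx * sy > 0 else 1.0
    )
    da = sum(k * v for k, v in pdiff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(v * math.log2(v + EPS) for v in pdiff.values())
    f["DifferenceVariance"] = sum(v * (k - da) ** 2 for k, v in pdiff.items())
    f["Id"] = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    f["Idm"] = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    f["Idmn"] = sum(v / (1 + (i - j) ** 2 / ng**2) for (i, j), v in p.items())
    f["Idn"] = sum(v / (1 + abs(i - j) / ng) for (i, j), v in p.items())
    hx = -sum(v * math.log2(v + EPS) for v in px.values())
    hy = -sum(v * math.log2(v + EPS) for v in py.values())
    hxy = -sum(v * math.log2(v + EPS) for v in p.values())
    hxy1 = -sum(v * math.log2(px[i] * py[j] + EPS) for (i, j), v in p.items())
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j] + EPS) for i in levels for j in levels
    )
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) != 0 else 0.0
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["InverseVariance"] = sum(v / (i - j) ** 2 for (i, j), v in p.items() if i != j)
    f["JointAverage"] = ux
    f["JointEnergy"] = sum(v**2 for v in p.values())
    f["JointEntropy"] = hxy
    f["MCC"] = _naive_mcc(p, px, py, levels)
    f["MaximumProbability"] = max(p.values())
    f["SumAverage"] = sum(k * v for k, v in psum.items())
    f["SumEntropy"] = -sum(v * math.log2(v + EPS) for v in psum.values())
    f["SumSquares"] = sum(v * (i - ux) ** 2 for (i, j), v in p.items())
    return f


def _naive_mcc(p, px, py, levels):
    ng = len(levels)
    if ng == 1:
        return 1.0
    q = np.zeros((ng, ng))
    for a, i in enumerate(levels):
        for b, j in enumerate(levels):
            total = 0.0
            for k in levels:
                if px[i] > 0 and py[k] > 0:
                    total += p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * py[k])
            q[a, b] = total
    eig = sorted(abs(np.linalg.eigvals(q).real))
    return math.sqrt(max(0.0, eig[-2]))


# -- run length / size zone / dependence share one feature template --------


def _naive_sz_features(counts, n_pixels):
    """counts: dict (gray level, size) -> count."""
    nr = sum(counts.values())
    f = {}
    by_level = defaultdict(float)
    by_size = defaultdict(float)
    for (i, j), v in counts.items():
        by_level[i] += v
        by_size[j] += v
    f["GrayLevelNonUniformity"] = sum(v**2 for v in by_level.values()) / nr
    f["GrayLevelNonUniformityNormalized"] = sum(v**2 for v in by_level.values()) / nr**2
    mu_i = sum(i * v for (i, j), v in counts.items()) / nr
    f["GrayLevelVariance"] = sum(v * (i - mu_i) ** 2 for (i, j), v in counts.items()) / nr
    f["HighGrayLevelRunEmphasis"] = sum(v * i**2 for (i, j), v in counts.items()) / nr
    f["LongRunEmphasis"] = sum(v * j**2 for (i, j), v in counts.items()) / nr
    f["LongRunHighGrayLevelEmphasis"] = sum(v * i**2 * j**2 for (i, j), v in counts.items()) / nr
    f["LongRunLowGrayLevelEmphasis"] = sum(v * j**2 / i**2 for (i, j), v in counts.items()) / nr
    f["LowGrayLevelRunEmphasis"] = sum(v / i**2 for (i, j), v in counts.items()) / nr
    f["RunEntropy"] = -sum((v / nr) * math.log2(v / nr + EPS) for v in counts.values())
    f["RunLengthNonUniformity"] = sum(v**2 for v in by_size.values()) / nr
    f["RunLengthNonUniformityNormalized"] = sum(v**2 for v in by_size.values()) / nr**2
    f["RunPercentage"] = nr / n_pixels
    mu_j = sum(j * v for (i, j), v in counts.items()) / nr
    f["RunVariance"] = sum(v * (j - mu_j) ** 2 for (i, j), v in counts.items()) / nr
    f["ShortRunEmphasis"] = sum(v / j**2 for (i, j), v in counts.items()) / nr
    f["ShortRunHighGrayLevelEmphasis"] = sum(v * i**2 / j**2 for (i, j), v in counts.items()) / nr
    f["ShortRunLowGrayLevelEmphasis"] = sum(v / (i**2 * j**2) for (i, j), v in counts.items()) / nr
    return f


def naive_glrlm_features(gray):
    rows, cols = gray.shape
    per_angle = []
    for dr, dc in DIRECTIONS:
        counts = defaultdict(float)
        seen = set()
        for r in range(rows):
            for c in range(cols):
                pr, pc = r - dr, c - dc
                if 0 <= pr < rows and 0 <= pc < cols and gray[pr, pc] == gray[r, c]:
                    continue  # not a run start
                length = 0
                rr, cc = r, c
                while 0 <= rr < rows and 0 <= cc < cols and gray[rr, cc] == gray[r, c]:
                    length += 1
                    rr += dr
                    cc += dc
                counts[(gray[r, c], length)] += 1
                seen.add((r, c))
        per_angle.append(_naive_sz_features(counts, gray.size))
    return {k: float(np.mean([f[k] for f in per_angle])) for k in per_angle[0]}


def naive_glszm_features(gray):
    rows, cols = gray.shape
    visited = np.zeros(gray.shape, dtype=bool)
    counts = defaultdict(float)
    for r in range(rows):
        for c in range(cols):
            if visited[r, c]:
                continue
            # flood fill with 8-connectivity
            stack, size, g = [(r, c)], 0, gray[r, c]
            visited[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (
                            0 <= r2 < rows
                            and 0 <= c2 < cols
                            and not visited[r2, c2]
                            and gray[r2, c2] == g
                        ):
                            visited[r2, c2] = True
                            stack.append((r2, c2))
            counts[(g, size)] += 1
    f = _naive_sz_features(counts, gray.size)
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


def _neighbors(gray, r, c):
    rows, cols = gray.shape
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if (dr, dc) == (0, 0):
                continue
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                out.append(gray[r2, c2])
    return out


def naive_ngtdm_features(gray):
    rows, cols = gray.shape
    n = gray.size
    s = defaultdict(float)
    cnt = Counter()
    for r in range(rows):
        for c in range(cols):
            nb = _neighbors(gray, r, c)
            s[gray[r, c]] += abs(gray[r, c] - sum(nb) / len(nb))
            cnt[gray[r, c]] += 1
    levels = sorted(cnt)
    p = {g: cnt[g] / n for g in levels}
    ngp = len(levels)

    f = {}
    denom = sum(p[g] * s[g] for g in levels)
    f["Coarseness"] = 1.0 / denom if denom != 0 else 1e6
    if ngp > 1:
        f["Contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in levels for j in levels)
            / (ngp * (ngp - 1))
            * sum(s.values())
            / n
        )
    else:
        f["Contrast"] = 0.0
    busy_den = sum(abs(i * p[i] - j * p[j]) for i in levels for j in levels)
    f["Busyness"] = denom / busy_den if busy_den != 0 else 0.0
    f["Complexity"] = (
        sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in levels
            for j in levels
        )
        / n
    )
    s_sum = sum(s.values())
    f["Strength"] = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in levels for j in levels) / s_sum
        if s_sum != 0
        else 0.0
    )
    return f


def naive_gldm_features(gray, alpha=0.0):
    rows, cols = gray.shape
    counts = defaultdict(float)
    for r in range(rows):
        for c in range(cols):
            dep = 1 + sum(1 for g in _neighbors(gray, r, c) if abs(g - gray[r, c]) <= alpha)
            counts[(gray[r, c], dep)] += 1
    f = _naive_sz_features(counts, gray.size)
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
    out.pop("GrayLevelNonUniformityNormalized", None)
    out.pop("RunPercentage", None)
    return out
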