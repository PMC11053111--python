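"""Feature vectors for each model family.

Four image representations are derived from a perfusion matrix: the global
left-ventricular mean (1 feature), the 17 AHA segment means, the 18
first-order intensity statistics, and the full radiomics vector (18
intensity + 75 texture = 93).  Clinical covariates are one-hot encoded, and
every model standardizes its features with training-set means and standard
deviations.

Transformers follow the scikit-learn fit/transform contract and return
pandas DataFrames with stable, documented column names so that per-split
feature-selection counts are reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import NotFittedError, ValidationError
from .polar import MeasurementMatrix, Parcellation17, make_parcellation17
from .texture import (
    DiscretizationRule,
    TEXTURE_FEATURE_NAMES,
    cohort_bin_width,
    discretize,
    texture_features,
)

__all__ = [
    "FIRSTORDER_FEATURE_NAMES",
    "RADIOMICS_ALL_NAMES",
    "GlobalMeanFeatures",
    "SegmentMeanFeatures",
    "FirstOrderFeatures",
    "RadiomicsFeatures",
    "Standardizer",
    "ClinicalEncoder",
    "global_mean_feature",
    "segment_mean_features",
    "first_order_features",
    "cohort_bin_width",
    "fit_standardizer",
    "apply_standardizer",
    "encode_clinical",
]

# alphabetical within the family, mirroring standard radiomics output order
FIRSTORDER_FEATURE_NAMES = (
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Energy",
    "firstorder_Entropy",
    "firstorder_InterquartileRange",
    "firstorder_Kurtosis",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_Median",
    "firstorder_Minimum",
    "firstorder_Range",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_Skewness",
    "firstorder_TotalEnergy",
    "firstorder_Uniformity",
    "firstorder_Variance",
)

RADIOMICS_ALL_NAMES = FIRSTORDER_FEATURE_NAMES + TEXTURE_FEATURE_NAMES  # 18 + 75 = 93


def _values(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, MeasurementMatrix) else np.asarray(matrix, float)


def global_mean_feature(matrix) -> pd.Series:
    """Mean signal over the entire 16x36 matrix (the whole left ventricle)."""
    return pd.Series({"global_mean": float(_values(matrix).mean())})


def segment_mean_features(matrix, parcellation: Parcellation17) -> pd.Series:
    """Mean signal per AHA segment, ordered segment 1..17."""
    means = parcellation.segment_means(matrix)
    return pd.Series(means, index=[f"segment_{k:02d}" for k in range(1, 18)])


def first_order_features(matrix, rule: DiscretizationRule) -> pd.Series:
    """The 18 standard first-order intensity statistics.

    The discretization rule is only used by the histogram-based members
    (entropy and uniformity); all others are computed on raw intensities
    with population (biased) moments.  Skewness and kurtosis of a constant
    image are defined as 0; kurtosis is the raw (Pearson) form, not excess.
    """
    x = _values(matrix).ravel()
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    core = x[(x >= p10) & (x <= p90)]

    gray = discretize(x.reshape(1, -1), rule).ravel()
    p = np.bincount(gray)[1:].astype(float)
    p = p[p > 0] / n

    energy = float((x**2).sum())
    feats = {
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_Energy": energy,
        "firstorder_Entropy": float(-(p * np.log2(p)).sum()),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "firstorder_Maximum": float(x.max()),
        "firstorder_Mean": mean,
        "firstorder_MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "firstorder_Median": float(p50),
        "firstorder_Minimum": float(x.min()),
        "firstorder_Range": float(x.max() - x.min()),
        "firstorder_RobustMeanAbsoluteDeviation": float(np.abs(core - core.mean()).mean()),
        "firstorder_RootMeanSquared": float(np.sqrt((x**2).mean())),
        "firstorder_Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "firstorder_TotalEnergy": energy,  # unit pixel area on the polar grid
        "firstorder_Uniformity": float((p**2).sum()),
        "firstorder_Variance": m2,
    }
    return pd.Series({k: feats[k] for k in FIRSTORDER_FEATURE_NAMES})


# --------------------------------------------------------------------------
# scikit-learn style transformers (stateless except the radiomics bin rule)


class _MatrixTransformer(TransformerMixin, BaseEstimator):
    """Base: transforms a sequence of matrices into a feature DataFrame."""

    def fit(self, X, y=None):
        return self

    def _frame(self, X, fn) -> pd.DataFrame:
        rows = [fn(m) for m in X]
        return pd.DataFrame(rows).reset_index(drop=True)


class GlobalMeanFeatures(_MatrixTransformer):
    """y in R^1: the global LV mean."""

    def transform(self, X) -> pd.DataFrame:
        return self._frame(X, global_mean_feature)


class SegmentMeanFeatures(_MatrixTransformer):
    """y in R^17: AHA segment means under a configurable parcellation."""

    def __init__(self, parcellation: Parcellation17 | None = None):
        self.parcellation = parcellation

    def transform(self, X) -> pd.DataFrame:
        parc = self.parcellation or make_parcellation17()
        return self._frame(X, lambda m: segment_mean_features(m, parc))


class FirstOrderFeatures(_MatrixTransformer):
    """y in R^18: first-order intensity statistics (radiomics-intensity model).

    The fixed-bin-width rule is fitted on the cohort passed to :meth:`fit`
    (pooled range / 16) unless an explicit rule is supplied.
    """

    def __init__(self, rule: DiscretizationRule | None = None, n_bins: int = 16):
        self.rule = rule
        self.n_bins = n_bins

    def fit(self, X, y=None):
        self.rule_ = self.rule or cohort_bin_width(X, self.n_bins)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "rule_"):
            raise NotFittedError("FirstOrderFeatures must be fitted to derive the bin rule")
        return self._frame(X, lambda m: first_order_features(m, self.rule_))


class RadiomicsFeatures(FirstOrderFeatures):
    """y in R^93: 18 first-order + 75 texture features (radiomics-all model)."""

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "rule_"):
            raise NotFittedError("RadiomicsFeatures must be fitted to derive the bin rule")

        def fn(m):
            row = first_order_features(m, self.rule_)
            row = pd.concat([row, pd.Series(texture_features(m, self.rule_))])
            return row

        return self._frame(X, fn)


class Standardizer(TransformerMixin, BaseEstimator):
    """Per-feature z-scoring with training means and population SDs.

    Constant training columns (SD = 0) transform to 0 so that penalized
    models simply ignore them.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("Standardizer expects a 2D feature table")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)  # population SD
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "mean_"):
            raise NotFittedError("Standardizer used before fitting")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"feature count mismatch: fitted {self.n_features_in_}, got {X.shape[1]}"
            )
        scale = np.where(self.scale_ > 0, self.scale_, 1.0)
        out = (X - self.mean_) / scale
        out[:, self.scale_ == 0] = 0.0
        return out


def fit_standardizer(X) -> Standardizer:
    return Standardizer().fit(np.atleast_2d(np.asarray(X, float)))


def apply_standardizer(standardizer: Standardizer, X) -> np.ndarray:
    return standardizer.transform(np.atleast_2d(np.asarray(X, float)))


class ClinicalEncoder(TransformerMixin, BaseEstimator):
    """Encode the clinical covariates: numeric pass-through, one-hot categoricals.

    ``schema`` maps each variable name either to ``"numeric"`` or to the
    list of admissible category levels.  An unseen level at transform time
    is an error naming the variable and the level.
    """

    def __init__(self, schema: dict):
        self.schema = schema

    def fit(self, X, y=None):
        self.feature_names_out_ = []
        for name, kind in self.schema.items():
            if kind == "numeric":
                self.feature_names_out_.append(name)
            else:
                self.feature_names_out_.extend(f"{name}={level}" for level in kind)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "feature_names_out_"):
            self.fit(X)
        if isinstance(X, dict):
            X = pd.DataFrame([X])
        X = pd.DataFrame(X)
        out = pd.DataFrame(0.0, index=range(len(X)), columns=self.feature_names_out_)
        for name, kind in self.schema.items():
            if name not in X.columns:
                raise ValidationError(f"clinical variable '{name}' missing from input")
            col = X[name]
            if kind == "numeric":
                out[name] = pd.to_numeric(col).to_numpy(dtype=float)
            else:
                levels = list(kind)
                for i, value in enumerate(col):
                    if value not in levels:
                        raise ValidationError(
                            f"unseen level {value!r} for clinical variable '{name}'"
                        )
                    out.iloc[i, out.columns.get_loc(f"{name}={value}")] = 1.0
        return out


def encode_clinical(row: dict, schema: dict) -> pd.Series:
    """Encode one raw clinical row under a schema; see :class:`ClinicalEncoder`."""
    frame = ClinicalEncoder(schema).fit(None).transform(row)
    return frame.iloc[0]
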