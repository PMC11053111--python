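"""Risk models: ElasticNet logistic regression and Cox PH, CNN wrapper, fusion.

Both linear families tune only the ElasticNet mixing parameter over the
fixed, sparsity-promoting grid ``L1_RATIO_GRID`` by 5-fold cross-validated
grid search on the training set (AUC for classification, Harrell's C-index
for survival), refit at the winning value; ties go to the larger (sparser)
l1_ratio.  The overall penalty strength is a fixed, configurable default.

Late fusion averages the prediction scores of an image model and the
clinical model trained on the identical split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .cnn import CnnSpec, NumpyCNN, build_cnn, count_trainable_parameters, train_cnn
from .errors import TrainingError, ValidationError

__all__ = [
    "L1_RATIO_GRID",
    "ElasticNetConfig",
    "ElasticNetMaceClassifier",
    "ElasticNetCoxRisk",
    "PolarCnnClassifier",
    "fit_lr_elasticnet",
    "fit_cox_elasticnet",
    "late_fusion",
    "fuse_cox_risks",
    "CnnSpec",
    "build_cnn",
    "count_trainable_parameters",
]

L1_RATIO_GRID = (0.50, 0.85, 0.9, 0.92, 0.95, 0.97, 0.98, 0.99, 0.995, 0.999, 1.0)

COEF_NONZERO_TOL = 1e-10


@dataclass
class ElasticNetConfig:
    """Shared hyperparameters of the two penalized linear families."""

    l1_ratio_grid: tuple = L1_RATIO_GRID
    cv_folds: int = 5
    # LR: inverse penalty strength (sklearn C); Cox: penalty strength alpha
    lr_C: float = 1.0
    cox_alpha: float = 0.05
    max_iter: int = 5000

    def __post_init__(self):
        if any(not (0 < r <= 1) for r in self.l1_ratio_grid):
            raise ValidationError("l1_ratio grid values must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")


def _cv_auc(scores, labels) -> float:
    from .evaluate import auc  # local import to avoid a cycle

    return auc(scores, labels)


class ElasticNetMaceClassifier(ClassifierMixin, BaseEstimator):
    """ElasticNet-penalized logistic regression with l1_ratio grid search.

    For each grid value the training-set 5-fold (stratified) CV AUC is
    estimated; the model is refit on the full training set at the best
    l1_ratio, ties broken toward the sparser (larger) value.

    Attributes (post-fit): ``coef_``, ``intercept_``, ``l1_ratio_``,
    ``selected_features_`` (indices of nonzero coefficients),
    ``cv_scores_`` (grid value -> mean CV AUC).
    """

    def __init__(self, config: ElasticNetConfig | None = None, random_state: int = 0):
        self.config = config
        self.random_state = random_state

    def _make_lr(self, l1_ratio, cfg):
        return LogisticRegression(
            solver="saga",
            l1_ratio=l1_ratio,
            C=cfg.lr_C,
            max_iter=cfg.max_iter,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        cfg = self.config or ElasticNetConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise TrainingError("training set contains a single outcome class")
        self.classes_ = classes

        folds = StratifiedKFold(
            n_splits=cfg.cv_folds, shuffle=True, random_state=self.random_state
        )
        split_cache = list(folds.split(X, y))
        self.cv_scores_ = {}
        for r in cfg.l1_ratio_grid:
            fold_scores = []
            for tr, va in split_cache:
                model = self._make_lr(r, cfg).fit(X[tr], y[tr])
                fold_scores.append(_cv_auc(model.predict_proba(X[va])[:, 1], y[va]))
            self.cv_scores_[r] = float(np.mean(fold_scores))

        # best mean CV AUC; ties (within fp tolerance) to the sparser model
        best = max(self.cv_scores_.values())
        self.l1_ratio_ = max(r for r, s in self.cv_scores_.items() if s >= best - 1e-12)
        final = self._make_lr(self.l1_ratio_, cfg).fit(X, y)
        self.model_ = final
        self.coef_ = final.coef_[0]
        self.intercept_ = float(final.intercept_[0])
        self.selected_features_ = np.flatnonzero(np.abs(self.coef_) > COEF_NONZERO_TOL)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"feature count mismatch: fitted {self.n_features_in_}, got {X.shape[1]}"
            )
        return self.model_.predict_proba(X)

    def decision_scores(self, X) -> np.ndarray:
        """Event-class probability per case."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


class ElasticNetCoxRisk(BaseEstimator):
    """ElasticNet-penalized Cox proportional hazards risk model.

    The risk score is the linear predictor; the l1_ratio is tuned by 5-fold
    event-stratified CV maximizing Harrell's C-index.
    """

    def __init__(self, config: ElasticNetConfig | None = None, random_state: int = 0):
        self.config = config
        self.random_state = random_state

    def _fit_one(self, l1_ratio, cfg, X, y_struct):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, alphas=[cfg.cox_alpha], normalize=False, max_iter=100000
        )
        return model.fit(X, y_struct)

    def fit(self, X, events, times):
        cfg = self.config or ElasticNetConfig()
        from .evaluate import concordance_index  # local import to avoid a cycle

        X = np.asarray(X, dtype=float)
        events = np.asarray(events, dtype=int)
        times = np.asarray(times, dtype=float)
        if events.sum() == 0:
            raise TrainingError("no events in the training set")
        y_struct = Surv.from_arrays(event=events.astype(bool), time=times)

        folds = StratifiedKFold(
            n_splits=cfg.cv_folds, shuffle=True, random_state=self.random_state
        )
        split_cache = list(folds.split(X, events))
        self.cv_scores_ = {}
        for r in cfg.l1_ratio_grid:
            fold_scores = []
            for tr, va in split_cache:
                if events[tr].sum() == 0:
                    raise TrainingError("a CV fold has no events")
                model = self._fit_one(r, cfg, X[tr], y_struct[tr])
                risk = model.predict(X[va])
                fold_scores.append(concordance_index(risk, events[va], times[va]))
            self.cv_scores_[r] = float(np.mean(fold_scores))

        best = max(self.cv_scores_.values())
        self.l1_ratio_ = max(r for r, s in self.cv_scores_.items() if s >= best - 1e-12)
        self.model_ = self._fit_one(self.l1_ratio_, cfg, X, y_struct)
        self.coef_ = self.model_.coef_.ravel()
        self.selected_features_ = np.flatnonzero(np.abs(self.coef_) > COEF_NONZERO_TOL)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_risk(self, X) -> np.ndarray:
        """Linear-predictor risk score (higher = earlier expected event)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"feature count mismatch: fitted {self.n_features_in_}, got {X.shape[1]}"
            )
        return self.model_.predict(X)


class PolarCnnClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn facade over the NumPy CNNs, fed raw 16x36 matrices."""

    def __init__(self, spec: CnnSpec | None = None):
        self.spec = spec

    def fit(self, X, y):
        spec = self.spec or CnnSpec()
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise TrainingError("training set contains a single outcome class")
        self.net_ = build_cnn(spec)
        train_cnn(self.net_, X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        x = np.stack([m.values if hasattr(m, "values") else np.asarray(m, float) for m in X])
        return self.net_.predict_proba(x)

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


def fit_lr_elasticnet(X, y, config: ElasticNetConfig | None = None, seed: int = 0) -> ElasticNetMaceClassifier:
    """Functional wrapper over :class:`ElasticNetMaceClassifier`."""
    return ElasticNetMaceClassifier(config=config, random_state=seed).fit(X, y)


def fit_cox_elasticnet(X, events, times, config: ElasticNetConfig | None = None, seed: int = 0) -> ElasticNetCoxRisk:
    """Functional wrapper over :class:`ElasticNetCoxRisk`."""
    return ElasticNetCoxRisk(config=config, random_state=seed).fit(X, events, times)


def late_fusion(image_probs, clinical_probs) -> np.ndarray:
    """Unweighted average of image- and clinical-model probabilities."""
    a = np.asarray(image_probs, dtype=float)
    b = np.asarray(clinical_probs, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"score length mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


def fuse_cox_risks(image_risk, clinical_risk, image_train_risk, clinical_train_risk) -> np.ndarray:
    """Average of Cox linear predictors after z-scoring with training statistics.

    Cox models emit unbounded linear predictors rather than probabilities, so
    each stream is standardized over its own training cases before averaging.
    """
    def z(x, ref):
        ref = np.asarray(ref, dtype=float)
        sd = ref.std()
        return (np.asarray(x, dtype=float) - ref.mean()) / (sd if sd > 0 else 1.0)

    a = z(image_risk, image_train_risk)
    b = z(clinical_risk, clinical_train_risk)
    if a.shape != b.shape:
        raise ValidationError(f"score length mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0
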