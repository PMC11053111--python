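"""Repeated-split validation protocol, metrics and summaries.

The protocol: 100 random stratified 75/25 train-test splits with fixed
per-repeat seeds (shared across all models so comparisons are paired);
within each training set the minority (event) class is oversampled by
triplication; features are standardized with training statistics (CNNs see
raw matrices but their training sets are augmented fourfold); the test AUC,
Youden-index cutoff with its sensitivity/specificity (classification) or
Harrell's C-index (survival) are recorded per split; means with 95%
percentile bootstrap confidence intervals (1000 resamples) summarise each
model, and paired bootstrap tests compare models on the shared splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .augment import augment_training_set
from .errors import ConfigurationError, TrainingError, ValidationError
from .features import (
    ClinicalEncoder,
    FirstOrderFeatures,
    GlobalMeanFeatures,
    RadiomicsFeatures,
    SegmentMeanFeatures,
    Standardizer,
)
from .models import (
    CnnSpec,
    ElasticNetConfig,
    ElasticNetCoxRisk,
    ElasticNetMaceClassifier,
    PolarCnnClassifier,
    fuse_cox_risks,
    late_fusion,
)
from .polar import make_parcellation17
from .signals import SignalKind, derive_signal

MODEL_FAMILIES = (
    "global",
    "regional",
    "radiomics_intensity",
    "radiomics_all",
    "cnn1",
    "cnn2",
    "clinical",
)

IMAGE_FEATURE_COUNTS = {
    "global": 1,
    "regional": 17,
    "radiomics_intensity": 18,
    "radiomics_all": 93,
}


@dataclass
class SplitPlan:
    """Shared split schedule: one seed per repeat, identical for all models."""

    n_repeats: int = 100
    train_fraction: float = 0.75
    seeds: tuple = ()

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if not self.seeds:
            self.seeds = tuple(range(self.n_repeats))
        if len(self.seeds) != self.n_repeats:
            raise ConfigurationError("need exactly one seed per repeat")


@dataclass
class SplitResult:
    """Per-repeat test performance of one model."""

    repeat: int
    model: str
    auc: float
    cutoff: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    c_index: float = float("nan")
    selected_features: tuple = ()
    l1_ratio: float = float("nan")
    test_scores: np.ndarray = field(default=None, repr=False)
    test_indices: np.ndarray = field(default=None, repr=False)


@dataclass
class SummaryReport:
    """Across-repeat means, bootstrap CIs and paired model comparisons."""

    means: pd.DataFrame  # one row per model, columns metric mean/lo/hi
    comparisons: pd.DataFrame  # pairwise two-sided bootstrap p-values
    n_boot: int


# --------------------------------------------------------------------------
# splits and oversampling


def stratified_split(labels, train_fraction: float, seed: int):
    """Disjoint, exhaustive train/test indices with per-class proportions.

    Each class contributes floor(train_fraction * class size) training
    cases (234 cases with 47 events at 0.75 give 175 = 35 + 140).
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both outcome classes must be present")
    if counts.min() < 2:
        raise ValidationError("every class needs at least 2 members")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        k = int(np.floor(train_fraction * len(idx)))
        train.append(idx[:k])
        test.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def oversample_positives(train_indices, labels, seed: int, factor: int = 3):
    """Triplicate every positive training case, then shuffle with the split seed.

    35 positives + 140 negatives become 245 cases (105 positive).
    """
    train_indices = np.asarray(train_indices, dtype=int)
    labels = np.asarray(labels, dtype=int)
    pos = train_indices[labels[train_indices] == 1]
    neg = train_indices[labels[train_indices] == 0]
    expanded = np.concatenate([neg] + [pos] * factor)
    rng = np.random.default_rng(seed)
    return rng.permutation(expanded)


# --------------------------------------------------------------------------
# metrics


def auc(scores, labels) -> float:
    """Area under the ROC curve by the midrank (rank-sum) convention."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes in the test set")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def youden_cutoff(scores, labels):
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed scores; a case is called positive when its
    score >= cutoff.  Ties in J break toward higher specificity (and then
    the larger cutoff).  Returns (cutoff, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("Youden cutoff needs both classes")
    best = None
    for t in np.unique(scores):
        called = scores >= t
        sens = float((called & (labels == 1)).sum() / n_pos)
        spec = float((~called & (labels == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        key = (j, spec, t)
        if best is None or key > (best[0], best[2], best[3]):
            best = (j, sens, spec, t)
    j, sens, spec, t = best
    return float(t), sens, spec


def concordance_index(risk_scores, events, times) -> float:
    """Harrell's C over comparable pairs; risk ties count 1/2.

    A pair is comparable when the earlier observed time belongs to an event.
    """
    risk = np.asarray(risk_scores, dtype=float)
    events = np.asarray(events, dtype=int)
    times = np.asarray(times, dtype=float)
    concordant = 0.0
    comparable = 0
    n = len(risk)
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            if times[j] > times[i] or (times[j] == times[i] and events[j] == 0):
                comparable += 1
                if risk[i] > risk[j]:
                    concordant += 1.0
                elif risk[i] == risk[j]:
                    concordant += 0.5
    if comparable == 0:
        raise ValidationError("no comparable pairs for the concordance index")
    return float(concordant / comparable)


# --------------------------------------------------------------------------
# aggregation


def bootstrap_summary(metrics_by_model: dict, n_boot: int = 1000, seed: int = 12345) -> SummaryReport:
    """Percentile bootstrap of per-split means, plus paired comparisons.

    The per-model 95% CI comes from ``n_boot`` resamples of the per-split
    metrics; pairwise p-values from the paired bootstrap of per-split
    differences (two-sided, floored at 1/n_boot).
    """
    lengths = {k: len(v) for k, v in metrics_by_model.items()}
    if len(set(lengths.values())) > 1:
        raise ValidationError(f"repeat counts differ across models: {lengths}")
    n_rep = next(iter(lengths.values()))
    if n_rep < 2:
        raise ValidationError("bootstrap_summary needs >= 2 repeats")

    rng = np.random.default_rng(seed)
    resample_idx = rng.integers(0, n_rep, size=(n_boot, n_rep))

    rows = []
    boot_means = {}
    for model, values in metrics_by_model.items():
        values = np.asarray(values, dtype=float)
        bm = values[resample_idx].mean(axis=1)
        boot_means[model] = bm
        lo, hi = np.percentile(bm, [2.5, 97.5])
        rows.append({"model": model, "mean": float(values.mean()), "ci_lo": float(lo), "ci_hi": float(hi)})
    means = pd.DataFrame(rows).set_index("model")

    comp_rows = []
    names = list(metrics_by_model)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diffs = np.asarray(metrics_by_model[a], float) - np.asarray(metrics_by_model[b], float)
            bd = diffs[resample_idx].mean(axis=1)
            p = 2.0 * min((bd <= 0).mean(), (bd >= 0).mean())
            p = float(np.clip(p, 1.0 / n_boot, 1.0))
            comp_rows.append({"model_a": a, "model_b": b, "mean_diff": float(diffs.mean()), "p_value": p})
    comparisons = pd.DataFrame(comp_rows)
    return SummaryReport(means=means, comparisons=comparisons, n_boot=n_boot)


def km_risk_groups(scores, events, times, *, group_rule: str = "median"):
    """Kaplan-Meier curves and log-rank test for median-split risk groups.

    Scores at or below the median go to the low-risk group.  Returns a dict
    with the two fitted survival tables, group masks, the log-rank
    chi-square statistic and its p-value.
    """
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events, dtype=int)
    times = np.asarray(times, dtype=float)
    if group_rule != "median":
        raise ConfigurationError(f"unknown group rule {group_rule!r}")
    cut = float(np.median(scores))
    low = scores <= cut
    high = ~low
    if low.sum() == 0 or high.sum() == 0:
        raise ValidationError("median split produced an empty risk group")

    fitters = {}
    for name, mask in (("low", low), ("high", high)):
        km = KaplanMeierFitter(label=name)
        km.fit(times[mask], events[mask])
        fitters[name] = km
    lr = logrank_test(times[low], times[high], events[low], events[high])
    return {
        "low": fitters["low"],
        "high": fitters["high"],
        "low_mask": low,
        "high_mask": high,
        "median_score": cut,
        "chi2": float(lr.test_statistic),
        "p_value": float(lr.p_value),
    }


def selection_counts(fitted_models, feature_names) -> pd.Series:
    """How many splits selected each feature (|coefficient| > 1e-10)."""
    counts = np.zeros(len(feature_names), dtype=int)
    for model in fitted_models:
        counts[np.asarray(model.selected_features_, dtype=int)] += 1
    return pd.Series(counts, index=list(feature_names), name="selection_count")


# --------------------------------------------------------------------------
# experiment driver


def _image_transformer(model_family: str, parcellation=None):
    if model_family == "global":
        return GlobalMeanFeatures()
    if model_family == "regional":
        return SegmentMeanFeatures(parcellation)
    if model_family == "radiomics_intensity":
        return FirstOrderFeatures()
    if model_family == "radiomics_all":
        return RadiomicsFeatures()
    raise ConfigurationError(f"unknown image model family {model_family!r}")


@dataclass
class ExperimentConfig:
    """Everything one `run_experiment` call needs besides the cohort."""

    signal: SignalKind | str = SignalKind.MFC_RADIUS
    rpp_adjust: bool = True
    elasticnet: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    cnn_spec: CnnSpec | None = None
    clinical_schema: dict | None = None
    task: str = "classification"  # or "survival" (linear families only)
    strict_bin_rule: bool = False  # train-only discretization range
    youden_on: str = "test"  # or "train"
    keep_models: bool = False


def run_experiment(records, model_family: str, plan: SplitPlan, config: ExperimentConfig | None = None):
    """Run the repeated-split protocol for one model family.

    ``records`` is a list of :class:`polarmace.polar.CohortRecord`.  Returns
    ``(results, summary, extras)`` where ``results`` is a list of
    :class:`SplitResult`, ``summary`` the bootstrap report over the AUC (or
    C-index), and ``extras`` holds selection counts / fitted models where
    applicable.
    """
    config = config or ExperimentConfig()
    if config.task not in ("classification", "survival"):
        raise ConfigurationError(f"unknown task {config.task!r}")
    is_cnn = model_family in ("cnn1", "cnn2")
    is_fused = model_family.startswith("fused:")
    base_family = model_family.split(":", 1)[1] if is_fused else model_family
    if config.task == "survival" and is_cnn:
        raise ConfigurationError("CNN families are classification-only")

    labels = np.array([r.outcome.event for r in records], dtype=int)
    times = np.array([r.outcome.time_days for r in records], dtype=float)
    signal = SignalKind(config.signal)

    matrices = None
    if base_family != "clinical":
        matrices = [derive_signal(r.study, signal, config.rpp_adjust) for r in records]

    clinical_frame = None
    if base_family == "clinical" or is_fused:
        if config.clinical_schema is None:
            raise ConfigurationError("clinical model requires a clinical_schema")
        encoder = ClinicalEncoder(config.clinical_schema).fit(None)
        clinical_frame = encoder.transform(pd.DataFrame([r.clinical for r in records]))

    # pooled-cohort feature tables for the linear image families; the pooled
    # bin rule (default) is split-independent so features can be precomputed
    feature_table = None
    feature_names = None
    if not is_cnn and base_family != "clinical" and not config.strict_bin_rule:
        tf = _image_transformer(base_family)
        feature_table = tf.fit(matrices).transform(matrices)
        feature_names = list(feature_table.columns)

    results = []
    fitted = []
    for repeat, seed in enumerate(plan.seeds):
        train_idx, test_idx = stratified_split(labels, plan.train_fraction, seed)
        train_over = oversample_positives(train_idx, labels, seed)

        def linear_scores(base, table=None):
            """Fit one penalized linear model on the oversampled split."""
            if base == "clinical":
                table = clinical_frame
            elif table is None:
                if config.strict_bin_rule:
                    tf = _image_transformer(base)
                    tf.fit([matrices[i] for i in train_over])
                    table = tf.transform(matrices)
                else:
                    table = feature_table
            X = table.to_numpy(dtype=float)
            std = Standardizer().fit(X[train_over])
            X_std = std.transform(X)
            if config.task == "survival":
                model = ElasticNetCoxRisk(config=config.elasticnet, random_state=seed).fit(
                    X_std[train_over], labels[train_over], times[train_over]
                )
                return model, model.predict_risk(X_std[test_idx]), model.predict_risk(X_std[train_over])
            model = ElasticNetMaceClassifier(config=config.elasticnet, random_state=seed).fit(
                X_std[train_over], labels[train_over]
            )
            return model, model.decision_scores(X_std[test_idx]), model.decision_scores(X_std[train_over])

        if is_cnn:
            spec = config.cnn_spec or CnnSpec(architecture=model_family)
            spec = CnnSpec(**{**spec.__dict__, "architecture": model_family, "seed": seed})
            augmented = augment_training_set(
                [matrices[i] for i in train_over], labels[train_over]
            )
            clf = PolarCnnClassifier(spec=spec).fit(augmented.matrices, augmented.labels)
            test_scores = clf.decision_scores([matrices[i] for i in test_idx])
            train_scores = clf.decision_scores([matrices[i] for i in train_over])
            model = clf
        else:
            model, test_scores, train_scores = linear_scores(base_family)

        if is_fused:
            clin_model, clin_test, clin_train = linear_scores("clinical")
            if config.task == "survival":
                test_scores = fuse_cox_risks(test_scores, clin_test, train_scores, clin_train)
            else:
                test_scores = late_fusion(test_scores, clin_test)

        if config.task == "survival":
            ci = concordance_index(test_scores, labels[test_idx], times[test_idx])
            result = SplitResult(
                repeat=repeat, model=model_family, auc=float("nan"), c_index=ci,
                selected_features=tuple(getattr(model, "selected_features_", ())),
                l1_ratio=getattr(model, "l1_ratio_", float("nan")),
                test_scores=np.asarray(test_scores), test_indices=test_idx,
            )
        else:
            test_auc = auc(test_scores, labels[test_idx])
            if config.youden_on == "train":
                cut, _, _ = youden_cutoff(train_scores, labels[train_over])
                called = np.asarray(test_scores) >= cut
                y_test = labels[test_idx]
                sens = float((called & (y_test == 1)).sum() / max(1, (y_test == 1).sum()))
                spec_ = float((~called & (y_test == 0)).sum() / max(1, (y_test == 0).sum()))
            else:
                cut, sens, spec_ = youden_cutoff(test_scores, labels[test_idx])
            result = SplitResult(
                repeat=repeat, model=model_family, auc=test_auc, cutoff=cut,
                sensitivity=sens, specificity=spec_,
                selected_features=tuple(getattr(model, "selected_features_", ())),
                l1_ratio=getattr(model, "l1_ratio_", float("nan")),
                test_scores=np.asarray(test_scores), test_indices=test_idx,
            )
        results.append(result)
        if config.keep_models or (not is_cnn and base_family != "clinical"):
            fitted.append(model)

    metric = "c_index" if config.task == "survival" else "auc"
    summary = bootstrap_summary({model_family: [getattr(r, metric) for r in results]})
    extras = {"fitted_models": fitted}
    if feature_names is not None and fitted and hasattr(fitted[0], "selected_features_"):
        extras["selection_counts"] = selection_counts(fitted, feature_names)
        extras["feature_names"] = feature_names
    return results, summary, extras


def results_frame(results) -> pd.DataFrame:
    """Tabulate per-split results (one row per repeat x model)."""
    return pd.DataFrame(
        [
            {
                "repeat": r.repeat,
                "model": r.model,
                "auc": r.auc,
                "cutoff": r.cutoff,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "c_index": r.c_index,
                "l1_ratio": r.l1_ratio,
                "n_selected": len(r.selected_features),
            }
            for r in results
        ]
    )
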