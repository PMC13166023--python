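"""Evaluation harness: Fisher-score discriminability, stratified repeated
cross-validated classification, paired statistical comparison of feature
sets, component ablation, and per-channel condition-difference maps.

Cross-validation pools epochs from all subjects before fold assignment
(the default protocol for inter-subject feature evaluation here); a
subject-grouped mode is available for stricter generalization estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import wilcoxon
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import GridSearchCV, GroupKFold, RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .decomposition import CeemdanParams
from .features import SSRIMEParams, extract_feature_matrix, ssrime_variant_matrices
from .synthetic import EpochedEEG

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "ComparisonResult",
    "EvaluationReport",
    "fisher_score",
    "fisher_scores_pairwise",
    "cross_validate",
    "compare_feature_sets",
    "delta_map",
    "ablation_study",
]

_EPS_VAR = 1e-12

#: Hyperparameter grids used when nested tuning is enabled.
CLASSIFIER_GRIDS = {
    "svm": {"clf__C": [0.1, 1.0, 10.0], "clf__gamma": ["scale", 0.01, 0.1]},
    "mlp": {"clf__alpha": [1e-4, 1e-2]},
    "rf": {"clf__max_features": ["sqrt", None]},
    "knn": {"clf__n_neighbors": [3, 5, 9]},
}


def make_classifier(name: str = "svm", seed: int = 0, tuned: bool = False,
                    inner_folds: int = 3, scale: bool = False):
    """Standard classifier pipeline, optionally wrapped in an inner grid
    search for nested cross-validation.

    Per-feature standardization is off by default: the feature sets here are
    already on a common normalized scale (relative energies summing to one),
    and z-scoring each column would re-amplify the deliberately suppressed
    non-δ/θ components, undoing the band weighting. Pass ``scale=True`` for
    feature sets on heterogeneous scales.
    """
    models = {
        "svm": SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed),
        "mlp": MLPClassifier(hidden_layer_sizes=(64,), max_iter=800, random_state=seed),
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
    }
    if name not in models:
        raise ValueError(f"unknown classifier {name!r}; choose from {sorted(models)}")
    pipe = Pipeline([("scale", StandardScaler() if scale else "passthrough"),
                     ("clf", models[name])])
    if tuned:
        return GridSearchCV(pipe, CLASSIFIER_GRIDS[name], cv=inner_folds, n_jobs=1)
    return pipe


def fisher_score(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature two-class Fisher score:
    (m1 − m0)² / (v1 + v0 + ε)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("fisher_score requires exactly two classes")
    masks = [y == c for c in classes]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("need >= 2 epochs per class")
    m0, m1 = (X[m].mean(axis=0) for m in masks)
    v0, v1 = (X[m].var(axis=0, ddof=1) for m in masks)
    return (m1 - m0) ** 2 / (v1 + v0 + _EPS_VAR)


def fisher_scores_pairwise(features: np.ndarray, labels: np.ndarray,
                           average: bool = False):
    """Fisher scores per pairwise class contrast; optionally averaged.

    Multi-class discriminability has no single canonical Fisher form, so
    scores are reported per contrast (e.g. 0v2, 0v3, 2v3)."""
    y = np.asarray(labels)
    classes = list(np.unique(y))
    out = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            mask = (y == a) | (y == b)
            out[f"{a}_vs_{b}"] = fisher_score(features[mask], y[mask])
    if average:
        return np.mean(list(out.values()), axis=0)
    return out


@dataclass
class CVResult:
    """Cross-validated performance: accuracies in percent."""

    fold_accuracies: np.ndarray
    fold_f1: np.ndarray
    n_folds: int
    n_repeats: int
    seed: int
    classifier: str

    @property
    def accuracy_mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))

    @property
    def f1_mean(self) -> float:
        return float(self.fold_f1.mean())

    def summary(self) -> dict:
        return {
            "accuracy_mean_pct": self.accuracy_mean,
            "accuracy_sd_pct": self.accuracy_sd,
            "f1_mean": self.f1_mean,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "classifier": self.classifier,
        }


def make_splits(labels, n_folds: int = 10, n_repeats: int = 10, seed: int = 0,
                groups=None) -> list:
    """Precomputed fold assignments (train_idx, test_idx) so that paired
    designs can evaluate several feature sets on identical folds."""
    y = np.asarray(labels)
    if groups is not None:
        cv = GroupKFold(n_splits=n_folds)
        return list(cv.split(np.zeros(len(y)), y, groups=np.asarray(groups)))
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(f"smallest class has {counts.min()} epochs; need >= n_folds={n_folds}")
    cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def cross_validate(features, labels, classifier: str = "svm", n_folds: int = 10,
                   n_repeats: int = 10, seed: int = 0, tuned: bool = False,
                   splits=None, groups=None, scale: bool = False) -> CVResult:
    """Stratified repeated k-fold classification over pooled epochs.

    ``splits`` overrides fold generation (paired ablation designs);
    ``groups`` switches to subject-grouped folds.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if splits is None:
        splits = make_splits(y, n_folds, n_repeats, seed, groups=groups)
    accs = np.empty(len(splits))
    f1s = np.empty(len(splits))
    for i, (tr, te) in enumerate(splits):
        clf = make_classifier(classifier, seed=seed, tuned=tuned, scale=scale)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        accs[i] = accuracy_score(y[te], pred) * 100.0
        f1s[i] = f1_score(y[te], pred, average="macro")
    return CVResult(accs, f1s, n_folds, n_repeats, seed, classifier)


@dataclass
class ComparisonResult:
    """Paired feature-set comparison: Wilcoxon signed-rank with Bonferroni
    correction and Cohen's d on the per-fold differences."""

    p_raw: float
    p_corrected: float
    effect_size_d: float
    n_pairs: int
    degenerate: bool = False


def compare_feature_sets(scores_a, scores_b, n_comparisons: int = 1) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired per-fold scores.

    All-zero differences are degenerate: p = 1 by convention, flagged.
    Cohen's d is mean(diff)/sd(diff) on the paired differences.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 6:
        raise ValueError("need paired score vectors of equal length >= 6")
    diff = a - b
    if np.all(diff == 0):
        return ComparisonResult(1.0, 1.0, 0.0, a.size, degenerate=True)
    stat, p = wilcoxon(a, b)
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else float(np.inf * np.sign(diff.mean()))
    return ComparisonResult(float(p), float(min(1.0, p * n_comparisons)), d, a.size)


def delta_map(features, labels, subject_ids, n_channels: int,
              low_label, high_label, imf_indices=None) -> np.ndarray:
    """Per-channel condition-difference map.

    Per subject: z-normalize the feature values over all of the subject's
    epochs and features jointly (removing the subject's amplitude scale),
    average across epochs within each condition, aggregate each channel
    over the selected per-channel components (default: all), and take
    high − low. The subject maps are then averaged. Subjects missing either
    condition are excluded with a warning.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    subs = np.asarray(subject_ids)
    n_feat = X.shape[1]
    if n_feat % n_channels:
        raise ValueError("feature count must be a multiple of n_channels")
    k = n_feat // n_channels
    idx = np.arange(k) if imf_indices is None else np.asarray(imf_indices)
    maps = []
    for s in np.unique(subs):
        m = subs == s
        lo_mask = m & (y == low_label)
        hi_mask = m & (y == high_label)
        if not lo_mask.any() or not hi_mask.any():
            warnings.warn(f"subject {s} missing a condition; excluded from delta_map")
            continue
        mu, sd = X[m].mean(), X[m].std()
        if sd == 0:
            sd = 1.0
        per_cond = []
        for mask in (lo_mask, hi_mask):
            z = (X[mask] - mu) / sd
            mean_feat = z.mean(axis=0).reshape(n_channels, k)
            per_cond.append(mean_feat[:, idx].mean(axis=1))
        maps.append(per_cond[1] - per_cond[0])
    if not maps:
        raise ValueError("no subject has both conditions")
    return np.mean(maps, axis=0)


@dataclass
class EvaluationReport:
    """Bundled results for one dataset/contrast."""

    cv: dict
    fisher: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    ablation: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "cv": {}, "fisher": {}, "comparisons": {}, "ablation": {}}
        for name, res in self.cv.items():
            out["cv"][name] = res.summary()
        for name, scores in self.fisher.items():
            out["fisher"][name] = np.asarray(scores).tolist()
        for name, comp in self.comparisons.items():
            out["comparisons"][name] = {
                "p_raw": comp.p_raw, "p_corrected": comp.p_corrected,
                "effect_size_d": comp.effect_size_d, "n_pairs": comp.n_pairs,
                "degenerate": comp.degenerate,
            }
        for name, res in self.ablation.items():
            out["ablation"][name] = res.summary()
        return out


def ablation_study(dataset: EpochedEEG, params: SSRIMEParams | None = None,
                   cparams: CeemdanParams | None = None, classifier: str = "svm",
                   n_folds: int = 10, n_repeats: int = 2, seed: int = 0,
                   include_baselines: bool = True, rwe_levels: int = 5) -> EvaluationReport:
    """Paired component ablation.

    Evaluates the full descriptor, each single-component-removed variant
    (−stabilization, −band weighting, −normalization), and the RIME/RWE/PSD
    baselines on identical fold assignments, then tests full-vs-variant
    differences with Wilcoxon + Bonferroni.
    """
    params = params or SSRIMEParams()
    cparams = cparams or CeemdanParams()
    matrices = ssrime_variant_matrices(dataset.data, dataset.fs, params, cparams,
                                       include_rime=True, base_seed=seed)
    if include_baselines:
        matrices["rwe"] = extract_feature_matrix(dataset.data, dataset.fs, "rwe",
                                                 n_levels=rwe_levels)
        matrices["psd"] = extract_feature_matrix(dataset.data, dataset.fs, "psd")
    splits = make_splits(dataset.labels, n_folds, n_repeats, seed)
    cv = {name: cross_validate(mat, dataset.labels, classifier, n_folds,
                               n_repeats, seed, splits=splits)
          for name, mat in matrices.items()}
    others = [name for name in cv if name != "ssrime"]
    comparisons = {}
    if len(splits) >= 6:
        comparisons = {
            f"ssrime_vs_{name}": compare_feature_sets(
                cv["ssrime"].fold_accuracies, cv[name].fold_accuracies,
                n_comparisons=len(others))
            for name in others
        }
    else:
        logger.info("fewer than 6 folds: skipping Wilcoxon comparisons")
    return EvaluationReport(cv=cv, comparisons=comparisons, ablation=cv, seed=seed)
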