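"""Filter and wrapper feature selection over the 23 canonical features.

Filter methods rank each feature against the seizure/normal label:
mutual information (Kraskov-style k-NN estimator), the non-negative
feature-selection chi-squared variant (per-class feature mass vs class
frequency), and the one-way ANOVA F statistic.  The wrapper method is
recursive feature elimination (RFE) evaluated by cross-validated F1;
prototype classifiers (RCE, k-NN), which expose no coefficients, supply
importances through permutation importance.

Importance lists are computed per subject and averaged (after min-max
normalization) across subjects, so a cohort-level ranking respects
individual variability.  The named feature sets that historically came
out of these experiments ship as built-ins (see ``BUILTIN_FEATURE_SETS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.feature_selection import mutual_info_classif
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .eeg_data import SEIZURE
from .features import CANONICAL_FEATURES

FILTER_METHODS = ("mutual_info", "chi_squared", "anova_f", "rfe")


@dataclass
class FeatureImportance:
    method: str
    scores: dict                     # feature name -> score
    ranking: list = field(default_factory=list)
    subject_id: str = "pooled"

    def __post_init__(self):
        if not self.ranking:
            self.ranking = rank_names(self.scores)


def rank_names(scores: dict) -> list:
    """Descending by score; ties broken lexicographically by name."""
    return sorted(scores, key=lambda nm: (-scores[nm], nm))


@dataclass(frozen=True)
class FeatureSet:
    name: str
    members: tuple

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError("feature set members must be unique")

    def __len__(self):
        return len(self.members)

    @classmethod
    def canonical(cls, name, members):
        """A set restricted to the 23 canonical per-channel features."""
        unknown = set(members) - set(CANONICAL_FEATURES)
        if unknown:
            raise ValueError(f"unknown canonical features {sorted(unknown)}")
        return cls(name, tuple(members))


def _rms(bands):
    return tuple(f"RMS_{b}" for b in bands)


def _ma(bands):
    return tuple(f"MA_{b}" for b in bands)


def _am(bands):
    return tuple(f"AM_{b}" for b in bands)


#: named selections from the historical feature-selection experiments,
#: plus the visually pruned 20-feature set (A6-band statistics dropped
#: for their static DC content) and the full 23-feature set.
BUILTIN_FEATURE_SETS = {
    fs.name: fs for fs in [
        FeatureSet.canonical("anova-f", ("CD", "SampEn") + _rms(["D4", "D3", "D2", "D1"])),
        FeatureSet.canonical("chi-squared",
                   _rms(["D4", "D3", "D2"]) + _ma(["D4", "D3", "D2", "D1"])),
        FeatureSet.canonical("svm-rfe", ("SampEn",) + _rms(["D4", "D2", "D1"])
                   + _ma(["D1"]) + _am(["D2", "D1"])),
        FeatureSet.canonical("knn-rfe", ("CD", "SampEn")
                   + _rms(["D6", "D5", "D4", "D3", "D2", "D1"])),
        FeatureSet.canonical("rce-rfe", ("CD", "SampEn") + _rms(["D2", "D1"])
                   + _am(["D6", "D5", "D4", "D3", "D2", "D1"])),
        FeatureSet.canonical("gui-pruned-20", tuple(
            nm for nm in CANONICAL_FEATURES
            if not nm.endswith("_A6"))),
        FeatureSet.canonical("full", tuple(CANONICAL_FEATURES)),
    ]
}


def get_feature_set(name: str) -> FeatureSet:
    try:
        return BUILTIN_FEATURE_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown feature set {name!r}; built-ins: "
            f"{sorted(BUILTIN_FEATURE_SETS)}") from None


def _as_name_list(feature_names, n_features):
    if feature_names is None:
        if n_features == len(CANONICAL_FEATURES):
            return list(CANONICAL_FEATURES)
        return [f"f{i}" for i in range(n_features)]
    names = list(feature_names)
    if len(names) != n_features:
        raise ValueError(f"{len(names)} names for {n_features} features")
    return names


def _require_two_classes(y):
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking requires >= 2 classes in y")


# ---------------------------------------------------------------------------
# filter methods
# ---------------------------------------------------------------------------

def rank_mutual_info(X, y, k_neighbors: int = 3, feature_names=None,
                     seed: int = 0, subject_id: str = "pooled"
                     ) -> FeatureImportance:
    """Mutual information of each feature with the label (k-NN estimator)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    _require_two_classes(y)
    names = _as_name_list(feature_names, X.shape[1])
    mi = mutual_info_classif(X, y, n_neighbors=k_neighbors, random_state=seed)
    return FeatureImportance("mutual_info", dict(zip(names, mi.tolist())),
                             subject_id=subject_id)


def rank_chi_squared(X_nonneg, y, feature_names=None,
                     subject_id: str = "pooled") -> FeatureImportance:
    """Feature-selection chi-squared on non-negative (quantized) features.

    The statistic compares per-class summed feature mass to the class
    frequencies, so it scales linearly with the feature — rank, not
    magnitude, is meaningful.
    """
    X = np.asarray(X_nonneg, dtype=np.float64)
    y = np.asarray(y)
    _require_two_classes(y)
    if np.any(X < 0):
        raise ValueError(
            "chi-squared ranking requires non-negative features; "
            "quantize them first (features.quantize)")
    names = _as_name_list(feature_names, X.shape[1])
    stat, _ = _sk_chi2(X, y)
    stat = np.nan_to_num(stat, nan=0.0)
    return FeatureImportance("chi_squared", dict(zip(names, stat.tolist())),
                             subject_id=subject_id)


def rank_anova_f(X, y, feature_names=None, subject_id: str = "pooled"
                 ) -> FeatureImportance:
    """One-way ANOVA F per feature (between- over within-class mean square).

    Degenerate features get explicit sentinels: zero within-class variance
    with equal class means scores 0, with unequal means +inf.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    _require_two_classes(y)
    names = _as_name_list(feature_names, X.shape[1])
    classes, inv = np.unique(y, return_inverse=True)
    n, p = X.shape
    k = classes.size
    counts = np.bincount(inv, minlength=k).astype(np.float64)
    if np.any(counts < 2):
        raise ValueError("ANOVA-F requires >= 2 samples per class")
    grand = X.mean(axis=0)
    ss_between = np.zeros(p)
    ss_within = np.zeros(p)
    for c in range(k):
        Xc = X[inv == c]
        mc = Xc.mean(axis=0)
        ss_between += counts[c] * (mc - grand) ** 2
        ss_within += ((Xc - mc) ** 2).sum(axis=0)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    scores = np.empty(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = ms_between / ms_within
    zero_w = ms_within == 0
    scores[zero_w & (ms_between == 0)] = 0.0
    scores[zero_w & (ms_between > 0)] = np.inf
    return FeatureImportance("anova_f", dict(zip(names, scores.tolist())),
                             subject_id=subject_id)


# ---------------------------------------------------------------------------
# wrapper method: recursive feature elimination
# ---------------------------------------------------------------------------

def _importances(est, X, y, seed):
    if hasattr(est, "coef_"):
        coef = np.asarray(est.coef_)
        return np.abs(coef).sum(axis=0) if coef.ndim > 1 else np.abs(coef)
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_)
    # prototype classifiers expose no coefficients: permutation fallback
    r = permutation_importance(est, X, y, n_repeats=3, random_state=seed,
                               scoring="f1_macro")
    return r.importances_mean


def rfe_select(classifier_factory, X, y, target_size: int = 1, step: int = 1,
               feature_names=None, cv: int = 3, tolerance: float = 0.005,
               seed: int = 0) -> FeatureSet:
    """Recursive feature elimination to the performance plateau.

    Repeatedly drops the ``step`` least-important features, scoring each
    intermediate set by ``cv``-fold cross-validated F1; returns the
    smallest set whose score is within ``tolerance`` (absolute F1) of the
    best seen along the elimination path.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    names = _as_name_list(feature_names, X.shape[1])
    if target_size > X.shape[1]:
        raise ValueError(
            f"target_size {target_size} exceeds {X.shape[1]} features")
    active = list(range(X.shape[1]))
    path = []                         # (score, feature index tuple)
    ybin = y == SEIZURE if y.dtype == object or y.dtype.kind in "SU" else y
    while True:
        Xa = X[:, active]
        est = classifier_factory()
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        score = float(np.mean(cross_val_score(
            est, Xa, ybin, cv=skf, scoring="f1")))
        path.append((score, tuple(active)))
        if len(active) <= target_size:
            break
        est.fit(Xa, ybin)
        imp = _importances(est, Xa, ybin, seed)
        n_drop = min(step, len(active) - target_size)
        drop = np.argsort(imp, kind="stable")[:n_drop]
        active = [a for j, a in enumerate(active) if j not in set(drop.tolist())]
    best = max(s for s, _ in path)
    plateau = [(s, idx) for s, idx in path if s >= best - tolerance]
    _, chosen = min(plateau, key=lambda t: len(t[1]))
    return FeatureSet("rfe", tuple(names[i] for i in sorted(chosen)))


class SklearnPrototypeClassifier(BaseEstimator, ClassifierMixin):
    """Thin sklearn-API adapter so RCE/k-NN can ride RFE and CV utilities.

    Fits the wrapped prototype model on internally quantized features;
    Unknown RCE outputs fall back to the normal class (the conservative
    single-stage resolution).
    """

    def __init__(self, kind: str = "rce", config=None):
        self.kind = kind
        self.config = config

    def fit(self, X, y):
        from . import classifiers as clf
        from .features import fit_quantizer, quantize
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._quant = fit_quantizer(X)
        Q = np.vstack([quantize(v, self._quant) for v in X])
        ylab = np.where(y.astype(bool), SEIZURE, "normal") \
            if y.dtype != object else y
        if self.kind == "rce":
            self._model = clf.rce_train_iterative(
                Q, ylab, self.config or clf.RCEConfig())
        else:
            self._model = clf.knn_train(Q, ylab, self.config or clf.KNNConfig())
        return self

    def predict(self, X):
        from . import classifiers as clf
        from .features import quantize
        X = np.asarray(X, dtype=np.float64)
        out = []
        for v in X:
            q = quantize(v, self._quant)
            if self.kind == "rce":
                pred = clf.rce_classify(self._model, q)
                lab = "normal" if pred.label == clf.UNKNOWN else pred.label
            else:
                lab = clf.knn_classify(self._model, q).label
            out.append(lab == SEIZURE)
        res = np.asarray(out)
        if self.classes_.dtype == object or self.classes_.dtype.kind in "SU":
            return np.where(res, SEIZURE, "normal")
        return res


# ---------------------------------------------------------------------------
# cross-subject aggregation
# ---------------------------------------------------------------------------

def aggregate_importance(per_subject) -> FeatureImportance:
    """Average min-max-normalized scores across subjects; re-rank."""
    per_subject = list(per_subject)
    if not per_subject:
        raise ValueError("no importance lists to aggregate")
    methods = {fi.method for fi in per_subject}
    if len(methods) > 1:
        raise ValueError(f"cannot aggregate mixed methods {sorted(methods)}")
    universe = sorted(per_subject[0].scores)
    for fi in per_subject[1:]:
        if sorted(fi.scores) != universe:
            raise ValueError("importance lists cover different features")
    if len(per_subject) == 1:
        fi = per_subject[0]
        return FeatureImportance(fi.method, dict(fi.scores), subject_id="pooled")
    acc = {nm: 0.0 for nm in universe}
    for fi in per_subject:
        vals = np.array([fi.scores[nm] for nm in universe], dtype=np.float64)
        finite = vals[np.isfinite(vals)]
        hi = finite.max() if finite.size else 1.0
        vals = np.where(np.isfinite(vals), vals, hi)
        lo, hi = vals.min(), vals.max()
        norm = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
        for nm, v in zip(universe, norm):
            acc[nm] += float(v)
    n = len(per_subject)
    scores = {nm: v / n for nm, v in acc.items()}
    return FeatureImportance(methods.pop(), scores, subject_id="pooled")
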