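"""Metrics, evaluation protocols, and end-to-end pipeline runners.

Epoch-level confusion counts treat seizure as the positive class:

* sensitivity (= recall) = TP / (TP + FN) * 100
* specificity             = TN / (TN + FP) * 100
* precision               = TP / (TP + FP) * 100
* F1 = 2 * precision * recall / (precision + recall)

A metric whose denominator is zero is *undefined* (``None``), never an
exception, and undefined values are excluded (and counted) when
averaging across subjects.  Cross-subject dispersion is reported as the
population variance (ddof = 0).

Protocols:

* **individual**: per subject, train on all-but-m of that subject's
  sessions and test on the held-out m (m = 1 is leave-one-session-out);
  the population second stage is trained on the *other* subjects.
* **population**: leave-one-subject-out; the model is trained on every
  other subject's pooled sessions and tested on all sessions of the
  held-out subject.
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import classifiers as clf
from .classifiers import (KNNConfig, RCEConfig, TwoStageConfig,
                          two_stage_classify, train_two_stage)
from .eeg_data import NORMAL, SEIZURE, balance_dataset, epoch_recording
from .features import (CANONICAL_FEATURES, CDParams, DWDConfig, FeatureConfig,
                       extract_epoch_matrix)
from .selection import get_feature_set
from .synthetic import generate_session

METRIC_NAMES = ("sensitivity", "specificity", "precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)


@dataclass(frozen=True)
class Metrics:
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    recall: float | None
    f1: float | None

    def as_dict(self):
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Percent-scale metrics with undefined (None) on zero denominators."""
    def ratio(num, den):
        return None if den == 0 else 100.0 * num / den

    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.tn + c.fp)
    prec = ratio(c.tp, c.tp + c.fp)
    rec = sens
    if prec is None or rec is None or prec + rec == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    return Metrics(sens, spec, prec, rec, f1)


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == SEIZURE) & (y_pred == SEIZURE)))
    fn = int(np.sum((y_true == SEIZURE) & (y_pred != SEIZURE)))
    tn = int(np.sum((y_true == NORMAL) & (y_pred != SEIZURE)))
    fp = int(np.sum((y_true == NORMAL) & (y_pred == SEIZURE)))
    return ConfusionCounts(tp, fn, tn, fp)


def _mean_var(values):
    """Mean and population variance over the defined (non-None) entries."""
    vals = [v for v in values if v is not None]
    excluded = len(values) - len(vals)
    if not vals:
        return None, None, excluded
    arr = np.asarray(vals, dtype=np.float64)
    return float(arr.mean()), float(arr.var(ddof=0)), excluded


@dataclass
class ExperimentResult:
    per_subject: dict                 # subject_id -> Metrics
    mean: dict = field(default_factory=dict)
    variance: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def summarize(self):
        for name in METRIC_NAMES:
            m, v, ex = _mean_var(
                [getattr(met, name) for met in self.per_subject.values()])
            self.mean[name] = m
            self.variance[name] = v
            self.excluded[name] = ex
        return self


# ---------------------------------------------------------------------------
# cohort feature extraction
# ---------------------------------------------------------------------------

@dataclass
class CohortFeatures:
    """Per-session feature matrices for a synthetic cohort.

    ``sessions[subject_id]`` is a list of (X, y) with X of shape
    [n_epochs x (n_channels * n_features)], channel-major ordering of the
    canonical feature subset, y in {"seizure", "normal"}.
    """
    sessions: dict
    feature_names: list
    epoch_duration_s: float
    profiles: dict = field(default_factory=dict)

    def subjects(self):
        return list(self.sessions)

    def pooled(self, exclude_subject=None):
        Xs, ys = [], []
        for sid, sess in self.sessions.items():
            if sid == exclude_subject:
                continue
            for X, y in sess:
                Xs.append(X)
                ys.append(y)
        return np.vstack(Xs), np.concatenate(ys)


def extract_cohort_features(cohort, epoch_duration_s: float = 5.0,
                            feature_set="rce-rfe",
                            config: FeatureConfig | None = None,
                            balance_seed: int | None = None,
                            verbose: bool = False) -> CohortFeatures:
    """Generate every session of a synthetic cohort and extract features.

    ``cohort`` is the (profile, session specs) list from
    ``synthetic.make_cohort``.  Features use the named (or explicit)
    canonical subset.  Signals are generated, consumed and released one
    session at a time.
    """
    if isinstance(feature_set, str):
        feature_set = get_feature_set(feature_set)
    names = list(feature_set.members if hasattr(feature_set, "members")
                 else feature_set)
    sessions = {}
    profiles = {}
    for profile, specs in cohort:
        per_session = []
        for spec in specs:
            t0 = time.time()
            rec = generate_session(profile, spec)
            eps = epoch_recording(rec, epoch_duration_s)
            cfg = config or FeatureConfig()
            cfg = replace(cfg, dwd=replace(cfg.dwd, fs=rec.fs))
            X, y = extract_epoch_matrix(eps, names, cfg)
            per_session.append((X, y))
            if verbose:
                print(f"  {rec.session_id}: {X.shape[0]} epochs "
                      f"({(y == SEIZURE).sum()} ictal) "
                      f"in {time.time() - t0:.1f} s")
        sessions[profile.subject_id] = per_session
        profiles[profile.subject_id] = profile
    return CohortFeatures(sessions=sessions, feature_names=names,
                          epoch_duration_s=epoch_duration_s,
                          profiles=profiles)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass
class ExperimentProtocol:
    mode: str = "individual_loso"     # individual_loso | individual_m_sessions
    #                                 # | population_loso_subject
    epoch_duration_s: float = 5.0
    feature_set: str = "rce-rfe"
    classifier: TwoStageConfig = field(default_factory=TwoStageConfig)
    m_test_sessions: int = 1
    balance_ratio: float = 3.0
    max_split_combinations: int = 50
    seed: int = 0


def _train_test_vectors(train_sessions, ratio, seed):
    X = np.vstack([s[0] for s in train_sessions])
    y = np.concatenate([s[1] for s in train_sessions])
    seiz = [v for v, l in zip(X, y) if l == SEIZURE]
    norm = [v for v, l in zip(X, y) if l == NORMAL]
    if not seiz:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seiz, norm = balance_dataset(seiz, norm, ratio=ratio, seed=seed)
    Xb = np.vstack([np.asarray(seiz), np.asarray(norm)])
    yb = np.array([SEIZURE] * len(seiz) + [NORMAL] * len(norm), dtype=object)
    return Xb, yb


def _population_pool(features: CohortFeatures, exclude_subject, ratio, seed):
    Xs, ys = [], []
    for sid, sess in features.sessions.items():
        if sid == exclude_subject:
            continue
        Xs.extend(s[0] for s in sess)
        ys.extend(s[1] for s in sess)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    seiz = [v for v, l in zip(X, y) if l == SEIZURE]
    norm = [v for v, l in zip(X, y) if l == NORMAL]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seiz, norm = balance_dataset(seiz, norm, ratio=ratio, seed=seed)
    Xb = np.vstack([np.asarray(seiz), np.asarray(norm)])
    yb = np.array([SEIZURE] * len(seiz) + [NORMAL] * len(norm), dtype=object)
    return Xb, yb


def _evaluate_model(model, test_sessions):
    counts = ConfusionCounts(0, 0, 0, 0)
    for X, y in test_sessions:
        preds = [two_stage_classify(model, v).label for v in X]
        counts = counts + counts_from_predictions(y, preds)
    return counts


def _splits(n_sessions, m, cap, rng):
    combos = list(itertools.combinations(range(n_sessions), m))
    if cap is not None and len(combos) > cap:
        idx = rng.choice(len(combos), size=cap, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    return combos


def run_individual_protocol(features: CohortFeatures,
                            protocol: ExperimentProtocol | None = None
                            ) -> ExperimentResult:
    """Per-subject train/test over session splits; see module docstring."""
    protocol = protocol or ExperimentProtocol()
    m = 1 if protocol.mode == "individual_loso" else protocol.m_test_sessions
    rng = np.random.default_rng(protocol.seed)
    per_subject = {}
    for sid, sess in features.sessions.items():
        if len(sess) < 2:
            warnings.warn(f"subject {sid} has < 2 sessions; skipped")
            continue
        if m >= len(sess):
            raise ValueError(
                f"cannot hold out {m} of {len(sess)} sessions for {sid}")
        split_metrics = []
        pop_data = None
        if protocol.classifier.secondary_kind == "population_knn":
            pop_data = _population_pool(features, sid, protocol.balance_ratio,
                                        protocol.seed)
        for combo in _splits(len(sess), m, protocol.max_split_combinations,
                             rng):
            test = [sess[i] for i in combo]
            train = [sess[i] for i in range(len(sess)) if i not in combo]
            data = _train_test_vectors(train, protocol.balance_ratio,
                                       protocol.seed)
            if data is None:
                warnings.warn(f"subject {sid}: no seizure epochs in a "
                              "training split; split skipped")
                continue
            model = train_two_stage(
                data, pop_data, protocol.classifier, subject_id=sid,
                population_subjects=[s for s in features.sessions if s != sid],
            )
            split_metrics.append(compute_metrics(_evaluate_model(model, test)))
        if split_metrics:
            per_subject[sid] = _average_metrics(split_metrics)
    result = ExperimentResult(per_subject=per_subject,
                              config={"mode": protocol.mode, "m": m})
    return result.summarize()


def _average_metrics(metrics_list) -> Metrics:
    vals = {}
    for name in METRIC_NAMES:
        m, _, _ = _mean_var([getattr(met, name) for met in metrics_list])
        vals[name] = m
    return Metrics(**vals)


def run_population_protocol(features: CohortFeatures,
                            protocol: ExperimentProtocol | None = None
                            ) -> ExperimentResult:
    """Leave-one-subject-out evaluation of a population-trained model."""
    protocol = protocol or ExperimentProtocol(mode="population_loso_subject")
    subjects = features.subjects()
    if len(subjects) < 2:
        raise ValueError("population protocol requires >= 2 subjects")
    config = protocol.classifier
    if config.secondary_kind == "population_knn":
        # the primary already pools the population; unknowns fall back to
        # the conservative class
        config = replace(config, secondary_kind="assign_normal")
    per_subject = {}
    for sid in subjects:
        pool = _population_pool(features, sid, protocol.balance_ratio,
                                protocol.seed)
        model = train_two_stage(pool, None, config, subject_id=sid,
                                population_subjects=[])
        counts = _evaluate_model(model, features.sessions[sid])
        per_subject[sid] = compute_metrics(counts)
    result = ExperimentResult(per_subject=per_subject,
                              config={"mode": "population_loso_subject"})
    return result.summarize()


# ---------------------------------------------------------------------------
# sweeps and comparisons
# ---------------------------------------------------------------------------

def sweep_epoch_duration(cohort, durations, base_protocol=None,
                         feature_config=None, verbose=False):
    """Re-run the full pipeline per epoch duration; rows of (duration, mean
    metrics).  Expensive: re-epochs, re-extracts, re-trains everything."""
    base_protocol = base_protocol or ExperimentProtocol()
    rows = []
    for dur in durations:
        feats = extract_cohort_features(
            cohort, epoch_duration_s=dur,
            feature_set=base_protocol.feature_set,
            config=feature_config, verbose=verbose)
        res = run_individual_protocol(
            feats, replace(base_protocol, epoch_duration_s=dur))
        rows.append({"epoch_duration_s": dur, **res.mean})
    return rows


def compare_strategies(features: CohortFeatures, strategies=None,
                       neighbor_counts=(1,), protocol=None):
    """Cross-product of Unknown-resolution strategies x neighbor counts."""
    strategies = list(strategies or clf.RESOLUTION_STRATEGIES)
    protocol = protocol or ExperimentProtocol()
    rows = []
    for strategy in strategies:
        for k in neighbor_counts:
            cfg = replace(protocol.classifier,
                          secondary_kind=strategy,
                          rce=replace(protocol.classifier.rce, k=k))
            res = run_individual_protocol(
                features, replace(protocol, classifier=cfg))
            rows.append({"strategy": strategy, "k": k, **res.mean})
    return rows


def latency_report(epoch, feature_config=None, repeats=3):
    """Informational wall-clock of extraction with/without CD + classify."""
    from .features import extract_epoch_features, fit_quantizer, quantize

    cfg = feature_config or FeatureConfig()
    out = {}
    full = [nm for nm in CANONICAL_FEATURES]
    nocd = [nm for nm in CANONICAL_FEATURES if nm != "CD"]
    for tag, names in [("with_cd", full), ("without_cd", nocd)]:
        t0 = time.time()
        for _ in range(repeats):
            fv = extract_epoch_features(epoch, names, cfg)
        out[f"extract_{tag}_s"] = (time.time() - t0) / repeats
    X = np.vstack([fv.flat(), fv.flat() * 0.9])
    q = fit_quantizer(X)
    model = clf.knn_train(np.vstack([quantize(v, q) for v in X]),
                          np.array([SEIZURE, NORMAL], dtype=object))
    t0 = time.time()
    for _ in range(100):
        clf.knn_classify(model, quantize(fv.flat(), q))
    out["classify_s"] = (time.time() - t0) / 100
    return out
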