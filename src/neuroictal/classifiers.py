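"""Capacity-limited prototype classifiers emulating neuromorphic hardware.

The target hardware stores training examples in content-addressable
memory cells: at most 4096 examples per board, each at most 256 bytes,
with distances computed in parallel.  Two classifiers share that memory
model:

* **k-NN** memorizes training vectors verbatim (seizure class presented
  first so the capacity cut never starves the rare class) and classifies
  by majority vote among the k nearest stored templates.
* **RCE network** (Reduced Coulomb Energy / restricted Coulomb energy):
  each stored prototype carries an *influence field* (IF) — a hypersphere
  radius under the network metric (L1 on byte features).  Training
  shrinks opposite-class fields that cover a new vector and commits the
  vector as a new prototype only if no same-class field already covers
  it; iterative training repeats passes until the decision space is a
  fixed point.  A query outside every field is classified *Unknown*,
  which a second-stage (population-trained) classifier may resolve.

SVM (linear kernel, class-weighted) and a small MLP serve as software
baselines; their low-confidence predictions (probability < 0.8) can be
routed to a second stage the same way RCE routes Unknowns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .eeg_data import NORMAL, SEIZURE
from .features import NEUROMORPHIC_PATTERN_BYTES, QuantizationMap

UNKNOWN = "unknown"

DEFAULT_CAPACITY = 4096
PROBABILITY_THRESHOLD = 0.8


class ProtocolError(ValueError):
    """A train/test split violates the evaluation protocol."""


@dataclass
class Prototype:
    vector: np.ndarray
    label: str
    influence_radius: float
    active: bool = True


@dataclass
class RCEConfig:
    max_if: float | None = None      # default: 0.4 * (255 * n_features)
    min_if: float = 2.0
    k: int = 1
    capacity: int = DEFAULT_CAPACITY
    distance: str = "l1"
    max_training_iterations: int = 50

    def resolved_max_if(self, n_features: int) -> float:
        return self.max_if if self.max_if is not None else 0.4 * 255 * n_features


@dataclass
class KNNConfig:
    k: int = 1
    capacity: int = DEFAULT_CAPACITY
    distance: str = "l2"             # "l1" = hardware-emulation mode


@dataclass
class Prediction:
    label: str
    distance_to_nearest: float = float("nan")
    firing_count: int = 0
    probability: float | None = None


def _distances(stored: np.ndarray, query: np.ndarray, metric: str):
    q = np.asarray(query, dtype=np.float64)
    s = stored.astype(np.float64)
    if metric == "l1":
        return np.abs(s - q).sum(axis=1)
    if metric == "l2":
        return np.sqrt(((s - q) ** 2).sum(axis=1))
    raise ValueError(f"unknown distance metric {metric!r}")


def _check_pattern_budget(vectors: np.ndarray):
    if vectors.shape[1] > NEUROMORPHIC_PATTERN_BYTES:
        raise ValueError(
            f"pattern of {vectors.shape[1]} bytes exceeds the "
            f"{NEUROMORPHIC_PATTERN_BYTES}-byte example limit"
        )


def _majority(labels, distances):
    """Majority vote; ties resolve toward seizure (sensitivity-first)."""
    votes = {}
    for l in labels:
        votes[l] = votes.get(l, 0) + 1
    best = max(votes.values())
    winners = [l for l, v in votes.items() if v == best]
    if len(winners) == 1:
        return winners[0]
    return SEIZURE if SEIZURE in winners else sorted(winners)[0]


# ---------------------------------------------------------------------------
# k-NN with capacity emulation
# ---------------------------------------------------------------------------

@dataclass
class KNNModel:
    vectors: np.ndarray
    labels: np.ndarray
    config: KNNConfig
    n_dropped: int = 0
    quantizer: QuantizationMap | None = None

    @property
    def n_stored(self) -> int:
        return self.vectors.shape[0]


def knn_train(vectors, labels, config: KNNConfig | None = None) -> KNNModel:
    """Memorize vectors seizure-first, truncating at memory capacity."""
    config = config or KNNConfig()
    X = np.asarray(vectors)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty or non-rectangular training set")
    if y.shape[0] != X.shape[0]:
        raise ValueError("label/vector length mismatch")
    _check_pattern_budget(X)
    order = np.concatenate([np.flatnonzero(y == SEIZURE),
                            np.flatnonzero(y != SEIZURE)])
    kept = order[: config.capacity]
    dropped = order.size - kept.size
    if dropped:
        warnings.warn(f"k-NN memory full: dropped {dropped} trailing vectors")
    return KNNModel(vectors=X[kept].copy(), labels=y[kept].copy(),
                    config=config, n_dropped=dropped)


def knn_classify(model: KNNModel, query, k: int | None = None) -> Prediction:
    k = k if k is not None else model.config.k
    query = np.asarray(query)
    if query.shape[0] != model.vectors.shape[1]:
        raise ValueError("query length differs from stored vectors")
    if k > model.n_stored:
        warnings.warn(f"k={k} exceeds stored count {model.n_stored}; clamped")
        k = model.n_stored
    d = _distances(model.vectors, query, model.config.distance)
    idx = np.argsort(d, kind="stable")[:k]
    label = _majority(model.labels[idx], d[idx])
    return Prediction(label=label, distance_to_nearest=float(d[idx[0]]),
                      firing_count=k)


# ---------------------------------------------------------------------------
# RCE network
# ---------------------------------------------------------------------------

@dataclass
class RCEModel:
    vectors: np.ndarray              # committed prototype matrix
    labels: np.ndarray
    radii: np.ndarray
    config: RCEConfig
    n_features: int
    converged: bool = True
    iterations: int = 0
    n_dropped: int = 0
    quantizer: QuantizationMap | None = None

    @property
    def n_prototypes(self) -> int:
        return self.vectors.shape[0]

    def as_prototypes(self):
        return [Prototype(v, l, r) for v, l, r in
                zip(self.vectors, self.labels, self.radii)]


def _empty_rce(n_features: int, config: RCEConfig) -> RCEModel:
    return RCEModel(
        vectors=np.empty((0, n_features), dtype=np.int64),
        labels=np.empty(0, dtype=object),
        radii=np.empty(0, dtype=np.float64),
        config=config, n_features=n_features,
    )


def rce_train_pass(model: RCEModel, vectors, labels,
                   config: RCEConfig | None = None):
    """One presentation pass of the RCE adaptation rules.

    For each training vector v with label y, in order:

    1. every opposite-class prototype whose field covers v shrinks to
       ``max(min_if, d(v, p) - 1)`` (the smallest exclusion step in the
       integer byte-feature metric);
    2. if no same-class prototype covers v, v is committed as a new
       prototype with radius ``clamp(min_d_opposite - 1, min_if, max_if)``
       (``max_if`` when no opposite prototype exists), capacity allowing.

    Returns ``(model, changed)``; ``changed`` reports whether any shrink
    or commitment occurred, so iterative training can detect a fixed point.
    """
    config = config or model.config
    X = np.asarray(vectors)
    y = np.asarray(labels)
    _check_pattern_budget(X)
    nf = X.shape[1]
    max_if = config.resolved_max_if(nf)
    changed = False
    n_dropped = model.n_dropped

    # growable prototype buffers (vectorized inner loop)
    cap = max(config.capacity, model.n_prototypes)
    vecs = np.empty((cap, nf), dtype=np.int64)
    n = model.n_prototypes
    vecs[:n] = model.vectors
    labs = np.empty(cap, dtype=object)
    labs[:n] = model.labels
    radii = np.empty(cap, dtype=np.float64)
    radii[:n] = model.radii
    memory_full_warned = False

    for v, lab in zip(X, y):
        v = v.astype(np.int64)
        if n:
            d = _distances(vecs[:n], v, config.distance)
            same = labs[:n] == lab
            opp = ~same
            rn = radii[:n]
            covered_same = bool(np.any(d[same] <= rn[same]))
            # shrink covering opposite-class fields
            hit = opp & (d <= rn)
            if np.any(hit):
                new_r = np.maximum(config.min_if, d[hit] - 1.0)
                shrunk = new_r < rn[hit]
                if np.any(shrunk):
                    idx = np.flatnonzero(hit)[shrunk]
                    radii[idx] = new_r[shrunk]
                    changed = True
            min_d_opp = float(d[opp].min()) if np.any(opp) else None
        else:
            covered_same = False
            min_d_opp = None
        if not covered_same:
            if n >= config.capacity:
                n_dropped += 1
                if not memory_full_warned:
                    warnings.warn(
                        "RCE memory full: prototype(s) not committed",
                        stacklevel=2)
                    memory_full_warned = True
                continue
            if min_d_opp is None:
                r = max_if
            else:
                r = min(max(min_d_opp - 1.0, config.min_if), max_if)
            vecs[n] = v
            labs[n] = lab
            radii[n] = r
            n += 1
            changed = True

    new_model = RCEModel(
        vectors=vecs[:n].copy(), labels=labs[:n].copy(),
        radii=radii[:n].copy(),
        config=config, n_features=nf,
        converged=model.converged, iterations=model.iterations,
        n_dropped=n_dropped, quantizer=model.quantizer,
    )
    return new_model, changed


def rce_train_iterative(vectors, labels, config: RCEConfig | None = None
                        ) -> RCEModel:
    """Repeat full-set passes until a pass changes nothing (fixed point).

    Seizure vectors are presented first within every pass, mirroring the
    k-NN training order; presentation order matters because it shapes the
    decision space.
    """
    config = config or RCEConfig()
    X = np.asarray(vectors)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty or non-rectangular training set")
    order = np.concatenate([np.flatnonzero(y == SEIZURE),
                            np.flatnonzero(y != SEIZURE)])
    X, y = X[order], y[order]
    model = _empty_rce(X.shape[1], config)
    converged = False
    it = 0
    for it in range(1, config.max_training_iterations + 1):
        model, changed = rce_train_pass(model, X, y, config)
        if not changed:
            converged = True
            break
    model.converged = converged
    model.iterations = it
    if not converged:
        warnings.warn(
            f"RCE training did not converge in "
            f"{config.max_training_iterations} iterations")
    return model


def rce_classify(model: RCEModel, query, k: int | None = None) -> Prediction:
    """Classify by the k nearest *firing* prototypes; no firing -> Unknown."""
    k = k if k is not None else model.config.k
    query = np.asarray(query)
    if model.n_prototypes == 0:
        return Prediction(label=UNKNOWN)
    d = _distances(model.vectors, query, model.config.distance)
    firing = np.flatnonzero(d <= model.radii)
    if firing.size == 0:
        return Prediction(label=UNKNOWN,
                          distance_to_nearest=float(d.min()),
                          firing_count=0)
    df = d[firing]
    nearest = np.argsort(df, kind="stable")[: min(k, firing.size)]
    label = _majority(model.labels[firing][nearest], df[nearest])
    return Prediction(label=str(label),
                      distance_to_nearest=float(df.min()),
                      firing_count=int(firing.size))


def check_no_covered_conflicts(model: RCEModel, vectors, labels) -> bool:
    """True iff no training vector lies strictly inside an opposite-class
    influence field (the converged-RCE invariant for separated data)."""
    X = np.asarray(vectors)
    y = np.asarray(labels)
    for v, lab in zip(X, y):
        d = _distances(model.vectors, v, model.config.distance)
        for i in range(model.n_prototypes):
            if model.labels[i] != lab and d[i] < model.radii[i]:
                return False
    return True


# ---------------------------------------------------------------------------
# Unknown / low-confidence resolution and two-stage composition
# ---------------------------------------------------------------------------

RESOLUTION_STRATEGIES = ("assign_seizure", "assign_normal", "population_knn")


def resolve_unknown(prediction: Prediction, strategy: str,
                    secondary_model: KNNModel | None = None,
                    query=None) -> Prediction:
    """Resolve an Unknown prediction; non-Unknowns pass through unchanged."""
    if strategy not in RESOLUTION_STRATEGIES:
        raise ValueError(f"unknown resolution strategy {strategy!r}")
    if prediction.label != UNKNOWN:
        return prediction
    if strategy == "assign_seizure":
        return Prediction(label=SEIZURE,
                          distance_to_nearest=prediction.distance_to_nearest)
    if strategy == "assign_normal":
        return Prediction(label=NORMAL,
                          distance_to_nearest=prediction.distance_to_nearest)
    if secondary_model is None:
        raise ValueError("population_knn strategy requires a secondary model")
    if query is None:
        raise ValueError("population_knn strategy requires the query vector")
    return knn_classify(secondary_model, query, k=1)


# ---------------------------------------------------------------------------
# SVM / ANN baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineModel:
    kind: str
    estimator: object
    classes: np.ndarray
    n_features: int
    mean: np.ndarray
    scale: np.ndarray


def train_baseline(kind: str, X, y, seed: int = 0,
                   ann_input_width: int | None = None) -> BaselineModel:
    """Fit the linear-kernel SVM or the fixed-architecture MLP baseline.

    Features are standardized internally (these models, unlike the
    prototype networks, run on unquantized features).  The MLP has the
    fixed 210-70-4-2 architecture (21 channels x 10 features in), ReLU
    activations and the LBFGS solver; ``ann_input_width`` overrides the
    expected input width for non-default feature sets.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if kind == "svm":
        est = SVC(kernel="linear", class_weight="balanced", probability=True,
                  random_state=seed)
    elif kind == "ann":
        width = ann_input_width if ann_input_width is not None else 210
        if X.shape[1] != width:
            raise ValueError(
                f"feature width {X.shape[1]} does not match the configured "
                f"ANN input layer ({width} nodes)"
            )
        est = MLPClassifier(hidden_layer_sizes=(70, 4), activation="relu",
                            solver="lbfgs", max_iter=500, random_state=seed)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit((X - mean) / scale, y)
    return BaselineModel(kind=kind, estimator=est, classes=est.classes_,
                         n_features=X.shape[1], mean=mean, scale=scale)


def baseline_predict_proba(model: BaselineModel, x) -> tuple[str, float]:
    x = (np.asarray(x, dtype=np.float64).reshape(1, -1) - model.mean) / model.scale
    proba = model.estimator.predict_proba(x)[0]
    i = int(np.argmax(proba))
    return str(model.classes[i]), float(proba[i])


# ---------------------------------------------------------------------------
# two-stage composition
# ---------------------------------------------------------------------------

@dataclass
class TwoStageConfig:
    primary_kind: str = "rce"                 # rce | knn | svm | ann
    secondary_kind: str = "population_knn"    # population_knn | assign_*
    probability_threshold: float = PROBABILITY_THRESHOLD
    rce: RCEConfig = field(default_factory=RCEConfig)
    knn: KNNConfig = field(default_factory=KNNConfig)
    seed: int = 0


@dataclass
class TwoStageModel:
    config: TwoStageConfig
    primary: object
    primary_quantizer: QuantizationMap | None
    secondary: KNNModel | None
    secondary_quantizer: QuantizationMap | None
    subject_id: str = ""


def train_two_stage(primary_data, population_data, config: TwoStageConfig,
                    subject_id: str = "",
                    population_subjects=()) -> TwoStageModel:
    """Compose an individual primary model with a population second stage.

    ``primary_data`` and ``population_data`` are ``(X, y)`` tuples of raw
    (unquantized) feature vectors.  The population pool must not contain
    the primary subject (leave-one-subject-out hygiene).
    """
    from .features import fit_quantizer, quantize  # local: avoid cycle noise

    if subject_id and subject_id in set(population_subjects):
        raise ProtocolError(
            f"subject {subject_id!r} appears in its own population pool")
    Xp, yp = primary_data
    Xp = np.asarray(Xp, dtype=np.float64)
    yp = np.asarray(yp)

    primary_quant = None
    if config.primary_kind in ("rce", "knn"):
        primary_quant = fit_quantizer(Xp)
        Q = np.vstack([quantize(v, primary_quant) for v in Xp])
        if config.primary_kind == "rce":
            primary = rce_train_iterative(Q, yp, config.rce)
        else:
            primary = knn_train(Q, yp, config.knn)
    elif config.primary_kind in ("svm", "ann"):
        primary = train_baseline(config.primary_kind, Xp, yp, seed=config.seed,
                                 ann_input_width=Xp.shape[1])
    else:
        raise ValueError(f"unknown primary kind {config.primary_kind!r}")

    secondary = secondary_quant = None
    if config.secondary_kind == "population_knn":
        if population_data is None:
            raise ValueError("population_knn second stage requires data")
        Xs, ys = population_data
        Xs = np.asarray(Xs, dtype=np.float64)
        secondary_quant = fit_quantizer(Xs)
        Qs = np.vstack([quantize(v, secondary_quant) for v in Xs])
        secondary = knn_train(Qs, np.asarray(ys), KNNConfig(k=1))
    return TwoStageModel(config=config, primary=primary,
                         primary_quantizer=primary_quant,
                         secondary=secondary,
                         secondary_quantizer=secondary_quant,
                         subject_id=subject_id)


def two_stage_classify(model: TwoStageModel, query) -> Prediction:
    """Classify one raw feature vector through the two-stage system."""
    from .features import quantize

    cfg = model.config
    query = np.asarray(query, dtype=np.float64)

    def secondary_predict():
        q = quantize(query, model.secondary_quantizer)
        return knn_classify(model.secondary, q, k=1)

    if cfg.primary_kind in ("rce", "knn"):
        q = quantize(query, model.primary_quantizer)
        if cfg.primary_kind == "rce":
            pred = rce_classify(model.primary, q)
            if pred.label != UNKNOWN:
                return pred
            if cfg.secondary_kind == "population_knn":
                return secondary_predict()
            return resolve_unknown(pred, cfg.secondary_kind)
        return knn_classify(model.primary, q)

    label, proba = baseline_predict_proba(model.primary, query)
    if proba >= cfg.probability_threshold:
        return Prediction(label=label, probability=proba)
    if cfg.secondary_kind == "population_knn":
        return secondary_predict()
    if cfg.secondary_kind == "assign_seizure":
        return Prediction(label=SEIZURE, probability=proba)
    if cfg.secondary_kind == "assign_normal":
        return Prediction(label=NORMAL, probability=proba)
    return Prediction(label=label, probability=proba)


# ---------------------------------------------------------------------------
# serialization (prototype models)
# ---------------------------------------------------------------------------

def save_prototype_model(model, path: str):
    """Persist a KNN/RCE model + quantizer to a single .npz container."""
    common = dict(
        schema=np.str_("neuroictal-prototype-v1"),
        kind=np.str_("rce" if isinstance(model, RCEModel) else "knn"),
        vectors=model.vectors, labels=model.labels.astype("U16"),
    )
    if isinstance(model, RCEModel):
        common.update(radii=model.radii,
                      config=np.array([model.config.resolved_max_if(model.n_features),
                                       model.config.min_if, model.config.k,
                                       model.config.capacity]),
                      converged=np.bool_(model.converged))
    else:
        common.update(config=np.array([model.config.k, model.config.capacity]),
                      distance=np.str_(model.config.distance))
    if model.quantizer is not None:
        common.update(q_mins=model.quantizer.mins, q_maxs=model.quantizer.maxs)
    np.savez(path, **common)


def load_prototype_model(path: str):
    with np.load(path, allow_pickle=False) as z:
        if str(z.get("schema", "")) != "neuroictal-prototype-v1":
            raise ValueError("not a neuroictal prototype-model container")
        quant = None
        if "q_mins" in z:
            quant = QuantizationMap(z["q_mins"], z["q_maxs"])
        kind = str(z["kind"])
        if kind == "rce":
            max_if, min_if, k, capacity = z["config"]
            return RCEModel(
                vectors=z["vectors"], labels=z["labels"].astype(object),
                radii=z["radii"],
                config=RCEConfig(max_if=float(max_if), min_if=float(min_if),
                                 k=int(k), capacity=int(capacity)),
                n_features=z["vectors"].shape[1],
                converged=bool(z["converged"]), quantizer=quant,
            )
        k, capacity = z["config"]
        return KNNModel(
            vectors=z["vectors"], labels=z["labels"].astype(object),
            config=KNNConfig(k=int(k), capacity=int(capacity),
                             distance=str(z["distance"])),
            quantizer=quant,
        )
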