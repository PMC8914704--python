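import numpy as np
import pytest

from neuroictal import (NORMAL, SEIZURE, UNKNOWN, KNNConfig, RCEConfig,
                        TwoStageConfig, baseline_predict_proba, knn_classify,
                        knn_train, rce_classify, rce_train_iterative,
                        rce_train_pass, resolve_unknown, train_baseline,
                        train_two_stage, two_stage_classify)
from neuroictal.classifiers import (ProtocolError, check_no_covered_conflicts,
                                    load_prototype_model,
                                    save_prototype_model, _empty_rce)


def obj(labels):
    return np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# independent RCE reference: plain-python simulation of the adaptation rules
# ---------------------------------------------------------------------------

def rce_reference(X, y, min_if, max_if, max_iters=50):
    """Step-by-step simulation: shrink covering opposite fields to
    max(min_if, d-1); commit uncovered vectors with radius
    clamp(min_d_opposite - 1, min_if, max_if); iterate to fixed point.
    Presentation order: seizure vectors first, as trained."""
    order = [i for i, l in enumerate(y) if l == SEIZURE] + \
            [i for i, l in enumerate(y) if l != SEIZURE]
    X = [np.asarray(X[i], dtype=float) for i in order]
    y = [y[i] for i in order]
    protos = []          # [vector, label, radius]
    for _ in range(max_iters):
        changed = False
        for v, lab in zip(X, y):
            covered_same = False
            min_d_opp = None
            for p in protos:
                d = float(np.abs(v - p[0]).sum())
                if p[1] == lab:
                    if d <= p[2]:
                        covered_same = True
                else:
                    if min_d_opp is None or d < min_d_opp:
                        min_d_opp = d
                    if d <= p[2]:
                        new_r = max(min_if, d - 1.0)
                        if new_r < p[2]:
                            p[2] = new_r
                            changed = True
            if not covered_same:
                r = max_if if min_d_opp is None else \
                    min(max(min_d_opp - 1.0, min_if), max_if)
                protos.append([v.copy(), lab, r])
                changed = True
        if not changed:
            break
    return protos


class TestKNN:
    def test_capacity_truncation_seizure_first(self, rng):
        X = rng.integers(0, 256, size=(6000, 16))
        y = obj([SEIZURE] * 3000 + [NORMAL] * 3000)
        with pytest.warns(UserWarning, match="memory full"):
            m = knn_train(X, y, KNNConfig(capacity=4096))
        assert m.n_stored == 4096
        assert int((m.labels == SEIZURE).sum()) == 3000
        assert int((m.labels == NORMAL).sum()) == 1096
        # normal vectors kept in presentation order
        assert np.array_equal(m.vectors[3000], X[3000])

    def test_stored_query_returns_own_label(self, rng):
        X = rng.integers(0, 256, size=(20, 8))
        y = obj([SEIZURE] * 10 + [NORMAL] * 10)
        m = knn_train(X, y)
        p = knn_classify(m, X[12], k=1)
        assert p.label == NORMAL and p.distance_to_nearest == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        X = rng.integers(0, 256, size=(500, 10))
        y = obj([SEIZURE if b else NORMAL for b in rng.integers(0, 2, 500)])
        m = knn_train(X, y, KNNConfig(k=3, distance="l2"))
        for _ in range(100):
            q = rng.integers(0, 256, size=10)
            d = np.sqrt(((X.astype(float) - q) ** 2).sum(axis=1))
            idx = np.argsort(d, kind="stable")[:3]
            votes = list(y[idx])
            expect = SEIZURE if votes.count(SEIZURE) * 2 >= 3 + 1 else \
                (NORMAL if votes.count(NORMAL) > votes.count(SEIZURE)
                 else SEIZURE)
            assert knn_classify(m, q).label == expect

    def test_tie_breaks_toward_seizure(self):
        X = np.array([[0, 0], [10, 10]])
        m = knn_train(X, obj([NORMAL, SEIZURE]))
        assert knn_classify(m, np.array([5, 5]), k=2).label == SEIZURE

    def test_k_clamped_with_warning(self, rng):
        m = knn_train(rng.integers(0, 256, size=(3, 4)),
                      obj([SEIZURE, NORMAL, NORMAL]))
        with pytest.warns(UserWarning, match="clamped"):
            p = knn_classify(m, np.zeros(4), k=10)
        assert p.label in (SEIZURE, NORMAL)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            knn_train(np.empty((0, 4)), obj([]))


class TestRCETraining:
    def test_first_vector_gets_max_if(self):
        m = rce_train_iterative(np.array([[10, 10]]), obj([SEIZURE]),
                                RCEConfig(max_if=100))
        assert m.n_prototypes == 1
        assert m.radii[0] == 100.0

    def test_identical_vectors_conflicting_labels(self):
        m = rce_train_iterative(np.array([[5, 5], [5, 5]]),
                                obj([SEIZURE, NORMAL]),
                                RCEConfig(max_if=100, min_if=2))
        assert m.n_prototypes == 2
        assert np.array_equal(m.radii, [2.0, 2.0])
        assert m.converged

    def test_hand_frozen_four_point_trace(self):
        # seizure-first order: (10,10)S r<-50; (12,10)S covered, no commit;
        # (30,10)N shrinks S to 19, commits at 19; (40,10)N covered by N.
        # pass 2: (12,10)S shrinks N to 17; pass 3: no change.
        X = np.array([[10, 10], [30, 10], [12, 10], [40, 10]])
        y = obj([SEIZURE, NORMAL, SEIZURE, NORMAL])
        m = rce_train_iterative(X, y, RCEConfig(max_if=50, min_if=2))
        assert m.converged and m.iterations == 3
        assert m.n_prototypes == 2
        assert np.array_equal(m.vectors, [[10, 10], [30, 10]])
        assert list(m.labels) == [SEIZURE, NORMAL]
        assert np.array_equal(m.radii, [19.0, 17.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_twenty_point_toy_matches_reference_simulation(self, seed):
        r = np.random.default_rng(seed)
        X = r.integers(0, 256, size=(20, 2))
        y = obj([SEIZURE if b else NORMAL for b in r.integers(0, 2, 20)])
        cfg = RCEConfig(max_if=120, min_if=2)
        m = rce_train_iterative(X, y, cfg)
        ref = rce_reference(X, y, min_if=2, max_if=120)
        assert m.n_prototypes == len(ref)
        for i, (v, lab, rad) in enumerate(ref):
            assert np.array_equal(m.vectors[i], v)
            assert m.labels[i] == lab
            assert m.radii[i] == rad

    def test_converged_model_is_fixed_point(self, rng):
        X = rng.integers(0, 256, size=(40, 6))
        y = obj([SEIZURE if b else NORMAL for b in rng.integers(0, 2, 40)])
        m = rce_train_iterative(X, y, RCEConfig(max_if=200, min_if=2))
        assert m.converged
        order = np.concatenate([np.flatnonzero(y == SEIZURE),
                                np.flatnonzero(y == NORMAL)])
        m2, changed = rce_train_pass(m, X[order], y[order])
        assert not changed
        assert np.array_equal(m2.vectors, m.vectors)
        assert np.array_equal(m2.radii, m.radii)

    def test_no_training_vector_inside_opposite_field(self, rng):
        # separated clusters: invariant must hold exactly after convergence
        X = np.vstack([rng.integers(0, 60, size=(15, 4)),
                       rng.integers(180, 255, size=(15, 4))])
        y = obj([SEIZURE] * 15 + [NORMAL] * 15)
        m = rce_train_iterative(X, y, RCEConfig(max_if=500, min_if=2))
        assert m.converged
        assert check_no_covered_conflicts(m, X, y)

    def test_separated_clusters_converge_in_two_passes(self, rng):
        X = np.vstack([rng.integers(0, 20, size=(10, 3)),
                       rng.integers(200, 255, size=(10, 3))])
        y = obj([SEIZURE] * 10 + [NORMAL] * 10)
        m = rce_train_iterative(X, y, RCEConfig(max_if=30))
        assert m.converged and m.iterations == 2

    def test_rce_stores_no_more_than_knn(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            X = r.integers(0, 256, size=(300, 8))
            y = obj([SEIZURE if b else NORMAL
                     for b in r.integers(0, 2, 300)])
            m = rce_train_iterative(X, y, RCEConfig())
            k = knn_train(X, y)
            assert m.n_prototypes <= k.n_stored

    def test_capacity_overflow_drops_with_warning(self, rng):
        X = rng.integers(0, 256, size=(30, 4))
        y = obj([SEIZURE] * 30)
        with pytest.warns(UserWarning, match="memory full"):
            m = rce_train_iterative(X, y, RCEConfig(max_if=3, min_if=1,
                                                    capacity=10))
        assert m.n_prototypes == 10
        assert m.n_dropped > 0

    def test_oversized_pattern_rejected(self, rng):
        X = rng.integers(0, 256, size=(2, 300))
        with pytest.raises(ValueError, match="256-byte"):
            rce_train_iterative(X, obj([SEIZURE, NORMAL]))


class TestRCEClassification:
    @pytest.fixture
    def model(self):
        X = np.array([[10, 10], [200, 200], [60, 10]])
        y = obj([SEIZURE, NORMAL, NORMAL])
        return rce_train_iterative(X, y, RCEConfig(max_if=60, min_if=2))

    def test_far_query_is_unknown(self, model):
        p = rce_classify(model, np.array([128, 128]))
        assert p.label == UNKNOWN and p.firing_count == 0

    def test_inside_single_field(self, model):
        p = rce_classify(model, np.array([12, 10]))
        assert p.label == SEIZURE and p.firing_count >= 1

    def test_overlap_resolved_by_nearest(self, model):
        # (30,10): d=20 to seizure prototype, d=30 to the normal one at
        # (60,10); both fire at radius >= their distance -> nearest wins
        d_s = abs(30 - 10)
        d_n = abs(30 - 60)
        assert d_s <= model.radii[list(model.labels).index(SEIZURE)]
        p = rce_classify(model, np.array([30, 10]))
        assert p.label == SEIZURE
        assert p.distance_to_nearest == d_s < d_n


class TestResolution:
    def test_assign_strategies(self):
        from neuroictal.classifiers import Prediction
        unk = Prediction(label=UNKNOWN)
        assert resolve_unknown(unk, "assign_normal").label == NORMAL
        assert resolve_unknown(unk, "assign_seizure").label == SEIZURE

    def test_non_unknown_passes_through(self):
        from neuroictal.classifiers import Prediction
        p = Prediction(label=SEIZURE, distance_to_nearest=3.0)
        assert resolve_unknown(p, "assign_normal") is p

    def test_population_knn_resolution(self, rng):
        from neuroictal.classifiers import Prediction
        X = rng.integers(0, 256, size=(10, 4))
        m = knn_train(X, obj([SEIZURE] * 5 + [NORMAL] * 5))
        p = resolve_unknown(Prediction(label=UNKNOWN), "population_knn",
                            secondary_model=m, query=X[7])
        assert p.label == NORMAL

    def test_population_knn_requires_secondary(self):
        from neuroictal.classifiers import Prediction
        with pytest.raises(ValueError, match="secondary"):
            resolve_unknown(Prediction(label=UNKNOWN), "population_knn")


class TestBaselines:
    def test_linearly_separable_svm(self, rng):
        X = np.vstack([rng.normal(0, 0.2, size=(30, 5)),
                       rng.normal(5, 0.2, size=(30, 5))])
        y = obj([SEIZURE] * 30 + [NORMAL] * 30)
        m = train_baseline("svm", X, y, seed=0)
        preds = [baseline_predict_proba(m, x)[0] for x in X]
        assert preds == list(y)

    def test_ann_input_width_enforced(self, rng):
        X = rng.normal(size=(20, 30))
        y = obj([SEIZURE] * 10 + [NORMAL] * 10)
        with pytest.raises(ValueError, match="210"):
            train_baseline("ann", X, y, seed=0)
        m = train_baseline("ann", X, y, seed=0, ann_input_width=30)
        assert m.n_features == 30

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 6))
        y = obj([SEIZURE if b else NORMAL for b in rng.integers(0, 2, 40)])
        a = train_baseline("svm", X, y, seed=5)
        b = train_baseline("svm", X, y, seed=5)
        q = rng.normal(size=6)
        assert baseline_predict_proba(a, q) == baseline_predict_proba(b, q)


class TestTwoStage:
    def _data(self, rng, n=40, spread=0.3):
        X = np.vstack([rng.normal(0, spread, size=(n // 2, 4)),
                       rng.normal(4, spread, size=(n // 2, 4))])
        y = obj([SEIZURE] * (n // 2) + [NORMAL] * (n // 2))
        return X, y

    def test_confident_primary_never_uses_secondary(self, rng):
        X, y = self._data(rng)
        model = train_two_stage((X, y), (X, y), TwoStageConfig(),
                                subject_id="A", population_subjects=["B"])
        for v in X:
            assert two_stage_classify(model, v).label in (SEIZURE, NORMAL)

    def test_all_unknown_equals_population_knn(self, rng):
        X, y = self._data(rng)
        # primary trained on a far-away region -> every query is Unknown
        Xfar = X + 1000.0
        cfg = TwoStageConfig(rce=RCEConfig(max_if=5, min_if=1))
        model = train_two_stage((Xfar, y), (X, y), cfg,
                                subject_id="A", population_subjects=["B"])
        from neuroictal.features import quantize
        from neuroictal import knn_classify as kc
        for v in X[::5]:
            got = two_stage_classify(model, v).label
            q = quantize(v, model.secondary_quantizer)
            assert got == kc(model.secondary, q, k=1).label

    def test_subject_overlap_rejected(self, rng):
        X, y = self._data(rng)
        with pytest.raises(ProtocolError):
            train_two_stage((X, y), (X, y), TwoStageConfig(),
                            subject_id="A", population_subjects=["A", "B"])

    def test_svm_primary_threshold_routing(self, rng):
        X, y = self._data(rng, spread=2.5)   # overlapping -> low confidence
        cfg = TwoStageConfig(primary_kind="svm", probability_threshold=0.8)
        model = train_two_stage((X, y), (X, y), cfg,
                                subject_id="A", population_subjects=["B"])
        routed = 0
        for v in X:
            _, proba = baseline_predict_proba(model.primary, v)
            if proba < 0.8:
                routed += 1
        assert routed > 0   # some low-confidence examples exist to route
        for v in X:
            assert two_stage_classify(model, v).label in (SEIZURE, NORMAL)


class TestSerialization:
    def test_rce_round_trip(self, tmp_path, rng):
        X = rng.integers(0, 256, size=(30, 6))
        y = obj([SEIZURE if b else NORMAL for b in rng.integers(0, 2, 30)])
        m = rce_train_iterative(X, y, RCEConfig(max_if=300, min_if=2))
        p = tmp_path / "m.npz"
        save_prototype_model(m, str(p))
        back = load_prototype_model(str(p))
        assert np.array_equal(back.vectors, m.vectors)
        assert np.array_equal(back.radii, m.radii)
        assert list(back.labels) == list(m.labels)
        q = rng.integers(0, 256, size=6)
        assert rce_classify(back, q).label == rce_classify(m, q).label

    def test_knn_round_trip(self, tmp_path, rng):
        X = rng.integers(0, 256, size=(10, 4))
        y = obj([SEIZURE] * 5 + [NORMAL] * 5)
        m = knn_train(X, y, KNNConfig(k=3, distance="l1"))
        p = tmp_path / "k.npz"
        save_prototype_model(m, str(p))
        back = load_prototype_model(str(p))
        assert back.config.distance == "l1"
        q = rng.integers(0, 256, size=4)
        assert knn_classify(back, q).label == knn_classify(m, q).label
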