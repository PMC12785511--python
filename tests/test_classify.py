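import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cecbbb._sfa import learn_breakpoints, sfa_words, window_fourier_features
from cecbbb.classify import (
    BlendedEnsembleClassifier,
    BossVSClassifier,
    DtwKnnClassifier,
    LabelScheme,
    blend,
    classification_metrics,
    default_omega_grid,
    dtw_distance,
    knn_predict_proba,
    label_from_logbb,
    preprocess,
    preprocess_dataset,
    tune_weight,
)
from cecbbb.exceptions import ConfigError, InvalidInputError
from oracles import dtw_bruteforce, sfa_word_counts_naive


class TestPreprocess:
    def test_hand_z_normalization(self):
        out = preprocess([1, 2, 3], trim_n=0)
        assert out.signal == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-5)

    def test_idempotent_on_normalized_trace(self, rng):
        x = rng.normal(size=300)
        z = (x - x.mean()) / x.std()
        out = preprocess(z, trim_n=0)
        assert out.signal == pytest.approx(z, abs=1e-12)

    def test_trim_and_non_numeric_removal(self):
        raw = list(range(200))
        raw[150] = "NA"
        out = preprocess(raw, trim_n=100)
        assert len(out.signal) == 99
        assert 150 not in out.index
        assert out.index[0] == 100

    def test_too_short_trace(self):
        with pytest.raises(InvalidInputError, match="too short"):
            preprocess([1.0, 2.0, 3.0], trim_n=100)

    def test_constant_trace_yields_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="all-constant"):
            out = preprocess([5.0] * 50, trim_n=10)
        assert np.all(out.signal == 0.0)

    def test_mixed_lengths_truncated_to_minimum(self, rng):
        traces = [rng.normal(size=n) for n in (300, 280, 320)]
        X = preprocess_dataset(traces, trim_n=100)
        assert X.shape == (3, 180)


class TestLabels:
    @pytest.mark.parametrize(
        "logbb,expected",
        [(1.30, 2), (0.00, 1), (-1.30, 0), (-1.0, 0), (0.3, 2), (0.2999, 1)],
    )
    def test_cutoffs(self, logbb, expected):
        assert label_from_logbb(logbb) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            label_from_logbb(float("nan"))

    def test_scheme_ordering_enforced(self):
        with pytest.raises(InvalidInputError):
            LabelScheme(low_cut=0.5, high_cut=0.3)


class TestDtw:
    def test_identity(self, rng):
        x = rng.normal(size=50)
        for radius in (0, 3, None):
            assert dtw_distance(x, x, radius) == 0.0

    def test_small_example_equals_enumeration(self):
        assert dtw_distance([0, 1, 2], [0, 2, 2]) == pytest.approx(1.0, abs=1e-12)
        assert dtw_bruteforce([0, 1, 2], [0, 2, 2]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(60):
            n, m = rng.integers(2, 7, size=2)
            x, y = rng.normal(size=n), rng.normal(size=m)
            r = int(rng.integers(max(abs(n - m), 1), 8))
            assert dtw_distance(x, y, r) == pytest.approx(
                dtw_bruteforce(x, y, r), rel=1e-10, abs=1e-10
            )

    def test_band_constrained_at_least_unconstrained(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        free = dtw_distance(x, y, None)
        prev = np.inf
        for r in (1, 3, 10, 30):
            d = dtw_distance(x, y, r)
            assert d >= free - 1e-12
            assert d <= prev + 1e-12  # wider band never increases the cost
            prev = d
        assert dtw_distance(x, y, 30) == pytest.approx(free, abs=1e-12)

    def test_guards(self):
        with pytest.raises(InvalidInputError):
            dtw_distance([], [1.0])
        with pytest.raises(InvalidInputError, match="infeasible"):
            dtw_distance([1.0] * 10, [1.0] * 3, 2)


class TestKnn:
    def test_exact_match_k1(self, rng):
        X = rng.normal(size=(5, 20))
        y = np.array([0, 1, 2, 1, 0])
        proba = knn_predict_proba(X, y, X[2], n_neighbors=1)
        assert proba == pytest.approx([0, 0, 1])

    def test_vote_counting(self):
        train = np.array([[0.0, 0, 0], [0.1, 0, 0], [0, 0.1, 0], [10, 10, 10.0]])
        y = np.array([2, 2, 1, 0])
        proba = knn_predict_proba(train, y, [0.0, 0.0, 0.0], n_neighbors=3)
        assert proba == pytest.approx([0, 1 / 3, 2 / 3])

    def test_exclude_self_omits_own_copy(self):
        train = np.array([[0.0, 0, 0], [0.0, 0, 0], [5, 5, 5.0]])
        y = np.array([0, 1, 2])
        with_self = knn_predict_proba(train, y, [0.0, 0, 0], n_neighbors=1)
        assert with_self == pytest.approx([1, 0, 0])
        loo = knn_predict_proba(train, y, [0.0, 0, 0], n_neighbors=1,
                                exclude_self=True)
        # own stored copy skipped; the duplicate (class 1) remains a neighbor
        assert loo == pytest.approx([0, 1, 0])

    def test_k_exceeding_neighbors(self, rng):
        X = rng.normal(size=(3, 10))
        y = np.array([0, 1, 2])
        with pytest.raises(ConfigError, match="n_neighbors"):
            knn_predict_proba(X, y, X[0], n_neighbors=5)

    def test_loo_excludes_each_sample(self, rng):
        X = np.repeat(rng.normal(size=(3, 15)), 2, axis=0)
        y = np.array([0, 0, 1, 1, 2, 2])
        est = DtwKnnClassifier(n_neighbors=1, band_radius=5).fit(X, y)
        proba = est.loo_predict_proba()
        # each sample's nearest remaining neighbor is its duplicate
        assert proba == pytest.approx(np.eye(3)[y])

    def test_distance_weighting_favors_closer_class(self):
        train = np.array([[0.0] * 8, [1.0] * 8, [1.05] * 8])
        y = np.array([0, 1, 1])
        q = np.array([0.2] * 8)
        uni = knn_predict_proba(train, y, q, n_neighbors=3, weights="uniform")
        dist = knn_predict_proba(train, y, q, n_neighbors=3, weights="distance")
        assert dist[0] > uni[0]


class TestSfa:
    def test_constant_series_collapses_to_one_word(self):
        bps = np.zeros((4, 2))
        words = sfa_words(np.ones(50), 16, 4, bps)
        assert len(words) == 1

    def test_word_counts_match_naive_oracle(self, rng):
        series = rng.normal(size=20)
        feats = window_fourier_features(series, 8, 4)
        bps = learn_breakpoints(feats, 3)
        words = sfa_words(series, 8, 4, bps)
        counts = {}
        for w in words:
            counts[w] = counts.get(w, 0) + 1
        assert counts == sfa_word_counts_naive(series, 8, 4, bps)

    def test_amplitude_scale_invariance(self, rng):
        series = rng.normal(size=64)
        feats = window_fourier_features(series, 16, 6)
        bps = learn_breakpoints(feats, 4)
        assert sfa_words(series, 16, 6, bps) == sfa_words(5.0 * series, 16, 6, bps)

    def test_window_larger_than_series(self):
        with pytest.raises(ConfigError):
            window_fourier_features(np.ones(10), 16, 4)


def sinusoid_set(rng, n_per_class=6, length=128):
    """Two classes with disjoint dominant frequencies."""
    t = np.arange(length)
    X, y = [], []
    for ci, freq in enumerate((4, 8)):
        for _ in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            X.append(np.sin(2 * np.pi * freq * t / length + phase)
                     + 0.05 * rng.normal(size=length))
            y.append(ci)
    return np.array(X), np.array(y)


class TestBossVS:
    def test_separable_frequencies_classified(self, rng):
        X, y = sinusoid_set(rng)
        est = BossVSClassifier(window_size=32, word_length=4, n_bins=3).fit(X, y)
        assert np.array_equal(est.predict(X), y)

    def test_refit_is_deterministic(self, rng):
        X, y = sinusoid_set(rng)
        a = BossVSClassifier(window_size=32, word_length=4, n_bins=3).fit(X, y)
        b = BossVSClassifier(window_size=32, word_length=4, n_bins=3).fit(X, y)
        assert np.array_equal(a.breakpoints_, b.breakpoints_)
        assert np.array_equal(a.tfidf_, b.tfidf_)

    def test_idf_penalizes_class_shared_words(self, rng):
        X, y = sinusoid_set(rng)
        est = BossVSClassifier(window_size=32, word_length=4, n_bins=3).fit(X, y)
        df = (est.tfidf_ > 0).sum(axis=0)
        assert est.idf_ == pytest.approx(np.log1p(est.classes_.size / df))
        # a word occurring in every class gets the minimal possible weight
        assert np.all(est.idf_ >= np.log1p(1.0) - 1e-12)
        if (df == est.classes_.size).any() and (df == 1).any():
            assert est.idf_[df == est.classes_.size].max() < est.idf_[df == 1].min()

    def test_probabilities_sum_to_one(self, rng):
        X, y = sinusoid_set(rng)
        est = BossVSClassifier(window_size=32, word_length=4, n_bins=3).fit(X, y)
        proba = est.predict_proba(rng.normal(size=(50, 128)))
        assert proba.sum(axis=1) == pytest.approx(np.ones(50), abs=1e-9)
        assert np.all(proba >= 0)

    def test_missing_requested_class_rejected(self, rng):
        X, y = sinusoid_set(rng)
        with pytest.raises(InvalidInputError, match="lacks class"):
            BossVSClassifier(window_size=32).fit(X, y, classes=[0, 1, 2])

    def test_config_guards(self, rng):
        X, y = sinusoid_set(rng)
        with pytest.raises(ConfigError):
            BossVSClassifier(window_size=256).fit(X, y)
        with pytest.raises(ConfigError):
            BossVSClassifier(window_size=8, word_length=12).fit(X, y)


class TestBlend:
    def test_endpoints(self, rng):
        p1 = rng.dirichlet(np.ones(3), size=10)
        p2 = rng.dirichlet(np.ones(3), size=10)
        assert np.array_equal(blend(p1, p2, 1.0), p1)
        assert np.array_equal(blend(p1, p2, 0.0), p2)

    def test_arithmetic_example(self):
        out = blend([1, 0, 0], [0, 0.5, 0.5], 0.05)
        assert out == pytest.approx([0.05, 0.475, 0.475], abs=1e-12)

    @given(omega=st.floats(0.0, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_convexity_preserves_normalization(self, omega):
        rng = np.random.default_rng(0)
        p1 = rng.dirichlet(np.ones(4), size=5)
        p2 = rng.dirichlet(np.ones(4), size=5)
        out = blend(p1, p2, omega)
        assert out.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-9)

    def test_mismatched_label_sets(self):
        with pytest.raises(InvalidInputError, match="shapes"):
            blend(np.ones((2, 3)) / 3, np.ones((2, 2)) / 2, 0.5)


class TestTuneWeight:
    def test_dominant_knn_component_wins(self, rng):
        """With a perfect k-NN and a random BOSSVS, the chosen blend is
        perfect and leans on the k-NN side (any weight past 0.5 is perfect,
        so the tie-break settles on the smallest such weight)."""
        y = np.array([0, 1, 2] * 10)
        perfect = np.eye(3)[y]
        random = rng.dirichlet(np.ones(3), size=30)
        omega = tune_weight(perfect, random, y)
        pred = np.argmax(blend(perfect, random, omega), axis=1)
        assert np.array_equal(pred, y)
        assert np.argmax(blend(perfect, random, 0.0), axis=1).tolist() != y.tolist()

    def test_identical_components_tie_break_to_zero(self, rng):
        y = np.array([0, 1, 2] * 5)
        p = rng.dirichlet(np.ones(3), size=15)
        assert tune_weight(p, p.copy(), y) == 0.0

    def test_mid_grid_blend_found_by_exhaustive_check(self):
        """Only a mixed blend resolves both samples; exhaustive grid search
        confirms the selected weight is the smallest perfect one."""
        y = np.array([0, 1])
        p_knn = np.array([[1.0, 0.0], [0.5, 0.5]])
        p_boss = np.array([[0.4, 0.6], [0.0, 1.0]])
        omega = tune_weight(p_knn, p_boss, y)
        from sklearn.metrics import f1_score

        scores = {
            w: f1_score(
                y, np.argmax(blend(p_knn, p_boss, w), axis=1), average="weighted"
            )
            for w in default_omega_grid()
        }
        best = max(scores.values())
        assert scores[omega] == best
        assert omega == min(w for w, s in scores.items() if s == best)
        assert 0.0 < omega < 1.0

    def test_empty_grid(self):
        with pytest.raises(ConfigError):
            tune_weight(np.ones((2, 2)), np.ones((2, 2)), [0, 1], grid=np.array([]))


class TestEnsembleEstimator:
    @pytest.mark.parametrize("omega", [0.0, 1.0])
    def test_endpoint_reproduces_base(self, small_traces, omega):
        X, y, _ = small_traces
        ens = BlendedEnsembleClassifier(
            knn=DtwKnnClassifier(n_neighbors=3, band_radius=5),
            bossvs=BossVSClassifier(window_size=32, word_length=4, n_bins=3),
            omega=omega,
        ).fit(X, y)
        base = ens.knn_ if omega == 1.0 else ens.bossvs_
        assert np.array_equal(ens.predict_proba(X), base.predict_proba(X))
        assert np.array_equal(ens.predict(X), base.predict(X))


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 0])
        proba = np.eye(3)[y]
        m = classification_metrics(y, y, proba, classes=[0, 1, 2])
        for key in ("accuracy", "balanced_accuracy", "f1_weighted",
                    "precision_weighted", "recall_weighted"):
            assert m[key] == 1.0
        assert all(r["auc"] == 1.0 for r in m["roc"].values())

    def test_hand_computed_example(self):
        m = classification_metrics([0, 1, 2, 2], [0, 2, 2, 2])
        assert m["accuracy"] == 0.75
        assert m["balanced_accuracy"] == pytest.approx(2 / 3)
        assert m["f1_weighted"] == pytest.approx(0.65)
        assert m["confusion_matrix"].sum() == 4

    def test_single_class_truth(self):
        with pytest.warns(UserWarning, match="ROC undefined"):
            m = classification_metrics(
                [1, 1, 1], [1, 1, 0], np.full((3, 3), 1 / 3), classes=[0, 1, 2]
            )
        assert m["balanced_accuracy"] == pytest.approx(2 / 3)  # recall of class 1

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            classification_metrics([0, 1], [0])
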