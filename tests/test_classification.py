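"""Fisher LDA oracles and the cross-session resampling protocol."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from fdbci import (
    FilterConfig,
    FisherLDA,
    SyntheticConfig,
    TrialSet,
    WindowSpec,
    generate_study,
    lda_fit,
    lda_predict,
    resampled_accuracy,
)
from fdbci.classification import (
    InsufficientTrialsError,
    ResamplingResult,
    stratified_subset_indices,
)


def _two_clouds(rng, n_per_class=200, sep=3.0, d=2):
    mu = np.zeros(d)
    mu[0] = sep
    x0 = rng.standard_normal((n_per_class, d)) - mu
    x1 = rng.standard_normal((n_per_class, d)) + mu
    X = np.vstack([x0, x1])
    y = np.repeat([0, 1], n_per_class)
    return X, y


class TestFisherLDA:
    def test_separable_clouds_near_bayes_accuracy(self):
        rng = np.random.default_rng(61)
        Xtr, ytr = _two_clouds(rng)
        Xte, yte = _two_clouds(rng)
        model = FisherLDA().fit(Xtr, ytr)
        assert np.mean(model.predict(Xte) == yte) >= 0.99

    def test_random_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(62)
        X = rng.standard_normal((400, 2))
        y = rng.integers(0, 2, size=400)
        Xte = rng.standard_normal((200, 2))
        yte = rng.integers(0, 2, size=200)
        model = FisherLDA().fit(X, y)
        assert abs(np.mean(model.predict(Xte) == yte) - 0.5) <= 0.1

    def test_training_accuracy_perfect_when_separable(self):
        rng = np.random.default_rng(63)
        X, y = _two_clouds(rng, n_per_class=50, sep=5.0)
        model = lda_fit(X, y)
        assert np.mean(lda_predict(model, X) == y) == 1.0

    def test_singular_covariance_takes_ridge_path(self):
        rng = np.random.default_rng(64)
        X, y = _two_clouds(rng, n_per_class=50)
        X = np.hstack([X, X[:, :1]])  # duplicated column -> singular pooled cov
        model = FisherLDA().fit(X, y)
        assert model.ridge_used_ > 0
        assert np.all(np.isfinite(model.coef_))

    def test_tie_on_decision_plane_goes_to_negative_class(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        model = FisherLDA().fit(X, y)
        assert model.decision_function(np.array([[0.0]]))[0] == 0.0
        assert model.predict(np.array([[0.0]]))[0] == 0

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(65)
        X, y = _two_clouds(rng, n_per_class=20)
        model = FisherLDA().fit(X, y)
        with pytest.raises(ValueError, match="expected shape"):
            model.predict(rng.standard_normal((5, 3)))

    def test_underdetermined_fit_rejected(self):
        rng = np.random.default_rng(66)
        X = rng.standard_normal((10, 12))
        y = np.arange(10) % 2
        with pytest.raises(InsufficientTrialsError, match="n=10 <= d=12"):
            FisherLDA().fit(X, y)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(67)
        with pytest.raises(ValueError, match="two classes"):
            FisherLDA().fit(rng.standard_normal((10, 2)), np.zeros(10))

    def test_accuracy_invariant_under_affine_feature_maps(self):
        rng = np.random.default_rng(68)
        Xtr, ytr = _two_clouds(rng, n_per_class=80, sep=1.0, d=4)
        Xte, yte = _two_clouds(rng, n_per_class=80, sep=1.0, d=4)
        base = FisherLDA().fit(Xtr, ytr).predict(Xte)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)  # well-conditioned, invertible
        c = rng.standard_normal(4)
        mapped = FisherLDA().fit(Xtr @ A + c, ytr).predict(Xte @ A + c)
        assert np.array_equal(base, mapped)

    def test_agrees_with_sklearn_reference(self):
        rng = np.random.default_rng(69)
        Xtr, ytr = _two_clouds(rng, n_per_class=100, sep=1.0, d=5)
        Xte, yte = _two_clouds(rng, n_per_class=100, sep=1.0, d=5)
        ours = FisherLDA().fit(Xtr, ytr)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(Xtr, ytr)
        agree = np.mean(ours.predict(Xte) == ref.predict(Xte))
        assert agree >= 0.99


class TestResamplingProtocol:
    def test_stratified_floor_rule(self):
        labels = np.repeat([0, 1], 72)
        rng = np.random.default_rng(71)
        idx = stratified_subset_indices(labels, 0.7, rng)
        assert len(idx) == 100  # floor(0.7 * 72) = 50 per class
        assert len(set(idx.tolist())) == 100
        assert int((labels[idx] == 0).sum()) == int((labels[idx] == 1).sum()) == 50

    def test_same_seed_reproduces_accuracy_vector(self, small_study):
        day1, day2 = small_study
        kw = dict(window=WindowSpec(1.0, 0.5), seed=5)
        a = resampled_accuracy(day1, day2, "higuchi", FilterConfig(8, 10), **kw)
        b = resampled_accuracy(day1, day2, "higuchi", FilterConfig(8, 10), **kw)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert a.reps == 30 and 0.0 <= a.mean <= 1.0

    def test_same_session_pair_rejected(self, small_study):
        day1, _ = small_study
        with pytest.raises(ValueError, match="different sessions"):
            resampled_accuracy(day1, day1, "higuchi", FilterConfig(8, 10))

    def test_subset_below_dimension_rejected(self):
        cfg = SyntheticConfig(n_channels=8, trials_per_class_per_session=4,
                              trial_seconds=2.0, erd_channels=(1,), seed=73)
        day1, day2 = generate_study(cfg)
        with pytest.raises(InsufficientTrialsError, match="n > d"):
            resampled_accuracy(day1, day2, "ar", FilterConfig(8, 10),
                               WindowSpec(1.0, 0.5))

    def test_total_separation_yields_perfect_repetitions(self):
        # class-1 rhythm fully suppressed at high amplitude: FD separates totally
        cfg = SyntheticConfig(n_channels=6, trials_per_class_per_session=24,
                              trial_seconds=2.0, erd_channels=(0, 1, 2, 3, 4, 5),
                              erd_depth=1.0, osc_amplitude=5.0, seed=74)
        day1, day2 = generate_study(cfg)
        res = resampled_accuracy(day1, day2, "higuchi", FilterConfig(8, 10),
                                 WindowSpec(1.0, 0.5), seed=3)
        assert np.all(res.accuracies == 1.0)

    def test_label_permutation_gives_chance_level(self):
        accs = []
        for s in range(20):
            cfg = SyntheticConfig(n_channels=6, trials_per_class_per_session=18,
                                  trial_seconds=2.0, erd_channels=(1, 3), seed=s)
            day1, day2 = generate_study(cfg)
            rng = np.random.default_rng(1000 + s)
            d1p = TrialSet(day1.data, rng.permutation(day1.labels), "day1", day1.fs)
            d2p = TrialSet(day2.data, rng.permutation(day2.labels), "day2", day2.fs)
            accs.append(resampled_accuracy(d1p, d2p, "higuchi", FilterConfig(8, 10),
                                           WindowSpec(1.0, 0.5), seed=s).mean)
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ResamplingResult(accuracies=np.array([0.5, 1.5]), technique="higuchi",
                             config=FilterConfig(8, 10), seed=0)
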