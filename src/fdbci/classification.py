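"""Two-class Fisher linear discriminant and the cross-session resampling protocol.

The classifier is Fisher's discriminant: ``w`` proportional to
``S_pooled^-1 (mu_1 - mu_0)`` with the decision threshold at the projected
midpoint of the class means.  Robustness to between-day nonstationarity is
measured by training on one session and testing on the other, repeated 30
times on stratified random 70% subsets drawn independently from each
session — so every repetition sees a different train/test realization and
the spread of the 30 accuracies feeds the rank-based statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, ClassifierMixin

from .dataio import TrialSet
from .features import FeatureExtractor, FeatureMatrix
from .preprocessing import FilterConfig, WindowSpec, butter_gain

__all__ = [
    "FisherLDA",
    "InsufficientTrialsError",
    "ResamplingResult",
    "lda_fit",
    "lda_predict",
    "resampled_accuracy",
    "CrossSessionEvaluator",
    "stratified_subset_indices",
]


class InsufficientTrialsError(ValueError):
    """Raised when a training set has no more trials than feature dimensions."""


class FisherLDA(BaseEstimator, ClassifierMixin):
    """Fisher's two-class linear discriminant.

    ``w`` solves ``S_pooled w = mu_1 - mu_0`` (pooled within-class
    covariance); the bias puts the decision threshold at the projected
    midpoint of the class means.  If the pooled covariance is numerically
    singular, a ridge ``lambda = 1e-6 tr(S)/d`` is added (once) to restore
    solvability.  Ties on the decision plane go to the negative-side class
    (``classes_[0]``) — a fixed, documented rule.
    """

    def __init__(self, ridge_scale: float = 1e-6):
        self.ridge_scale = ridge_scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D; got shape {X.shape}")
        if y.shape[0] != X.shape[0]:
            raise ValueError(f"y length {y.shape[0]} != n_samples {X.shape[0]}")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"exactly two classes required; found {classes.tolist()}")
        n, d = X.shape
        if n <= d:
            raise InsufficientTrialsError(
                f"training needs more trials than feature dimensions (n={n} <= d={d}); "
                "the 70% subset size is chosen to respect this minimum"
            )
        x0, x1 = X[y == classes[0]], X[y == classes[1]]
        mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
        n0, n1 = x0.shape[0], x1.shape[0]
        s0 = np.cov(x0, rowvar=False, ddof=1) if n0 > 1 else np.zeros((d, d))
        s1 = np.cov(x1, rowvar=False, ddof=1) if n1 > 1 else np.zeros((d, d))
        pooled = ((n0 - 1) * s0 + (n1 - 1) * s1) / max(n0 + n1 - 2, 1)
        pooled = np.atleast_2d(pooled)
        delta = mu1 - mu0
        try:
            w = cho_solve(cho_factor(pooled), delta)
            self.ridge_used_ = 0.0
        except np.linalg.LinAlgError:
            lam = self.ridge_scale * np.trace(pooled) / d
            if lam <= 0:
                lam = self.ridge_scale
            w = cho_solve(cho_factor(pooled + lam * np.eye(d)), delta)
            self.ridge_used_ = float(lam)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError("non-finite discriminant weights")
        self.classes_ = classes
        self.coef_ = w
        self.intercept_ = float(-w @ (mu0 + mu1) / 2.0)
        self.means_ = np.stack([mu0, mu1])
        self.n_features_in_ = d
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected shape (*, {self.n_features_in_}); got {X.shape}"
            )
        return X @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        # strict inequality: points exactly on the plane fall to classes_[0]
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


def lda_fit(train: FeatureMatrix | np.ndarray, labels: np.ndarray) -> FisherLDA:
    """Fit Fisher's discriminant to a feature matrix."""
    X = train.values if isinstance(train, FeatureMatrix) else train
    return FisherLDA().fit(X, labels)


def lda_predict(model: FisherLDA, test: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predict class labels (ties on the plane go to the negative-side class)."""
    X = test.values if isinstance(test, FeatureMatrix) else test
    return model.predict(X)


# ---------------------------------------------------------------------------
# cross-session resampled evaluation
# ---------------------------------------------------------------------------


@dataclass
class ResamplingResult:
    """The per-repetition accuracies of one (band, technique) evaluation."""

    accuracies: np.ndarray
    technique: str
    config: FilterConfig
    seed: int
    frac: float = 0.7

    def __post_init__(self):
        self.accuracies = np.asarray(self.accuracies, dtype=np.float64)
        if self.accuracies.ndim != 1 or self.accuracies.size < 1:
            raise ValueError("accuracies must be a non-empty 1-D array")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def reps(self) -> int:
        return self.accuracies.size

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.reps > 1 else 0.0


def stratified_subset_indices(labels: np.ndarray, frac: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-stratified subset: ``floor(frac * n_class)`` per class."""
    labels = np.asarray(labels)
    picks = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        take = int(np.floor(frac * members.size))
        if take < 1:
            raise ValueError(
                f"subset fraction {frac} leaves no trials for class {cls} "
                f"(class size {members.size})"
            )
        picks.append(rng.choice(members, size=take, replace=False))
    return np.concatenate(picks)


class CrossSessionEvaluator:
    """Shared engine for evaluating many filter configurations on one session pair.

    The spectra of both sessions' trials are computed once; each candidate
    band then costs one inverse FFT plus feature extraction (float32
    throughout the engine), and each of the ``reps`` repetitions refits the
    discriminant on a fresh stratified subset.  Used by
    :func:`resampled_accuracy` for a single band and by the grid search for
    hundreds.
    """

    def __init__(self, train_ts: TrialSet, test_ts: TrialSet, technique: str,
                 window: WindowSpec = WindowSpec(), *, k_max: int = 8, ar_order: int = 2):
        if train_ts.session_id == test_ts.session_id:
            raise ValueError(
                "cross-session evaluation needs two different sessions; both are "
                f"{train_ts.session_id!r}"
            )
        if train_ts.fs != test_ts.fs:
            raise ValueError(f"sampling rates differ: {train_ts.fs} vs {test_ts.fs}")
        if train_ts.n_samples != test_ts.n_samples:
            raise ValueError(
                f"trial lengths differ: {train_ts.n_samples} vs {test_ts.n_samples}"
            )
        if train_ts.n_channels != test_ts.n_channels:
            raise ValueError(
                f"channel counts differ: {train_ts.n_channels} vs {test_ts.n_channels}"
            )
        train_ts.require_two_classes()
        test_ts.require_two_classes()
        if not np.array_equal(train_ts.classes, test_ts.classes):
            raise ValueError("train and test sessions carry different class labels")

        self.fs = float(train_ts.fs)
        self.n_samples = train_ts.n_samples
        self.window = window
        self.window_slice = window.sample_slice(self.fs, self.n_samples)
        self.extractor = FeatureExtractor(technique=technique, k_max=k_max,
                                          ar_order=ar_order).fit()
        self.technique = technique
        self.labels_train = train_ts.labels
        self.labels_test = test_ts.labels
        self.freqs = np.fft.rfftfreq(self.n_samples, 1.0 / self.fs)
        self._spectra = {}
        for key, ts in (("train", train_ts), ("test", test_ts)):
            x = ts.data.astype(np.float32)
            x -= x.mean(axis=-1, keepdims=True)
            self._spectra[key] = (rfft(x, axis=-1), ts.n_channels)

    def features(self, cfg: FilterConfig) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrices (train, test) for one band, all trials."""
        from scipy.fft import irfft

        gain = butter_gain(self.freqs, cfg.f_low, cfg.f_high, self.fs).astype(np.float32)
        out = []
        for key in ("train", "test"):
            spectra, n_channels = self._spectra[key]
            filtered = irfft(spectra * gain, n=self.n_samples, axis=-1)
            windowed = filtered[..., self.window_slice]
            out.append(self.extractor.transform(windowed))
        return out[0], out[1]

    def evaluate(self, cfg: FilterConfig, *, reps: int = 30, frac: float = 0.7,
                 seed: int = 0) -> ResamplingResult:
        """30-repetition stratified resampled accuracy for one band.

        Repetition ``r`` draws its subsets from substream ``(seed, r)``:
        train-session class subsets first, then test-session ones, each
        ``floor(frac * n_class)`` trials without replacement.  Bit
        reproducible given ``seed``.
        """
        feats_train, feats_test = self.features(cfg)
        d = feats_train.shape[1]
        n_sub = sum(
            int(np.floor(frac * np.sum(self.labels_train == c)))
            for c in np.unique(self.labels_train)
        )
        if n_sub <= d:
            raise InsufficientTrialsError(
                f"70%-style subsets of {n_sub} trials cannot train a {d}-dimensional "
                "discriminant; the subset fraction must keep n > d"
            )
        accuracies = np.empty(reps)
        for r in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
            idx_train = stratified_subset_indices(self.labels_train, frac, rng)
            idx_test = stratified_subset_indices(self.labels_test, frac, rng)
            model = FisherLDA().fit(feats_train[idx_train], self.labels_train[idx_train])
            pred = model.predict(feats_test[idx_test])
            accuracies[r] = np.mean(pred == self.labels_test[idx_test])
        return ResamplingResult(accuracies=accuracies, technique=self.technique,
                                config=cfg, seed=seed, frac=frac)


def resampled_accuracy(
    train_ts: TrialSet,
    test_ts: TrialSet,
    technique: str,
    cfg: FilterConfig,
    window: WindowSpec = WindowSpec(),
    *,
    reps: int = 30,
    frac: float = 0.7,
    seed: int = 0,
    k_max: int = 8,
    ar_order: int = 2,
) -> ResamplingResult:
    """Cross-session resampled accuracy of one (band, technique) pair.

    Filters both sessions with ``cfg``, extracts the analysis window and the
    per-trial features, then repeats ``reps`` times: draw stratified
    ``frac`` subsets independently from the training and testing session,
    fit the linear discriminant on the former and score accuracy on the
    latter.
    """
    engine = CrossSessionEvaluator(train_ts, test_ts, technique, window,
                                   k_max=k_max, ar_order=ar_order)
    return engine.evaluate(cfg, reps=reps, frac=frac, seed=seed)
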