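"""Bayesian decoding of stimulus category from trial responses.

Trial-averaged inferred spike rates are well described by exponential
distributions, so the decoder models p(r | c) for each neuron and category
as an exponential density whose mean is the training-set sample mean (the
maximum-likelihood estimate).  With Bayes' theorem,

    p(c | r) = p(r | c) p(c) / p(r),

the prediction is the category with the higher posterior; responses of a
neuron group are combined under conditional independence.  Performance is
the fraction of correctly predicted test trials under a 70/30
train/test split, repeated over random splits and random neuron subsets,
with a label-shuffle control run under the identical protocol.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

_MEAN_FLOOR_FRAC = 1e-6


class ExponentialNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive-Bayes classifier with exponential class-conditional likelihoods.

    Parameters
    ----------
    priors : {"empirical", "uniform"}, default "empirical"
        Class priors p(c): training-set category frequencies, or uniform.

    Attributes
    ----------
    classes_ : ndarray of shape (n_classes,)
    means_ : ndarray of shape (n_classes, n_features)
        Per-class exponential mean parameters (sample means, floored at a
        tiny positive fraction of the grand mean so densities stay proper).
    class_prior_ : ndarray of shape (n_classes,)
    n_ties_ : int
        Number of exact posterior ties seen by predict (broken toward the
        first class, and counted for reproducibility).
    """

    def __init__(self, priors: str = "empirical"):
        self.priors = priors

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        if np.any(X < 0):
            raise ValueError("responses must be non-negative rates")
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two categories in training data")
        if counts.min() < 2:
            raise ValueError("need at least 2 training trials per category")
        grand = X.mean()
        floor = _MEAN_FLOOR_FRAC * (grand if grand > 0 else 1.0)
        self.means_ = np.vstack(
            [np.clip(X[y == c].mean(axis=0), floor, None) for c in self.classes_]
        )
        if self.priors == "uniform":
            self.class_prior_ = np.full(len(self.classes_), 1 / len(self.classes_))
        elif self.priors == "empirical":
            self.class_prior_ = counts / counts.sum()
        else:
            raise ValueError(f"unknown priors mode {self.priors!r}")
        self.n_features_in_ = X.shape[1]
        self.n_ties_ = 0
        return self

    def _joint_log_likelihood(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.any(X < 0):
            raise ValueError("responses must be non-negative rates")
        # log prior + sum_j [-log mu_cj - r_j / mu_cj]
        return np.log(self.class_prior_) + (
            -np.log(self.means_).sum(axis=1) - X @ (1.0 / self.means_).T
        )

    def predict_proba(self, X):
        check_is_fitted(self, "means_")
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        check_is_fitted(self, "means_")
        jll = self._joint_log_likelihood(X)
        ties = np.isclose(jll[:, 0:1], jll[:, 1:]).any(axis=1)
        self.n_ties_ += int(ties.sum())
        # argmax takes the first (lowest-sorted) class on exact ties
        return self.classes_[np.argmax(jll, axis=1)]


def fit_exponential_likelihoods(X, y, priors: str = "empirical") -> ExponentialNaiveBayes:
    """Fit the exponential naive-Bayes decoder (thin wrapper)."""
    return ExponentialNaiveBayes(priors=priors).fit(X, y)


def decode_trial(model: ExponentialNaiveBayes, response) -> tuple[object, np.ndarray]:
    """Predicted category and posterior for a single trial response vector."""
    response = np.atleast_2d(np.asarray(response, dtype=float))
    return model.predict(response)[0], model.predict_proba(response)[0]


def decision_boundary(mu1: float, mu2: float, prior1: float = 0.5) -> float:
    """Response at which the two single-neuron class posteriors are equal.

    For exponential likelihoods with means mu1 < mu2 and priors (p, 1-p):
    r* = [ln(mu2/mu1) + ln(prior1/(1-prior1))] / (1/mu1 - 1/mu2).
    """
    if mu1 == mu2:
        raise ValueError("equal means have no decision boundary")
    return (np.log(mu2 / mu1) + np.log(prior1 / (1 - prior1))) / (1 / mu1 - 1 / mu2)


def _stratified_split(y, test_frac, rng):
    train, test = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_test = max(int(round(test_frac * len(idx))), 1)
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.concatenate(train), np.concatenate(test)


def cross_validated_performance(
    rates: np.ndarray,
    labels: np.ndarray,
    group_sizes=range(1, 11),
    test_frac: float = 0.3,
    n_repeats: int = 100,
    seed: int | np.random.Generator = 0,
    priors: str = "empirical",
) -> dict[int, float]:
    """Decoding performance by neuron-group size.

    For every group size, each repeat draws a random neuron subset (without
    replacement), a stratified 70/30 train/test split, fits the decoder on
    the training trials and scores the fraction of correctly predicted test
    trials; values are averaged over repeats.  Group sizes exceeding the
    population are skipped.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    labels = np.asarray(labels)
    n_neurons = rates.shape[0]
    out: dict[int, float] = {}
    for size in group_sizes:
        if size > n_neurons:
            continue
        scores = np.empty(n_repeats)
        for r in range(n_repeats):
            neurons = rng.choice(n_neurons, size=size, replace=False)
            train, test = _stratified_split(labels, test_frac, rng)
            model = ExponentialNaiveBayes(priors=priors).fit(
                rates[np.ix_(neurons, train)].T, labels[train]
            )
            pred = model.predict(rates[np.ix_(neurons, test)].T)
            scores[r] = np.mean(pred == labels[test])
        out[size] = float(scores.mean())
    return out


def shuffle_control(
    rates: np.ndarray,
    labels: np.ndarray,
    group_sizes=range(1, 11),
    test_frac: float = 0.3,
    n_repeats: int = 100,
    seed: int | np.random.Generator = 0,
    priors: str = "empirical",
) -> dict[int, float]:
    """Same protocol with category labels shuffled across trials per repeat."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = np.asarray(labels)
    out: dict[int, float] = {}
    for size in group_sizes:
        perm = rng.permutation(len(labels))
        res = cross_validated_performance(
            rates,
            labels[perm],
            group_sizes=[size],
            test_frac=test_frac,
            n_repeats=n_repeats,
            seed=rng,
            priors=priors,
        )
        out.update(res)
    return out
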