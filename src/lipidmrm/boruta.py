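"""Boruta-style all-relevant feature selection with shadow features.

Each iteration appends a shuffled ("shadow") copy of every still-undecided
feature, fits a random forest, and scores a *hit* for every real feature
whose importance exceeds the best shadow importance. After each iteration a
two-sided binomial test on the accumulated hit counts (null: hitting is a
fair coin) confirms features that hit significantly more than half the time
and rejects (and drops) features that hit significantly less; whatever is
unresolved when the iteration budget runs out stays *tentative*.

Importance defaults to the Z-score of the per-tree mean-decrease-in-impurity
(mean over trees divided by its SD): normalizing by the between-tree spread
penalizes features whose apparent importance is unstable, which is what
keeps chance in-sample associations from being confirmed. The raw forest
MDI is available via ``importance="impurity"``. The procedure is
deterministic under a fixed ``random_state``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binomtest
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

__all__ = ["BorutaSelector"]

CONFIRMED, TENTATIVE, REJECTED = "confirmed", "tentative", "rejected"


class BorutaSelector(BaseEstimator):
    """All-relevant feature selection against shuffled shadow probes.

    Parameters
    ----------
    n_estimators : int
        Trees per forest fit.
    max_iter : int
        Iteration budget; unresolved features end tentative.
    alpha : float
        Two-sided binomial significance level for confirm/reject calls.
    bonferroni : bool
        Divide ``alpha`` by the number of features when testing (the
        multiplicity adjustment the reference implementation applies by
        default); without it, chance in-sample associations are confirmed
        far too often.
    random_state : int
        Seeds both the shadow shuffles and the forests.

    Attributes
    ----------
    decisions_ : ndarray of str, shape (n_features,)
        "confirmed" / "rejected" / "tentative" per feature.
    support_ : ndarray of bool
        True for confirmed features.
    hits_ : ndarray of int
        Hit count per feature over the iterations it stayed active.
    n_iter_ : int
        Iterations actually run.
    """

    def __init__(self, n_estimators: int = 100, max_iter: int = 100,
                 alpha: float = 0.01, bonferroni: bool = True,
                 importance: str = "z_score", random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.alpha = alpha
        self.bonferroni = bonferroni
        self.importance = importance
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be samples x features")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2 or counts.min() < 2:
            raise ValueError("need two groups with >= 2 samples each")
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        active = np.ones(p, dtype=bool)
        hits = np.zeros(p, dtype=int)
        trials = np.zeros(p, dtype=int)
        decisions = np.array([TENTATIVE] * p, dtype=object)
        level = self.alpha / p if self.bonferroni else self.alpha
        it = 0
        while it < self.max_iter and active.any():
            it += 1
            idx = np.flatnonzero(active)
            # keep >= 5 shadow probes even when few features remain active,
            # so the max-shadow reference stays a meaningful null
            reps = int(np.ceil(5 / idx.size)) if idx.size < 5 else 1
            shadows = np.tile(X[:, idx], (1, reps)).copy()
            for j in range(shadows.shape[1]):
                rng.shuffle(shadows[:, j])
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                random_state=int(rng.integers(2**31)),
            )
            forest.fit(np.hstack([X[:, idx], shadows]), y)
            if self.importance == "impurity":
                imp = forest.feature_importances_
            elif self.importance == "z_score":
                per_tree = np.array(
                    [t.feature_importances_ for t in forest.estimators_]
                )
                sd = per_tree.std(axis=0, ddof=1)
                imp = np.where(sd > 0, per_tree.mean(axis=0) / np.where(sd > 0, sd, 1.0), 0.0)
            else:
                raise ValueError(f"unknown importance {self.importance!r}")
            real_imp, shadow_imp = imp[: idx.size], imp[idx.size:]
            threshold = shadow_imp.max()
            hits[idx[real_imp > threshold]] += 1
            trials[idx] += 1
            for j in idx:
                res = binomtest(int(hits[j]), int(trials[j]), 0.5)
                if res.pvalue < level:
                    if hits[j] > trials[j] / 2:
                        decisions[j] = CONFIRMED
                    else:
                        decisions[j] = REJECTED
                    active[j] = False
        self.decisions_ = decisions.astype(str)
        self.support_ = self.decisions_ == CONFIRMED
        self.hits_ = hits
        self.trials_ = trials
        self.n_iter_ = it
        self.n_features_in_ = p
        return self

    def get_support(self, indices: bool = False):
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        return np.asarray(X)[:, self.support_]
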