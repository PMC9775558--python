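"""AUC-trained composite score as a scikit-learn estimator.

:class:`CompositeScoreClassifier` fits the free weights of one of the
composite scores (s0..s4) by maximizing the exact rank AUC of the score on
the training set with the Nelder-Mead simplex.  Exact AUC is piecewise
constant in the weights, so the fit multi-starts (the zero vector plus
random initializations scaled to the feature spread, each with a widened
initial simplex) and can optionally polish the best point against a
sigmoid-smoothed AUC surrogate; the polished point is kept only if it
improves the exact AUC, and the reported training AUC is always exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import SCORE_TERMS
from .metrics import auc, max_mcc

#: column order accepted for plain arrays passed as X
FEATURE_ORDER = ("E_over_N", "lnS1", "lnlp", "P")


def _as_feature_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in FEATURE_ORDER if c not in X.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_ORDER):
        raise ValueError(
            f"array X must have {len(FEATURE_ORDER)} columns in order {FEATURE_ORDER}"
        )
    return pd.DataFrame(arr, columns=list(FEATURE_ORDER))


class CompositeScoreClassifier(ClassifierMixin, BaseEstimator):
    """Composite LLPS score with AUC-optimized weights.

    Parameters
    ----------
    score:
        Name of the composite score to train (``"s0"`` .. ``"s4"``).
    n_restarts:
        Number of random restarts in addition to the zero start.
    max_iter:
        Nelder-Mead iteration cap per start.
    xatol, fatol:
        Simplex convergence tolerances.
    polish:
        If True, refine the best start against a sigmoid-smoothed AUC and
        keep the result only when the exact AUC improves.
    polish_temperature:
        Smoothing temperature of the surrogate, as a fraction of the score
        standard deviation at the point being polished.
    max_pairs:
        Cap on the number of positive-negative pairs evaluated by the
        surrogate (subsampled with the estimator's RNG beyond this).
    random_state:
        Seed for restart initializations and surrogate subsampling.

    Attributes
    ----------
    weights_ : dict mapping feature name to fitted coefficient
    train_auc_ : exact AUC of the fitted score on the training data
    threshold_ : decision threshold (maximizes MCC on the training data)
    train_max_mcc_ : MCC at ``threshold_`` on the training data
    classes_ : array([0, 1])
    """

    def __init__(
        self,
        score: str = "s4",
        n_restarts: int = 5,
        max_iter: int = 400,
        xatol: float = 1e-3,
        fatol: float = 1e-5,
        polish: bool = True,
        polish_temperature: float = 0.05,
        max_pairs: int = 2_000_000,
        random_state: int | None = None,
    ):
        self.score = score
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.xatol = xatol
        self.fatol = fatol
        self.polish = polish
        self.polish_temperature = polish_temperature
        self.max_pairs = max_pairs
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _design(self, X):
        free, fixed = SCORE_TERMS[self.score]
        df = _as_feature_frame(X)
        F = df.loc[:, list(free)].to_numpy(dtype=float)
        base = df.loc[:, fixed].to_numpy(dtype=float)
        return F, base, free

    def _soft_auc(self, s, y, tau):
        pos = s[y == 1]
        neg = s[y == 0]
        if pos.size * neg.size > self.max_pairs:
            rng = self._rng_
            take = int(np.sqrt(self.max_pairs))
            pos = rng.choice(pos, size=min(pos.size, take), replace=False)
            neg = rng.choice(neg, size=min(neg.size, take), replace=False)
        diff = pos[:, None] - neg[None, :]
        return float(np.mean(expit(diff / tau)))

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        if self.score not in SCORE_TERMS:
            raise ValueError(f"unknown score {self.score!r}")
        F, base, free = self._design(X)
        y = np.asarray(y).astype(int).ravel()
        if y.shape[0] != F.shape[0]:
            raise ValueError("X and y have different lengths")
        if set(np.unique(y)) - {0, 1} or len(np.unique(y)) < 2:
            raise ValueError("y must contain both classes, coded 0/1")
        rng = np.random.default_rng(self.random_state)
        self._rng_ = rng

        # weight scale: unit weight change should move the score by about
        # one score-unit, so scale each axis by the feature spread
        spread = F.std(axis=0)
        spread[spread == 0] = 1.0
        scale = 1.0 / spread

        def objective(w):
            return -auc(base + F @ w, y)

        def run_nm(w0):
            step = np.where(w0 == 0, scale, 0.5 * np.abs(w0) + 0.1 * scale)
            simplex = np.vstack([w0, w0 + np.diag(step)])
            res = minimize(
                objective,
                w0,
                method="Nelder-Mead",
                options={
                    "initial_simplex": simplex,
                    "maxiter": self.max_iter,
                    "xatol": self.xatol,
                    "fatol": self.fatol,
                    "adaptive": True,
                },
            )
            return res.x, -res.fun

        nw = len(free)
        starts = [np.zeros(nw)]
        for _ in range(self.n_restarts):
            starts.append(rng.normal(scale=scale, size=nw))
        best_w, best_auc = None, -np.inf
        for w0 in starts:
            w, a = run_nm(w0)
            if a > best_auc:
                best_w, best_auc = w, a
        # the zero start guarantees train AUC >= AUC of the fixed term alone
        if best_auc < -objective(np.zeros(nw)):
            best_w, best_auc = np.zeros(nw), -objective(np.zeros(nw))

        if self.polish:
            s0 = base + F @ best_w
            tau = max(self.polish_temperature * float(np.std(s0)), 1e-9)

            def soft_objective(w):
                return -self._soft_auc(base + F @ w, y, tau)

            res = minimize(
                soft_objective,
                best_w,
                method="Nelder-Mead",
                options={"maxiter": self.max_iter, "xatol": self.xatol,
                         "fatol": 1e-9, "adaptive": True},
            )
            a = -objective(res.x)
            if a > best_auc:
                best_w, best_auc = res.x, a

        self.weights_ = dict(zip(free, (float(v) for v in best_w)))
        self.train_auc_ = float(best_auc)
        s = base + F @ best_w
        self.train_max_mcc_, self.threshold_ = max_mcc(s, y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(FEATURE_ORDER)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        F, base, free = self._design(X)
        w = np.array([self.weights_[t] for t in free])
        return base + F @ w

    def predict(self, X):
        return (self.decision_function(X) >= self.threshold_).astype(int)

    def auc_score(self, X, y) -> float:
        """Exact rank AUC of the fitted score on (X, y)."""
        return auc(self.decision_function(X), np.asarray(y).astype(int))


def optimize_weights(
    features, labels, score_name: str = "s4", **config
) -> tuple[dict[str, float], float]:
    """Fit the named score's weights by simplex AUC maximization.

    Thin functional wrapper over :class:`CompositeScoreClassifier`;
    returns ``(weights, train_auc)``.
    """
    est = CompositeScoreClassifier(score=score_name, **config)
    est.fit(features, labels)
    return est.weights_, est.train_auc_
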