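"""Trial-outcome decoding from pre-stimulus power ratios with a
cross-validated Fisher linear discriminant (F-LDA).

The decoder predicts whether a trial will be correct or incorrect from the
vector of per-electrode pre-stimulus log PR values. Per iteration, equal
numbers of correct and incorrect trials are drawn, a Fisher discriminant is
fit and evaluated with stratified 5-fold cross-validation, and the
iteration's mean fold accuracy recorded; the empirical p-value is the
fraction of iterations with accuracy below 0.5 (chance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["FisherLDA", "DecoderResult", "flda_fit_predict", "decode_outcome"]


class FisherLDA:
    """Two-class Fisher linear discriminant.

    The projection w maximizes between-class over within-class scatter,
    w = Sw^{-1} (m1 - m0); classification thresholds the projection at the
    midpoint of the projected class means (equal priors, as training sets
    are balanced by construction). When the within-class scatter matrix is
    ill-conditioned a ridge term lambda*I with lambda =
    ``ridge`` * trace(Sw)/dim is added.
    """

    def __init__(self, ridge: float = 1e-3):
        self.ridge = ridge
        self.w_ = None
        self.threshold_ = None
        self.regularized_ = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FisherLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        if X.ndim == 1:
            X = X[:, None]
        X0, X1 = X[~y], X[y]
        if len(X0) < 2 or len(X1) < 2:
            raise ValueError("need at least 2 trials per class")
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        sw = (X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)
        d = sw.shape[0]
        lam = self.ridge * np.trace(sw) / d
        n_train = len(X0) + len(X1)
        self.regularized_ = n_train <= d + 2 or np.linalg.cond(sw) > 1e8
        if self.regularized_:
            sw = sw + lam * np.eye(d)
        self.w_ = np.linalg.solve(sw, m1 - m0)
        self.threshold_ = 0.5 * (self.w_ @ m0 + self.w_ @ m1)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.w_ - self.threshold_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X) > 0


def flda_fit_predict(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    ridge: float = 1e-3,
    seed=None,
) -> np.ndarray:
    """Stratified k-fold cross-validated Fisher-LDA fold accuracies.

    Folds are stratified so class proportions per fold differ from the
    global proportions by at most one trial. Returns the per-fold accuracy
    array.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    rs = None
    if seed is not None:
        rs = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
    acc = np.empty(n_folds)
    for i, (tr, te) in enumerate(skf.split(X, y)):
        model = FisherLDA(ridge=ridge).fit(X[tr], y[tr])
        acc[i] = (model.predict(X[te]) == y[te]).mean()
    return acc


@dataclass
class DecoderResult:
    """Balanced-subsampling cross-validated decoding accuracy distribution."""

    accuracies: np.ndarray = field(repr=False)  # per-iteration mean CV accuracy
    n_iterations: int
    n_per_class: int
    seed: int | None

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1))

    @property
    def pvalue(self) -> float:
        """Fraction of iterations with accuracy below chance (0.5)."""
        return float((self.accuracies < 0.5).mean())

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean,
            "sd_accuracy": self.sd,
            "pvalue": self.pvalue,
            "n_iterations": self.n_iterations,
            "n_per_class": self.n_per_class,
        }


def decode_outcome(
    features: np.ndarray,
    outcomes: np.ndarray,
    n_iterations: int = 10_000,
    seed=None,
    n_folds: int = 5,
    ridge: float = 1e-3,
    min_per_class: int = 10,
) -> DecoderResult:
    """Decode trial outcome from state features with balanced subsampling.

    Per iteration, ``min(class counts)`` trials are drawn without
    replacement from each class, and the stratified ``n_folds``-fold
    F-LDA accuracy recorded. Deterministic given ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    if X.ndim == 1:
        X = X[:, None]
    idx1 = np.flatnonzero(y)
    idx0 = np.flatnonzero(~y)
    n_sub = min(idx0.size, idx1.size)
    if n_sub < min_per_class:
        raise ValueError(
            f"minority class has {n_sub} trials; need at least {min_per_class}"
        )
    rng = np.random.default_rng(seed)
    acc = np.empty(n_iterations)
    for i in range(n_iterations):
        pick = np.concatenate(
            [
                rng.choice(idx0, size=n_sub, replace=False),
                rng.choice(idx1, size=n_sub, replace=False),
            ]
        )
        fold_seed = int(rng.integers(0, 2**31 - 1))
        acc[i] = flda_fit_predict(
            X[pick], y[pick], n_folds=n_folds, ridge=ridge, seed=fold_seed
        ).mean()
    return DecoderResult(
        accuracies=acc,
        n_iterations=n_iterations,
        n_per_class=n_sub,
        seed=seed if isinstance(seed, int) else None,
    )
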