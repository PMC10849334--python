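"""Shadow-feature relevance engine on random forests.

Each iteration augments the feature matrix with freshly permuted "shadow"
copies of every column, fits a random-forest classifier on the augmented
matrix, and records impurity-based importances.  A feature scores a *hit*
when its importance strictly exceeds the maximum importance among all
shadow features in that iteration (the canonical shadow-max rule).  After
a fixed number of iterations, hit counts are tested one-sided against
Binomial(n_iterations, 1/2): a significantly high count confirms the
feature, a significantly low count rejects it, anything else stays
tentative.

The per-feature importance score (IS) is the *shadow-relative* importance:
the feature's mean raw importance divided by the mean raw importance of
its own shadow, truncated below at parity (1).  Comparing each feature to
its own permuted copy cancels the variance/allele-frequency bias of
impurity importances — a shadow has exactly the marginal distribution of
its source, so any excess importance reflects association with the
response, not marker variability.  A feature no more important than its
shadow carries no signal, hence the truncation at 1: downstream
inverse-importance weighting then treats all no-signal features alike
instead of amplifying sampling noise.  A pseudocount at the scale of an
average feature's importance share (1/(2p), since impurity importances
sum to one over the augmented matrix) keeps the ratio defined when a
column is never used for a split and damps the ratio noise of weakly
used features toward parity.

Unlike classical Boruta, no feature is ever eliminated between
iterations — the adversarial weighting downstream needs a score for
every marker, decided or not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"

#: pseudocount, as a fraction of the mean importance 1/(2p), added to both
#: numerator and denominator of the shadow-relative ratio
PSEUDOCOUNT_FRACTION = 1.0


@dataclass
class BorutaConfig:
    """Settings for one shadow-feature relevance run."""

    n_iterations: int = 20
    trees_per_forest: int = 500
    alpha: float = 0.01
    seed: int = 0
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 5:
            raise ValueError("n_iterations must be >= 5")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if self.trees_per_forest < 1:
            raise ValueError("trees_per_forest must be positive")


@dataclass
class ImportanceResult:
    """Per-feature importance scores, hit counts and relevance decisions.

    ``IS`` is the shadow-relative score (>= 1; parity means
    indistinguishable from noise).  ``raw_importances`` and
    ``shadow_importances`` hold the mean raw impurity importances the
    ratio was formed from.
    """

    IS: np.ndarray
    hits: np.ndarray
    decisions: np.ndarray
    n_iterations: int
    raw_importances: np.ndarray | None = None
    shadow_importances: np.ndarray | None = None

    def to_csv(self, path: str | Path, marker_ids: list[str] | None = None) -> None:
        ids = marker_ids or [f"m{i}" for i in range(self.IS.size)]
        pd.DataFrame(
            {
                "marker_id": ids,
                "IS": self.IS,
                "hits": self.hits,
                "decision": self.decisions,
            }
        ).to_csv(path, index=False)


def augment_with_shadows(
    F: np.ndarray, rng: np.random.Generator | int
) -> np.ndarray:
    """Append an independently row-permuted shadow copy of every column.

    Column ``p + k`` of the result holds the same multiset of values as
    column ``k``, in a random order, destroying any association with the
    response while preserving the marginal distribution.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] == 0:
        raise ValueError("feature matrix must be n x p with p >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, p = F.shape
    shadows = np.empty_like(F)
    for k in range(p):
        shadows[:, k] = F[rng.permutation(n), k]
    return np.hstack([F, shadows])


def decide(hits: np.ndarray, n_iterations: int, alpha: float) -> np.ndarray:
    """Binomial-tail decisions from hit counts.

    Upper tail P[Bin(T, 1/2) >= hits] < alpha confirms; lower tail
    P[Bin(T, 1/2) <= hits] < alpha rejects; otherwise tentative.  The
    tests are one-sided and uncorrected; decisions are informative only
    and never feed the downstream weights.
    """
    hits = np.asarray(hits)
    upper = binom.sf(hits - 1, n_iterations, 0.5)  # P[X >= hits]
    lower = binom.cdf(hits, n_iterations, 0.5)  # P[X <= hits]
    out = np.full(hits.shape, TENTATIVE, dtype=object)
    out[upper < alpha] = CONFIRMED
    out[lower < alpha] = REJECTED
    return out


class BorutaRelevance(BaseEstimator):
    """Shadow-feature relevance estimator for binary classification targets.

    Parameters
    ----------
    n_iterations : int, default=20
        Number of shadow/forest rounds.
    trees_per_forest : int, default=500
        Trees per random forest; each forest subsamples sqrt(2p) features
        per split over the shadow-augmented matrix.
    alpha : float, default=0.01
        One-sided significance level of the binomial decision rule.
    random_state : int, default=0
        Seeds both the shadow permutations and the forests.

    Attributes
    ----------
    importances_ : ndarray of shape (p,)
        Shadow-relative importance score of each original feature (the IS
        fed to the adversarial weighting); >= 1, parity = no signal.
    raw_importances_ : ndarray of shape (p,)
        Mean raw impurity importance across iterations.
    shadow_importances_ : ndarray of shape (p,)
        Mean raw impurity importance of each feature's shadow.
    hits_ : ndarray of shape (p,)
        Iterations in which the feature beat every shadow feature.
    decisions_ : ndarray of shape (p,)
        "Confirmed" / "Tentative" / "Rejected" labels.
    """

    def __init__(
        self,
        n_iterations: int = 20,
        trees_per_forest: int = 500,
        alpha: float = 0.01,
        random_state: int = 0,
        max_depth: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.trees_per_forest = trees_per_forest
        self.alpha = alpha
        self.random_state = random_state
        self.max_depth = max_depth

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BorutaRelevance":
        # validates hyperparameters through the shared config contract
        BorutaConfig(
            n_iterations=self.n_iterations,
            trees_per_forest=self.trees_per_forest,
            alpha=self.alpha,
            seed=self.random_state,
            max_depth=self.max_depth,
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need at least 2 features")
        if X.shape[0] < 4:
            raise ValueError("need at least 4 samples")
        if np.unique(y).size < 2:
            raise ValueError("response must contain both classes")
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        orig_sum = np.zeros(p)
        shadow_sum = np.zeros(p)
        hits = np.zeros(p, dtype=int)
        for _ in range(self.n_iterations):
            augmented = augment_with_shadows(X, rng)
            forest = RandomForestClassifier(
                n_estimators=self.trees_per_forest,
                max_features="sqrt",
                max_depth=self.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(augmented, y)
            importances = forest.feature_importances_
            orig, shadow = importances[:p], importances[p:]
            orig_sum += orig
            shadow_sum += shadow
            hits += orig > shadow.max()
        self.raw_importances_ = orig_sum / self.n_iterations
        self.shadow_importances_ = shadow_sum / self.n_iterations
        c = PSEUDOCOUNT_FRACTION / (2 * p)
        self.importances_ = np.maximum(
            (self.raw_importances_ + c) / (self.shadow_importances_ + c), 1.0
        )
        self.hits_ = hits
        self.decisions_ = decide(hits, self.n_iterations, self.alpha)
        self.n_iterations_ = self.n_iterations
        return self

    def result(self) -> ImportanceResult:
        check_is_fitted(self, "importances_")
        return ImportanceResult(
            IS=self.importances_,
            hits=self.hits_,
            decisions=self.decisions_,
            n_iterations=self.n_iterations_,
            raw_importances=self.raw_importances_,
            shadow_importances=self.shadow_importances_,
        )


def boruta_run(
    F: np.ndarray, y: np.ndarray, config: BorutaConfig | None = None
) -> ImportanceResult:
    """Functional wrapper: run the relevance estimator, return its result."""
    config = config or BorutaConfig()
    est = BorutaRelevance(
        n_iterations=config.n_iterations,
        trees_per_forest=config.trees_per_forest,
        alpha=config.alpha,
        random_state=config.seed,
        max_depth=config.max_depth,
    )
    return est.fit(F, y).result()
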