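"""Shadow-feature relevance screening (Boruta-style all-relevant selection).

Each iteration duplicates every still-active feature, permutes the
duplicate's values to destroy any association with the label ("shadow"
features), fits a random forest on the joined table, and scores a *hit*
for a real feature whose importance exceeds the best shadow importance.
Hit counts across iterations follow Binomial(n, 1/2) for a feature that is
indistinguishable from noise, so a two-sided binomial test at ``alpha``
confirms features with significantly many hits and rejects features with
significantly few; whatever is still undecided at ``max_iter`` is left
*tentative*.

The importance measure defaults to permutation importance (mean decrease
in accuracy on a held-out stratified split, averaged over
``n_permutation_repeats`` shuffles); the forest's impurity (Gini)
importance is available via ``importance="gini"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass
class SelectionResult:
    """Outcome of a shadow-feature screen.

    ``status`` maps each feature to confirmed / rejected / tentative;
    ``hits`` and ``n_trials`` give the per-feature hit record the binomial
    test was run on; ``importance_history`` has one row per iteration with
    the importance of every feature then active plus the per-iteration
    maximum shadow importance (column ``shadow_max``).
    """

    status: pd.Series
    hits: pd.Series
    n_trials: pd.Series
    importance_history: pd.DataFrame
    n_iter: int
    alpha: float

    @property
    def confirmed(self) -> list[str]:
        return list(self.status.index[self.status == CONFIRMED])

    @property
    def rejected(self) -> list[str]:
        return list(self.status.index[self.status == REJECTED])

    @property
    def tentative(self) -> list[str]:
        return list(self.status.index[self.status == TENTATIVE])

    def to_frame(self) -> pd.DataFrame:
        mean = self.importance_history.reindex(columns=self.status.index).mean()
        sd = self.importance_history.reindex(columns=self.status.index).std()
        return pd.DataFrame(
            {
                "status": self.status,
                "hits": self.hits,
                "n_trials": self.n_trials,
                "importance_mean": mean,
                "importance_sd": sd,
            }
        ).rename_axis("feature")


class ShadowFeatureSelector(SelectorMixin, BaseEstimator):
    """All-relevant feature screen with permuted shadow probes.

    Parameters
    ----------
    alpha : float, default 0.01
        Significance level of the two-sided binomial test that confirms or
        rejects a feature.
    max_iter : int, default 100
        Maximum number of shadow iterations; undecided features are left
        tentative.
    n_trees : int, default 100
        Forest size per iteration.
    importance : {"permutation", "gini"}, default "permutation"
        Importance measure compared against the shadows.
    n_permutation_repeats : int, default 3
        Shuffles per feature for permutation importance.
    validation_fraction : float, default 0.3
        Held-out fraction used to score permutation importance.
    keep_tentative : bool, default False
        Whether tentative features count as selected in ``transform``.
    random_state : int or None
        Master seed for shadow permutations, forests and splits.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        max_iter: int = 100,
        n_trees: int = 100,
        importance: str = "permutation",
        n_permutation_repeats: int = 3,
        validation_fraction: float = 0.3,
        keep_tentative: bool = False,
        random_state: int | None = None,
    ) -> None:
        self.alpha = alpha
        self.max_iter = max_iter
        self.n_trees = n_trees
        self.importance = importance
        self.n_permutation_repeats = n_permutation_repeats
        self.validation_fraction = validation_fraction
        self.keep_tentative = keep_tentative
        self.random_state = random_state

    def _iter_importances(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Importance of each column of X (real + shadow) for one iteration."""
        n_cols = X.shape[1]
        seed = int(rng.integers(2**31 - 1))
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
        if self.importance == "gini":
            forest.fit(X, y)
            return forest.feature_importances_
        if self.importance != "permutation":
            raise ValueError(
                f"importance must be 'permutation' or 'gini', got {self.importance!r}"
            )
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y,
            test_size=self.validation_fraction,
            stratify=y,
            random_state=seed,
        )
        forest.fit(X_tr, y_tr)
        baseline = forest.score(X_val, y_val)
        # batch all permuted variants into one predict call: block (j, r)
        # is X_val with column j shuffled, laid out contiguously
        m = len(X_val)
        reps = self.n_permutation_repeats
        stacked = np.tile(X_val, (n_cols * reps, 1))
        for j in range(n_cols):
            for r in range(reps):
                block = slice((j * reps + r) * m, (j * reps + r + 1) * m)
                stacked[block, j] = X_val[rng.permutation(m), j]
        correct = (forest.predict(stacked) == np.tile(y_val, n_cols * reps))
        acc = correct.reshape(n_cols, reps, m).mean(axis=(1, 2))
        return baseline - acc

    def fit(self, X, y) -> "ShadowFeatureSelector":
        X_df = pd.DataFrame(X).copy()
        X_df.columns = [str(c) for c in X_df.columns]
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("shadow selection requires at least two classes")
        if X_df.shape[1] < 1:
            raise ValueError("shadow selection requires at least one feature")
        features = list(X_df.columns)
        rng = np.random.default_rng(self.random_state)

        status = pd.Series(TENTATIVE, index=features)
        hits = pd.Series(0, index=features)
        trials = pd.Series(0, index=features)
        history: list[dict[str, float]] = []

        n_iter = 0
        while n_iter < self.max_iter and (status == TENTATIVE).any():
            n_iter += 1
            active = list(status.index[status != REJECTED])
            X_act = X_df[active].to_numpy(dtype=float)
            shadow = X_act.copy()
            for j in range(shadow.shape[1]):
                shadow[:, j] = shadow[rng.permutation(len(shadow)), j]
            joined = np.hstack([X_act, shadow])
            imps = self._iter_importances(joined, y, rng)
            real_imp = imps[: len(active)]
            shadow_max = imps[len(active):].max()

            record = dict(zip(active, real_imp))
            record["shadow_max"] = shadow_max
            history.append(record)

            for feat, imp in zip(active, real_imp):
                if status[feat] != TENTATIVE:
                    continue
                trials[feat] += 1
                if imp > shadow_max:
                    hits[feat] += 1
                test = binomtest(int(hits[feat]), int(trials[feat]), 0.5)
                if test.pvalue < self.alpha:
                    status[feat] = (
                        CONFIRMED if hits[feat] > trials[feat] / 2 else REJECTED
                    )

        self.result_ = SelectionResult(
            status=status,
            hits=hits,
            n_trials=trials,
            importance_history=pd.DataFrame(history),
            n_iter=n_iter,
            alpha=self.alpha,
        )
        self.status_ = status
        self.n_iter_ = n_iter
        self.feature_names_in_ = np.asarray(features, dtype=object)
        self.n_features_in_ = len(features)
        selected = status == CONFIRMED
        if self.keep_tentative:
            selected |= status == TENTATIVE
        self.support_ = selected.to_numpy()
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


def shadow_select(
    X, y, alpha: float = 0.01, max_iter: int = 100, seed: int | None = None, **kwargs
) -> SelectionResult:
    """Functional wrapper: run the shadow screen and return its result."""
    selector = ShadowFeatureSelector(
        alpha=alpha, max_iter=max_iter, random_state=seed, **kwargs
    )
    selector.fit(X, y)
    return selector.result_
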