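"""Random-forest SNP selection: shadow-feature confirmation + incremental
feature selection.

A regression forest ranks SNPs by importance.  The shadow-feature
(Boruta-style) loop appends a shuffled copy of every candidate column to the
design, refits the forest, and flags a real SNP as a "hit" when it out-scores
the best shadow; a two-sided binomial tally over iterations (Bonferroni
across SNPs) classifies each SNP as confirmed or rejected, with undecided
survivors left tentative.  Incremental feature selection (IFS) then walks the
ranking, scoring nested top-k subsets by out-of-fold Pearson correlation and
picking the smallest k attaining the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_predict

__all__ = [
    "ImportanceRanking",
    "IFSCurve",
    "rf_importance",
    "boruta_select",
    "incremental_feature_selection",
    "select_optimal_k",
]


@dataclass
class ImportanceRanking:
    """Ranked SNPs with Boruta-style status labels."""

    snp_ids: list[str]  # ordered by decreasing relevance
    importance: dict[str, float]
    status: dict[str, str]  # confirmed | tentative | rejected
    n_iterations: int

    def confirmed(self) -> list[str]:
        return [s for s in self.snp_ids if self.status[s] == "confirmed"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "importance": [self.importance[s] for s in self.snp_ids],
                "status": [self.status[s] for s in self.snp_ids],
            }
        )


@dataclass
class IFSCurve:
    """Score of nested top-k feature subsets."""

    k_values: list[int]
    scores: list[float]

    @property
    def best_k(self) -> int:
        return select_optimal_k(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "score": self.scores})


def _forest(n_trees: int, seed: int) -> RandomForestRegressor:
    # sqrt(p) candidate features per split: the usual forest setting for
    # high-dimensional genomic predictors, and far cheaper than sklearn's
    # all-features regression default.
    return RandomForestRegressor(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )


def rf_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 300,
    seed: int = 0,
    n_repeats: int = 3,
    method: str = "permutation",
) -> np.ndarray:
    """Per-SNP importance from a regression forest.

    ``method='permutation'`` (default) measures the increase in prediction
    error when a column is shuffled; ``'impurity'`` uses the forest's
    split-gain totals (much cheaper, adequate when all features share the
    same coding).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute upstream")
    if method == "impurity":
        return _forest(n_trees, seed).fit(X, y).feature_importances_.copy()
    if method != "permutation":
        raise ValueError(f"unknown importance method {method!r}")
    # permutation importance is scored on a held-out split: scored on the
    # training data a fully-grown forest credits even pure-noise columns
    from sklearn.inspection import permutation_importance
    from sklearn.model_selection import train_test_split

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, random_state=seed
    )
    forest = _forest(n_trees, seed).fit(X_tr, y_tr)
    res = permutation_importance(
        forest, X_te, y_te, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    return res.importances_mean


def _iteration_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int, seed: int, method: str
) -> np.ndarray:
    forest = _forest(n_trees, seed).fit(X, y)
    if method == "impurity":
        return forest.feature_importances_
    from sklearn.inspection import permutation_importance

    return permutation_importance(
        forest, X, y, n_repeats=1, random_state=seed, n_jobs=1
    ).importances_mean


def boruta_select(
    X: np.ndarray,
    y: np.ndarray,
    snp_ids: list[str] | None = None,
    max_iter: int = 100,
    alpha: float = 0.01,
    n_trees: int = 100,
    seed: int = 0,
    importance: str = "impurity",
) -> ImportanceRanking:
    """Shadow-feature (Boruta-style) selection with a binomial tally.

    Each iteration shuffles a shadow copy of every still-active column, fits
    the forest on [active | shadows], and counts a hit for every active
    column beating the best shadow importance.  After ``t`` iterations a
    column with ``h`` hits is confirmed when P(Bin(t, 1/2) >= h) < alpha/p
    and rejected when P(Bin(t, 1/2) <= h) < alpha/p (Bonferroni over the
    ``p`` original columns); rejected columns drop out of later designs.
    Ranking: confirmed, then tentative, then rejected, each by mean
    importance over the iterations in which the column was active.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if snp_ids is None:
        snp_ids = [f"f{j}" for j in range(p)]
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10 (binomial tally underpowered)")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    rng = np.random.default_rng(seed)
    status = np.full(p, "tentative", dtype=object)
    hits = np.zeros(p, dtype=int)
    imp_sum = np.zeros(p)
    imp_n = np.zeros(p, dtype=int)
    thr = alpha / p
    t = 0
    while t < max_iter and (status == "tentative").any():
        active = np.flatnonzero(status != "rejected")
        shadows = X[:, active].copy()
        for c in range(shadows.shape[1]):
            rng.shuffle(shadows[:, c])
        design = np.hstack([X[:, active], shadows])
        imp = _iteration_importance(
            design, y, n_trees, seed=int(rng.integers(2**31 - 1)), method=importance
        )
        real_imp = imp[: active.size]
        best_shadow = imp[active.size :].max() if active.size else 0.0
        imp_sum[active] += real_imp
        imp_n[active] += 1
        t += 1
        tentative = status == "tentative"
        hit_mask = np.zeros(p, dtype=bool)
        hit_mask[active[real_imp > best_shadow]] = True
        hits[tentative & hit_mask] += 1
        # binomial decisions for still-tentative features
        for j in np.flatnonzero(tentative):
            if binom.sf(hits[j] - 1, t, 0.5) < thr:
                status[j] = "confirmed"
            elif binom.cdf(hits[j], t, 0.5) < thr:
                status[j] = "rejected"
    mean_imp = np.where(imp_n > 0, imp_sum / np.maximum(imp_n, 1), 0.0)
    rank_key = {"confirmed": 0, "tentative": 1, "rejected": 2}
    order = sorted(
        range(p), key=lambda j: (rank_key[status[j]], -mean_imp[j], snp_ids[j])
    )
    return ImportanceRanking(
        snp_ids=[snp_ids[j] for j in order],
        importance={snp_ids[j]: float(mean_imp[j]) for j in range(p)},
        status={snp_ids[j]: str(status[j]) for j in range(p)},
        n_iterations=t,
    )


def _ifs_grid(max_k: int, dense_until: int = 200, step: int = 10) -> list[int]:
    ks = list(range(1, min(max_k, dense_until) + 1))
    ks += list(range(dense_until + step, max_k + 1, step))
    return ks


def incremental_feature_selection_matrix(
    features: np.ndarray,
    y: np.ndarray,
    max_k: int,
    cv_folds: int = 5,
    seed: int = 0,
    n_trees: int = 100,
    dense_until: int = 200,
    step: int = 10,
) -> IFSCurve:
    """IFS over pre-ordered feature columns (first column = top ranked)."""
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if max_k > features.shape[1]:
        raise ValueError("max_k exceeds number of ranked features")
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    ks, scores = [], []
    for k in _ifs_grid(max_k, dense_until, step):
        pred = cross_val_predict(
            _forest(n_trees, seed), features[:, :k], y, cv=cv, n_jobs=1
        )
        r = pearsonr(pred, y).statistic if np.ptp(pred) > 0 else 0.0
        ks.append(k)
        scores.append(float(r))
    return IFSCurve(k_values=ks, scores=scores)


def incremental_feature_selection(
    X: np.ndarray,
    y: np.ndarray,
    ranking: ImportanceRanking,
    snp_ids: list[str],
    max_k: int,
    cv_folds: int = 5,
    seed: int = 0,
    n_trees: int = 100,
    dense_until: int = 200,
    step: int = 10,
) -> IFSCurve:
    """IFS following a ranking: top-k SNP subsets scored by out-of-fold
    Pearson correlation between forest predictions and the trait."""
    idx = {s: j for j, s in enumerate(snp_ids)}
    cols = [idx[s] for s in ranking.snp_ids[:max_k]]
    return incremental_feature_selection_matrix(
        np.asarray(X, dtype=float)[:, cols], y, max_k=len(cols),
        cv_folds=cv_folds, seed=seed, n_trees=n_trees,
        dense_until=dense_until, step=step,
    )


def select_optimal_k(curve: IFSCurve) -> int:
    """Smallest k attaining the maximum IFS score."""
    if not curve.k_values:
        raise ValueError("empty IFS curve")
    scores = np.asarray(curve.scores)
    return int(curve.k_values[int(scores.argmax())])
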