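"""Iterative random-forest importance aggregation for marker refinement.

A single random forest gives one, somewhat unstable, importance ranking.  The
refinement procedure here fits 100 forests (500 trees each, mtry = floor(sqrt(p)))
with different seeds, ranks the features by out-of-bag permutation importance
(mean decrease in accuracy) in every iteration, and aggregates:

* the cumulative top-N matrix ``C[v, N]`` — in how many iterations feature v
  ranked within the top N — separates consistently informative features from
  noise;
* the top-1 frequency — how often a feature was the single most important —
  picks the final marker panel (features reaching a minimum frequency);
* a final forest restricted to the selected markers is scored by its
  out-of-bag error and out-of-bag ROC AUC.

The forest members are scikit-learn decision trees; the bagging loop is kept
in-package so that per-tree out-of-bag membership is available for the
permutation importance and the OOB vote matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier


class RfSelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bagged forest with explicit OOB bookkeeping
# ---------------------------------------------------------------------------


class _BaggedForest:
    """Random forest as an explicit bagging loop over sklearn decision trees.

    Keeps each tree's bootstrap/out-of-bag membership so OOB permutation
    importance (the mean-decrease-accuracy convention) and OOB class votes can
    be computed exactly.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_masks_: list[np.ndarray] = []

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_BaggedForest":
        # trees see float32 features; predictions later bypass re-validation
        x32 = np.ascontiguousarray(x, dtype=np.float32)
        n, p = x32.shape
        rng = np.random.default_rng(self.seed)
        mtry = self.mtry or max(1, int(np.floor(np.sqrt(p))))
        self.classes_ = np.unique(y)
        self.trees_, self.oob_masks_ = [], []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeClassifier(
                max_features=mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(x32[idx], y[idx])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        self._x, self._y = x32, y
        return self

    def oob_decision_function(self) -> np.ndarray:
        """Per-sample OOB class-probability votes (fraction of OOB trees voting
        for each class); samples never out of bag get uniform votes."""
        n = self._x.shape[0]
        k = len(self.classes_)
        votes = np.zeros((n, k))
        counts = np.zeros(n)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if not oob.any():
                continue
            pred = tree.predict(self._x[oob], check_input=False)
            for ci, c in enumerate(self.classes_):
                votes[np.flatnonzero(oob)[pred == c], ci] += 1
            counts[oob] += 1
        never = counts == 0
        votes = votes / np.maximum(counts, 1)[:, None]
        votes[never] = 1.0 / k
        return votes

    def oob_error(self) -> float:
        votes = self.oob_decision_function()
        pred = self.classes_[votes.argmax(axis=1)]
        return float((pred != self._y).mean())

    def permutation_importance(self, rng: np.random.Generator) -> np.ndarray:
        """OOB permutation importance: per tree, the drop in OOB accuracy when
        one feature's OOB values are shuffled, averaged over trees."""
        n, p = self._x.shape
        deltas = np.zeros(p)
        n_used = 0
        for tree, oob in zip(self.trees_, self.oob_masks_):
            m = int(oob.sum())
            if m < 2:
                continue
            x_oob = self._x[oob]
            y_oob = self._y[oob]
            # one stacked predict per tree: the intact block + p permuted blocks
            blocks = np.tile(x_oob, (p + 1, 1))
            perm_idx = rng.random((p, m)).argsort(axis=1)
            for j in range(p):
                sl = slice((j + 1) * m, (j + 2) * m)
                blocks[sl, j] = x_oob[perm_idx[j], j]
            pred = tree.predict(
                np.ascontiguousarray(blocks), check_input=False
            ).reshape(p + 1, m)
            acc = (pred == y_oob).mean(axis=1)
            deltas += acc[0] - acc[1:]
            n_used += 1
        if n_used == 0:
            raise RfSelectionError("no tree had out-of-bag samples")
        return deltas / n_used


# ---------------------------------------------------------------------------
# Iteration log and aggregation
# ---------------------------------------------------------------------------


@dataclass
class RfIterationLog:
    """Importance rankings of ``n_iterations`` independently seeded forests.

    ``rankings[i, v]`` is the rank (1 = most important) of feature v in
    iteration i; every row is a permutation of 1..p.  Ties in importance are
    broken by ascending feature order, so the log is reproducible from the
    per-iteration seeds.
    """

    rankings: np.ndarray
    seeds: list[int]
    feature_ids: list[str]
    n_trees: int
    mtry: int

    @property
    def n_iterations(self) -> int:
        return self.rankings.shape[0]

    @property
    def n_features(self) -> int:
        return self.rankings.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rankings, columns=self.feature_ids)


def iterate_rf_importance(
    x: np.ndarray | pd.DataFrame,
    y,
    feature_ids: list[str] | None = None,
    n_iterations: int = 100,
    n_trees: int = 500,
    seed: int = 0,
    importance: str = "permutation",
) -> RfIterationLog:
    """Fit ``n_iterations`` forests (seed = base seed + i) and log importance ranks.

    ``importance`` is ``"permutation"`` (OOB mean decrease accuracy, default)
    or ``"gini"`` (impurity-based).
    """
    if isinstance(x, pd.DataFrame):
        feature_ids = feature_ids or list(x.columns)
        x = x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if p < 2:
        raise RfSelectionError("ranking needs at least 2 features")
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise RfSelectionError("y must contain exactly two classes")
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(p)]
    if importance not in ("permutation", "gini"):
        raise RfSelectionError("importance must be 'permutation' or 'gini'")

    mtry = max(1, int(np.floor(np.sqrt(p))))
    rankings = np.empty((n_iterations, p), dtype=int)
    seeds = [seed + i for i in range(n_iterations)]
    for i, s in enumerate(seeds):
        forest = _BaggedForest(n_trees=n_trees, mtry=mtry, seed=s).fit(x, y)
        if importance == "permutation":
            imp = forest.permutation_importance(np.random.default_rng(s + 10_000_019))
        else:
            imp = np.mean([t.feature_importances_ for t in forest.trees_], axis=0)
        order = np.lexsort((np.arange(p), -imp))  # descending, ties by feature order
        ranks = np.empty(p, dtype=int)
        ranks[order] = np.arange(1, p + 1)
        rankings[i] = ranks
    return RfIterationLog(
        rankings=rankings, seeds=seeds, feature_ids=feature_ids,
        n_trees=n_trees, mtry=mtry,
    )


def cumulative_topn(log: RfIterationLog) -> pd.DataFrame:
    """Cumulative top-N matrix: C[v, N] = iterations where v ranked <= N."""
    p = log.n_features
    counts = np.zeros((p, p), dtype=int)  # features x N
    for v in range(p):
        ranks = log.rankings[:, v]
        hist = np.bincount(ranks, minlength=p + 1)[1:]
        counts[v] = np.cumsum(hist)
    return pd.DataFrame(
        counts, index=pd.Index(log.feature_ids, name="feature_id"),
        columns=pd.RangeIndex(1, p + 1, name="top_n"),
    )


def stable_set(log: RfIterationLog, n_star: int | str = "auto") -> tuple[list[str], int]:
    """Features whose cumulative top-N count reaches n_iterations at N*.

    ``n_star="auto"`` picks the smallest N whose stable-set size is unchanged
    for 3 consecutive N values.
    """
    c = cumulative_topn(log)
    full = log.n_iterations
    sizes = (c.to_numpy() == full).sum(axis=0)  # per N
    if n_star == "auto":
        n_star = log.n_features
        for n in range(1, log.n_features - 1):
            if sizes[n - 1] == sizes[n] == sizes[n + 1] and sizes[n - 1] > 0:
                n_star = n
                break
    n_star = int(n_star)
    members = list(c.index[(c[n_star] == full)])
    return members, n_star


def select_by_frequency(frequencies: pd.Series, min_frequency: int = 4) -> list[str]:
    """Ids whose frequency is at least ``min_frequency``.

    The threshold is inclusive: a panel quoted as "appeared more than four
    times" that contains members at exactly 4 only adds up under >=.
    """
    return list(frequencies.index[frequencies >= min_frequency])


def top1_frequency(log: RfIterationLog) -> pd.Series:
    """How often each feature was rank 1 across iterations (sums to n_iterations)."""
    freq = (log.rankings == 1).sum(axis=0)
    return pd.Series(freq, index=pd.Index(log.feature_ids, name="feature_id"), name="top1_frequency")


def top1_select(log: RfIterationLog, min_frequency: int = 4) -> list[str]:
    """Marker ids selected by the top-1 frequency rule."""
    return select_by_frequency(top1_frequency(log), min_frequency)


def final_model_eval(
    x: np.ndarray | pd.DataFrame, y, n_trees: int = 500, seed: int = 0
) -> tuple[float, float]:
    """Fit one forest on the selected markers; return (OOB error, OOB ROC AUC)."""
    if isinstance(x, pd.DataFrame):
        x = x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] < 1:
        raise RfSelectionError("no markers selected")
    y = np.asarray(y)
    mtry = max(1, int(np.floor(np.sqrt(x.shape[1]))))
    forest = _BaggedForest(n_trees=n_trees, mtry=mtry, seed=seed).fit(x, y)
    votes = forest.oob_decision_function()
    oob_error = forest.oob_error()
    # probability votes for the second class (sklearn's positive-class order)
    auc = float(roc_auc_score(y == forest.classes_[1], votes[:, 1]))
    return oob_error, auc


# ---------------------------------------------------------------------------
# Model/Results wrapper
# ---------------------------------------------------------------------------


@dataclass
class RFSelectionResults:
    """Aggregated outcome of the iterative-forest selection."""

    log: RfIterationLog
    cumulative: pd.DataFrame
    top1: pd.Series
    stable_features: list[str]
    n_star: int
    selected_markers: list[str]
    min_frequency: int
    final_oob_error: float
    final_auc: float

    def summary(self) -> str:
        lines = [
            "Iterative random-forest selection",
            "=" * 50,
            f"{'iterations x trees':<28}{self.log.n_iterations} x {self.log.n_trees}",
            f"{'features in':<28}{self.log.n_features:>8d}",
            f"{'mtry':<28}{self.log.mtry:>8d}",
            f"{'stable set (N* = %d)' % self.n_star:<28}{len(self.stable_features):>8d}",
            f"{'selected (top-1 freq >= %d)' % self.min_frequency:<28}{len(self.selected_markers):>8d}",
            f"{'final OOB error':<28}{self.final_oob_error:>12.4f}",
            f"{'final OOB ROC AUC':<28}{self.final_auc:>12.4f}",
        ]
        return "\n".join(lines)


class RFMarkerSelector:
    """Iterative-forest marker selection over a candidate feature matrix.

    ``fit()`` runs the full procedure: 100 seeded forests, importance ranking,
    cumulative top-N and top-1 aggregation, frequency-threshold selection, and
    a final forest on the selected markers scored by OOB error and OOB AUC.
    """

    def __init__(self, x, y, feature_ids: list[str] | None = None):
        if isinstance(x, pd.DataFrame):
            feature_ids = feature_ids or list(x.columns)
            x = x.to_numpy(dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y)
        self.feature_ids = feature_ids or [f"x{j}" for j in range(self.x.shape[1])]

    def fit(
        self,
        n_iterations: int = 100,
        n_trees: int = 500,
        min_frequency: int = 4,
        n_star: int | str = "auto",
        seed: int = 0,
        importance: str = "permutation",
        restrict_to_stable: bool = False,
    ) -> RFSelectionResults:
        log = iterate_rf_importance(
            self.x, self.y, feature_ids=self.feature_ids,
            n_iterations=n_iterations, n_trees=n_trees, seed=seed,
            importance=importance,
        )
        cumulative = cumulative_topn(log)
        stable, used_n_star = stable_set(log, n_star)
        freq = top1_frequency(log)
        if restrict_to_stable:
            freq = freq.loc[[f for f in freq.index if f in set(stable)]]
        selected = select_by_frequency(freq, min_frequency)
        if not selected:
            raise RfSelectionError(
                f"no feature reached top-1 frequency {min_frequency}"
            )
        cols = [self.feature_ids.index(f) for f in selected]
        oob_error, auc = final_model_eval(
            self.x[:, cols], self.y, n_trees=n_trees, seed=seed
        )
        return RFSelectionResults(
            log=log,
            cumulative=cumulative,
            top1=top1_frequency(log),
            stable_features=stable,
            n_star=used_n_star,
            selected_markers=selected,
            min_frequency=min_frequency,
            final_oob_error=oob_error,
            final_auc=auc,
        )
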