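"""Shadow-feature (Boruta) importance ranking, class-signal summaries, and an
illustrative CART tree.

The Boruta wrapper decides, per feature, whether it carries information about
a class label beyond chance: every iteration appends an independently
shuffled "shadow" copy of each surviving column, fits a random forest, and
scores a hit when a real feature's importance exceeds the best shadow's.
Hits are tested against Binomial(n_iter, 1/2) two-sided with Bonferroni
correction over the still-undecided features; significant excess confirms a
feature, significant deficit rejects it (rejected columns and their shadows
leave the model). Features undecided at ``max_iter`` stay Tentative and are
reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier, export_text

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"

#: deterministic class orders used to break argmax ties
CLASS_ORDERS = {
    "mean": ["Low", "Mid", "High"],
    "trajectory": ["EarlyUp", "EarlyDown", "LateUp", "LateDown", "Control"],
    "noise": ["Low", "Mid", "High"],
}


class BorutaSelector(BaseEstimator):
    """All-relevant feature selection against shuffled shadow features.

    Parameters
    ----------
    n_estimators : trees per random forest fit.
    max_iter : maximum shadow iterations (the reference analysis used 100).
    p_threshold : family-wise significance level for the binomial decisions.
    importance : ``"permutation"`` (the default: permutation importance on
        a held-out third, which is calibrated against chance in-sample
        associations) or ``"gini"`` (faster in-sample impurity importance).
    random_state : seed controlling shadow shuffles and forest fits.

    Attributes
    ----------
    decisions_ : pd.Series mapping feature -> Confirmed/Tentative/Rejected.
    importance_history_ : DataFrame (iteration x feature), NaN once rejected.
    mean_importance_ : per-feature mean importance over iterations run.
    n_hits_ : per-feature hit counts; n_iter_ : iterations actually run.
    support_ : boolean mask of Confirmed features.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_iter: int = 100,
        p_threshold: float = 0.01,
        importance: str = "permutation",
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.p_threshold = p_threshold
        self.importance = importance
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _importances(self, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
        rf = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=seed, n_jobs=1
        )
        if self.importance == "gini":
            # in-sample impurity importance rewards fixed chance associations
            # every iteration, so the binomial test can confirm pure-noise
            # features; use only when speed matters more than calibration
            rf.fit(X, y)
            return rf.feature_importances_
        if self.importance == "permutation":
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, test_size=1 / 3, random_state=seed, stratify=y
            )
            rf.fit(Xtr, ytr)
            res = permutation_importance(
                rf, Xte, yte, n_repeats=1, random_state=seed, n_jobs=1
            )
            return res.importances_mean
        raise ValueError(f"unknown importance provider {self.importance!r}")

    def fit(self, X, y) -> "BorutaSelector":
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        yv = np.asarray(y)
        classes, counts = np.unique(yv, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need >= 2 classes")
        if counts.min() < 2:
            raise ValueError("every class needs >= 2 instances")
        if not np.isfinite(Xv).all():
            raise ValueError("feature matrix contains missing values")

        n_feat = Xv.shape[1]
        rng = np.random.default_rng(self.random_state)
        decisions = np.array([TENTATIVE] * n_feat, dtype=object)
        hits = np.zeros(n_feat, dtype=int)
        history = np.full((self.max_iter, n_feat), np.nan)

        n_iter = 0
        for it in range(self.max_iter):
            active = decisions != REJECTED  # confirmed stay in the model
            idx = np.flatnonzero(active)
            Xa = Xv[:, idx]
            shadows = Xa.copy()
            for j in range(shadows.shape[1]):
                rng.shuffle(shadows[:, j])
            imp = self._importances(
                np.hstack([Xa, shadows]), yv, seed=int(rng.integers(2**31))
            )
            real_imp = imp[: len(idx)]
            shadow_max = imp[len(idx):].max()
            history[it, idx] = real_imp
            hits[idx[real_imp > shadow_max]] += 1
            n_iter = it + 1

            undecided = np.flatnonzero(decisions == TENTATIVE)
            if len(undecided):
                for j in undecided:
                    p = stats.binomtest(int(hits[j]), n_iter, 0.5).pvalue
                    if p * len(undecided) < self.p_threshold:
                        decisions[j] = CONFIRMED if hits[j] > n_iter / 2 else REJECTED
            if not (decisions == TENTATIVE).any():
                break

        history = history[:n_iter]
        self.feature_names_in_ = np.array(names)
        self.n_iter_ = n_iter
        self.decisions_ = pd.Series(decisions, index=names, name="decision")
        self.importance_history_ = pd.DataFrame(history, columns=names)
        with np.errstate(invalid="ignore"):
            self.mean_importance_ = pd.Series(
                np.nanmean(history, axis=0), index=names, name="mean_importance"
            )
        self.n_hits_ = pd.Series(hits, index=names, name="n_hits")
        self.support_ = (decisions == CONFIRMED)
        return self

    def get_support(self, indices: bool = False):
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


@dataclass
class ImportanceResult:
    """Boruta output for one analysis (mean / trajectory / noise)."""

    decisions: pd.Series
    importance_history: pd.DataFrame
    mean_importance: pd.Series
    n_hits: pd.Series
    n_iter: int
    analysis: str

    @property
    def confirmed(self) -> list[str]:
        return list(self.decisions.index[self.decisions == CONFIRMED])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "decision": self.decisions,
                "mean_importance": self.mean_importance,
                "n_hits": self.n_hits,
            }
        )
        out["n_iter"] = self.n_iter
        out.index.name = "feature"
        return out


def boruta_rank(
    feature_table: pd.DataFrame,
    labels: pd.Series,
    analysis: str = "trajectory",
    max_iter: int = 100,
    p_threshold: float = 0.01,
    seed: int | None = None,
    importance: str = "permutation",
) -> ImportanceResult:
    """Rank the feature table's columns for predicting ``labels``.

    Non-feature columns (``context``) are dropped; rows are aligned on the
    label index, so pooled multi-context tables are ranked as one set.
    """
    X = feature_table.drop(columns=[c for c in ("context",) if c in feature_table])
    common = X.index.intersection(labels.index)
    X = X.loc[common]
    y = labels.loc[common]
    counts = y.value_counts()
    if (counts < 10).any():
        small = counts[counts < 10]
        raise ValueError(f"classes with < 10 instances: {dict(small)}")
    sel = BorutaSelector(
        max_iter=max_iter,
        p_threshold=p_threshold,
        random_state=seed,
        importance=importance,
    ).fit(X, y.to_numpy())
    return ImportanceResult(
        decisions=sel.decisions_,
        importance_history=sel.importance_history_,
        mean_importance=sel.mean_importance_,
        n_hits=sel.n_hits_,
        n_iter=sel.n_iter_,
        analysis=analysis,
    )


def group_signal_summary(
    feature_table: pd.DataFrame,
    labels: pd.Series,
    class_order: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-feature class means and the class with maximum mean signal.

    Argmax ties are broken by ``class_order`` (first listed wins); default is
    the sorted class names.
    """
    X = feature_table.drop(columns=[c for c in ("context",) if c in feature_table])
    common = X.index.intersection(labels.index)
    X, y = X.loc[common], labels.loc[common]
    classes = class_order or sorted(y.unique())
    means = pd.DataFrame(
        {cls: X.loc[y == cls].mean(axis=0) for cls in classes if (y == cls).any()}
    )
    argmax = means.idxmax(axis=1)  # idxmax keeps first occurrence = class order
    return means, argmax.rename("max_class")


def _gini(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - (p**2).sum())


def fit_tree(
    feature_table: pd.DataFrame,
    labels: pd.Series,
    min_leaf: int = 50,
    complexity: float = 0.007,
    max_depth_report: int = 4,
    seed: int = 0,
) -> dict:
    """Illustrative CART tree (Gini), rpart-style stopping.

    rpart's ``cp`` retains a split only if it improves the fit by a fraction
    ``cp`` of the root risk; here that is mapped to sklearn's
    ``min_impurity_decrease = complexity * root Gini``. The returned dict
    carries a text rendering truncated to ``max_depth_report`` levels, the
    fitted depth/leaf count, and the estimator itself.
    """
    X = feature_table.drop(columns=[c for c in ("context",) if c in feature_table])
    common = X.index.intersection(labels.index)
    X, y = X.loc[common], labels.loc[common].to_numpy()
    if len(X) == 0:
        raise ValueError("empty feature table")
    # min_leaf > n/2 admits no split and yields a single-leaf tree
    tree = DecisionTreeClassifier(
        min_samples_leaf=min_leaf,
        min_impurity_decrease=complexity * _gini(y),
        random_state=seed,
    ).fit(X, y)
    return {
        "text": export_text(
            tree, feature_names=list(X.columns), max_depth=max_depth_report
        ),
        "depth": int(tree.get_depth()),
        "n_leaves": int(tree.get_n_leaves()),
        "classes": [str(c) for c in tree.classes_],
        "estimator": tree,
    }


def compare_profiles(results: list[ImportanceResult]) -> dict:
    """Correlate mean-importance profiles across analyses and PCA them.

    Returns the Pearson correlation matrix between analyses, 2-component PCA
    coordinates of each analysis in importance space, and the explained
    variance fractions.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 importance results")
    shared = results[0].mean_importance.index
    for r in results[1:]:
        shared = shared.intersection(r.mean_importance.index)
    if len(shared) == 0:
        raise ValueError("importance results share no features")
    mat = pd.DataFrame(
        {r.analysis: r.mean_importance.reindex(shared) for r in results}
    )  # features x analyses
    corr = mat.corr(method="pearson")
    n_comp = max(1, min(2, len(results) - 1, len(shared)))
    pca = PCA(n_components=n_comp, random_state=0)
    coords = pca.fit_transform(mat.T.to_numpy())
    return {
        "correlation": corr,
        "coordinates": pd.DataFrame(
            coords,
            index=mat.columns,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
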