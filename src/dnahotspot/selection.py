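"""Two-step feature selection: SVM-RFE ranking, then correlation pruning.

Step 1 iteratively fits a linear-kernel SVM on min-max-scaled features and
drops the feature with the smallest absolute weight, recording a stratified
cross-validated AUC of an RBF classifier at every subset size; the kept
subset is the size with the best mean AUC (ties favor the smaller subset).
Step 2 removes, from each remaining pair whose Pearson correlation exceeds
a threshold (0.65 by default, signed r), the member with the worse RFE
rank, re-checking after every drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = ["SelectionConfig", "SelectionResult", "svm_rfe", "pearson_prune", "two_step_select"]


@dataclass
class SelectionConfig:
    cv_folds: int = 10
    seed: int = 0
    correlation_threshold: float = 0.65
    #: prune on signed r (paper-style "highly positive correlation"); set
    #: True to prune on |r| instead
    use_abs_correlation: bool = False
    linear_c: float = 1.0
    rbf_c: float = 4.5
    rbf_gamma: float = 0.05


@dataclass
class SelectionResult:
    elimination_order: list[str]  # worst first
    ranking: dict[str, int]  # 1 = best (survived longest)
    cv_curve: list[tuple[int, float]]  # (subset size, mean CV AUC)
    step1_subset: list[str]
    correlation_matrix: pd.DataFrame | None = None
    pruned_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    final_subset: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "elimination_order": self.elimination_order,
            "ranking": self.ranking,
            "cv_curve": [[int(s), float(a)] for s, a in self.cv_curve],
            "step1_subset": self.step1_subset,
            "pruned_pairs": [[a, b, float(r)] for a, b, r in self.pruned_pairs],
            "final_subset": self.final_subset,
        }


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def _cv_auc(X: np.ndarray, y: np.ndarray, config: SelectionConfig) -> float:
    n_splits = min(config.cv_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    clf = SVC(kernel="rbf", C=config.rbf_c, gamma=config.rbf_gamma)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="roc_auc")
    return float(scores.mean())


def svm_rfe(
    table: FeatureTable, config: SelectionConfig | None = None
) -> SelectionResult:
    """Recursive feature elimination with linear-SVM weight magnitudes.

    One feature is removed per iteration (smallest ``|w|``, ties broken by
    column order); the returned subset is the CV-AUC-optimal prefix of the
    ranking.
    """
    config = config or SelectionConfig()
    y = table.y
    if y is None:
        raise ValueError("table has no labels")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    names = list(table.feature_names)
    if len(names) < 2:
        raise ValueError("need at least 2 features for RFE")

    X_full = _minmax_scale(table.X)
    active = list(range(len(names)))
    elimination: list[int] = []
    curve: list[tuple[int, float]] = []

    while active:
        X = X_full[:, active]
        curve.append((len(active), _cv_auc(X, y, config)))
        if len(active) == 1:
            elimination.append(active.pop(0))
            break
        svm = SVC(kernel="linear", C=config.linear_c)
        svm.fit(X, y)
        w = np.abs(np.asarray(svm.coef_).ravel())
        drop = int(np.argmin(w))  # argmin keeps first on ties -> column order
        elimination.append(active.pop(drop))

    # elimination recorded best-last; rank 1 = eliminated last
    order_worst_first = [names[i] for i in elimination]
    ranking = {
        name: len(names) - pos for pos, name in enumerate(order_worst_first)
    }

    best_size, _ = max(curve, key=lambda t: (t[1], -t[0]))
    survivors = order_worst_first[::-1][:best_size]
    step1 = [n for n in names if n in set(survivors)]  # keep column order
    return SelectionResult(
        elimination_order=order_worst_first,
        ranking=ranking,
        cv_curve=curve,
        step1_subset=step1,
    )


def _correlations(frame: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    corr = frame[cols].corr(method="pearson")
    return corr.fillna(0.0)  # zero-variance columns: r treated as 0


def pearson_prune(
    table: FeatureTable,
    subset: list[str],
    ranking: dict[str, int],
    threshold: float = 0.65,
    use_abs: bool = False,
) -> tuple[list[str], list[tuple[str, str, float]], pd.DataFrame]:
    """Drop the worse-ranked member of every over-correlated pair.

    Pairs are processed in decreasing correlation; correlations are
    recomputed on the survivors after every drop.  Returns the final
    subset, the pruned pairs with their coefficients, and the step-1
    correlation matrix.
    """
    if not subset:
        raise ValueError("empty candidate subset")
    keep = list(subset)
    corr0 = _correlations(table.frame, keep)
    pruned: list[tuple[str, str, float]] = []
    while len(keep) > 1:
        corr = _correlations(table.frame, keep)
        vals = corr.abs() if use_abs else corr
        best_pair = None
        best_r = threshold
        for i, a in enumerate(keep):
            for b in keep[i + 1:]:
                r = float(vals.loc[a, b])
                if r > best_r:
                    best_r = r
                    best_pair = (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        loser = a if ranking.get(a, 0) > ranking.get(b, 0) else b
        pruned.append((a, b, float(corr.loc[a, b])))
        keep.remove(loser)
    return keep, pruned, corr0


def two_step_select(
    table: FeatureTable, config: SelectionConfig | None = None
) -> SelectionResult:
    """SVM-RFE followed by correlation pruning; full audit trail retained."""
    config = config or SelectionConfig()
    result = svm_rfe(table, config)
    final, pruned, corr = pearson_prune(
        table,
        result.step1_subset,
        result.ranking,
        threshold=config.correlation_threshold,
        use_abs=config.use_abs_correlation,
    )
    result.correlation_matrix = corr
    result.pruned_pairs = pruned
    result.final_subset = final
    assert result.final_subset, "step 1 keeps at least one feature"
    return result
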