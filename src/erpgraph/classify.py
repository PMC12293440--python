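"""Feature ranking, classifiers and repeated cross-validated evaluation.

Ranking methods: per-feature two-sample t statistic, ReliefF (k nearest
hits/misses on min-max-scaled features) and greedy MRMR (mutual
information on tertile-discretized features).  Classifiers: SVM with an
RBF kernel of fixed unit kernel scale (box constraint tuned by inner
cross-validation on the training fold only), Fisher LDA, and the single
Euclidean nearest neighbor.  Evaluation is stratified k-fold
cross-validation repeated R times with feature ranking re-fit inside
every training fold, so no selection information leaks from test folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import PipelineConfig
from .graphs import FeatureMatrix

__all__ = [
    "RankingResult",
    "EvalReport",
    "ttest_rank",
    "relieff_rank",
    "mrmr_rank",
    "train_predict",
    "repeated_cv",
    "confusion_metrics",
]


@dataclass
class RankingResult:
    """Per-feature relevance scores and the descending-relevance order."""

    scores: np.ndarray
    order: np.ndarray
    method: str

    def top(self, n: int) -> np.ndarray:
        return self.order[:n]


@dataclass
class EvalReport:
    """Cross-validation outcome: per-repeat metrics (%) and their means."""

    per_repeat: pd.DataFrame  # columns accuracy/sensitivity/specificity/f1
    config: dict = field(default_factory=dict)
    seed: int = 0
    flags: list = field(default_factory=list)

    @property
    def means(self) -> dict:
        return {k: float(v) for k, v in self.per_repeat.mean().items()}

    def to_frame(self) -> pd.DataFrame:
        df = self.per_repeat.copy()
        df.loc["mean"] = df.mean()
        return df


def _stable_order(scores: np.ndarray) -> np.ndarray:
    """Descending score order with deterministic index tie-break."""
    idx = np.arange(scores.size)
    return np.lexsort((idx, -scores))


def ttest_rank(X: np.ndarray, y: np.ndarray) -> RankingResult:
    """Rank features by |two-sample t statistic| between the classes.

    Zero pooled variance is floored at 1e-12 (flagged via warning) so a
    perfectly separating constant-variance feature ranks first rather
    than producing NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("t-test ranking requires exactly 2 classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 members")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    na, nb = len(a), len(b)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    floored = pooled < 1e-12
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} feature(s) with zero within-class "
            "variance; pooled variance floored at 1e-12"
        )
    pooled = np.maximum(pooled, 1e-12)
    t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(
        pooled * (1.0 / na + 1.0 / nb)
    )
    scores = np.abs(t)
    return RankingResult(scores=scores, order=_stable_order(scores),
                        method="ttest")


def relieff_rank(X: np.ndarray, y: np.ndarray, k: int = 10) -> RankingResult:
    """ReliefF feature weights.

    For every instance, the k nearest hits (same class) and k nearest
    misses (other class) by Euclidean distance on min-max-scaled
    features update each feature's weight by the mean absolute
    difference to the misses minus the mean absolute difference to the
    hits; weights are averaged over all instances.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("ReliefF requires exactly 2 classes")
    if (counts <= k).any():
        small = int(counts.min())
        raise ValueError(
            f"k={k} neighbors requires more than k members per class "
            f"(smallest class has {small}); use k <= {small - 1}"
        )
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    rng_safe = np.where(rng_ > 0, rng_, 1.0)
    Xs = (X - lo) / rng_safe
    n = X.shape[0]
    d2 = np.square(Xs[:, None, :] - Xs[None, :, :]).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    same = y[:, None] == y[None, :]
    w = np.zeros(X.shape[1])
    for i in range(n):
        hits = np.argsort(np.where(same[i], d2[i], np.inf),
                          kind="stable")[:k]
        misses = np.argsort(np.where(~same[i], d2[i], np.inf),
                            kind="stable")[:k]
        diff_hit = np.abs(Xs[hits] - Xs[i]).mean(axis=0)
        diff_miss = np.abs(Xs[misses] - Xs[i]).mean(axis=0)
        w += diff_miss - diff_hit
    w /= n
    return RankingResult(scores=w, order=_stable_order(w), method="relieff")


def _tertile_discretize(X: np.ndarray) -> np.ndarray:
    q = np.quantile(X, [1 / 3, 2 / 3], axis=0)
    return (X > q[0]).astype(int) + (X > q[1]).astype(int)


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (nats) between two discrete label vectors."""
    av, ai = np.unique(a, return_inverse=True)
    bv, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((av.size, bv.size))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank(X: np.ndarray, y: np.ndarray,
              n_select: int | None = None) -> RankingResult:
    """Greedy minimum-redundancy maximum-relevance selection.

    Features are discretized into tertiles; the first pick maximizes
    MI(feature; label), each later pick maximizes
    relevance - mean MI(feature; already-selected).  Deterministic
    (ties broken by feature index).  Unselected features are appended
    in relevance order with score 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    if n_select is None:
        n_select = p
    if n_select > p:
        raise ValueError("n_select exceeds the number of features")
    Xd = _tertile_discretize(X)
    relevance = np.array([_mutual_information(Xd[:, j], y) for j in range(p)])
    selected: list[int] = []
    scores = np.zeros(p)
    remaining = list(range(p))
    red_cache = np.zeros(p)
    for step in range(n_select):
        if not remaining:
            break
        if step == 0:
            crit = relevance.copy()
        else:
            crit = relevance - red_cache / len(selected)
        best = min(remaining, key=lambda j: (-crit[j], j))
        selected.append(best)
        scores[best] = n_select - step  # encode selection rank
        remaining.remove(best)
        for j in remaining:
            red_cache[j] += _mutual_information(Xd[:, j], Xd[:, best])
    rest = sorted(remaining, key=lambda j: (-relevance[j], j))
    order = np.array(selected + rest, dtype=int)
    return RankingResult(scores=scores, order=order, method="mrmr")


_RANKERS = {"ttest": ttest_rank, "relieff": relieff_rank, "mrmr": mrmr_rank}


def rank_features(X, y, method: str, **kw) -> RankingResult:
    try:
        ranker = _RANKERS[method]
    except KeyError:
        raise ValueError(f"unknown selector {method!r}") from None
    return ranker(X, y, **kw)


def _make_classifier(spec: str, seed: int, n_features: int = 1):
    if spec == "svm_rbf":
        # K(a, b) = exp(-||a-b||^2 / s^2); box constraint and kernel
        # scale tuned by seeded search on the training fold only (the
        # unit scale s = 1 is part of the grid).
        d = max(n_features, 1)
        scales = [1.0, 0.5 * np.sqrt(d), np.sqrt(d), 2.0 * np.sqrt(d)]
        grid = {
            "C": np.logspace(-2, 2, 5),
            "gamma": [1.0 / s**2 for s in scales],
        }
        inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        return GridSearchCV(SVC(kernel="rbf"), grid, cv=inner, n_jobs=None)
    if spec == "lda":
        return LinearDiscriminantAnalysis(solver="svd")
    if spec == "knn":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean",
                                    weights="uniform")
    raise ValueError(f"unknown classifier {spec!r}")


def train_predict(
    classifier: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit one classifier on the training fold and predict the test fold.

    Features are standardized with the training-fold mean and standard
    deviation before fitting.
    """
    if np.unique(y_train).size < 2:
        raise ValueError("training fold must contain both classes")
    scaler = StandardScaler().fit(X_train)
    clf = _make_classifier(classifier, seed, n_features=X_train.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LDA collinearity warnings
        clf.fit(scaler.transform(X_train), y_train)
        return clf.predict(scaler.transform(X_test))


def confusion_metrics(tp: int, tn: int, fp: int, fn: int):
    """(accuracy, sensitivity, specificity, F1) in percent.

    A zero denominator yields 0 for that metric, with the flag list
    naming it.
    """
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("empty confusion matrix")
    flags = []

    def _ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / total * 100.0
    sens = _ratio(tp, tp + fn, "sensitivity") * 100.0
    spec = _ratio(tn, tn + fp, "specificity") * 100.0
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1") * 100.0
    return (acc, sens, spec, f1), flags


#: Condition tags treated as the positive class when present.
_POSITIVE_PREFERENCE = ("pleasant", "DT", "high")


def _positive_class(classes, positive=None):
    if positive is not None:
        if positive not in classes:
            raise ValueError(f"positive class {positive!r} not in labels")
        return positive
    for cand in _POSITIVE_PREFERENCE:
        if cand in classes:
            return cand
    return sorted(map(str, classes))[-1]


def repeated_cv(
    fm: FeatureMatrix,
    config: PipelineConfig,
    positive_class=None,
) -> EvalReport:
    """Repeated stratified k-fold evaluation with per-fold selection.

    Per repeat: a seeded stratified fold assignment; inside each
    training fold the configured selector ranks the features and the
    top ``config.n_top_features`` are used; confusion counts accumulate
    over the folds; metrics are computed per repeat and the report's
    means average the repeats.
    """
    X, y = fm.X, np.asarray(fm.y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("evaluation requires exactly 2 classes")
    if (counts < config.cv_folds).any():
        raise ValueError(
            f"each class needs at least cv_folds={config.cv_folds} members"
        )
    pos = _positive_class(classes, positive_class)
    n_top = min(config.n_top_features, X.shape[1])
    rows = []
    all_flags: list[str] = []
    ss = np.random.SeedSequence(config.seed)
    repeat_seeds = ss.generate_state(config.cv_repeats)
    for rep in range(config.cv_repeats):
        rep_seed = int(repeat_seeds[rep] % (2**31 - 1))
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=rep_seed
        )
        tp = tn = fp = fn = 0
        for train_idx, test_idx in skf.split(X, y):
            kw = {}
            if config.selector == "relieff":
                _, tr_counts = np.unique(y[train_idx], return_counts=True)
                kw["k"] = min(10, int(tr_counts.min()) - 1)
            ranking = rank_features(X[train_idx], y[train_idx],
                                    config.selector, **kw)
            cols = ranking.top(n_top)
            pred = train_predict(
                config.classifier,
                X[np.ix_(train_idx, cols)],
                y[train_idx],
                X[np.ix_(test_idx, cols)],
                seed=rep_seed,
            )
            truth = y[test_idx]
            tp += int(((pred == pos) & (truth == pos)).sum())
            tn += int(((pred != pos) & (truth != pos)).sum())
            fp += int(((pred == pos) & (truth != pos)).sum())
            fn += int(((pred != pos) & (truth == pos)).sum())
        (acc, sens, spec, f1), flags = confusion_metrics(tp, tn, fp, fn)
        all_flags.extend(flags)
        rows.append(
            {"accuracy": acc, "sensitivity": sens, "specificity": spec,
             "f1": f1}
        )
    report = EvalReport(
        per_repeat=pd.DataFrame(rows),
        config={
            "selector": config.selector,
            "classifier": config.classifier,
            "cv_folds": config.cv_folds,
            "cv_repeats": config.cv_repeats,
            "n_top_features": n_top,
            "positive_class": str(pos),
        },
        seed=config.seed,
        flags=all_flags,
    )
    return report
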