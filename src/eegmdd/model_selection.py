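"""Stratified k-fold cross-validation, SVM grid search, and sequential
backward selection (SBS) wrapper feature selection.

Cross-validated accuracy is the selection criterion everywhere: the grid
search scans the 200-point (C, gamma) grid {1000, 10000} x {0.0001, 0.0002,
..., 0.0100}, and SBS greedily removes the feature whose removal yields the
highest 5-fold CV accuracy until a single feature remains, reporting the
best subset along the whole trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from .classifiers import LabeledDataset
from .features import FeatureDescriptor


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus hyperparameters.

    kinds: 'knn' (params: k), 'lda' (penalty_ratio, priors, ridge),
    'svm' (C, gamma), 'cksvm' (C, gamma, ne), or 'custom'
    (params: factory -> estimator with fit(X, y)/predict(X)).
    """

    kind: str
    params: tuple = ()

    @classmethod
    def make(cls, kind: str, **params) -> "ClassifierSpec":
        return cls(kind=kind, params=tuple(sorted(params.items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def with_params(self, **updates) -> "ClassifierSpec":
        d = self.param_dict
        d.update(updates)
        return ClassifierSpec.make(self.kind, **d)


def fit_classifier(spec: ClassifierSpec, train: LabeledDataset):
    p = spec.param_dict
    if spec.kind == "knn":
        return clf.knn_fit(train, k=p.get("k", 3))
    if spec.kind == "lda":
        return clf.lda_fit(train, penalty_ratio=p.get("penalty_ratio", 1.0),
                           priors=p.get("priors"), ridge=p.get("ridge"))
    if spec.kind == "svm":
        return clf.svm_fit(train, C=p["C"], gamma=p["gamma"])
    if spec.kind == "cksvm":
        return clf.cksvm_fit(train, C=p["C"], gamma=p["gamma"],
                             ne=p.get("ne", 5))
    if spec.kind == "custom":
        est = p["factory"]()
        est.fit(train.X, train.y)
        return est
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


@dataclass
class CVResult:
    """Per-fold accuracies (percent), their mean +/- std, and the folds."""

    fold_accuracies: list[float]
    seed: int
    fold_assignments: list[np.ndarray]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        if len(self.fold_accuracies) < 2:
            return 0.0
        return float(np.std(self.fold_accuracies, ddof=1))


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment; class counts per fold differ by at
    most one from balance."""
    counts = [int(np.sum(y == lab)) for lab in np.unique(y)]
    if min(counts) < k:
        raise ValueError(f"every class needs at least k={k} members, "
                         f"got counts {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]


def stratified_kfold_cv(data: LabeledDataset, spec: ClassifierSpec,
                        k: int = 5, seed: int = 0,
                        folds: list[np.ndarray] | None = None) -> CVResult:
    """Stratified k-fold CV accuracy of ``spec`` on ``data``.

    Within each iteration the held-out fold never influences training.  The
    same seed always yields the same folds and accuracies.
    """
    if folds is None:
        folds = stratified_folds(data.y, k, seed)
    accs = []
    all_idx = np.arange(data.X.shape[0])
    for test_idx in folds:
        train_mask = np.ones(len(all_idx), bool)
        train_mask[test_idx] = False
        train = LabeledDataset(data.X[train_mask], data.y[train_mask])
        model = fit_classifier(spec, train)
        pred = np.asarray(model.predict(data.X[test_idx]))
        accs.append(100.0 * float(np.mean(pred == data.y[test_idx])))
    return CVResult(fold_accuracies=accs, seed=seed, fold_assignments=folds)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def default_svm_grid() -> list[tuple[float, float]]:
    """C in {1000, 10000} x gamma in 0.0001..0.0100 step 0.0001: 200 points."""
    gammas = [i / 10000.0 for i in range(1, 101)]
    return [(C, g) for C in (1000.0, 10000.0) for g in gammas]


@dataclass
class GridSearchResult:
    grid: list[tuple[float, float]]
    accuracies: list[float]
    best_pair: tuple[float, float]
    best_accuracy: float


def grid_search_svm(data: LabeledDataset,
                    grid: list[tuple[float, float]] | None = None,
                    k: int = 5, seed: int = 0,
                    folds: list[np.ndarray] | None = None) -> GridSearchResult:
    """Mean k-fold CV accuracy for every (C, gamma); ties between pairs are
    broken toward the smallest gamma, then the smallest C."""
    if grid is None:
        grid = default_svm_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if folds is None:
        folds = stratified_folds(data.y, k, seed)
    accs = []
    for C, gamma in grid:
        spec = ClassifierSpec.make("svm", C=C, gamma=gamma)
        accs.append(stratified_kfold_cv(data, spec, k=k, seed=seed,
                                        folds=folds).mean)
    best = max(range(len(grid)),
               key=lambda i: (accs[i], -grid[i][1], -grid[i][0]))
    return GridSearchResult(grid=list(grid), accuracies=accs,
                            best_pair=grid[best], best_accuracy=accs[best])


# ---------------------------------------------------------------------------
# Sequential backward selection
# ---------------------------------------------------------------------------

@dataclass
class SBSStep:
    """One point of the SBS trace (step 0 is the initial full set)."""

    step: int
    removed_index: int | None  # canonical column index of the discarded feature
    subset: tuple[int, ...]    # surviving canonical column indices
    cv_mean: float
    cv_std: float
    hyperparams: tuple = ()


@dataclass
class SBSTrace:
    steps: list[SBSStep]
    descriptors: list | None = None
    seed: int = 0

    @property
    def optimal_step(self) -> SBSStep:
        """Highest CV accuracy over the whole trace; accuracy ties prefer
        the smaller subset (parsimony)."""
        return max(self.steps,
                   key=lambda s: (s.cv_mean, -len(s.subset)))

    @property
    def optimal_subset(self) -> tuple[int, ...]:
        return self.optimal_step.subset

    def removed_descriptor(self, step: SBSStep):
        if step.removed_index is None or self.descriptors is None:
            return None
        return self.descriptors[step.removed_index]


class _FastLDACV:
    """Incremental per-fold LDA statistics for the SBS inner loop.

    Holds, per fold, the class means, the pooled covariance of the current
    feature subset and its (possibly ridged) inverse P.  Every
    single-feature-removal candidate is then scored in O(s) from P via the
    Schur complement: removing feature j turns w = P d into
    w' = (P d - P[:, j] (P d)_j / P_jj) restricted to the surviving rows,
    and committing a removal downdates P in O(s^2).  The inverse is
    refreshed from scratch periodically to stop round-off accumulation.

    Matches lda_fit with default parameters (empirical priors, penalty
    ratio 1); if the full-pool covariance is not positive definite a ridge
    of 1e-6 * trace/d is applied and kept for the whole trace.
    """

    REFRESH_EVERY = 48

    def __init__(self, data: LabeledDataset, folds: list[np.ndarray]):
        self.n_features = data.X.shape[1]
        self.cols = np.arange(self.n_features)
        self.fold_stats = []
        self._since_refresh = 0
        all_idx = np.arange(data.X.shape[0])
        for test_idx in folds:
            train_mask = np.ones(len(all_idx), bool)
            train_mask[test_idx] = False
            X, y = data.X[train_mask], data.y[train_mask]
            Xp, Xn = X[y == clf.POSITIVE], X[y == clf.NEGATIVE]
            mp, mn = Xp.mean(axis=0), Xn.mean(axis=0)
            cov = ((Xp - mp).T @ (Xp - mp) + (Xn - mn).T @ (Xn - mn)) \
                / (X.shape[0] - 2)
            prior_term = np.log((len(y) - np.sum(y == clf.POSITIVE))
                                / np.sum(y == clf.POSITIVE))
            st = {
                "mp": mp, "mn": mn, "cov": cov, "prior": prior_term,
                "Xt": data.X[test_idx], "yt": data.y[test_idx],
            }
            self.fold_stats.append(st)
        self._refresh()

    def _invert(self, st) -> np.ndarray:
        sub = st["cov"][np.ix_(self.cols, self.cols)]
        d = len(self.cols)
        try:
            factor = cho_factor(sub)
            P = cho_solve(factor, np.eye(d))
            if not np.all(np.isfinite(P)):
                raise LinAlgError
            return P
        except (LinAlgError, np.linalg.LinAlgError):
            eps = 1e-6 * np.trace(sub) / d
            return cho_solve(cho_factor(sub + eps * np.eye(d)), np.eye(d))

    def _refresh(self) -> None:
        for st in self.fold_stats:
            st["P"] = self._invert(st)
        self._since_refresh = 0

    @staticmethod
    def _acc(scores: np.ndarray, yt: np.ndarray) -> np.ndarray:
        pred = np.where(scores > 0, clf.POSITIVE, clf.NEGATIVE)
        return 100.0 * np.mean(pred == yt[:, None], axis=0)

    def evaluate_current(self) -> tuple[float, float]:
        accs = []
        for st in self.fold_stats:
            c = self.cols
            diff = st["mp"][c] - st["mn"][c]
            w = st["P"] @ diff
            bias = -0.5 * w @ (st["mp"][c] + st["mn"][c]) - st["prior"]
            scores = st["Xt"][:, c] @ w + bias
            accs.append(self._acc(scores[:, None], st["yt"])[0])
        return (float(np.mean(accs)),
                float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0)

    def evaluate_removals(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean and std of CV accuracy for every single-feature removal of
        the current subset, vectorized over candidates."""
        c = self.cols
        per_fold = []
        for st in self.fold_stats:
            P = st["P"]
            diff = st["mp"][c] - st["mn"][c]
            msum = st["mp"][c] + st["mn"][c]
            Pd = P @ diff
            dg = np.diag(P).copy()
            # column j of W is the candidate weight vector after removing j
            # (its j-th row is dropped implicitly via the corrections below)
            W = Pd[:, None] - P * (Pd / dg)[None, :]
            Xt = st["Xt"][:, c]
            wdiag = np.diag(W)  # ~0 up to round-off; subtracted for exactness
            scores = Xt @ W - Xt * wdiag[None, :]
            bias = -0.5 * (msum @ W - msum * wdiag) - st["prior"]
            per_fold.append(self._acc(scores + bias[None, :], st["yt"]))
        A = np.vstack(per_fold)  # folds x candidates
        means = A.mean(axis=0)
        stds = A.std(axis=0, ddof=1) if A.shape[0] > 1 else np.zeros(A.shape[1])
        return means, stds

    def remove(self, pos: int) -> None:
        """Commit the removal of the feature at position ``pos`` of the
        current subset."""
        self.cols = np.delete(self.cols, pos)
        self._since_refresh += 1
        if self._since_refresh >= self.REFRESH_EVERY or len(self.cols) <= 2:
            self._refresh()
            return
        for st in self.fold_stats:
            P = st["P"]
            pj = P[:, pos]
            P = P - np.outer(pj, P[pos, :]) / P[pos, pos]
            st["P"] = np.delete(np.delete(P, pos, axis=0), pos, axis=1)


def sbs_select(data: LabeledDataset, spec: ClassifierSpec, k: int = 5,
               seed: int = 0, reoptimize: bool = False,
               descriptors: list | None = None,
               min_size: int = 1) -> SBSTrace:
    """Greedy sequential backward elimination.

    At each subset size every remaining feature is removed in turn, the
    reduced subset is scored by stratified k-fold CV, and the feature whose
    removal yields the highest accuracy is discarded; ties discard the
    feature with the larger canonical column index.  The trace records the
    initial full-set evaluation plus one discard event per size down to
    ``min_size``; the optimal subset is the accuracy argmax over the trace.

    With ``reoptimize`` and an SVM spec, the (C, gamma) grid search is rerun
    once per subset size on the current best subset and the winning pair is
    used for that size's evaluations.
    """
    n_feat = data.X.shape[1]
    if n_feat < 2:
        raise ValueError("SBS needs at least two features")
    if not np.all(np.isfinite(data.X)):
        raise ValueError("feature values must be finite")
    folds = stratified_folds(data.y, k, seed)

    use_fast_lda = spec.kind == "lda" and not spec.param_dict
    fast = _FastLDACV(data, folds) if use_fast_lda else None

    def evaluate(cols: tuple[int, ...], cur_spec: ClassifierSpec):
        sub = LabeledDataset(data.X[:, np.array(cols)], data.y)
        res = stratified_kfold_cv(sub, cur_spec, k=k, seed=seed, folds=folds)
        return res.mean, res.std

    current: tuple[int, ...] = tuple(range(n_feat))
    cur_spec = spec
    steps: list[SBSStep] = []
    if reoptimize and spec.kind == "svm":
        cur_spec = _regrid(data, current, spec, k, seed, folds)
    mean, std = fast.evaluate_current() if fast is not None \
        else evaluate(current, cur_spec)
    steps.append(SBSStep(0, None, current, mean, std, cur_spec.params))

    step_no = 0
    while len(current) > min_size:
        step_no += 1
        if reoptimize and spec.kind == "svm":
            cur_spec = _regrid(data, current, spec, k, seed, folds)
        if fast is not None:
            means, stds = fast.evaluate_removals()
            # ties discard the larger canonical index: since the subset is
            # kept in ascending order, the last argmax wins
            best_pos = int(len(means) - 1 - np.argmax(means[::-1]))
            best_acc, best_std = float(means[best_pos]), float(stds[best_pos])
            fast.remove(best_pos)
        else:
            best_acc, best_std, best_pos = -np.inf, 0.0, None
            for pos, col in enumerate(current):
                cand = current[:pos] + current[pos + 1:]
                mean, std = evaluate(cand, cur_spec)
                if mean >= best_acc:
                    best_acc, best_std, best_pos = mean, std, pos
        removed = current[best_pos]
        current = current[:best_pos] + current[best_pos + 1:]
        steps.append(SBSStep(step_no, removed, current, best_acc, best_std,
                             cur_spec.params))
    return SBSTrace(steps=steps, descriptors=descriptors, seed=seed)


def _regrid(data, cols, spec, k, seed, folds) -> ClassifierSpec:
    sub = LabeledDataset(data.X[:, np.array(cols)], data.y)
    res = grid_search_svm(sub, k=k, seed=seed, folds=folds)
    return spec.with_params(C=res.best_pair[0], gamma=res.best_pair[1])
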