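"""Binary MDD-vs-HC classifiers: K-NN, LDA, Gaussian-kernel soft-margin SVM,
and the conformal-kernel SVM (CK-SVM).

Labels are +1 for MDD and -1 for HC throughout; every decision function
predicts MDD iff its score is strictly positive.

The CK-SVM retrains the SVM under a conformally transformed kernel
K~(a, b) = c(a) c(b) K(a, b), where the conformal factor

    c(x) = sum_{x_i in T} exp(-||phi(x) - phi(x_i)||^2 / tau_i)

magnifies feature-space resolution near the anchor set T: the support
vectors within the margin (SVWM), i.e., support vectors whose decision value
lies in [-1, +1].  tau_i is the mean squared feature-space distance from
anchor i to its ne nearest anchors.  Under the Gaussian kernel
||phi(a) - phi(b)||^2 = 2 - 2 K(a, b) and K(x, x) = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

POSITIVE, NEGATIVE = 1, -1


@dataclass
class LabeledDataset:
    """Feature vectors with +1/-1 labels and optional subject identifiers."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")
        if not set(np.unique(self.y)) <= {POSITIVE, NEGATIVE}:
            raise ValueError("labels must be +1 (MDD) or -1 (HC)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature values must be finite")

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise ValueError("training set must contain both classes")


def dataset_from_table(table) -> LabeledDataset:
    """Build a LabeledDataset from a FeatureTable (MDD -> +1, HC -> -1)."""
    mapping = {"MDD": POSITIVE, "HC": NEGATIVE}
    try:
        y = np.array([mapping[c] for c in table.class_labels])
    except KeyError as err:
        raise ValueError(f"cannot train on class label {err}") from None
    return LabeledDataset(table.values, y, subject_ids=list(table.subject_ids))


# ---------------------------------------------------------------------------
# K-NN
# ---------------------------------------------------------------------------

def knn_predict(train: LabeledDataset, x: np.ndarray, k: int = 3) -> int:
    """Majority vote among the K nearest training points (Euclidean metric).

    Distance ties at the K-th neighbor are resolved by training-set order
    (stable sort); a tied vote falls to the nearest neighbor's label.
    """
    if train.X.shape[0] == 0:
        raise ValueError("empty training set")
    if k > train.X.shape[0]:
        raise ValueError(f"K={k} exceeds training size {train.X.shape[0]}")
    x = np.asarray(x, dtype=float).ravel()
    dists = np.linalg.norm(train.X - x, axis=1)
    order = np.argsort(dists, kind="stable")[:k]
    votes = train.y[order].sum()
    if votes > 0:
        return POSITIVE
    if votes < 0:
        return NEGATIVE
    return int(train.y[order[0]])


@dataclass
class KNNModel:
    train: LabeledDataset
    k: int = 3
    train_subject_ids: list[str] | None = None

    def decision(self, x: np.ndarray) -> float:
        return float(knn_predict(self.train, x, self.k))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([knn_predict(self.train, row, self.k) for row in X])


def knn_fit(train: LabeledDataset, k: int = 3) -> KNNModel:
    train.require_both_classes()
    return KNNModel(train=train, k=k, train_subject_ids=train.subject_ids)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Fisher/Bayes linear discriminant with cost-sensitive bias.

    score(x) = w.x + b with w = Sigma^-1 (m_MDD - m_HC) and the bias placed
    so that with equal priors and penalties the boundary passes through the
    midpoint of the class means; the term -ln(penalty_ratio * p_HC / p_MDD)
    shifts it, where penalty_ratio = C_MDD / C_HC.
    """

    weight: np.ndarray
    bias: float
    mean_mdd: np.ndarray
    mean_hc: np.ndarray
    covariance: np.ndarray
    penalty_ratio: float = 1.0
    priors: tuple[float, float] = (0.5, 0.5)  # (p_MDD, p_HC)
    ridge: float = 0.0
    train_subject_ids: list[str] | None = None

    def decision(self, x: np.ndarray) -> float:
        return float(np.asarray(x, dtype=float).ravel() @ self.weight + self.bias)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = X @ self.weight + self.bias
        return np.where(scores > 0, POSITIVE, NEGATIVE)


def _pooled_covariance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    parts = []
    dofs = 0
    for label in (POSITIVE, NEGATIVE):
        Xi = X[y == label]
        mi = Xi.mean(axis=0)
        parts.append((Xi - mi).T @ (Xi - mi))
        dofs += Xi.shape[0] - 1
    if dofs < 1:
        raise ValueError("need at least two samples per class for a covariance")
    return (parts[0] + parts[1]) / dofs


def lda_fit(train: LabeledDataset, penalty_ratio: float = 1.0,
            priors: tuple[float, float] | None = None,
            ridge: float | None = None) -> LDAModel:
    """Fit the linear discriminant.

    ``priors`` defaults to the empirical class proportions.  If the pooled
    covariance is singular (e.g., more features than samples) a ridge
    eps = 1e-6 * trace(Sigma)/n is added; pass ``ridge`` explicitly to
    control the amount, or 0 to forbid regularization.
    """
    train.require_both_classes()
    X, y = train.X, train.y
    m_mdd = X[y == POSITIVE].mean(axis=0)
    m_hc = X[y == NEGATIVE].mean(axis=0)
    cov = _pooled_covariance(X, y)
    if priors is None:
        p_mdd = float(np.mean(y == POSITIVE))
        priors = (p_mdd, 1.0 - p_mdd)
    n = X.shape[1]
    used_ridge = 0.0
    diff = m_mdd - m_hc

    def _solve(c):
        factor = cho_factor(c)
        return cho_solve(factor, diff)

    try:
        if ridge:
            raise LinAlgError
        w = _solve(cov)
        if not np.all(np.isfinite(w)):
            raise LinAlgError
    except (LinAlgError, np.linalg.LinAlgError):
        if ridge == 0:
            raise ValueError("singular pooled covariance and ridge disabled")
        used_ridge = ridge if ridge is not None else 1e-6 * np.trace(cov) / n
        w = _solve(cov + used_ridge * np.eye(n))
    bias = float(-0.5 * w @ (m_mdd + m_hc)
                 - np.log(penalty_ratio * priors[1] / priors[0]))
    return LDAModel(weight=w, bias=bias, mean_mdd=m_mdd, mean_hc=m_hc,
                    covariance=cov, penalty_ratio=penalty_ratio, priors=priors,
                    ridge=used_ridge, train_subject_ids=train.subject_ids)


def lda_decision(model: LDAModel, x: np.ndarray) -> float:
    return model.decision(x)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

def gaussian_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """K(a, b) = exp(-gamma ||a - b||^2); K(x, x) = 1."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    return np.exp(-gamma * cdist(A, B, "sqeuclidean"))


@dataclass
class SVMModel:
    """Soft-margin Gaussian-kernel SVM solution.

    ``dual_coef`` stores alpha_i * y_i for the support vectors, so the
    decision function is D(x) = sum_i dual_coef_i K(sv_i, x) + bias.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    sv_labels: np.ndarray
    bias: float
    C: float
    gamma: float
    train_subject_ids: list[str] | None = None

    @property
    def alphas(self) -> np.ndarray:
        return self.dual_coef * self.sv_labels

    def decision_many(self, X: np.ndarray) -> np.ndarray:
        K = gaussian_kernel(X, self.support_vectors, self.gamma)
        return K @ self.dual_coef + self.bias

    def decision(self, x: np.ndarray) -> float:
        return float(self.decision_many(np.atleast_2d(x))[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_many(np.atleast_2d(X)) > 0,
                        POSITIVE, NEGATIVE)


def svm_fit(train: LabeledDataset, C: float, gamma: float,
            tol: float = 1e-8) -> SVMModel:
    """Solve the soft-margin dual (libsvm via scikit-learn) with the
    Gaussian kernel."""
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    train.require_both_classes()
    svc = SVC(C=C, kernel="rbf", gamma=gamma, tol=tol)
    svc.fit(train.X, train.y)
    return SVMModel(
        support_vectors=train.X[svc.support_].copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        sv_labels=train.y[svc.support_].copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        gamma=gamma,
        train_subject_ids=train.subject_ids,
    )


def svm_decision(model: SVMModel, x: np.ndarray) -> float:
    return model.decision(x)


def svwm(model: SVMModel, train: LabeledDataset | None = None) -> np.ndarray:
    """Support vectors within the margin: SVs with |D(x)| <= 1.

    Returns the anchor vectors (rows).  May be empty when every support
    vector is a bounded SV outside the margin.
    """
    scores = model.decision_many(model.support_vectors)
    mask = np.abs(scores) <= 1.0 + 1e-9
    return model.support_vectors[mask]


# ---------------------------------------------------------------------------
# CK-SVM
# ---------------------------------------------------------------------------

@dataclass
class CKSVMModel:
    """Conformal-kernel SVM: base SVM plus the retrained dual under K~."""

    base: SVMModel
    anchors: np.ndarray
    tau: np.ndarray  # per-anchor squared-distance scale, > 0
    ne: int
    c_train: np.ndarray
    sv2_vectors: np.ndarray
    sv2_dual_coef: np.ndarray
    sv2_c: np.ndarray  # conformal factors of the retrained SVs
    bias2: float
    train_subject_ids: list[str] | None = None

    @property
    def C(self) -> float:
        return self.base.C

    @property
    def gamma(self) -> float:
        return self.base.gamma

    def conformal_factor_many(self, X: np.ndarray) -> np.ndarray:
        K = gaussian_kernel(X, self.anchors, self.base.gamma)
        d2 = 2.0 - 2.0 * K  # squared feature-space distance
        return np.exp(-d2 / self.tau).sum(axis=1)

    def decision_many(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cx = self.conformal_factor_many(X)
        K = gaussian_kernel(X, self.sv2_vectors, self.base.gamma)
        Kt = cx[:, None] * self.sv2_c[None, :] * K
        return Kt @ self.sv2_dual_coef + self.bias2

    def decision(self, x: np.ndarray) -> float:
        return float(self.decision_many(np.atleast_2d(x))[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_many(np.atleast_2d(X)) > 0,
                        POSITIVE, NEGATIVE)


def anchor_scales(anchors: np.ndarray, gamma: float, ne: int = 5) -> np.ndarray:
    """tau_i = mean of the ne smallest positive squared feature-space
    distances from anchor i to the other anchors.

    Zero distances (duplicate anchors) are skipped; with fewer than ne other
    anchors all available ones are used.  A lone anchor falls back to the
    unit-sphere scale tau = 2 (the feature-space diameter bound).
    """
    K = gaussian_kernel(anchors, anchors, gamma)
    d2 = 2.0 - 2.0 * K
    n = anchors.shape[0]
    tau = np.empty(n)
    for i in range(n):
        others = np.delete(d2[i], i)
        pos = np.sort(others[others > 1e-15])
        if pos.size == 0:
            tau[i] = 2.0
        else:
            tau[i] = float(pos[: min(ne, pos.size)].mean())
    return tau


def conformal_factor(x: np.ndarray, model: CKSVMModel) -> float:
    """c(x) = sum over anchors of exp(-||phi(x) - phi(x_i)||^2 / tau_i);
    strictly positive, and >= 1 when x coincides with an anchor."""
    return float(model.conformal_factor_many(np.atleast_2d(x))[0])


def conformal_kernel(a: np.ndarray, b: np.ndarray, model: CKSVMModel) -> float:
    """K~(a, b) = c(a) c(b) K(a, b)."""
    a2, b2 = np.atleast_2d(a), np.atleast_2d(b)
    ca = model.conformal_factor_many(a2)[0]
    cb = model.conformal_factor_many(b2)[0]
    return float(ca * cb * gaussian_kernel(a2, b2, model.base.gamma)[0, 0])


def cksvm_fit(train: LabeledDataset, C: float, gamma: float, ne: int = 5,
              tol: float = 1e-8,
              conformal_fn=None) -> CKSVMModel:
    """Two-step CK-SVM training.

    Step 1 trains the base Gaussian SVM at the given (C, gamma); no second
    hyperparameter search is performed.  Step 2 builds the SVWM anchor set
    and per-anchor scales, then retrains the SVM on the same training set
    with the conformal kernel K~ at the same (C, gamma).  If the SVWM is
    empty the anchor set falls back to all support vectors (with a warning).

    ``conformal_fn`` (mapping an (m, n) array to m factors) overrides the
    conformal factor; it exists for validation (c == 1 must reproduce the
    base SVM) and experimentation.
    """
    base = svm_fit(train, C, gamma, tol=tol)
    anchors = svwm(base)
    if anchors.shape[0] == 0:
        warnings.warn("empty SVWM anchor set; falling back to all support "
                      "vectors", RuntimeWarning, stacklevel=2)
        anchors = base.support_vectors
    tau = anchor_scales(anchors, gamma, ne=ne)

    placeholder = CKSVMModel(
        base=base, anchors=anchors, tau=tau, ne=ne,
        c_train=np.ones(train.X.shape[0]), sv2_vectors=np.empty((0, train.n)),
        sv2_dual_coef=np.empty(0), sv2_c=np.empty(0), bias2=0.0,
    )
    if conformal_fn is None:
        conformal_fn = placeholder.conformal_factor_many
    c_train = np.asarray(conformal_fn(train.X), dtype=float)
    if np.any(c_train <= 0):
        raise ValueError("conformal factors must be strictly positive")

    K = gaussian_kernel(train.X, train.X, gamma)
    Kt = c_train[:, None] * c_train[None, :] * K
    svc = SVC(C=C, kernel="precomputed", tol=tol)
    svc.fit(Kt, train.y)
    sv_idx = svc.support_
    model = CKSVMModel(
        base=base,
        anchors=anchors,
        tau=tau,
        ne=ne,
        c_train=c_train,
        sv2_vectors=train.X[sv_idx].copy(),
        sv2_dual_coef=svc.dual_coef_[0].copy(),
        sv2_c=c_train[sv_idx].copy(),
        bias2=float(svc.intercept_[0]),
        train_subject_ids=train.subject_ids,
    )
    if conformal_fn is not placeholder.conformal_factor_many:
        # keep the override active at prediction time
        model.conformal_factor_many = conformal_fn  # type: ignore[method-assign]
    return model


def cksvm_decision(model: CKSVMModel, x: np.ndarray) -> float:
    return model.decision(x)
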