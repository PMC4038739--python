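"""Polynomial-kernel soft-margin SVM trained by sequential minimal
optimization (SMO), one-vs-one multiclass voting, and a small
information-gain decision tree.

The SVM solves the usual dual problem

    max_a  sum_k a_k - 1/2 sum_kl a_k a_l y_k y_l K(x_k, x_l)
    s.t.   0 <= a_k <= C,   sum_k a_k y_k = 0

with the homogeneous polynomial kernel K(x, y) = <x, y>^p (an optional
constant offset turns it into the inhomogeneous variant).  SMO optimizes
one pair of dual variables at a time in closed form, which keeps the
solver dependency-free and exact at convergence: every returned model
satisfies the box constraints, the equality constraint, and the KKT
conditions to ``kkt_tol``.

Features are standardized (zero mean, unit variance) by default before the
kernel is applied; the statistics are learned from the training set only
and stored with the model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ContractError, DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


def polynomial_kernel(
    X: np.ndarray, Y: np.ndarray, degree: int, coef0: float = 0.0
) -> np.ndarray:
    """Gram matrix (<x, y> + coef0)^degree for row vectors of X and Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ContractError(f"feature lengths differ: {X.shape[1]} vs {Y.shape[1]}")
    return (X @ Y.T + coef0) ** degree


def kernel(x: np.ndarray, y: np.ndarray, degree: int, coef0: float = 0.0) -> float:
    """Scalar kernel value between two feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ContractError(f"feature lengths differ: {x.shape} vs {y.shape}")
    return float((np.dot(x, y) + coef0) ** degree)


@dataclass(frozen=True)
class SVMConfig:
    degree: int = 1
    C: float = 1.0
    coef0: float = 0.0  # 0 -> homogeneous kernel, the documented default
    kkt_tol: float = 1e-3
    max_passes: int = 200
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValidationError("kernel degree must be >= 1")
        if self.C <= 0:
            raise ValidationError("C must be positive")
        if self.kkt_tol <= 0:
            raise ValidationError("kkt_tol must be positive")


@dataclass
class SVMModel:
    """Trained binary SVM.  ``class_labels[0]`` maps to +1; a decision value
    of exactly zero predicts ``class_labels[0]`` (logged)."""

    support_vectors: np.ndarray  # (m, d), already standardized if applicable
    dual_coef: np.ndarray  # alpha_k * y_k, only alpha_k > 0 kept
    bias: float
    config: SVMConfig
    class_labels: tuple[str, str] = ("+1", "-1")
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    n_features: int = 0
    # training-set diagnostics (not serialized)
    train_alpha: np.ndarray | None = None
    train_y: np.ndarray | None = None

    def _transform(self, x: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(x, dtype=float))
        if X.shape[1] != self.n_features:
            raise ContractError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_std
        return X

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        X = self._transform(x)
        K = polynomial_kernel(
            X, self.support_vectors, self.config.degree, self.config.coef0
        )
        return K @ self.dual_coef + self.bias


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)  # constant features pass through centred
    return (X - mean) / std, mean, std


def _smo_solve(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float,
    max_passes: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """SMO on a precomputed kernel matrix.

    Working pairs are chosen by the maximal-violating-pair rule: among
    points still allowed to move up (respectively down) along the equality
    constraint, pick the two with the largest mutual KKT violation, then
    update that pair of dual variables in closed form.  Convergence is
    declared when the largest violation drops below ``tol``; ``max_passes``
    bounds the number of pair updates at ``max_passes * n``.

    Returns the dual variables and the bias of ``f(x) = sum a_k y_k K + b``.
    The rng breaks exact ties in pair selection.
    """
    n = len(y)
    alpha = np.zeros(n)
    G = np.zeros(n)  # K @ (alpha * y), maintained incrementally
    eps = 1e-12
    eps_b = 1e-10
    converged = False
    last_pair = (None, None)

    for _ in range(max_passes * n):
        yg = y - G  # candidate bias per point: exact for free SVs
        up = ((y > 0) & (alpha < C - eps_b)) | ((y < 0) & (alpha > eps_b))
        low = ((y > 0) & (alpha > eps_b)) | ((y < 0) & (alpha < C - eps_b))
        if not up.any() or not low.any():
            converged = True
            break
        up_idx = np.where(up)[0]
        low_idx = np.where(low)[0]
        i1 = int(up_idx[np.argmax(yg[up_idx])])
        i2 = int(low_idx[np.argmin(yg[low_idx])])
        gap = yg[i1] - yg[i2]
        if gap < tol:
            converged = True
            break
        if i1 == i2:
            break
        last_pair = (i1, i2)

        a1, a2 = alpha[i1], alpha[i2]
        y1, y2 = y[i1], y[i2]
        E1, E2 = G[i1] - y1, G[i2] - y2
        s = y1 * y2
        if s > 0:
            L, H = max(0.0, a1 + a2 - C), min(C, a1 + a2)
        else:
            L, H = max(0.0, a2 - a1), min(C, C + a2 - a1)
        if H - L < eps:
            break
        k11, k12, k22 = K[i1, i1], K[i1, i2], K[i2, i2]
        eta = k11 + k22 - 2.0 * k12
        if eta > eps:
            a2_new = min(max(a2 + y2 * (E1 - E2) / eta, L), H)
        else:
            # flat direction: move to the end with the lower dual objective
            # (the bias contribution cancels along the feasible direction)
            f1 = y1 * E1 - a1 * k11 - s * a2 * k12
            f2 = y2 * E2 - s * a1 * k12 - a2 * k22
            L1 = a1 + s * (a2 - L)
            H1 = a1 + s * (a2 - H)
            obj_L = (
                L1 * f1 + L * f2 + 0.5 * L1**2 * k11 + 0.5 * L**2 * k22 + s * L * L1 * k12
            )
            obj_H = (
                H1 * f1 + H * f2 + 0.5 * H1**2 * k11 + 0.5 * H**2 * k22 + s * H * H1 * k12
            )
            if obj_L < obj_H - eps:
                a2_new = L
            elif obj_H < obj_L - eps:
                a2_new = H
            else:
                break
        if abs(a2_new - a2) < eps * (a2_new + a2 + eps):
            break
        a1_new = min(max(a1 + s * (a2 - a2_new), 0.0), C)  # guard rounding drift
        G += K[:, i1] * (y1 * (a1_new - a1)) + K[:, i2] * (y2 * (a2_new - a2))
        alpha[i1], alpha[i2] = a1_new, a2_new
    else:
        logger.warning(
            "SMO stopped at the %d-update cap without clean convergence",
            max_passes * n,
        )

    yg = y - G
    free = (alpha > eps_b) & (alpha < C - eps_b)
    if free.any():
        b = float(np.mean(yg[free]))
    else:
        up = ((y > 0) & (alpha < C - eps_b)) | ((y < 0) & (alpha > eps_b))
        low = ((y > 0) & (alpha > eps_b)) | ((y < 0) & (alpha < C - eps_b))
        hi = np.max(yg[up]) if up.any() else np.min(yg[low])
        lo = np.min(yg[low]) if low.any() else hi
        b = float(0.5 * (hi + lo))
    if not converged:
        logger.debug("SMO exit without meeting tol; last pair %s", last_pair)
    return alpha, b


def train_svm_smo(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SVMConfig = SVMConfig(),
    class_labels: tuple[str, str] = ("+1", "-1"),
) -> SVMModel:
    """Train a binary SVM; ``y`` holds +/-1 (class_labels[0] == +1)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValidationError("X must be (n, d) with one label per row")
    if X.shape[0] < 2:
        raise DegenerateDataError("need at least 2 training samples")
    uniq = set(np.unique(y).tolist())
    if uniq != {-1.0, 1.0}:
        raise DegenerateDataError(f"labels must contain both classes, got {sorted(uniq)}")

    mean = std = None
    Xw = X
    if cfg.standardize:
        Xw, mean, std = _standardize_fit(X)
    K = polynomial_kernel(Xw, Xw, cfg.degree, cfg.coef0)
    rng = np.random.default_rng(cfg.seed)
    alpha, b = _smo_solve(K, y, cfg.C, cfg.kkt_tol, cfg.max_passes, rng)

    sv = alpha > 1e-10
    model = SVMModel(
        support_vectors=Xw[sv].copy(),
        dual_coef=(alpha * y)[sv].copy(),
        bias=b,  # f(x) = sum_k a_k y_k K(s_k, x) + bias
        config=cfg,
        class_labels=class_labels,
        scaler_mean=mean,
        scaler_std=std,
        n_features=X.shape[1],
        train_alpha=alpha,
        train_y=y,
    )
    return model


def kkt_violations(model: SVMModel, X: np.ndarray, y: np.ndarray) -> float:
    """Largest KKT violation of the trained model on its training set
    (0 means exact optimality; compare against ``cfg.kkt_tol``).  Also
    covers the equality constraint |sum alpha_k y_k|.
    """
    if model.train_alpha is None or model.train_y is None:
        raise ContractError("model carries no training diagnostics")
    f = model.decision_function(X)
    margins = np.asarray(y, dtype=float) * f
    alpha = model.train_alpha
    C = model.config.C
    viol = abs(float(np.dot(alpha, model.train_y)))
    for i in range(len(margins)):
        a = alpha[i]
        if a < 1e-10:
            if margins[i] < 1.0:
                viol = max(viol, 1.0 - margins[i])
        elif a > C - 1e-10:
            if margins[i] > 1.0:
                viol = max(viol, margins[i] - 1.0)
        else:
            viol = max(viol, abs(margins[i] - 1.0))
    return float(viol)


def predict(model: SVMModel, x: np.ndarray) -> tuple[str, float]:
    """Predict one sample; returns (label, decision value).  A decision
    value of exactly 0 goes to the first class label (logged)."""
    val = float(model.decision_function(np.atleast_2d(x))[0])
    if val == 0.0:
        logger.info("decision value exactly 0; tie broken to %s", model.class_labels[0])
        return model.class_labels[0], val
    return (model.class_labels[0] if val > 0 else model.class_labels[1]), val


def fit_binary(
    X: np.ndarray, labels: list[str] | np.ndarray, cfg: SVMConfig = SVMConfig()
) -> SVMModel:
    """String-label convenience wrapper; classes ordered by first appearance
    is avoided in favour of sorted order so results don't depend on sample
    order."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise DegenerateDataError(f"need exactly 2 classes, got {classes}")
    y = np.where(labels == classes[0], 1.0, -1.0)
    return train_svm_smo(X, y, cfg, class_labels=(classes[0], classes[1]))


@dataclass
class MulticlassModel:
    """One-vs-one ensemble: one binary SVM per unordered class pair."""

    classes: tuple[str, ...]
    pairwise_models: dict[tuple[str, str], SVMModel]


def train_multiclass(
    X: np.ndarray, labels: list[str] | np.ndarray, cfg: SVMConfig = SVMConfig()
) -> MulticlassModel:
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise DegenerateDataError("need at least 2 classes")
    models: dict[tuple[str, str], SVMModel] = {}
    for a_i in range(len(classes)):
        for b_i in range(a_i + 1, len(classes)):
            a, b = classes[a_i], classes[b_i]
            sel = (labels == a) | (labels == b)
            models[(a, b)] = fit_binary(X[sel], labels[sel], cfg)
    return MulticlassModel(classes=classes, pairwise_models=models)


def predict_multiclass(model: MulticlassModel, x: np.ndarray) -> str:
    """Majority vote across pairwise models; ties broken by largest summed
    |decision value|, then class order (logged)."""
    votes = {c: 0 for c in model.classes}
    weight = {c: 0.0 for c in model.classes}
    for (a, b), m in model.pairwise_models.items():
        lab, val = predict(m, x)
        votes[lab] += 1
        weight[lab] += abs(val)
    best = max(votes.values())
    tied = [c for c in model.classes if votes[c] == best]
    if len(tied) == 1:
        return tied[0]
    logger.info("multiclass vote tie between %s; using decision magnitudes", tied)
    best_w = max(weight[c] for c in tied)
    tied_w = [c for c in tied if weight[c] == best_w]
    return tied_w[0]


# ---------------------------------------------------------------------------
# model serialization


def model_to_json(model: SVMModel, path: str | Path, feature_hash: str = "") -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kind": "svm_binary",
        "class_labels": list(model.class_labels),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "bias": model.bias,
        "n_features": model.n_features,
        "scaler_mean": None if model.scaler_mean is None else model.scaler_mean.tolist(),
        "scaler_std": None if model.scaler_std is None else model.scaler_std.tolist(),
        "config": {
            "degree": model.config.degree,
            "C": model.config.C,
            "coef0": model.config.coef0,
            "kkt_tol": model.config.kkt_tol,
            "max_passes": model.config.max_passes,
            "standardize": model.config.standardize,
            "seed": model.config.seed,
        },
        "feature_index_hash": feature_hash,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def model_from_json(path: str | Path) -> SVMModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValidationError(f"unsupported model schema {doc.get('schema_version')}")
    cfg = SVMConfig(**doc["config"])
    return SVMModel(
        support_vectors=np.asarray(doc["support_vectors"], dtype=float),
        dual_coef=np.asarray(doc["dual_coef"], dtype=float),
        bias=float(doc["bias"]),
        config=cfg,
        class_labels=tuple(doc["class_labels"]),
        scaler_mean=None
        if doc["scaler_mean"] is None
        else np.asarray(doc["scaler_mean"], dtype=float),
        scaler_std=None
        if doc["scaler_std"] is None
        else np.asarray(doc["scaler_std"], dtype=float),
        n_features=int(doc["n_features"]),
    )


# ---------------------------------------------------------------------------
# information-gain decision tree


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


@dataclass
class TreeNode:
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None  # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.label is not None


@dataclass
class TreeModel:
    root: TreeNode
    min_leaf: int = 1

    def predict_one(self, x: np.ndarray) -> str:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.label


def _majority(labels: np.ndarray) -> str:
    classes, counts = np.unique(labels, return_counts=True)
    return str(classes[np.argmax(counts)])  # np.unique sorts -> first label wins ties


def _best_split(X: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Exhaustive (feature, midpoint-threshold) search maximizing information
    gain; returns (gain, feature, threshold)."""
    n, d = X.shape
    h0 = _entropy(y)
    best = (0.0, -1, 0.0)
    for j in range(d):
        vals = np.unique(X[:, j])
        if len(vals) < 2:
            continue
        for t in (vals[:-1] + vals[1:]) / 2.0:
            left = X[:, j] <= t
            nl = int(left.sum())
            gain = h0 - (nl / n) * _entropy(y[left]) - ((n - nl) / n) * _entropy(y[~left])
            if gain > best[0] + 1e-12:
                best = (gain, j, float(t))
    return best


def _lookahead_split(X: np.ndarray, y: np.ndarray) -> tuple[int, float] | None:
    """When no single split gains information (e.g. an XOR pattern), pick
    the split whose children gain most in a one-step lookahead."""
    n, d = X.shape
    best_score, best = 0.0, None
    for j in range(d):
        vals = np.unique(X[:, j])
        for t in (vals[:-1] + vals[1:]) / 2.0:
            left = X[:, j] <= t
            nl = int(left.sum())
            if nl == 0 or nl == n:
                continue
            gl, _, _ = _best_split(X[left], y[left])
            gr, _, _ = _best_split(X[~left], y[~left])
            score = (nl / n) * gl + ((n - nl) / n) * gr
            if score > best_score + 1e-12:
                best_score, best = score, (j, float(t))
    return best


def train_decision_tree(
    X: np.ndarray, labels: list[str] | np.ndarray, min_leaf: int = 1
) -> TreeModel:
    """Greedy binary tree splitting on maximum information gain; stops on
    pure nodes, zero-gain nodes (after a one-step lookahead), or nodes
    smaller than ``2 * min_leaf``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)

    def build(idx: np.ndarray) -> TreeNode:
        ys = y[idx]
        if len(np.unique(ys)) == 1 or len(idx) < 2 * min_leaf:
            return TreeNode(label=_majority(ys))
        gain, j, t = _best_split(X[idx], ys)
        if j < 0 or gain <= 0:
            found = _lookahead_split(X[idx], ys)
            if found is None:
                return TreeNode(label=_majority(ys))
            j, t = found
        left = idx[X[idx, j] <= t]
        right = idx[X[idx, j] > t]
        if len(left) < min_leaf or len(right) < min_leaf:
            return TreeNode(label=_majority(ys))
        return TreeNode(feature=j, threshold=t, left=build(left), right=build(right))

    return TreeModel(root=build(np.arange(len(y))), min_leaf=min_leaf)
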