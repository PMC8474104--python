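"""Trained genotype predictors on probe intensities.

The multinomial regression model (MRM) is a softmax classifier with the
heterozygote as reference class: per non-reference class g a linear score
l_g = a_g + sum_k (b_gk x_k + c_gk y_k + d_gk x_k y_k), so that
p(het) = 1/(1 + e^{l_hom} + e^{l_norm}), p(hom) = e^{l_hom}/(...),
p(norm) = e^{l_norm}/(...). Fitting maximizes the ridge-penalized
log-likelihood.

CART grows a binary tree by exhaustive Gini-minimizing splits, with growth
stopped at nodes of fewer than five individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import minimize

# genotype codes: 0 = WT/norm, 1 = het (MRM reference class), 2 = hom-del
REFERENCE_CLASS = 1
NONREF_CLASSES = (2, 0)  # order of the two linear predictors (hom, norm)


class FitError(ValueError):
    """Training data cannot support a fit (e.g. a class is absent)."""


@dataclass
class MRMModel:
    feature_names: list[str]
    coef_hom: np.ndarray       # intercept followed by per-feature coefficients
    coef_norm: np.ndarray
    ridge: float
    iterations: int
    final_loglik: float
    converged: bool
    reference_class: int = REFERENCE_CLASS

    def to_dict(self) -> dict[str, Any]:
        return {
            "type": "mrm",
            "reference_class": self.reference_class,
            "feature_names": list(self.feature_names),
            "coef_hom": [float(v) for v in self.coef_hom],
            "coef_norm": [float(v) for v in self.coef_norm],
            "ridge": self.ridge,
            "iterations": self.iterations,
            "final_loglik": self.final_loglik,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MRMModel":
        return cls(feature_names=list(d["feature_names"]),
                   coef_hom=np.asarray(d["coef_hom"], float),
                   coef_norm=np.asarray(d["coef_norm"], float),
                   ridge=float(d["ridge"]), iterations=int(d["iterations"]),
                   final_loglik=float(d["final_loglik"]), converged=bool(d["converged"]),
                   reference_class=int(d.get("reference_class", REFERENCE_CLASS)))


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def _class_probabilities(Xd: np.ndarray, coef_hom: np.ndarray,
                         coef_norm: np.ndarray) -> np.ndarray:
    """(n, 3) probabilities ordered by genotype code (WT, het, hom)."""
    l_hom = Xd @ coef_hom
    l_norm = Xd @ coef_norm
    logits = np.column_stack([l_norm, np.zeros(len(Xd)), l_hom])  # codes 0,1,2
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def fit_mrm(train_features: np.ndarray, train_labels: np.ndarray,
            feature_names: list[str] | None = None, ridge: float = 1e-4,
            tol: float = 1e-8, max_iter: int = 500) -> MRMModel:
    """Ridge-penalized multinomial fit (het as reference class)."""
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    present = set(np.unique(y))
    if present != {0, 1, 2}:
        raise FitError(f"all three genotype classes required in training data; got {sorted(present)}")
    if feature_names is None:
        feature_names = [f"f{k}" for k in range(X.shape[1])]
    Xd = _design(X)
    n, p1 = Xd.shape
    Y = np.zeros((n, 3))
    Y[np.arange(n), y] = 1.0
    penalty_mask = np.ones(p1)
    penalty_mask[0] = 0.0  # intercepts unpenalized

    def unpack(theta):
        return theta[:p1], theta[p1:]

    def objective(theta):
        ch, cn = unpack(theta)
        P = _class_probabilities(Xd, ch, cn)
        ll = np.sum(Y * np.log(np.clip(P, 1e-300, None)))
        pen = 0.5 * ridge * (np.sum((ch * penalty_mask) ** 2) + np.sum((cn * penalty_mask) ** 2))
        # gradient of -ll + pen w.r.t. each coefficient block
        resid_hom = P[:, 2] - Y[:, 2]
        resid_norm = P[:, 0] - Y[:, 0]
        g_hom = Xd.T @ resid_hom + ridge * ch * penalty_mask
        g_norm = Xd.T @ resid_norm + ridge * cn * penalty_mask
        return -ll + pen, np.concatenate([g_hom, g_norm])

    theta0 = np.zeros(2 * p1)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10})
    if not res.success:
        warnings.warn(f"MRM fit did not converge: {res.message}", stacklevel=2)
    ch, cn = unpack(res.x)
    P = _class_probabilities(Xd, ch, cn)
    final_ll = float(np.sum(Y * np.log(np.clip(P, 1e-300, None))))
    return MRMModel(feature_names=list(feature_names), coef_hom=ch, coef_norm=cn,
                    ridge=ridge, iterations=int(res.nit), final_loglik=final_ll,
                    converged=bool(res.success))


def predict_mrm(model: MRMModel, features: np.ndarray,
                feature_names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (n,3; columns = genotype codes 0,1,2) and argmax
    calls with ties broken toward the lowest genotype code."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise FitError(f"feature count {X.shape[1] if X.ndim == 2 else '?'} does not match "
                       f"model ({len(model.feature_names)})")
    if feature_names is not None and list(feature_names) != list(model.feature_names):
        raise FitError("feature names do not match the trained model")
    P = _class_probabilities(_design(X), model.coef_hom, model.coef_norm)
    calls = np.argmax(P, axis=1).astype(np.int8)  # first max = lowest code
    return P, calls


# ------------------------------------------------------------------- CART

@dataclass
class CARTNode:
    n: int
    class_counts: np.ndarray
    feature: int | None = None
    threshold: float | None = None
    left: "CARTNode | None" = None
    right: "CARTNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def majority(self) -> int:
        return int(np.argmax(self.class_counts))  # ties -> lowest code

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"n": self.n, "class_counts": [int(c) for c in self.class_counts]}
        if not self.is_leaf:
            d.update(feature=self.feature, threshold=self.threshold,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


@dataclass
class CARTModel:
    root: CARTNode
    feature_names: list[str]
    min_node_size: int = 5

    def to_dict(self) -> dict[str, Any]:
        return {"type": "cart", "min_node_size": self.min_node_size,
                "feature_names": list(self.feature_names), "tree": self.root.to_dict()}


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(X: np.ndarray, y: np.ndarray) -> tuple[int, float, float] | None:
    """Exhaustive (feature, midpoint-threshold) search minimizing weighted Gini."""
    n, p = X.shape
    counts_total = np.bincount(y, minlength=3)
    parent = _gini(counts_total)
    best: tuple[float, int, float] | None = None
    for f in range(p):
        order = np.argsort(X[:, f], kind="stable")
        xs, ys = X[order, f], y[order]
        onehot = np.zeros((n, 3))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        distinct = np.nonzero(np.diff(xs) > 0)[0]  # split after index i
        for i in distinct:
            left = cum[i]
            right = counts_total - left
            nl, nr = i + 1, n - i - 1
            score = (nl * _gini(left) + nr * _gini(right)) / n
            if best is None or score < best[0] - 1e-15:
                best = (score, f, float((xs[i] + xs[i + 1]) / 2.0))
    if best is None or best[0] >= parent - 1e-12:
        return None
    return best[1], best[2], best[0]


def _grow(X: np.ndarray, y: np.ndarray, min_node_size: int) -> CARTNode:
    counts = np.bincount(y, minlength=3)
    node = CARTNode(n=len(y), class_counts=counts)
    if len(y) < min_node_size or _gini(counts) == 0.0:
        return node
    split = _best_split(X, y)
    if split is None:
        return node
    f, t, _ = split
    mask = X[:, f] <= t
    node.feature, node.threshold = f, t
    node.left = _grow(X[mask], y[mask], min_node_size)
    node.right = _grow(X[~mask], y[~mask], min_node_size)
    return node


def fit_cart(train_features: np.ndarray, train_labels: np.ndarray,
             feature_names: list[str] | None = None, min_node_size: int = 5) -> CARTModel:
    """Greedy Gini tree; nodes with fewer than min_node_size samples are leaves."""
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if set(np.unique(y)) != {0, 1, 2}:
        raise FitError("all three genotype classes required in training data")
    if feature_names is None:
        feature_names = [f"f{k}" for k in range(X.shape[1])]
    return CARTModel(root=_grow(X, y, min_node_size), feature_names=list(feature_names),
                     min_node_size=min_node_size)


def predict_cart(model: CARTModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise FitError("feature count does not match the trained tree")
    out = np.empty(len(X), dtype=np.int8)
    for i, row in enumerate(X):
        node = model.root
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        out[i] = node.majority()
    return out


# ------------------------------------------------- bootstrap training study

@dataclass
class TrainingCurve:
    sizes: list[int]
    reps: int
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    mean_sensitivity: dict         # class -> array over sizes
    sd_sensitivity: dict
    mean_ppv: dict
    sd_ppv: dict
    resampled_draws: int = 0

    def plateau_size(self) -> int:
        """Smallest n whose mean accuracy is within 1 SD of the largest n's."""
        target = self.mean_accuracy[-1] - self.sd_accuracy[-1]
        for n, acc in zip(self.sizes, self.mean_accuracy):
            if acc >= target:
                return int(n)
        return int(self.sizes[-1])


def _per_class_rates(truth: np.ndarray, calls: np.ndarray) -> tuple[dict, dict]:
    sens, ppv = {}, {}
    for c in (0, 1, 2):
        tp = np.sum((truth == c) & (calls == c))
        sens[c] = tp / max(np.sum(truth == c), 1) if np.any(truth == c) else np.nan
        ppv[c] = tp / max(np.sum(calls == c), 1) if np.any(calls == c) else np.nan
    return sens, ppv


def bootstrap_training_curve(features: np.ndarray, labels: np.ndarray,
                             method: str = "mrm",
                             sizes=(50, 100, 200, 500), reps: int = 1000,
                             seed: int = 0, **fit_kwargs) -> TrainingCurve:
    """Random training subsets of each size; fit, predict the held-out rest,
    aggregate per-class sensitivity/PPV and accuracy over replicates.

    Draws missing a genotype class are rejected and redrawn (counted)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_total = len(y)
    sizes = [int(s) for s in sizes]
    if max(sizes) > n_total - 50:
        raise ValueError("largest training size leaves fewer than 50 held-out samples")
    rng = np.random.default_rng(seed)
    fit = {"mrm": fit_mrm, "cart": fit_cart}[method]

    acc = np.zeros((len(sizes), reps))
    sens = {c: np.full((len(sizes), reps), np.nan) for c in (0, 1, 2)}
    ppv = {c: np.full((len(sizes), reps), np.nan) for c in (0, 1, 2)}
    resampled = 0
    for si, n in enumerate(sizes):
        for r in range(reps):
            for _ in range(100):
                idx = rng.choice(n_total, size=n, replace=False)
                if len(np.unique(y[idx])) == 3:
                    break
                resampled += 1
            else:
                raise FitError("could not draw a training set containing all classes")
            holdout = np.setdiff1d(np.arange(n_total), idx)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit(X[idx], y[idx], **fit_kwargs)
            if method == "mrm":
                _, calls = predict_mrm(model, X[holdout])
            else:
                calls = predict_cart(model, X[holdout])
            truth = y[holdout]
            acc[si, r] = np.mean(calls == truth)
            s_r, p_r = _per_class_rates(truth, calls)
            for c in (0, 1, 2):
                sens[c][si, r] = s_r[c]
                ppv[c][si, r] = p_r[c]
    return TrainingCurve(
        sizes=sizes, reps=reps,
        mean_accuracy=acc.mean(axis=1), sd_accuracy=acc.std(axis=1, ddof=1) if reps > 1 else np.zeros(len(sizes)),
        mean_sensitivity={c: np.nanmean(sens[c], axis=1) for c in (0, 1, 2)},
        sd_sensitivity={c: np.nanstd(sens[c], axis=1, ddof=1) if reps > 1 else np.zeros(len(sizes))
                        for c in (0, 1, 2)},
        mean_ppv={c: np.nanmean(ppv[c], axis=1) for c in (0, 1, 2)},
        sd_ppv={c: np.nanstd(ppv[c], axis=1, ddof=1) if reps > 1 else np.zeros(len(sizes))
                for c in (0, 1, 2)},
        resampled_draws=resampled)


# -------------------------------------------------------------------- ROC

@dataclass
class ROCCurve:
    genotype: int
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curves(class_probabilities: np.ndarray, truth: np.ndarray) -> dict[int, ROCCurve]:
    """One-vs-rest ROC per genotype class; AUC by trapezoid over all
    probability thresholds."""
    P = np.asarray(class_probabilities, dtype=float)
    y = np.asarray(truth, dtype=int)
    out = {}
    for c in (0, 1, 2):
        pos = (y == c)
        if pos.all() or not pos.any():
            raise ValueError(f"ROC undefined: truth contains a single class for genotype {c}")
        scores = P[:, c]
        order = np.argsort(-scores, kind="stable")
        tp = np.cumsum(pos[order])
        fp = np.cumsum(~pos[order])
        # collapse tied thresholds
        distinct = np.nonzero(np.diff(scores[order]) != 0)[0]
        keep = np.concatenate([distinct, [len(scores) - 1]])
        tpr = np.concatenate([[0.0], tp[keep] / pos.sum()])
        fpr = np.concatenate([[0.0], fp[keep] / (~pos).sum()])
        auc = float(np.trapezoid(tpr, fpr))
        out[c] = ROCCurve(genotype=c, fpr=fpr, tpr=tpr, auc=auc)
    return out
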