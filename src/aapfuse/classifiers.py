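"""Base classifiers and the average-probability fusion model.

Three base learners are provided, each exposing ``fit(X, y)`` and
``predict_proba_pos(X)`` (probability of the positive class):

* :class:`GaussianNB` — naive Bayes with per-class, per-feature Gaussian
  densities; maximum-likelihood means/variances with a variance floor.
* :class:`LogisticRegressionIRLS` — logistic regression fitted by
  iteratively reweighted least squares with a small ridge penalty that
  keeps weights finite even on separable data.
* :class:`NearestNeighbor` — 1-NN with Euclidean distance; emits hard
  0/1 pseudo-probabilities (its ROC is a single point).

The fusion model pairs the base classifier with the best cross-validated
sensitivity with the one with the best specificity and scores a sample by
the arithmetic mean of their positive-class probabilities; the label is
positive iff the fused probability is >= the decision threshold (default
0.5, with the boundary mapped to positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .bpb import BpBModel


class ProbClassifier(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "ProbClassifier": ...
    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray: ...


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes 0 and 1")
    return X, y


def _as_matrix(model_dim: int, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model_dim:
        raise ValueError(
            f"feature dimension mismatch: model expects {model_dim}, got {X.shape[1]}"
        )
    return X


class GaussianNB:
    """Gaussian naive Bayes with a relative variance floor.

    Variances below ``1e-9 * max(feature variance)`` (or an absolute 1e-9
    when all variances are zero) are raised to that floor, so constant
    features degrade gracefully to contributing equally to both classes.
    """

    def __init__(self) -> None:
        self.priors_: Optional[np.ndarray] = None
        self.means_: Optional[np.ndarray] = None
        self.vars_: Optional[np.ndarray] = None
        self.variance_floor_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNB":
        X, y = _check_xy(X, y)
        for cls in (0, 1):
            if np.sum(y == cls) < 2:
                raise ValueError(f"class {cls} needs >= 2 samples")
        self.priors_ = np.asarray([np.mean(y == 0), np.mean(y == 1)])
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
        self.vars_ = np.stack([X[y == c].var(axis=0) for c in (0, 1)])
        max_var = float(self.vars_.max())
        self.variance_floor_ = 1e-9 * max_var if max_var > 0 else 1e-9
        self.vars_ = np.maximum(self.vars_, self.variance_floor_)
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise ValueError("classifier is not fitted")
        X = _as_matrix(self.means_.shape[1], X)
        # log joint per class, computed in the log domain to avoid underflow
        log_joint = np.empty((X.shape[0], 2))
        for c in (0, 1):
            z = (X - self.means_[c]) ** 2 / self.vars_[c]
            log_like = -0.5 * (z + np.log(2 * np.pi * self.vars_[c])).sum(axis=1)
            log_joint[:, c] = np.log(self.priors_[c]) + log_like
        log_norm = logsumexp(log_joint, axis=1)
        return np.exp(log_joint[:, 1] - log_norm)


class LogisticRegressionIRLS:
    """Binary logistic regression via IRLS with an L2 ridge on the slopes.

    The intercept is unpenalised.  Convergence: max absolute weight change
    below ``tol`` (default 1e-8) or ``max_iter`` (default 100) iterations.
    """

    def __init__(self, ridge: float = 1e-8, max_iter: int = 100, tol: float = 1e-8):
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol
        self.weights_: Optional[np.ndarray] = None  # [intercept, slopes...]
        self.converged_: bool = False
        self.n_iterations_: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticRegressionIRLS":
        X, y = _check_xy(X, y)
        n, d = X.shape
        A = np.hstack([np.ones((n, 1)), X])
        w = np.zeros(d + 1)
        penalty = np.full(d + 1, self.ridge)
        penalty[0] = 0.0
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            eta = A @ w
            p = expit(eta)
            # IRLS working weights; clipped so the normal matrix stays SPD
            s = np.clip(p * (1 - p), 1e-10, None)
            grad = A.T @ (y - p) - penalty * w
            H = (A * s[:, None]).T @ A + np.diag(penalty)
            step = np.linalg.solve(H, grad)
            w = w + step
            self.n_iterations_ = it
            if np.max(np.abs(step)) < self.tol:
                self.converged_ = True
                break
        if not np.isfinite(w).all():
            raise FloatingPointError("IRLS produced non-finite weights")
        self.weights_ = w
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise ValueError("classifier is not fitted")
        X = _as_matrix(len(self.weights_) - 1, X)
        return expit(self.weights_[0] + X @ self.weights_[1:])


class NearestNeighbor:
    """1-nearest-neighbour classifier; distance ties go to the lowest
    training index, and probabilities are hard 0/1."""

    def __init__(self) -> None:
        self.X_: Optional[np.ndarray] = None
        self.y_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestNeighbor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("training set is empty")
        self.X_, self.y_ = X, y
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        if self.X_ is None:
            raise ValueError("classifier is not fitted")
        X = _as_matrix(self.X_.shape[1], X)
        out = np.empty(len(X))
        for i, x in enumerate(X):
            d2 = ((self.X_ - x) ** 2).sum(axis=1)
            out[i] = float(self.y_[int(np.argmin(d2))])
        return out


CLASSIFIER_REGISTRY = {
    "nb": GaussianNB,
    "lr": LogisticRegressionIRLS,
    "nna": NearestNeighbor,
}


def make_classifier(name: str) -> ProbClassifier:
    try:
        return CLASSIFIER_REGISTRY[name]()
    except KeyError:
        raise ValueError(
            f"unknown classifier {name!r}; known: {sorted(CLASSIFIER_REGISTRY)}"
        ) from None


def select_base_pair(
    candidates: Sequence[tuple[str, float, float]],
) -> tuple[str, str]:
    """Choose the (best-sensitivity, best-specificity) classifier pair.

    ``candidates`` is an ordered sequence of ``(name, sn, sp)``.  Ties go
    to the earlier candidate.  If one classifier wins both criteria, the
    runner-up on specificity is taken so the pair is distinct.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate classifiers")
    names = [c[0] for c in candidates]
    sn = np.asarray([c[1] for c in candidates], dtype=float)
    sp = np.asarray([c[2] for c in candidates], dtype=float)
    best_sn = int(np.argmax(sn))
    best_sp = int(np.argmax(sp))
    if best_sn == best_sp:
        sp_rest = sp.copy()
        sp_rest[best_sn] = -np.inf
        best_sp = int(np.argmax(sp_rest))
    return names[best_sn], names[best_sp]


@dataclass
class FusionModel:
    """Two trained base classifiers fused by averaging probabilities.

    ``base_a`` is the best-sensitivity base, ``base_b`` the
    best-specificity base.  ``feature_indices`` selects columns of the
    full encoded matrix; ``bpb_model`` carries the fitted terminal
    posterior tables when the BpB encoder is part of the pipeline, and
    ``feature_names`` records the full encoded column order the model
    expects before selection.
    """

    base_a: ProbClassifier
    base_b: ProbClassifier
    base_a_name: str
    base_b_name: str
    feature_indices: np.ndarray
    feature_names: list[str]
    threshold: float = 0.5
    bpb_model: Optional[BpBModel] = None
    encoders: list[str] = field(default_factory=lambda: ["bpb"])

    def fuse_predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fused probability and hard label for already-selected features."""
        p_a = self.base_a.predict_proba_pos(X)
        p_b = self.base_b.predict_proba_pos(X)
        fused = (p_a + p_b) / 2.0
        labels = (fused >= self.threshold).astype(int)
        return fused, labels

    # -- plain-text serialization ------------------------------------------

    def _base_state(self, clf: ProbClassifier) -> dict:
        if isinstance(clf, GaussianNB):
            return {
                "priors": clf.priors_.tolist(),
                "means": clf.means_.tolist(),
                "vars": clf.vars_.tolist(),
                "variance_floor": clf.variance_floor_,
            }
        if isinstance(clf, LogisticRegressionIRLS):
            return {
                "weights": clf.weights_.tolist(),
                "ridge": clf.ridge,
                "converged": clf.converged_,
                "n_iterations": clf.n_iterations_,
            }
        if isinstance(clf, NearestNeighbor):
            return {"X": clf.X_.tolist(), "y": clf.y_.tolist()}
        raise TypeError(f"cannot serialize {type(clf).__name__}")

    @staticmethod
    def _restore_base(name: str, state: dict) -> ProbClassifier:
        clf = make_classifier(name)
        if isinstance(clf, GaussianNB):
            clf.priors_ = np.asarray(state["priors"])
            clf.means_ = np.asarray(state["means"])
            clf.vars_ = np.asarray(state["vars"])
            clf.variance_floor_ = state["variance_floor"]
        elif isinstance(clf, LogisticRegressionIRLS):
            clf.weights_ = np.asarray(state["weights"])
            clf.ridge = state["ridge"]
            clf.converged_ = state["converged"]
            clf.n_iterations_ = state["n_iterations"]
        elif isinstance(clf, NearestNeighbor):
            clf.X_ = np.asarray(state["X"], dtype=float)
            clf.y_ = np.asarray(state["y"], dtype=int)
        return clf

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "aapfuse-fusion-1",
            "base_a": {"name": self.base_a_name, "state": self._base_state(self.base_a)},
            "base_b": {"name": self.base_b_name, "state": self._base_state(self.base_b)},
            "feature_indices": np.asarray(self.feature_indices).tolist(),
            "feature_names": self.feature_names,
            "threshold": self.threshold,
            "encoders": self.encoders,
            "bpb": None,
        }
        if self.bpb_model is not None:
            payload["bpb"] = {
                "m": self.bpb_model.m,
                "pseudocount": self.bpb_model.pseudocount,
                "alphabet": self.bpb_model.alphabet,
                "tables": {k: v.tolist() for k, v in self.bpb_model.tables.items()},
            }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "aapfuse-fusion-1":
            raise ValueError(f"{path}: not an aapfuse fusion model file")
        bpb_model = None
        if payload["bpb"] is not None:
            b = payload["bpb"]
            bpb_model = BpBModel(
                m=int(b["m"]),
                pseudocount=float(b["pseudocount"]),
                tables={k: np.asarray(v, float) for k, v in b["tables"].items()},
                alphabet=b["alphabet"],
            )
        return cls(
            base_a=cls._restore_base(payload["base_a"]["name"], payload["base_a"]["state"]),
            base_b=cls._restore_base(payload["base_b"]["name"], payload["base_b"]["state"]),
            base_a_name=payload["base_a"]["name"],
            base_b_name=payload["base_b"]["name"],
            feature_indices=np.asarray(payload["feature_indices"], dtype=int),
            feature_names=list(payload["feature_names"]),
            threshold=float(payload["threshold"]),
            bpb_model=bpb_model,
            encoders=list(payload["encoders"]),
        )
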