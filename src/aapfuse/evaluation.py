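"""Cross-validated evaluation: confusion metrics, ROC/AUC, fold layout.

Performance is reported from a single confusion matrix pooled over all
cross-validation folds (micro-averaging), which is stable for fold sizes
of ~20 samples; per-fold metrics are kept alongside for inspection.

Metrics
-------
Sensitivity ``Sn = TP / (TP + FN)``, specificity ``Sp = TN / (TN + FP)``,
accuracy ``Acc = (TP + TN) / total`` and Matthews correlation

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)),

with MCC defined as 0 (and a warning) when any factor of the denominator
vanishes.  The ROC curve sweeps the decision threshold over all distinct
scores with ties grouped; AUC is the trapezoidal area, which equals the
Mann–Whitney pair-counting statistic with half credit for tied scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn import metrics as _skm

from .classifiers import make_classifier
from .peptide_io import PeptideDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("all confusion counts are zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """Return (Sn, Sp, Acc, MCC) from pooled confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC denominator is zero; reporting MCC = 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / sqrt(denom)
    return sn, sp, acc, mcc


def stratified_folds(
    y: np.ndarray, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified partition into k folds of (train, test) indices.

    Each class is shuffled with its own seeded draw and dealt round-robin,
    so per-class counts across folds differ by at most one.  ``k`` may go
    up to the total sample count (leave-one-out), in which case small
    folds can lack one class.
    """
    y = np.asarray(y)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    offset = 0  # rotate the deal across classes so remainders spread out
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_of[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    folds = []
    for f in range(k):
        test = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        folds.append((train, test))
    return folds


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) and trapezoidal AUC from pooled scores."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _skm.roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_skm.auc(fpr, tpr))


@dataclass
class EvalReport:
    """Pooled cross-validation result of one pipeline configuration."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    roc: np.ndarray
    auc: float
    fold_seed: int
    pair: tuple[str, str]
    per_fold: list[dict] = field(default_factory=list)
    scores: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    ids: Optional[list[str]] = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": {
                "tp": self.counts.tp, "tn": self.counts.tn,
                "fp": self.counts.fp, "fn": self.counts.fn,
            },
            "sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc,
            "auc": self.auc,
            "fold_seed": self.fold_seed,
            "pair": list(self.pair),
            "per_fold": self.per_fold,
            "roc": np.asarray(self.roc).tolist(),
            "extras": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.extras.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    def scores_tsv(self, path: str | Path) -> None:
        """Write pooled per-sample scores (id, label, fused score)."""
        if self.scores is None or self.labels is None or self.ids is None:
            raise ValueError("report carries no pooled scores")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tlabel\tfused_score\n")
            for i, lab, s in zip(self.ids, self.labels, self.scores):
                fh.write(f"{i}\t{lab}\t{s:.10g}\n")


def pair_cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    pair: tuple[str, str],
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> float:
    """Pooled k-fold accuracy of the average-probability fusion of a pair.

    This is the evaluator behind incremental feature selection; features
    are taken as given (no per-fold re-encoding).
    """
    y = np.asarray(y)
    correct = 0
    for train, test in stratified_folds(y, k=k, seed=seed):
        if len(test) == 0 or len(np.unique(y[train])) < 2:
            continue
        p = np.zeros(len(test))
        for name in pair:
            clf = make_classifier(name).fit(X[train], y[train])
            p += clf.predict_proba_pos(X[test])
        pred = (p / len(pair) >= threshold).astype(int)
        correct += int(np.sum(pred == y[test]))
    return correct / len(y)


def classifier_cv_metrics(
    X: np.ndarray, y: np.ndarray, name: str, k: int = 10, seed: int = 0
) -> tuple[float, float, float]:
    """Pooled (Sn, Sp, Acc) of a single classifier under k-fold CV."""
    y = np.asarray(y)
    pred = np.empty(len(y), dtype=int)
    for train, test in stratified_folds(y, k=k, seed=seed):
        clf = make_classifier(name).fit(X[train], y[train])
        pred[test] = (clf.predict_proba_pos(X[test]) >= 0.5).astype(int)
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )
    sn, sp, acc, _ = confusion_metrics(counts)
    return sn, sp, acc


def cross_validate(dataset: PeptideDataset, config) -> EvalReport:
    """Evaluate the configured fusion pipeline by stratified k-fold CV.

    Per fold: fit BpB tables (on the training fold by default), encode
    both splits, apply the configured feature selection, train both base
    classifiers on the training fold, and score the test fold.  Test-fold
    predictions are pooled into one confusion matrix and one score list.
    """
    from . import bpb as bpb_mod
    from .pipeline import PipelineConfig, encode_features, run_selection, _resolve_pair

    if not isinstance(config, PipelineConfig):
        raise TypeError("config must be a PipelineConfig")
    y = dataset.labels()
    n = len(y)

    full_bpb = None
    if "bpb" in config.encoders and config.bpb_refit == "full":
        full_bpb = bpb_mod.fit_bpb(dataset, m=config.m, pseudocount=config.pseudocount)

    selected: Optional[np.ndarray] = None
    extras: dict = {}
    if config.feature_indices is not None:
        selected = np.asarray(config.feature_indices, dtype=int)
    elif config.selection == "full":
        X_full_df, _ = encode_features(dataset, config, bpb_model=full_bpb)
        relief, ifs = run_selection(X_full_df.to_numpy(), y, config)
        selected = np.asarray(ifs.selected, dtype=int)
        extras.update(
            ifs_curve=ifs.curve, chosen_k=ifs.chosen_k,
            relief_weights=relief.weights, relief_ranking=relief.ranking,
            selected=selected,
        )

    scores = np.empty(n)
    pred = np.empty(n, dtype=int)
    per_fold: list[dict] = []
    pair_used: tuple[str, str] = ("?", "?")
    for fold_id, (train, test) in enumerate(
        stratified_folds(y, k=config.k, seed=config.seed)
    ):
        if len(test) == 0:
            continue
        train_ds = dataset.subset(train)
        bpb_model = full_bpb
        if "bpb" in config.encoders and config.bpb_refit == "fold":
            bpb_model = bpb_mod.fit_bpb(
                train_ds, m=config.m, pseudocount=config.pseudocount
            )
        X_tr_df, _ = encode_features(train_ds, config, bpb_model=bpb_model)
        X_te_df, _ = encode_features(
            dataset.subset(test), config, bpb_model=bpb_model
        )
        X_tr, X_te = X_tr_df.to_numpy(), X_te_df.to_numpy()

        fold_sel = selected
        if config.selection == "nested":
            _, ifs = run_selection(X_tr, y[train], config)
            fold_sel = np.asarray(ifs.selected, dtype=int)
        if fold_sel is not None:
            X_tr, X_te = X_tr[:, fold_sel], X_te[:, fold_sel]

        pair = _resolve_pair(X_tr, y[train], config)
        pair_used = pair
        p = np.zeros(len(test))
        for name in pair:
            clf = make_classifier(name).fit(X_tr, y[train])
            p += clf.predict_proba_pos(X_te)
        p /= len(pair)
        scores[test] = p
        pred[test] = (p >= config.threshold).astype(int)
        per_fold.append(
            {
                "fold": fold_id,
                "n_test": int(len(test)),
                "acc": float(np.mean(pred[test] == y[test])),
            }
        )

    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )
    sn, sp, acc, mcc = confusion_metrics(counts)
    roc, auc = roc_auc(scores, y)
    return EvalReport(
        counts=counts, sn=sn, sp=sp, acc=acc, mcc=mcc,
        roc=roc, auc=auc, fold_seed=config.seed, pair=pair_used,
        per_fold=per_fold, scores=scores, labels=y, ids=dataset.ids,
        extras=extras,
    )
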