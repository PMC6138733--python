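"""End-to-end prediction pipeline: encode → select → fuse.

A :class:`PipelineConfig` names the encoders, the feature-selection
protocol, the base-classifier pair and the cross-validation layout; the
functions here turn a labelled dataset into feature matrices, a trained
:class:`~aapfuse.classifiers.FusionModel`, and per-sequence predictions.

Two protocol choices matter for how optimistic the resulting estimates
are, and both are explicit in the config:

* ``bpb_refit`` — ``"fold"`` (default) refits the terminal posterior
  tables on each training fold only; ``"full"`` fits them once on the
  whole dataset before cross-validation, which leaks test-fold labels
  into the encoding but mirrors the simplest single-fit workflow.
* ``selection`` — ``None`` uses all features; ``"full"`` runs
  Relief + IFS once on the full dataset and then cross-validates on the
  chosen subset (the classical, slightly optimistic protocol);
  ``"nested"`` re-runs selection inside every training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bpb as bpb_mod
from . import ctd as ctd_mod
from . import dft as dft_mod
from .classifiers import (
    CLASSIFIER_REGISTRY,
    FusionModel,
    make_classifier,
    select_base_pair,
)
from .peptide_io import PeptideDataset, ValidationError
from .relief import ifs_select, relief_rank

KNOWN_ENCODERS = ("bpb", "ctd", "dft")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a training or evaluation run."""

    encoders: tuple[str, ...] = ("bpb",)
    m: int = 10                      #: BpB terminal window length
    pseudocount: float = 1.0         #: BpB add-k smoothing
    n_freq: int = 10                 #: DFT low-frequency components per scale
    center_profiles: bool = False    #: zero-mean DFT profiles (kills DC)
    classifier_pair: tuple[str, str] | str = ("lr", "nb")  #: (best-Sn, best-Sp) or "auto"
    k: int = 10                      #: cross-validation folds
    seed: int = 0                    #: master seed for folds and Relief
    bpb_refit: str = "fold"          #: "fold" or "full"
    selection: Optional[str] = None  #: None, "full" or "nested"
    relief_n_iter: int | str = "all"
    threshold: float = 0.5
    feature_indices: Optional[np.ndarray] = None  #: explicit column subset

    def __post_init__(self) -> None:
        for enc in self.encoders:
            if enc not in KNOWN_ENCODERS:
                raise ValueError(f"unknown encoder {enc!r}; known: {KNOWN_ENCODERS}")
        if not self.encoders:
            raise ValueError("at least one encoder is required")
        if self.bpb_refit not in ("fold", "full"):
            raise ValueError("bpb_refit must be 'fold' or 'full'")
        if self.selection not in (None, "full", "nested"):
            raise ValueError("selection must be None, 'full' or 'nested'")
        if isinstance(self.classifier_pair, str):
            if self.classifier_pair != "auto":
                raise ValueError("classifier_pair must be a (name, name) pair or 'auto'")
        else:
            for name in self.classifier_pair:
                if name not in CLASSIFIER_REGISTRY:
                    raise ValueError(
                        f"unknown classifier {name!r}; known: {sorted(CLASSIFIER_REGISTRY)}"
                    )


def encode_features(
    dataset: PeptideDataset,
    config: PipelineConfig,
    bpb_model: Optional[bpb_mod.BpBModel] = None,
    fit_on: Optional[PeptideDataset] = None,
) -> tuple[pd.DataFrame, Optional[bpb_mod.BpBModel]]:
    """Encode a dataset with the configured encoders, in fixed order.

    When the BpB encoder is active and no fitted model is passed, tables
    are fitted on ``fit_on`` (defaults to ``dataset`` itself, which then
    must be labelled).
    """
    blocks: list[pd.DataFrame] = []
    for enc in config.encoders:
        if enc == "bpb":
            if bpb_model is None:
                bpb_model = bpb_mod.fit_bpb(
                    fit_on or dataset, m=config.m, pseudocount=config.pseudocount
                )
            blocks.append(bpb_mod.encode_dataset(bpb_model, dataset))
        elif enc == "ctd":
            blocks.append(ctd_mod.encode_dataset(dataset))
        elif enc == "dft":
            blocks.append(
                dft_mod.encode_dataset(
                    dataset, n_freq=config.n_freq, center=config.center_profiles
                )
            )
    return pd.concat(blocks, axis=1), bpb_model


def _resolve_pair(
    X: np.ndarray, y: np.ndarray, config: PipelineConfig
) -> tuple[str, str]:
    """Fixed pair, or pick (best-Sn, best-Sp) by inner cross-validation."""
    if config.classifier_pair != "auto":
        return tuple(config.classifier_pair)  # type: ignore[return-value]
    from .evaluation import classifier_cv_metrics

    candidates = []
    for name in ("nb", "lr", "nna"):
        sn, sp, _ = classifier_cv_metrics(X, y, name, k=config.k, seed=config.seed)
        candidates.append((name, sn, sp))
    return select_base_pair(candidates)


def run_selection(
    X: np.ndarray, y: np.ndarray, config: PipelineConfig
):
    """Relief ranking followed by IFS with the fused-pair evaluator.

    Returns ``(relief_result, ifs_result)``; the IFS evaluator is the
    pooled cross-validated accuracy of the configured classifier pair at a
    fixed seed.
    """
    from .evaluation import pair_cv_accuracy

    pair = _resolve_pair(X, y, config)
    relief = relief_rank(X, y, n_iter=config.relief_n_iter, seed=config.seed)

    def evaluator(X_sub: np.ndarray, y_sub: np.ndarray) -> float:
        return pair_cv_accuracy(
            X_sub, y_sub, pair, k=config.k, seed=config.seed,
            threshold=config.threshold,
        )

    ifs = ifs_select(X, y, relief.ranking, evaluator)
    return relief, ifs


def train_fusion(
    dataset: PeptideDataset, config: PipelineConfig
) -> FusionModel:
    """Fit the full pipeline on a labelled dataset and return the model."""
    y = dataset.labels()
    X_df, bpb_model = encode_features(dataset, config)
    X = X_df.to_numpy()

    if config.feature_indices is not None:
        indices = np.asarray(config.feature_indices, dtype=int)
    elif config.selection is not None:
        _, ifs = run_selection(X, y, config)
        indices = np.asarray(ifs.selected, dtype=int)
    else:
        indices = np.arange(X.shape[1])

    pair = _resolve_pair(X[:, indices], y, config)
    base_a = make_classifier(pair[0]).fit(X[:, indices], y)
    base_b = make_classifier(pair[1]).fit(X[:, indices], y)
    return FusionModel(
        base_a=base_a,
        base_b=base_b,
        base_a_name=pair[0],
        base_b_name=pair[1],
        feature_indices=indices,
        feature_names=list(X_df.columns),
        threshold=config.threshold,
        bpb_model=bpb_model,
        encoders=list(config.encoders),
    )


def _config_from_model(model: FusionModel) -> PipelineConfig:
    n_freq = 10
    dft_names = [n for n in model.feature_names if n.startswith("DFT_")]
    if dft_names:
        n_freq = len(dft_names) // len(dft_mod.DEFAULT_SCALES)
    return PipelineConfig(
        encoders=tuple(model.encoders),
        m=model.bpb_model.m if model.bpb_model is not None else 10,
        pseudocount=(
            model.bpb_model.pseudocount if model.bpb_model is not None else 1.0
        ),
        n_freq=n_freq,
        threshold=model.threshold,
    )


def predict_dataset(model: FusionModel, dataset: PeptideDataset) -> pd.DataFrame:
    """Score every record of a dataset with a trained fusion model.

    Returns a frame indexed by id with columns ``fused_prob`` and
    ``predicted_label``.
    """
    config = _config_from_model(model)
    X_df, _ = encode_features(dataset, config, bpb_model=model.bpb_model)
    if list(X_df.columns) != model.feature_names:
        raise ValidationError(
            "encoded feature space does not match the model: "
            f"{X_df.shape[1]} columns vs {len(model.feature_names)} expected"
        )
    X = X_df.to_numpy()[:, model.feature_indices]
    fused, labels = model.fuse_predict(X)
    return pd.DataFrame(
        {"fused_prob": fused, "predicted_label": labels}, index=dataset.ids
    )
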