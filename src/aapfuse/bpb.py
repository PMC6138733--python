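"""Bi-profile Bayes (BpB) terminal-profile encoder.

BpB turns a peptide into position-specific posterior probabilities at its
two termini.  From a labelled training set, four ``m × 20`` tables are
estimated: for each of the first ``m`` (N-terminal) and last ``m``
(C-terminal) positions, the probability of observing each residue given
the positive class, and the same given the negative class.  A peptide is
then encoded as the ``4m``-vector of table lookups for its own residues,
laid out as

    [N-terminal vs positive | C-terminal vs positive |
     N-terminal vs negative | C-terminal vs negative]

so that, with the default window ``m = 10``, every peptide becomes a
40-dimensional feature vector.  Because the tables are class-conditional
statistics of the *training* set, the encoder must be refit whenever the
training split changes (see :func:`aapfuse.evaluation.cross_validate`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .peptide_io import CANONICAL_ALPHABET, PeptideDataset, ValidationError

_TABLE_KEYS = ("n_pos", "c_pos", "n_neg", "c_neg")


@dataclass
class BpBModel:
    """Fitted position-by-residue posterior tables for the two termini.

    ``tables[key]`` has shape ``(m, 20)`` with rows indexed by window
    position (N-terminal position ``i`` = sequence position ``i``;
    C-terminal position ``i`` = sequence position ``L - m + i``, both
    1-based) and columns by :data:`~aapfuse.peptide_io.CANONICAL_ALPHABET`
    order.  With ``pseudocount > 0`` every row sums to 1 and every entry is
    strictly inside (0, 1).
    """

    m: int
    pseudocount: float
    tables: dict[str, np.ndarray]
    alphabet: str = CANONICAL_ALPHABET
    _residue_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if set(self.tables) != set(_TABLE_KEYS):
            raise ValueError(f"tables must have keys {_TABLE_KEYS}")
        for key in _TABLE_KEYS:
            tab = np.asarray(self.tables[key], dtype=float)
            if tab.shape != (self.m, len(self.alphabet)):
                raise ValueError(
                    f"table {key!r} has shape {tab.shape}, "
                    f"expected ({self.m}, {len(self.alphabet)})"
                )
            self.tables[key] = tab
        self._residue_index = {a: i for i, a in enumerate(self.alphabet)}

    @property
    def feature_names(self) -> list[str]:
        names = []
        for key in _TABLE_KEYS:
            terminus, cls = key.split("_")
            names += [
                f"BpB_{terminus.upper()}_{cls}_{i + 1}" for i in range(self.m)
            ]
        return names

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "aapfuse-bpb-1",
            "m": self.m,
            "pseudocount": self.pseudocount,
            "alphabet": self.alphabet,
            "tables": {k: self.tables[k].tolist() for k in _TABLE_KEYS},
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "BpBModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "aapfuse-bpb-1":
            raise ValueError(f"{path}: not an aapfuse BpB model file")
        return cls(
            m=int(payload["m"]),
            pseudocount=float(payload["pseudocount"]),
            tables={k: np.asarray(v, float) for k, v in payload["tables"].items()},
            alphabet=payload["alphabet"],
        )


def _window_indices(seq: str, m: int, terminus: str) -> np.ndarray:
    if terminus == "n":
        window = seq[:m]
    else:
        window = seq[len(seq) - m :]
    return np.asarray([CANONICAL_ALPHABET.index(ch) for ch in window])


def fit_bpb(
    train: PeptideDataset, m: int = 10, pseudocount: float = 1.0
) -> BpBModel:
    """Estimate the four terminal posterior tables from a labelled dataset.

    Entry ``(i, a)`` of the (N, positive) table is
    ``(count of residue a at N-terminal position i among positives +
    pseudocount) / (n_pos + 20 * pseudocount)``, and analogously for the
    other terminus/class combinations.
    """
    if m < 1:
        raise ValueError("window length m must be >= 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    for rec in train:
        if len(rec) < m:
            raise ValidationError(
                f"record {rec.id!r} has length {len(rec)} < window m={m}"
            )
    by_class = {1: [], 0: []}
    for rec in train:
        if rec.label is None:
            raise ValidationError(f"record {rec.id!r} has no label")
        by_class[rec.label].append(rec.sequence)
    for cls, name in ((1, "positive"), (0, "negative")):
        if not by_class[cls]:
            raise ValidationError(f"training set has no {name} samples")

    n_res = len(CANONICAL_ALPHABET)
    tables: dict[str, np.ndarray] = {}
    for terminus in ("n", "c"):
        for cls, tag in ((1, "pos"), (0, "neg")):
            counts = np.zeros((m, n_res))
            for seq in by_class[cls]:
                idx = _window_indices(seq, m, terminus)
                counts[np.arange(m), idx] += 1
            denom = len(by_class[cls]) + n_res * pseudocount
            tables[f"{terminus}_{tag}"] = (counts + pseudocount) / denom
    return BpBModel(m=m, pseudocount=pseudocount, tables=tables)


def encode_bpb(model: BpBModel, sequence: str) -> np.ndarray:
    """Encode one sequence as its ``4m`` terminal posterior lookups."""
    if len(sequence) < model.m:
        raise ValidationError(
            f"sequence length {len(sequence)} < window m={model.m}"
        )
    parts = []
    for key in _TABLE_KEYS:
        terminus = key.split("_")[0]
        idx = _window_indices(sequence, model.m, terminus)
        parts.append(model.tables[key][np.arange(model.m), idx])
    return np.concatenate(parts)


def encode_dataset(model: BpBModel, dataset: PeptideDataset) -> pd.DataFrame:
    """Encode every record; rows indexed by id, columns by feature name."""
    rows = [encode_bpb(model, rec.sequence) for rec in dataset]
    return pd.DataFrame(rows, index=dataset.ids, columns=model.feature_names)
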