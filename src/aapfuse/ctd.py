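"""Composition–Transition–Distribution (CTD) descriptors.

Residues are partitioned into four physicochemical groups —
hydrophobic, polar, positively charged, negatively charged — and a
peptide of length ``L`` is summarised by 30 numbers:

* **Composition** (4): frequency ``N_i / L`` of each group.
* **Transition** (6): for each unordered group pair ``{i, j}``, the
  frequency ``(N_ij + N_ji) / (L - 1)`` of adjacent residues switching
  between the two groups.
* **Distribution** (20): for each group, the 1-based sequence positions of
  its 1st, 25%, 50%, 75% and 100% occurrences (occurrence index
  ``ceil(q * N_i)``, first mark fixed at occurrence 1), each divided by
  ``L``.  A group absent from the sequence contributes five zeros.
"""

from __future__ import annotations

from math import ceil

import numpy as np
import pandas as pd

from .peptide_io import PeptideDataset, ValidationError

#: Residue → group index (1-based). Group 1 hydrophobic, 2 polar,
#: 3 positively charged, 4 negatively charged.
GROUPS: dict[str, int] = {}
for _res in "AFGILMPVW":
    GROUPS[_res] = 1
for _res in "CNQSTY":
    GROUPS[_res] = 2
for _res in "HKR":
    GROUPS[_res] = 3
for _res in "DE":
    GROUPS[_res] = 4

_PAIRS = [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]
_QUANTILES = (0.25, 0.50, 0.75, 1.00)

CTD_FEATURE_NAMES: list[str] = (
    [f"CTD_C_g{i}" for i in range(1, 5)]
    + [f"CTD_T_g{i}g{j}" for i, j in _PAIRS]
    + [
        f"CTD_D_g{i}_q{tag}"
        for i in range(1, 5)
        for tag in ("first", "25", "50", "75", "100")
    ]
)


def ctd_encode(sequence: str) -> np.ndarray:
    """Return the 30 CTD features of a validated sequence (length >= 2)."""
    L = len(sequence)
    if L < 2:
        raise ValidationError(
            "CTD requires length >= 2 (transition undefined otherwise)"
        )
    groups = np.asarray([GROUPS[ch] for ch in sequence])

    composition = np.asarray([np.sum(groups == i) for i in range(1, 5)]) / L

    transition = np.zeros(len(_PAIRS))
    a, b = groups[:-1], groups[1:]
    for p, (i, j) in enumerate(_PAIRS):
        n_ij = np.sum((a == i) & (b == j))
        n_ji = np.sum((a == j) & (b == i))
        transition[p] = (n_ij + n_ji) / (L - 1)

    distribution = np.zeros(20)
    for gi, g in enumerate(range(1, 5)):
        positions = np.flatnonzero(groups == g) + 1  # 1-based
        n = len(positions)
        if n == 0:
            continue
        marks = [positions[0]]
        for q in _QUANTILES:
            marks.append(positions[ceil(q * n) - 1])
        distribution[gi * 5 : gi * 5 + 5] = np.asarray(marks) / L

    return np.concatenate([composition, transition, distribution])


def encode_dataset(dataset: PeptideDataset) -> pd.DataFrame:
    rows = [ctd_encode(rec.sequence) for rec in dataset]
    return pd.DataFrame(rows, index=dataset.ids, columns=CTD_FEATURE_NAMES)
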