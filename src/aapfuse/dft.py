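"""Discrete-Fourier power-spectrum features of physicochemical profiles.

A peptide is mapped residue-by-residue onto a numeric profile via an amino
acid property scale ``H``, then transformed with the DFT

    F(k) = sum_{n=1..L} H(p_n) exp(-2*pi*i*n*k / L),   k = 0..L-1,

and summarised by the power spectrum ``PS(k) = |F(k)|^2``.  Low-frequency
components capture the broad compositional periodicity of the profile
(hydrophobic/hydrophilic alternation and mean level); by default the first
10 powers (k = 0..9, DC included) of a hydrophobicity profile
(Kyte–Doolittle) and a hydrophilicity profile (Hopp–Woods) are emitted,
giving a 20-dimensional vector.

The ``n = 1..L`` phase convention differs from the usual ``n = 0..L-1``
only by a unit-modulus factor per coefficient, so the power spectrum is
identical and the implementation can delegate to the FFT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .peptide_io import CANONICAL_ALPHABET, PeptideDataset, ValidationError

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Hopp–Woods hydrophilicity scale.
HOPP_WOODS: dict[str, float] = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}


@dataclass(frozen=True)
class PropertyScale:
    """A named residue → real value mapping covering all 20 residues."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(CANONICAL_ALPHABET) - set(self.values)
        if missing:
            raise ValueError(
                f"scale {self.name!r} is missing residues {sorted(missing)}"
            )

    def profile(self, sequence: str) -> np.ndarray:
        return np.asarray([self.values[ch] for ch in sequence], dtype=float)

    @classmethod
    def from_table(cls, path: str | Path, name: str | None = None) -> "PropertyScale":
        """Load a two-column (residue, value) whitespace-delimited table."""
        values: dict[str, float] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, val = line.split()
            values[res.upper()] = float(val)
        return cls(name or Path(path).stem, values)


DEFAULT_SCALES = (
    PropertyScale("hydrophobicity", KYTE_DOOLITTLE),
    PropertyScale("hydrophilicity", HOPP_WOODS),
)


def dft_power(profile: np.ndarray) -> np.ndarray:
    """Power spectrum ``PS(k) = |F(k)|^2`` of a real profile, k = 0..L-1."""
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size == 0:
        raise ValidationError("profile must be a non-empty 1-D array")
    coeff = np.fft.fft(profile)
    return np.abs(coeff) ** 2


def dft_feature_names(
    scales: tuple[PropertyScale, ...] = DEFAULT_SCALES, n_freq: int = 10
) -> list[str]:
    return [f"DFT_{s.name}_k{k}" for s in scales for k in range(n_freq)]


def dft_encode(
    sequence: str,
    scales: tuple[PropertyScale, ...] = DEFAULT_SCALES,
    n_freq: int = 10,
    center: bool = False,
) -> np.ndarray:
    """Low-frequency powers ``PS(0)..PS(n_freq-1)`` for each scale in order.

    ``center=True`` subtracts the profile mean first, which zeroes the DC
    component ``PS(0)``.
    """
    if len(sequence) < n_freq:
        raise ValidationError(
            f"sequence length {len(sequence)} < n_freq={n_freq}; "
            "DFT features need at least n_freq residues"
        )
    parts = []
    for scale in scales:
        profile = scale.profile(sequence)
        if center:
            profile = profile - profile.mean()
        parts.append(dft_power(profile)[:n_freq])
    return np.concatenate(parts)


def encode_dataset(
    dataset: PeptideDataset,
    scales: tuple[PropertyScale, ...] = DEFAULT_SCALES,
    n_freq: int = 10,
    center: bool = False,
) -> pd.DataFrame:
    rows = []
    for rec in dataset:
        try:
            rows.append(dft_encode(rec.sequence, scales, n_freq, center))
        except ValidationError as err:
            raise ValidationError(f"record {rec.id!r}: {err}") from err
    return pd.DataFrame(
        rows, index=dataset.ids, columns=dft_feature_names(scales, n_freq)
    )
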