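"""Reading, validating and writing labelled peptide datasets.

Peptides are short amino-acid sequences over the 20-letter canonical
alphabet.  Datasets are ordered collections of uniquely identified records,
each optionally carrying a binary class label (1 = anti-angiogenic
"positive", 0 = "negative").  Labels can come from three places, in
priority order: an explicit ``label`` argument applied to every record of a
file, a ``|1`` / ``|0`` suffix on the FASTA header, or a two-column TSV
mapping record id to label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, in the fixed alphabetical order used by
#: every encoder in this package.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_ALPHABET)


class ValidationError(ValueError):
    """A record or sequence violates the dataset contract."""


def canonicalize(sequence: str) -> str:
    """Strip whitespace, uppercase, and validate a raw sequence.

    Raises :class:`ValidationError` if any residue is outside the canonical
    20-letter alphabet (ambiguity codes B, J, O, U, X, Z are rejected, not
    remapped).
    """
    cleaned = "".join(sequence.split()).upper()
    for ch in cleaned:
        if ch not in _CANONICAL_SET:
            raise ValidationError(
                f"non-canonical residue {ch!r} in sequence {cleaned!r}"
            )
    return cleaned


@dataclass(frozen=True)
class PeptideRecord:
    """One validated peptide with an optional binary label."""

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        for ch in self.sequence:
            if ch not in _CANONICAL_SET:
                raise ValidationError(
                    f"record {self.id!r}: non-canonical residue {ch!r}"
                )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideDataset:
    """An ordered collection of peptide records with unique ids."""

    records: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) tally of the labels present."""
        n_pos = sum(1 for r in self.records if r.label == 1)
        n_neg = sum(1 for r in self.records if r.label == 0)
        return n_pos, n_neg

    def labels(self) -> np.ndarray:
        """Label vector; raises if any record is unlabelled."""
        out = []
        for r in self.records:
            if r.label is None:
                raise ValidationError(f"record {r.id!r} has no label")
            out.append(r.label)
        return np.asarray(out, dtype=int)

    def subset(self, indices: Sequence[int]) -> "PeptideDataset":
        return PeptideDataset([self.records[i] for i in indices])

    def with_labels(self, labels: dict[str, int]) -> "PeptideDataset":
        """Return a copy with labels assigned from an id → {0,1} mapping."""
        recs = []
        for r in self.records:
            if r.id not in labels:
                raise ValidationError(f"no label provided for record {r.id!r}")
            recs.append(PeptideRecord(r.id, r.sequence, int(labels[r.id])))
        return PeptideDataset(recs)

    @staticmethod
    def concat(parts: Iterable["PeptideDataset"]) -> "PeptideDataset":
        recs: list[PeptideRecord] = []
        for part in parts:
            recs.extend(part.records)
        return PeptideDataset(recs)


def _label_from_header(header_id: str) -> tuple[str, Optional[int]]:
    """Split a ``name|1`` / ``name|0`` header into (id, label)."""
    if "|" in header_id:
        stem, _, tag = header_id.rpartition("|")
        if tag in ("0", "1") and stem:
            return stem, int(tag)
    return header_id, None


def read_fasta(
    path: str | Path,
    label: Optional[int] = None,
    drop_invalid: bool = False,
) -> PeptideDataset:
    """Read a FASTA file into a :class:`PeptideDataset`.

    Parameters
    ----------
    path:
        FASTA file of peptide sequences.
    label:
        If given, assign this class to every record; otherwise labels are
        taken from ``|1`` / ``|0`` header suffixes when present.
    drop_invalid:
        Discard records with non-canonical residues (logged as warnings)
        instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[PeptideRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id, header_label = _label_from_header(entry.id)
        rec_label = label if label is not None else header_label
        try:
            seq = canonicalize(str(entry.seq))
            if not seq:
                raise ValidationError(f"record {rec_id!r} has an empty sequence")
            records.append(PeptideRecord(rec_id, seq, rec_label))
        except ValidationError as err:
            if drop_invalid:
                logger.warning("dropping record %r: %s", rec_id, err)
                continue
            raise ValidationError(f"record {rec_id!r}: {err}") from err
    if not records:
        raise ValidationError(f"no valid records in {path}")
    return PeptideDataset(records)


def write_fasta(dataset: PeptideDataset, path: str | Path) -> None:
    """Write a dataset to FASTA; labels are encoded as ``|1`` / ``|0``
    header suffixes so that write → read round-trips exactly."""
    out = []
    for r in dataset:
        header = r.id if r.label is None else f"{r.id}|{r.label}"
        out.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(out, fh, "fasta-2line")


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    """Read an ``id<TAB>{0,1}`` label file."""
    labels: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValidationError(
                    f"{path}:{lineno}: expected 'id<TAB>0|1', got {line!r}"
                )
            if parts[0] in labels:
                raise ValidationError(f"{path}:{lineno}: duplicate id {parts[0]!r}")
            labels[parts[0]] = int(parts[1])
    if not labels:
        raise ValidationError(f"no labels in {path}")
    return labels
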