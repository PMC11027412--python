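"""Peptide FASTA input/output, sequence validation, and dataset splitting.

Datasets are ordered collections of :class:`PeptideRecord`; labels are
binary (``"positive"``/``"negative"``) and may be attached per file or via
a two-column id/label TSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

from ._tables import ALPHABET

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

#: CKSAAP at its largest gap (3) needs at least one pair: L - 3 - 1 >= 1.
MIN_LENGTH = 5
#: Typical upper bound for this peptide class; longer sequences only warn.
TYPICAL_MAX_LENGTH = 30

_ALPHABET_SET = frozenset(ALPHABET)


class FastaParseError(ValueError):
    """Malformed FASTA syntax."""


class ValidationError(ValueError):
    """A peptide record violating the sequence contract."""


class SplitError(ValueError):
    """A stratified split that cannot be performed."""


@dataclass(frozen=True)
class PeptideRecord:
    """One identified amino-acid sequence with an optional class label."""

    id: str
    sequence: str
    label: Optional[str] = None

    def validate(self) -> "PeptideRecord":
        if not self.id:
            raise ValidationError("peptide record has an empty id")
        seq = self.sequence.upper()
        bad = set(seq) - _ALPHABET_SET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-canonical residue(s) "
                f"{''.join(sorted(bad))!r}"
            )
        if len(seq) < MIN_LENGTH:
            raise ValidationError(
                f"record {self.id!r}: length {len(seq)} < minimum {MIN_LENGTH}"
            )
        if len(seq) > TYPICAL_MAX_LENGTH:
            warnings.warn(
                f"record {self.id!r}: length {len(seq)} exceeds the typical "
                f"maximum of {TYPICAL_MAX_LENGTH}; descriptors remain defined",
                stacklevel=2,
            )
        if self.label not in (None, POSITIVE, NEGATIVE):
            raise ValidationError(
                f"record {self.id!r}: unknown label {self.label!r}"
            )
        return self if seq == self.sequence else replace(self, sequence=seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered peptide collection; ids unique, every record labeled
    when used for training."""

    records: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == POSITIVE)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == NEGATIVE)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        """0/1 label vector (positive = 1); raises if any record unlabeled."""
        out = np.empty(len(self.records), dtype=int)
        for i, r in enumerate(self.records):
            if r.label is None:
                raise ValidationError(f"record {r.id!r} is unlabeled")
            out[i] = 1 if r.label == POSITIVE else 0
        return out

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])

    def with_labels(self, labels: dict[str, str]) -> "LabeledDataset":
        """Attach labels from an id -> label mapping."""
        recs = []
        for r in self.records:
            if r.id in labels:
                recs.append(replace(r, label=labels[r.id]).validate())
            else:
                recs.append(r)
        return LabeledDataset(recs)

    @staticmethod
    def concat(*parts: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset([r for p in parts for r in p.records])


def read_fasta(
    path: str | Path,
    label: Optional[str] = None,
    skip_invalid: bool = False,
) -> LabeledDataset:
    """Read a peptide FASTA file into a validated :class:`LabeledDataset`.

    Parameters
    ----------
    path
        FASTA file; header lines begin with ``>``.
    label
        If given (``"positive"`` or ``"negative"``), applied to all entries.
    skip_invalid
        Downgrade validation failures to logged warnings, dropping the
        offending records, instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(
                f"{path}: line 1 does not start a FASTA header ('>')"
            )
    records: list[PeptideRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rec = PeptideRecord(id=entry.id, sequence=str(entry.seq), label=label)
        try:
            records.append(rec.validate())
        except ValidationError:
            if skip_invalid:
                logger.warning("skipping invalid record %r in %s", entry.id, path)
            else:
                raise
    return LabeledDataset(records)


def write_fasta(data: LabeledDataset, path: str | Path) -> None:
    """Write records as single-line-sequence FASTA (round-trip safe)."""
    with Path(path).open("w") as fh:
        for r in data:
            fh.write(f">{r.id}\n{r.sequence}\n")


def read_label_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, label) TSV into a mapping."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).open(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FastaParseError(f"{path}:{lineno}: expected two columns")
        pid, lab = parts
        if lab not in (POSITIVE, NEGATIVE):
            raise ValidationError(f"{path}:{lineno}: unknown label {lab!r}")
        out[pid] = lab
    return out


def stratified_split(
    data: LabeledDataset, test_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic stratified train/test split.

    Class proportions are preserved to within one record per class; the
    split is disjoint and reproducible for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise SplitError(f"test_fraction must be in (0, 1), got {test_fraction}")
    labels = data.labels()
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise SplitError(
                f"class {cls} has {len(idx)} member(s); need at least 2 to split"
            )
        n_test = int(round(len(idx) * test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    return data.subset(sorted(train_idx)), data.subset(sorted(test_idx))
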