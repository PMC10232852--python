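"""Reading, validation, one-hot encoding and splitting of fixed-length RNA windows.

The unit of data throughout the package is a 41-nt RNA window centred on the
queried uridine (20 nt of context on each side).  Sequences are read from
per-class FASTA files (or plain one-sequence-per-line text), normalised to the
{A, C, G, U} alphabet (T is accepted as an alias of U, since site lists are
frequently deposited in DNA coordinates), and encoded as strict one-hot rows
in the fixed channel order (A, C, G, U)::

    A -> [1, 0, 0, 0]   C -> [0, 1, 0, 0]   G -> [0, 0, 1, 0]   U -> [0, 0, 0, 1]

Splitting is stratified by class and seeded, so a (records, fractions, seed)
triple always reproduces the same partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "WINDOW_LENGTH",
    "CENTER_POSITION",
    "ALPHABET",
    "SequenceRecord",
    "EncodedBatch",
    "DatasetSplit",
    "InvalidSequenceError",
    "read_labeled_sequences",
    "read_sequences",
    "validate_records",
    "one_hot_encode",
    "decode_one_hot",
    "stratified_split",
    "three_way_split",
    "write_fasta",
]

WINDOW_LENGTH = 41
#: 1-based position of the queried uridine.
CENTER_POSITION = 21
ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class InvalidSequenceError(ValueError):
    """Raised when input sequences fail length/alphabet validation.

    Carries a per-record rejection report in :attr:`report`.
    """

    def __init__(self, report: list[tuple[str, str]]):
        self.report = report
        lines = "; ".join(f"{rid}: {reason}" for rid, reason in report[:10])
        more = "" if len(report) <= 10 else f" (+{len(report) - 10} more)"
        super().__init__(f"{len(report)} invalid sequence(s): {lines}{more}")


@dataclass
class SequenceRecord:
    """A labelled fixed-length RNA window.

    Parameters
    ----------
    id : str
        Identifier (FASTA header or synthesised ``line<N>`` for plain text).
    seq : str
        Sequence over {A, C, G, U}; length :data:`WINDOW_LENGTH` after
        validation.
    label : int or None
        Binary class (1 = modified / m5U, 0 = unmodified), or ``None`` for
        unlabelled prediction inputs.
    """

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.strip().upper().replace("T", "U")


@dataclass
class EncodedBatch:
    """One-hot encoded sequences: ``x`` is N x L x 4 in channel order (A,C,G,U)."""

    x: np.ndarray
    y: np.ndarray | None
    ids: list[str]

    def __len__(self) -> int:
        return self.x.shape[0]


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive, class-stratified train/validation/test partition."""

    train: list[SequenceRecord]
    validation: list[SequenceRecord]
    test: list[SequenceRecord]
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    seed: int = 0

    def __iter__(self):
        return iter((self.train, self.validation, self.test))


def _normalize(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def _looks_like_fasta(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.lstrip().startswith(">")
    return False


def read_sequences(path: str | Path, label: int | None = None) -> list[SequenceRecord]:
    """Read FASTA or one-sequence-per-line text into (unvalidated) records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    if _looks_like_fasta(path):
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(SequenceRecord(rec.id, str(rec.seq), label))
    else:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.strip():
                    records.append(SequenceRecord(f"{path.stem}|line{i}", line, label))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def validate_records(
    records: Sequence[SequenceRecord],
    length: int = WINDOW_LENGTH,
    skip_invalid: bool = False,
    check_center: bool = True,
) -> list[SequenceRecord]:
    """Validate length/alphabet; warn (never fail) on non-U centre bases.

    Returns the valid records.  With ``skip_invalid`` the offenders are
    dropped silently from the return value (the report is attached to the
    warning); otherwise any offender aborts with
    :class:`InvalidSequenceError` listing every offending id.
    """
    valid: list[SequenceRecord] = []
    report: list[tuple[str, str]] = []
    n_center_violations = 0
    for rec in records:
        if len(rec.seq) != length:
            report.append((rec.id, f"length {len(rec.seq)} != {length}"))
            continue
        bad = set(rec.seq) - set(ALPHABET)
        if bad:
            report.append((rec.id, f"invalid characters {sorted(bad)}"))
            continue
        if check_center and length == WINDOW_LENGTH and rec.seq[CENTER_POSITION - 1] != "U":
            n_center_violations += 1
        valid.append(rec)
    if report and not skip_invalid:
        raise InvalidSequenceError(report)
    if report:
        warnings.warn(f"skipped {len(report)} invalid sequence(s)", stacklevel=2)
    if n_center_violations:
        warnings.warn(
            f"{n_center_violations} record(s) do not have U at the centre "
            f"(position {CENTER_POSITION}); expected for the m5U problem domain",
            stacklevel=2,
        )
    return valid


def read_labeled_sequences(
    pos_path: str | Path,
    neg_path: str | Path,
    skip_invalid: bool = False,
) -> list[SequenceRecord]:
    """Read the two-file per-class layout: positives labelled 1, negatives 0.

    Duplicate sequences appearing in both classes are surfaced with a warning
    (their intent is ambiguous); they are kept.
    """
    pos = read_sequences(pos_path, label=1)
    neg = read_sequences(neg_path, label=0)
    records = validate_records(pos + neg, skip_invalid=skip_invalid)
    pos_seqs = {r.seq for r in records if r.label == 1}
    dupes = [r.id for r in records if r.label == 0 and r.seq in pos_seqs]
    if dupes:
        warnings.warn(
            f"{len(dupes)} sequence(s) occur in both classes: {dupes[:5]}...",
            stacklevel=2,
        )
    return records


def one_hot_encode(records: Sequence[SequenceRecord], dtype=np.float32) -> EncodedBatch:
    """Encode records as a strict one-hot N x L x 4 tensor, channels (A,C,G,U)."""
    if not records:
        raise ValueError("no records to encode")
    length = len(records[0].seq)
    x = np.zeros((len(records), length, 4), dtype=dtype)
    for n, rec in enumerate(records):
        if len(rec.seq) != length:
            raise ValueError(f"mixed sequence lengths ({rec.id})")
        try:
            idx = [_BASE_INDEX[b] for b in rec.seq]
        except KeyError as exc:  # pragma: no cover - validate_records guards this
            raise InvalidSequenceError([(rec.id, f"invalid character {exc}")]) from exc
        x[n, np.arange(length), idx] = 1.0
    labels = [rec.label for rec in records]
    y = None
    if all(lab is not None for lab in labels):
        y = np.asarray(labels, dtype=dtype)
    return EncodedBatch(x=x, y=y, ids=[rec.id for rec in records])


def decode_one_hot(x: np.ndarray) -> list[str]:
    """Inverse of :func:`one_hot_encode` (valid one-hot input assumed)."""
    x = np.asarray(x)
    if x.ndim == 2:
        x = x[None]
    idx = x.argmax(axis=2)
    return ["".join(ALPHABET[i] for i in row) for row in idx]


def _stratified_partition(
    records: Sequence[SequenceRecord],
    fractions: Sequence[float],
    seed: int,
    shuffle: bool = True,
) -> list[list[SequenceRecord]]:
    """Split each class separately into len(fractions) parts by cumulative rounding."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {tuple(fractions)}")
    if any(not 0.0 < f < 1.0 for f in fractions):
        raise ValueError(f"every fraction must lie in (0, 1), got {tuple(fractions)}")
    rng = np.random.default_rng(seed)
    parts: list[list[SequenceRecord]] = [[] for _ in fractions]
    labels = sorted({rec.label for rec in records}, key=lambda v: (v is None, v))
    for lab in labels:
        members = [rec for rec in records if rec.label == lab]
        if len(members) < 2:
            raise ValueError(f"need at least 2 records in class {lab}")
        order = rng.permutation(len(members)) if shuffle else np.arange(len(members))
        cuts = np.round(np.cumsum(fractions) * len(members)).astype(int)
        start = 0
        for part, stop in zip(parts, cuts):
            part.extend(members[i] for i in order[start:stop])
            start = stop
    return parts


def stratified_split(
    records: Sequence[SequenceRecord],
    train_frac: float = 0.8,
    seed: int = 0,
    shuffle: bool = True,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Class-stratified two-way split (train, test); deterministic under seed."""
    train, test = _stratified_partition(records, (train_frac, 1.0 - train_frac), seed, shuffle)
    return train, test


def three_way_split(
    records: Sequence[SequenceRecord],
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
    shuffle: bool = True,
) -> DatasetSplit:
    """Class-stratified train/validation/test split (defaults 70/10/20)."""
    if len(fractions) != 3:
        raise ValueError("three fractions required")
    train, val, test = _stratified_partition(records, fractions, seed, shuffle)
    return DatasetSplit(train=train, validation=val, test=test,
                        fractions=tuple(fractions), seed=seed)


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrap not needed at L=41)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")
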