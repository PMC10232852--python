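"""Planted-motif synthetic benchmarks for the m5U window-classification task.

Real m5U benchmarks pair experimentally mapped 5-methyluridine sites with
unmodified uridines sampled from the same transcripts, as 41-nt windows with
the queried U at position 21.  This module emulates that structure without any
download: negatives are i.i.d. draws from a background base distribution with
the centre fixed to U; positives are the same background with short motifs
written into fixed windows.  The default motifs reproduce the discriminative
signal reported for m5U context — ``GGU`` at 1-based positions 18-20 and
``CXAXCCC`` at 23-29 (``X`` = wildcard drawn from background), i.e. a
G-enriched region immediately upstream of the site and a C-enriched region
downstream.

Each motif is planted independently with probability ``plant_prob``
(default 0.9), so a fraction of positives is indistinguishable from
background and both false negatives and false positives occur at realistic,
non-zero rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqdata import ALPHABET, CENTER_POSITION, WINDOW_LENGTH, SequenceRecord

__all__ = [
    "MotifSpec",
    "SyntheticConfig",
    "CompositionMatrix",
    "DEFAULT_MOTIFS",
    "PAPER_FLAVORED_BACKGROUND",
    "generate_dataset",
    "composition_matrix",
    "motif_positions",
    "write_dataset",
]

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class MotifSpec:
    """A fixed-position motif over {A,C,G,U,X}; X is drawn from background.

    ``start`` is 1-based within the 41-nt window.  Motifs may not cross the
    centre position (21), which is definitionally U in both classes.
    """

    pattern: str
    start: int

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(ALPHABET + "X")
        if bad:
            raise ValueError(f"invalid motif characters {sorted(bad)}")
        if self.start < 1 or self.start + len(self.pattern) - 1 > WINDOW_LENGTH:
            raise ValueError(f"motif {self.pattern}@{self.start} outside window")
        if self.start <= CENTER_POSITION <= self.start + len(self.pattern) - 1:
            raise ValueError(
                f"motif {self.pattern}@{self.start} crosses the centre position "
                f"{CENTER_POSITION} (fixed U)"
            )

    @property
    def span(self) -> range:
        """0-based positions covered by the motif."""
        return range(self.start - 1, self.start - 1 + len(self.pattern))

    def fixed_positions(self) -> list[int]:
        """0-based positions with a literal (non-wildcard) base."""
        return [self.start - 1 + i for i, c in enumerate(self.pattern.upper()) if c != "X"]


#: The two discriminative context motifs: GGU upstream (18-20), CXAXCCC downstream (23-29).
DEFAULT_MOTIFS: tuple[MotifSpec, ...] = (
    MotifSpec("GGU", 18),
    MotifSpec("CXAXCCC", 23),
)

#: Background preset with upstream-G / downstream-C enrichment for logo demos;
#: a single distribution (A, C, G, U) used at every non-centre position.
PAPER_FLAVORED_BACKGROUND = (0.20, 0.30, 0.30, 0.20)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the package's standard study conditions."""

    n_pos: int = 2000
    n_neg: int = 2000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motifs: tuple[MotifSpec, ...] = DEFAULT_MOTIFS
    plant_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
            raise ValueError("background must be a length-4 probability vector")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant_prob must lie in [0, 1]")
        covered: set[int] = set()
        for m in self.motifs:
            span = set(m.span)
            if span & covered:
                raise ValueError(f"overlapping motifs at positions {sorted(span & covered)}")
            covered |= span


@dataclass
class CompositionMatrix:
    """Per-position base frequencies (rows sum to 1), channel order (A,C,G,U)."""

    freq: np.ndarray
    n: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.freq, columns=list(ALPHABET),
                            index=np.arange(1, self.freq.shape[0] + 1))


def motif_positions(motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS) -> list[int]:
    """Sorted 0-based positions covered by the given motifs."""
    pos: set[int] = set()
    for m in motifs:
        pos |= set(m.span)
    return sorted(pos)


def _random_windows(rng: np.random.Generator, n: int, background: np.ndarray) -> np.ndarray:
    """n x 41 array of base indices, centre fixed to U."""
    idx = rng.choice(4, size=(n, WINDOW_LENGTH), p=background)
    idx[:, CENTER_POSITION - 1] = _BASE_INDEX["U"]
    return idx


def generate_dataset(config: SyntheticConfig) -> list[SequenceRecord]:
    """Generate labelled synthetic records; positives first, then negatives.

    Positives are background windows in which each motif is independently
    written at its position with probability ``plant_prob`` (wildcards drawn
    from background); negatives are pure background.  Both classes carry U at
    the centre.  Byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background, dtype=float)

    pos_idx = _random_windows(rng, config.n_pos, bg)
    for m in config.motifs:
        planted = rng.random(config.n_pos) < config.plant_prob
        for offset, char in enumerate(m.pattern.upper()):
            if char == "X":
                continue
            pos_idx[planted, m.start - 1 + offset] = _BASE_INDEX[char]
    neg_idx = _random_windows(rng, config.n_neg, bg)

    records = [
        SequenceRecord(f"pos_{i}", "".join(ALPHABET[b] for b in row), label=1)
        for i, row in enumerate(pos_idx)
    ]
    records += [
        SequenceRecord(f"neg_{i}", "".join(ALPHABET[b] for b in row), label=0)
        for i, row in enumerate(neg_idx)
    ]
    return records


def composition_matrix(records: Sequence[SequenceRecord]) -> CompositionMatrix:
    """Per-position nucleotide composition of a set of equal-length sequences."""
    if not records:
        raise ValueError("no records")
    length = len(records[0].seq)
    counts = np.zeros((length, 4), dtype=float)
    for rec in records:
        if len(rec.seq) != length:
            raise ValueError(f"mixed sequence lengths ({rec.id})")
        for i, base in enumerate(rec.seq):
            counts[i, _BASE_INDEX[base]] += 1
    return CompositionMatrix(freq=counts / len(records), n=len(records))


def write_dataset(records: Sequence[SequenceRecord], out_dir: str | Path,
                  stem: str = "synthetic") -> tuple[Path, Path]:
    """Write the two-file per-class FASTA layout consumed by ``seqdata``."""
    from .seqdata import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos_path = out_dir / f"{stem}_pos.fasta"
    neg_path = out_dir / f"{stem}_neg.fasta"
    write_fasta([r for r in records if r.label == 1], pos_path)
    write_fasta([r for r in records if r.label == 0], neg_path)
    return pos_path, neg_path
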