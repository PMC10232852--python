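"""In-silico saturation mutagenesis of 41-nt windows.

Every position of a window is substituted with each of the three alternative
bases (41 x 3 = 123 single-base mutants), the trained ensemble scores all
mutants plus the wild type in one batch, and the effect of mutation ``(i, b)``
is the probability change ``delta[i, b] = p(mutant) - p(wild type)``.
Positive effects push the window toward the modified (positive) class.
Wild-type cells are fixed at zero.  The centre position is mutated like any
other (mutating the centre U away is biologically definitional-breaking for
m5U, so downstream summaries may mask it, but the model's response to it is
still informative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqdata import ALPHABET, CENTER_POSITION, WINDOW_LENGTH, SequenceRecord, one_hot_encode
from .training import EnsembleModel, predict_proba

__all__ = [
    "MutationEffectMatrix", "saturation_mutants", "effect_scores",
    "effect_heatmap_table", "read_heatmap_table",
]

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class MutationEffectMatrix:
    """41x4 grid of predicted-probability changes under single-base substitution."""

    delta: np.ndarray
    wt_prob: float
    seq_id: str
    seq: str

    def masked(self, mask_center: bool = True) -> np.ndarray:
        """Copy of delta with the centre row zeroed (centre U is definitional)."""
        d = self.delta.copy()
        if mask_center:
            d[CENTER_POSITION - 1] = 0.0
        return d

    def top_positions(self, k: int = 3, mask_center: bool = False) -> list[int]:
        """0-based positions of the k largest per-position |delta| maxima."""
        mag = np.abs(self.masked(mask_center)).max(axis=1)
        return list(np.argsort(mag)[::-1][:k])


def _validate_seq(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if len(seq) != WINDOW_LENGTH or set(seq) - set(ALPHABET):
        raise ValueError(f"need a valid {WINDOW_LENGTH}-nt sequence over {{A,C,G,U}}")
    return seq


def saturation_mutants(seq: str) -> list[tuple[int, str, str]]:
    """All 123 single-base mutants as (0-based position, base, mutant sequence).

    Position-major, bases in (A, C, G, U) order; the wild-type base at each
    position is skipped, so every mutant has Hamming distance 1 to the input.
    """
    seq = _validate_seq(seq)
    mutants = []
    for i, wt in enumerate(seq):
        for base in ALPHABET:
            if base != wt:
                mutants.append((i, base, seq[:i] + base + seq[i + 1:]))
    return mutants


def effect_scores(ensemble: EnsembleModel, seq: str, seq_id: str = "") -> MutationEffectMatrix:
    """Score all single-base mutants of one window in a single forward batch."""
    seq = _validate_seq(seq)
    mutants = saturation_mutants(seq)
    records = [SequenceRecord("wt", seq)] + [
        SequenceRecord(f"mut_{i}_{b}", m) for i, b, m in mutants
    ]
    batch = one_hot_encode(records)
    probs = predict_proba(ensemble, batch.x)
    wt_prob = float(probs[0])
    delta = np.zeros((WINDOW_LENGTH, 4), dtype=np.float64)
    for (i, base, _), p in zip(mutants, probs[1:]):
        delta[i, _BASE_INDEX[base]] = p - wt_prob
    return MutationEffectMatrix(delta=delta, wt_prob=wt_prob, seq_id=seq_id, seq=seq)


def effect_heatmap_table(mem: MutationEffectMatrix):
    """4x41 DataFrame (rows A,C,G,U; columns 1..41); wild-type cells hold 'WT'.

    Numeric cells carry the probability change; the table round-trips through
    :func:`read_heatmap_table`.
    """
    import pandas as pd

    table = pd.DataFrame(mem.delta.T.astype(object),
                         index=list(ALPHABET),
                         columns=np.arange(1, WINDOW_LENGTH + 1))
    for i, base in enumerate(mem.seq):
        table.loc[base, i + 1] = "WT"
    return table


def read_heatmap_table(path: str | Path) -> MutationEffectMatrix:
    """Inverse of writing :func:`effect_heatmap_table` to CSV."""
    import pandas as pd

    table = pd.read_csv(path, index_col=0)
    table.columns = table.columns.astype(int)
    wt = table.apply(lambda col: col[col == "WT"].index[0])
    seq = "".join(wt[i] for i in sorted(wt.index))
    values = table.replace("WT", 0.0).astype(float).to_numpy().T
    return MutationEffectMatrix(delta=values, wt_prob=np.nan, seq_id=Path(path).stem, seq=seq)
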