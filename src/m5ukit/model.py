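"""Model/Results front end for m5U site classification.

Follows the familiar two-object pattern of statistical modelling packages:
:class:`M5USiteClassifier` binds data and an architecture choice, ``fit()``
runs the full training protocol (stratified 70/10/20 split, 5-member
ensemble, 20 epochs each) and returns an :class:`M5UClassifierResults`
carrying the trained ensemble, held-out metrics and per-member loss
histories, with prediction, interpretation (UMAP, Shapley logos) and
saturation mutagenesis hanging off it.

Example
-------
>>> from m5ukit import synthdata
>>> from m5ukit.model import M5USiteClassifier
>>> records = synthdata.generate_dataset(synthdata.SyntheticConfig(seed=7))
>>> res = M5USiteClassifier(records, architecture="CNN_BiLSTM").fit(seed=7)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import interpret, mutagenesis
from .architectures import ArchitectureSpec, architecture_spec
from .metrics import MetricReport, evaluate
from .seqdata import (DatasetSplit, EncodedBatch, SequenceRecord, one_hot_encode,
                      read_labeled_sequences, three_way_split, validate_records)
from .training import (EnsembleModel, TrainingConfig, load_ensemble, predict_class,
                       predict_proba, save_ensemble, train_ensemble)

__all__ = ["M5USiteClassifier", "M5UClassifierResults"]


class M5USiteClassifier:
    """A convolutional-recurrent m5U window classifier bound to a dataset.

    Parameters
    ----------
    records : sequence of SequenceRecord
        Labelled 41-nt windows (label 1 = m5U, 0 = unmodified).
    architecture : str or ArchitectureSpec
        One of the five family names (default ``"CNN_BiLSTM"``, the stack
        with the best benchmark record) or an explicit spec.
    training : TrainingConfig
        The training regime; defaults to the published protocol.
    split_fractions : (float, float, float)
        Stratified train/validation/test fractions, default (0.70, 0.10, 0.20).
    """

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        architecture: str | ArchitectureSpec = "CNN_BiLSTM",
        training: TrainingConfig | None = None,
        split_fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    ):
        self.records = validate_records(list(records))
        if not self.records:
            raise ValueError("no valid records")
        self.spec = (architecture if isinstance(architecture, ArchitectureSpec)
                     else architecture_spec(architecture))
        self.training = training if training is not None else TrainingConfig()
        self.split_fractions = split_fractions

    @classmethod
    def from_fasta(cls, pos_path, neg_path, **kwargs) -> "M5USiteClassifier":
        """Build from the two-file per-class FASTA layout."""
        return cls(read_labeled_sequences(pos_path, neg_path), **kwargs)

    def fit(self, seed: int | None = None, verbose: bool = False) -> "M5UClassifierResults":
        """Split, train the ensemble, and evaluate on the held-out test set."""
        config = self.training if seed is None else replace(self.training, seed=seed)
        split = three_way_split(self.records, fractions=self.split_fractions,
                                seed=config.seed)
        ensemble = train_ensemble(self.spec, split, config, verbose=verbose)
        return M5UClassifierResults(model=self, ensemble=ensemble, split=split)


class M5UClassifierResults:
    """Fitted ensemble plus its data split; evaluation and interpretation API."""

    def __init__(self, model: M5USiteClassifier | None, ensemble: EnsembleModel,
                 split: DatasetSplit):
        self.model = model
        self.ensemble = ensemble
        self.split = split
        self._test_batch: EncodedBatch | None = None
        self._report: MetricReport | None = None

    # -- evaluation --------------------------------------------------------
    @property
    def test_batch(self) -> EncodedBatch:
        if self._test_batch is None:
            self._test_batch = one_hot_encode(self.split.test)
        return self._test_batch

    @property
    def report(self) -> MetricReport:
        """Seven-metric report on the held-out test fraction."""
        if self._report is None:
            batch = self.test_batch
            self._report = evaluate(batch.y, predict_proba(self.ensemble, batch))
        return self._report

    def predict_proba(self, data) -> np.ndarray:
        """Ensemble-mean probability for records, a batch, or a raw tensor."""
        if isinstance(data, EncodedBatch) or isinstance(data, np.ndarray):
            return predict_proba(self.ensemble, data)
        return predict_proba(self.ensemble, one_hot_encode(list(data)))

    def predict_class(self, data, threshold: float = 0.5) -> np.ndarray:
        return predict_class(self.predict_proba(data), threshold)

    def summary(self) -> str:
        """Aligned text summary: architecture, fit protocol, test metrics."""
        spec, cfg = self.ensemble.spec, self.ensemble.config
        n_params = self.ensemble.members[0].n_params
        split_n = tuple(len(part) for part in self.split)
        lines = [
            "m5U site classifier results",
            "=" * 45,
            f"{'architecture:':<24}{spec.name}",
            f"{'trainable parameters:':<24}{n_params:,} per member",
            f"{'ensemble members:':<24}{len(self.ensemble)}",
            f"{'training:':<24}adam lr={cfg.learning_rate}, "
            f"{cfg.epochs} epochs, batch {cfg.batch_size}",
            f"{'split (train/val/test):':<24}{split_n[0]}/{split_n[1]}/{split_n[2]}",
            f"{'seed:':<24}{cfg.seed}",
            "-" * 45,
            "held-out test metrics",
            str(self.report),
        ]
        return "\n".join(lines)

    # -- interpretation ----------------------------------------------------
    def layer_activation(self, layer_selector, data=None, member: int = 0):
        """Activations of one member's layer on ``data`` (default: test set)."""
        batch = self.test_batch if data is None else (
            data if isinstance(data, EncodedBatch) else one_hot_encode(list(data)))
        return interpret.extract_layer_output(self.ensemble, layer_selector,
                                              batch, member=member)

    def layer_embedding(self, layer_selector, data=None, member: int = 0,
                        n_neighbors: int = 15, min_dist: float = 0.1, seed: int = 0):
        """2-D UMAP of one layer's activations."""
        act = self.layer_activation(layer_selector, data, member)
        return interpret.umap_project(act, n_neighbors=n_neighbors,
                                      min_dist=min_dist, seed=seed)

    def background_batch(self, n: int = 100, seed: int = 0) -> EncodedBatch:
        """Seeded random subsample of training sequences (SHAP reference)."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self.split.train), size=min(n, len(self.split.train)),
                         replace=False)
        return one_hot_encode([self.split.train[i] for i in idx])

    def attributions(self, records: Sequence[SequenceRecord], background=None,
                     n_samples: int = 64, seed: int = 0):
        """Shapley attribution matrices for the given records."""
        bg = background if background is not None else self.background_batch(seed=seed)
        batch = one_hot_encode(list(records))
        return [
            interpret.shap_attributions(self.ensemble, batch.x[i], bg,
                                        method="expected_gradients",
                                        n_samples=n_samples, seed=seed + i,
                                        seq_id=batch.ids[i])
            for i in range(len(batch))
        ]

    def attribution_logo(self, records, background=None, n_samples: int = 64,
                         seed: int = 0):
        """Normalized, accumulated attribution matrix over ``records``."""
        attrs = self.attributions(records, background, n_samples, seed)
        return interpret.normalize_and_accumulate(attrs, [r.seq for r in records])

    def mutation_effects(self, seq_or_record) -> mutagenesis.MutationEffectMatrix:
        """Saturation-mutagenesis effect matrix for one window."""
        if isinstance(seq_or_record, SequenceRecord):
            return mutagenesis.effect_scores(self.ensemble, seq_or_record.seq,
                                             seq_id=seq_or_record.id)
        return mutagenesis.effect_scores(self.ensemble, seq_or_record)

    # -- persistence -------------------------------------------------------
    def save(self, out_dir) -> Path:
        return save_ensemble(self.ensemble, out_dir)

    @classmethod
    def from_saved(cls, in_dir, split: DatasetSplit | None = None) -> "M5UClassifierResults":
        ensemble = load_ensemble(in_dir)
        empty = DatasetSplit(train=[], validation=[], test=[])
        return cls(model=None, ensemble=ensemble, split=split or empty)
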