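"""Shared fixtures: tiny architectures, small synthetic datasets, FASTA writers."""

from __future__ import annotations

import pytest

from m5ukit.architectures import ArchitectureSpec, LayerSpec
from m5ukit.seqdata import three_way_split
from m5ukit.synthdata import SyntheticConfig, generate_dataset
from m5ukit.training import TrainingConfig, train_ensemble


def tiny_spec(name: str = "CNN") -> ArchitectureSpec:
    """A small conv stack that trains in seconds on a few hundred windows."""
    return ArchitectureSpec(name=name, layers=[
        LayerSpec("conv1d", {"filters": 32, "kernel_size": 7, "stride": 1,
                             "activation": "relu"}),
        LayerSpec("maxpool1d", {"pool_size": 4, "stride": 4}),
        LayerSpec("dense", {"units": 32}),
        LayerSpec("dropout", {"rate": 0.2}),
        LayerSpec("activation", {"kind": "relu"}),
        LayerSpec("output", {"units": 1, "activation": "sigmoid"}),
    ])


@pytest.fixture(scope="session")
def small_records():
    """400 balanced synthetic windows with the default planted motifs."""
    return generate_dataset(SyntheticConfig(n_pos=200, n_neg=200, seed=5))


@pytest.fixture(scope="session")
def small_split(small_records):
    return three_way_split(small_records, seed=5)


@pytest.fixture(scope="session")
def small_ensemble(small_split):
    """A quickly trained 2-member ensemble of the tiny conv stack."""
    cfg = TrainingConfig(epochs=8, repeats=2, seed=5)
    return train_ensemble(tiny_spec(), small_split, cfg)


@pytest.fixture()
def write_class_fastas(tmp_path):
    """Writer producing the two-file per-class FASTA layout in tmp_path."""

    def _write(records, stem="data"):
        pos = tmp_path / f"{stem}_pos.fasta"
        neg = tmp_path / f"{stem}_neg.fasta"
        with open(pos, "w") as fp, open(neg, "w") as fn:
            for r in records:
                fh = fp if r.label == 1 else fn
                fh.write(f">{r.id}\n{r.seq}\n")
        return pos, neg

    return _write
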