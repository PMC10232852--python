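"""The five convolutional/recurrent architectures and their hyperparameter grid.

Each architecture is held as a declarative, ordered stack of
:class:`LayerSpec` entries (the same layers a practitioner would write in a
Keras model template): valid 1-D convolutions with ReLU, non-overlapping max
pooling, bidirectional LSTM/GRU blocks (tanh cell activation, sigmoid
recurrent activation), a 256-unit dense block with 20% dropout and ReLU, and
a single sigmoid output unit.  Recurrent "units" are counted per direction,
so a bidirectional block of ``u`` units emits ``2u`` channels.

``build_model`` realises a spec as an executable :class:`~m5ukit.nn.Network`,
inserting the framework-implicit glue (``return_sequences`` on stacked
recurrent layers, a flatten before dense layers that receive a sequence).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import nn

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "GridSearchSpace",
    "FAMILIES",
    "architecture_spec",
    "conv_output_length",
    "shape_trace",
    "build_model",
    "grid_search",
]

FAMILIES = ("CNN", "BiLSTM", "BiGRU", "CNN_BiLSTM", "CNN_BiGRU")
_KINDS = ("conv1d", "maxpool1d", "bilstm", "bigru", "dense", "dropout", "activation", "output")


@dataclass(frozen=True)
class LayerSpec:
    """One declarative layer: a kind plus kind-specific parameters."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; one of {_KINDS}")
        for key in ("filters", "kernel_size", "stride", "pool_size", "units"):
            if key in self.params and (not isinstance(self.params[key], int)
                                       or self.params[key] < 1):
                raise ValueError(f"{self.kind}.{key} must be a positive integer")
        if self.kind == "dropout" and not 0.0 <= self.params.get("rate", 0.0) < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass
class ArchitectureSpec:
    """An ordered layer stack for one model family, on (41, 4) one-hot input."""

    name: str
    layers: list[LayerSpec]
    input_shape: tuple[int, int] = (41, 4)

    def __post_init__(self) -> None:
        if not self.layers or self.layers[-1].kind != "output":
            raise ValueError("architecture must end with an output layer")

    # -- structured-text round trip (user-editable model templates) -------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "layers": [{"kind": l.kind, "params": dict(l.params)} for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        layers = [LayerSpec(e["kind"], dict(e.get("params", {}))) for e in d["layers"]]
        return cls(name=d["name"], layers=layers,
                   input_shape=tuple(d.get("input_shape", (41, 4))))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ArchitectureSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GridSearchSpace:
    """The exhaustive hyperparameter grid searched when tuning the stacks."""

    conv_layers: tuple = (1, 2, 3)
    kernel_size: tuple = (3, 5, 7, 9, 11)
    filters: tuple = (50, 150, 250)
    pool_size: tuple = (2, 4, 6, 8, 10)
    lstm_layers: tuple = (1, 2, 3)
    lstm_units: tuple = (32, 64, 128, 256)
    gru_layers: tuple = (1, 2, 3)
    gru_units: tuple = (32, 64, 128, 256)


def conv_output_length(length: int, kernel: int, stride: int = 1) -> int:
    """Output length of a valid (unpadded) convolution or pooling window."""
    if kernel > length:
        raise ValueError(f"kernel/pool size {kernel} exceeds input length {length}")
    if stride < 1:
        raise ValueError("stride must be positive")
    return (length - kernel) // stride + 1


def _dense_block(units: int = 256, rate: float = 0.2) -> list[LayerSpec]:
    return [
        LayerSpec("dense", {"units": units}),
        LayerSpec("dropout", {"rate": rate}),
        LayerSpec("activation", {"kind": "relu"}),
        LayerSpec("output", {"units": 1, "activation": "sigmoid"}),
    ]


def _conv(filters: int, kernel: int) -> LayerSpec:
    return LayerSpec("conv1d", {"filters": filters, "kernel_size": kernel,
                                "stride": 1, "activation": "relu"})


def architecture_spec(name: str) -> ArchitectureSpec:
    """Return the published stack for one of the five model families.

    Accepts the canonical names (``CNN_BiLSTM``) and their CLI spellings
    (``cnn-bilstm``).
    """
    key = name.replace("-", "_").upper()
    canonical = {f.upper(): f for f in FAMILIES}
    if key not in canonical:
        raise ValueError(f"unknown architecture {name!r}; one of {FAMILIES}")
    family = canonical[key]
    if family == "CNN":
        layers = [_conv(250, 11), _conv(250, 11),
                  LayerSpec("maxpool1d", {"pool_size": 10, "stride": 10})]
    elif family == "BiLSTM":
        layers = [LayerSpec("bilstm", {"units": 256}), LayerSpec("bilstm", {"units": 256})]
    elif family == "BiGRU":
        layers = [LayerSpec("bigru", {"units": 256})]
    elif family == "CNN_BiLSTM":
        layers = [_conv(250, 7), _conv(250, 7),
                  LayerSpec("maxpool1d", {"pool_size": 4, "stride": 4}),
                  LayerSpec("bilstm", {"units": 64})]
    else:  # CNN_BiGRU
        layers = [_conv(250, 11),
                  LayerSpec("maxpool1d", {"pool_size": 10, "stride": 10}),
                  LayerSpec("bigru", {"units": 256})]
    return ArchitectureSpec(name=family, layers=layers + _dense_block())


def shape_trace(spec: ArchitectureSpec) -> list[int]:
    """Time-axis length after the input and each conv/pool layer.

    This is the symbolic trace the built model must match, e.g. the CNN gives
    ``41 -> 31 -> 21 -> 2`` and CNN_BiLSTM ``41 -> 35 -> 29 -> 7``.
    """
    trace = [spec.input_shape[0]]
    for layer in spec.layers:
        if layer.kind == "conv1d":
            trace.append(conv_output_length(trace[-1], layer.params["kernel_size"],
                                            layer.params.get("stride", 1)))
        elif layer.kind == "maxpool1d":
            trace.append(conv_output_length(trace[-1], layer.params["pool_size"],
                                            layer.params.get("stride",
                                                             layer.params["pool_size"])))
    return trace


def build_model(spec: ArchitectureSpec, seed: int = 0, dtype=np.float32) -> nn.Network:
    """Realise an :class:`ArchitectureSpec` as an executable network.

    Stacked recurrent layers return full sequences except the last, which
    emits its final hidden states; a flatten is inserted when a dense layer
    receives sequence-shaped input.
    """
    kinds = [l.kind for l in spec.layers]
    layers: list[nn.Layer] = []
    sequence_shaped = True
    for i, ls in enumerate(spec.layers):
        p = ls.params
        if ls.kind == "conv1d":
            layers.append(nn.Conv1D(p["filters"], p["kernel_size"], p.get("stride", 1),
                                    p.get("activation", "relu")))
        elif ls.kind == "maxpool1d":
            layers.append(nn.MaxPool1D(p["pool_size"], p.get("stride")))
        elif ls.kind in ("bilstm", "bigru"):
            more_recurrent = any(k in ("bilstm", "bigru") for k in kinds[i + 1:])
            cls = nn.BiLSTM if ls.kind == "bilstm" else nn.BiGRU
            layers.append(cls(p["units"], return_sequences=more_recurrent))
            sequence_shaped = more_recurrent
        elif ls.kind in ("dense", "output"):
            if sequence_shaped:
                layers.append(nn.Flatten())
                sequence_shaped = False
            units = p.get("units", 1 if ls.kind == "output" else 256)
            act = p.get("activation", "sigmoid" if ls.kind == "output" else None)
            name = "output" if ls.kind == "output" else "dense"
            layers.append(nn.Dense(units, activation=act, name=name))
        elif ls.kind == "dropout":
            layers.append(nn.Dropout(p["rate"]))
        elif ls.kind == "activation":
            layers.append(nn.Activation(p.get("kind", "relu")))
    return nn.Network(layers, input_shape=spec.input_shape, dtype=dtype, seed=seed)


# -- grid search -----------------------------------------------------------

def _family_configs(space: GridSearchSpace, family: str) -> Iterable[dict]:
    family = family.replace("-", "_").upper()
    if family == "CNN":
        for nl, k, f, p in itertools.product(space.conv_layers, space.kernel_size,
                                             space.filters, space.pool_size):
            yield {"conv_layers": nl, "kernel_size": k, "filters": f, "pool_size": p}
    elif family in ("BILSTM", "BIGRU"):
        nl_set = space.lstm_layers if family == "BILSTM" else space.gru_layers
        u_set = space.lstm_units if family == "BILSTM" else space.gru_units
        for nl, u in itertools.product(nl_set, u_set):
            yield {"rnn_layers": nl, "units": u}
    elif family in ("CNN_BILSTM", "CNN_BIGRU"):
        u_set = space.lstm_units if family == "CNN_BILSTM" else space.gru_units
        for nl, k, f, p, u in itertools.product(space.conv_layers, space.kernel_size,
                                                space.filters, space.pool_size, u_set):
            yield {"conv_layers": nl, "kernel_size": k, "filters": f,
                   "pool_size": p, "units": u}
    else:
        raise ValueError(f"unknown family {family!r}")


def _config_to_spec(family: str, cfg: dict) -> ArchitectureSpec:
    family = family.replace("-", "_").upper()
    canonical = {f.upper(): f for f in FAMILIES}[family]
    layers: list[LayerSpec] = []
    if "conv_layers" in cfg:
        layers += [_conv(cfg["filters"], cfg["kernel_size"])] * cfg["conv_layers"]
        layers.append(LayerSpec("maxpool1d", {"pool_size": cfg["pool_size"],
                                              "stride": cfg["pool_size"]}))
    kind = "bilstm" if "BILSTM" in family else ("bigru" if "BIGRU" in family else None)
    if kind is not None:
        layers += [LayerSpec(kind, {"units": cfg["units"]})] * cfg.get("rnn_layers", 1)
    return ArchitectureSpec(name=canonical, layers=layers + _dense_block())


def grid_search(
    space: GridSearchSpace,
    data,
    family: str,
    budget: int | None = None,
    epochs: int = 5,
    seed: int = 0,
    table_path: str | Path | None = None,
):
    """Select the configuration with the best validation accuracy.

    Trains one model per candidate configuration (single member, ``epochs``
    epochs) on ``data`` (a :class:`~m5ukit.seqdata.DatasetSplit`) and scores
    validation-set accuracy; ties break toward fewer parameters.  ``budget``
    randomly subsamples the candidate list (seeded).  Configurations whose
    shape chain is infeasible on the input length are recorded as such and
    skipped.

    Returns ``(best_spec, table)`` where ``table`` is a pandas DataFrame of
    every evaluated configuration; with ``table_path`` the table is also
    written as CSV.
    """
    import pandas as pd

    from .metrics import accuracy, confusion
    from .training import TrainingConfig, train_once

    configs = list(_family_configs(space, family))
    if not configs:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    if budget is not None and budget < len(configs):
        keep = rng.choice(len(configs), size=budget, replace=False)
        configs = [configs[i] for i in sorted(keep)]

    from .seqdata import one_hot_encode

    val_batch = one_hot_encode(data.validation)
    rows = []
    best: tuple[float, int, ArchitectureSpec] | None = None
    for i, cfg in enumerate(configs):
        spec = _config_to_spec(family, cfg)
        try:
            shape_trace(spec)
        except ValueError:
            rows.append({**cfg, "val_acc": np.nan, "n_params": np.nan,
                         "status": "infeasible"})
            continue
        tc = TrainingConfig(epochs=epochs, repeats=1, seed=int(rng.integers(2**31)))
        model, _ = train_once(spec, data, tc)
        probs = model.predict(val_batch.x)
        acc = accuracy(confusion(val_batch.y, (probs >= 0.5).astype(int)))
        n_params = model.n_params
        rows.append({**cfg, "val_acc": acc, "n_params": n_params, "status": "ok"})
        key = (acc, -n_params)
        if best is None or key > (best[0], -best[1]):
            best = (acc, n_params, spec)
    table = pd.DataFrame(rows)
    if table_path is not None:
        table.to_csv(table_path, index=False)
    if best is None:
        raise ValueError("no feasible configuration in the search space")
    return best[2], table
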