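"""Training regime and ensembling.

Every model is trained with Adam (learning rate 0.001), binary cross-entropy,
batch size 64, for exactly 20 epochs — no early stopping and no schedule.
The validation fraction is scored after every epoch (loss history only; it
never influences the weights).  The deployed predictor is an ensemble of 5
independently trained members whose averaged probability is the prediction;
member ``i`` uses seed ``seed + i`` and re-draws its own train/validation
partition from the pooled train+validation records, so members differ through
both initialisation and data order while the test fraction stays untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .architectures import ArchitectureSpec, build_model
from .seqdata import DatasetSplit, EncodedBatch, one_hot_encode, stratified_split

__all__ = [
    "TrainingConfig", "TrainingHistory", "EnsembleModel",
    "train_once", "train_ensemble", "predict_proba", "predict_class",
    "save_ensemble", "load_ensemble",
]


@dataclass(frozen=True)
class TrainingConfig:
    """The fixed training regime; defaults are the published values."""

    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 64
    repeats: int = 5
    seed: int = 0
    class_weighting: bool = False
    optimizer: str = "adam"
    loss: str = "binary_cross_entropy"

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.repeats) < 1:
            raise ValueError("epochs, batch_size and repeats must be positive")
        if self.optimizer != "adam" or self.loss != "binary_cross_entropy":
            raise ValueError("only adam + binary cross-entropy are supported")


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss and end-of-epoch validation loss."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


@dataclass
class EnsembleModel:
    """A bag of independently trained members sharing one architecture."""

    members: list[nn.Network]
    spec: ArchitectureSpec
    config: TrainingConfig
    histories: list[TrainingHistory]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.histories):
            raise ValueError("one history per member required")

    def __len__(self) -> int:
        return len(self.members)


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights balancing the classes to equal total mass."""
    n, n_pos = len(y), y.sum()
    w_pos = n / (2.0 * n_pos)
    w_neg = n / (2.0 * (n - n_pos))
    return np.where(y == 1, w_pos, w_neg)


def train_once(
    spec: ArchitectureSpec,
    split: DatasetSplit,
    config: TrainingConfig,
    seed: int | None = None,
) -> tuple[nn.Network, TrainingHistory]:
    """Train a single model on ``split.train``; returns (model, history).

    ``seed`` (default ``config.seed``) drives weight initialisation, dropout
    and the per-epoch shuffling of minibatches.
    """
    if not split.train:
        raise ValueError("empty training set")
    seed = config.seed if seed is None else seed
    model = build_model(spec, seed=seed)
    optimizer = nn.Adam(learning_rate=config.learning_rate)
    rng = np.random.default_rng(seed)

    train = one_hot_encode(split.train)
    val = one_hot_encode(split.validation) if split.validation else None
    if train.y is None:
        raise ValueError("training records must be labelled")
    weights = _class_weights(train.y) if config.class_weighting else None

    history = TrainingHistory()
    n = len(train)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, sizes = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = train.x[idx], train.y[idx]
            if weights is None:
                loss = model.train_step(xb, yb, optimizer)
            else:
                loss = _weighted_train_step(model, xb, yb, weights[idx], optimizer)
            losses.append(loss)
            sizes.append(len(idx))
        history.train_loss.append(float(np.average(losses, weights=sizes)))
        if val is not None:
            history.val_loss.append(nn.binary_cross_entropy(model.predict(val.x), val.y))
    return model, history


def _weighted_train_step(model: nn.Network, x, y, w, optimizer) -> float:
    """Minibatch step with per-sample weights (mean-normalised within batch)."""
    p = model.forward(x, training=True)
    w = np.asarray(w, dtype=np.float64)
    w = w / w.mean()
    pc = np.clip(p.astype(np.float64), 1e-7, 1 - 1e-7)
    loss = float(-np.mean(w * (y * np.log(pc) + (1 - y) * np.log(1 - pc))))
    model.zero_grads()
    dz = ((p - y) * w / x.shape[0]).astype(model.dtype)[:, None]
    da = model.layers[-1].backward_preact(dz)
    for layer in reversed(model.layers[:-1]):
        da = layer.backward(da)
    optimizer.step(model.parameters(), model.gradients())
    return loss


def _member_split(split: DatasetSplit, seed: int) -> DatasetSplit:
    """Re-draw the train/validation partition from the pooled train+validation
    records (test untouched), preserving the train:validation proportion."""
    pool = split.train + split.validation
    if not split.validation:
        return replace(split, seed=seed)
    frac = len(split.train) / len(pool)
    train, val = stratified_split(pool, train_frac=frac, seed=seed)
    return DatasetSplit(train=train, validation=val, test=split.test,
                        fractions=split.fractions, seed=seed)


def train_ensemble(
    spec: ArchitectureSpec,
    split: DatasetSplit,
    config: TrainingConfig,
    verbose: bool = False,
) -> EnsembleModel:
    """Train ``config.repeats`` members with seeds ``config.seed + i``."""
    members, histories = [], []
    for i in range(config.repeats):
        seed = config.seed + i
        member_split = _member_split(split, seed)
        model, history = train_once(spec, member_split, config, seed=seed)
        members.append(model)
        histories.append(history)
        if verbose:
            tail = f", val loss {history.val_loss[-1]:.4f}" if history.val_loss else ""
            print(f"  member {i + 1}/{config.repeats}: "
                  f"train loss {history.train_loss[-1]:.4f}{tail}")
    return EnsembleModel(members=members, spec=spec, config=config, histories=histories)


def predict_proba(ensemble: EnsembleModel, batch: EncodedBatch | np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    """Arithmetic mean of the member probabilities."""
    x = batch.x if isinstance(batch, EncodedBatch) else np.asarray(batch)
    if x.ndim != 3 or x.shape[1:] != tuple(ensemble.spec.input_shape):
        raise ValueError(
            f"batch shape {x.shape[1:]} does not match model input "
            f"{tuple(ensemble.spec.input_shape)}")
    probs = np.stack([m.predict(x, batch_size=batch_size) for m in ensemble.members])
    return probs.mean(axis=0)


def predict_class(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary class from probability; ties (p == threshold) go to positive."""
    return (np.asarray(probs) >= threshold).astype(int)


# -- persistence -----------------------------------------------------------

def save_ensemble(ensemble: EnsembleModel, out_dir: str | Path) -> Path:
    """Write member weights (npz) plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    member_files = []
    for i, member in enumerate(ensemble.members):
        fname = f"member_{i}.npz"
        member.save_weights(out_dir / fname)
        member_files.append(fname)
    manifest = {
        "architecture": ensemble.spec.to_dict(),
        "training": {
            "learning_rate": ensemble.config.learning_rate,
            "epochs": ensemble.config.epochs,
            "batch_size": ensemble.config.batch_size,
            "repeats": ensemble.config.repeats,
            "seed": ensemble.config.seed,
            "class_weighting": ensemble.config.class_weighting,
        },
        "member_files": member_files,
        "member_seeds": [ensemble.config.seed + i for i in range(len(ensemble.members))],
        "histories": [{"train_loss": h.train_loss, "val_loss": h.val_loss}
                      for h in ensemble.histories],
    }
    path = out_dir / "ensemble.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def load_ensemble(in_dir: str | Path) -> EnsembleModel:
    """Reload a saved ensemble; predictions are bit-identical to pre-save."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "ensemble.json").read_text())
    spec = ArchitectureSpec.from_dict(manifest["architecture"])
    config = TrainingConfig(**manifest["training"])
    members, histories = [], []
    for i, fname in enumerate(manifest["member_files"]):
        model = build_model(spec, seed=manifest["member_seeds"][i])
        model.load_weights(in_dir / fname)
        members.append(model)
    for h in manifest["histories"]:
        histories.append(TrainingHistory(train_loss=h["train_loss"], val_loss=h["val_loss"]))
    return EnsembleModel(members=members, spec=spec, config=config, histories=histories)
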