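"""Model interpretation: hidden-layer manifolds and Shapley attribution.

Two complementary views of a trained site classifier are provided.

**Layer-wise manifold projection.**  Any hidden layer's activations are
extracted (multi-dimensional outputs flattened time-major to one row per
sample) and projected to 2-D with UMAP.  On a well-trained model the classes,
inseparable in the raw one-hot input, resolve into two clusters in the last
hidden layers; the silhouette score quantifies that separation.

**Shapley attribution.**  The contribution of feature ``i`` to prediction
``f(x)`` is its Shapley value

.. math::

    \\phi_i(f, x) = \\sum_{S \\subseteq S_{all} \\setminus i}
        \\frac{|S|!\\,(M - |S| - 1)!}{M!}
        \\left[ f_x(S \\cup i) - f_x(S) \\right]

where ``f_x(S)`` is the model output with features in ``S`` taken from ``x``
and the rest from a background reference, averaged over the background set.
Attributions satisfy additivity: ``f(x) = phi_0 + sum_i phi_i`` with
``phi_0`` the mean output over the background.  Three estimators are
provided: exact subset enumeration (small feature counts), permutation
sampling, and expected gradients (the path-integral estimator used for the
full 41x4 sequence models, where enumeration over positions is intractable).

The per-sequence logo pipeline mirrors the standard presentation: each
sequence's attribution matrix is rescaled so its largest magnitude is 0.25
(keeping per-sequence sums in [-1, 1] for sparse attributions), and scaled
values are accumulated position-by-observed-base across the dataset.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .nn import Network
from .seqdata import ALPHABET, EncodedBatch
from .training import EnsembleModel, predict_proba

__all__ = [
    "LayerActivation", "Embedding2D", "AttributionMatrix", "NormalizedAttribution",
    "extract_layer_output", "umap_project", "class_separation",
    "exact_shapley", "sampling_shapley", "expected_gradients",
    "shap_attributions", "per_base_importance", "normalize_and_accumulate",
    "attribution_table",
]

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class LayerActivation:
    """Activations of one layer: one flattened row per input sample."""

    layer_name: str
    matrix: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None


@dataclass
class Embedding2D:
    """A 2-D UMAP embedding of one layer's activations."""

    coords: np.ndarray
    layer_name: str
    umap_params: dict

    def to_csv(self, path, ids: Sequence[str] | None = None,
               labels: Sequence[int] | None = None) -> None:
        import pandas as pd

        n = self.coords.shape[0]
        df = pd.DataFrame({
            "id": ids if ids is not None else np.arange(n),
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
        })
        if labels is not None:
            df["label"] = labels
        df.to_csv(path, index=False)


@dataclass
class AttributionMatrix:
    """Shapley attributions for one sample.

    ``phi`` has the shape of the explained input (41x4 for sequence windows,
    with values on the one-hot channels).  ``phi0`` is the base value (mean
    model output over the background); ``residual = f_x - phi0 - sum(phi)``
    measures how far the estimate is from exact additivity (zero for the
    enumeration estimator, Monte-Carlo noise for expected gradients).
    """

    phi: np.ndarray
    phi0: float
    f_x: float
    residual: float
    seq_id: str = ""

    def check_additivity(self, tol: float = 1e-6) -> None:
        if abs(self.residual) > tol:
            raise AssertionError(
                f"additivity violated: |{self.residual:.3g}| > {tol:g}")


@dataclass
class NormalizedAttribution:
    """Per-sequence rescaled attributions and their dataset-level accumulation."""

    scaled: np.ndarray          # (n_seq, L, 4)
    accumulated: np.ndarray     # (L, 4), position-by-observed-base sums
    per_sequence_sum: np.ndarray


# -- layer activations and manifolds ---------------------------------------

def _single_model(model: Network | EnsembleModel, member: int = 0) -> Network:
    if isinstance(model, EnsembleModel):
        return model.members[member]
    return model


def extract_layer_output(
    model: Network | EnsembleModel,
    layer_selector: str | int,
    batch: EncodedBatch,
    member: int = 0,
    batch_size: int = 256,
) -> LayerActivation:
    """Forward pass truncated at a layer; output flattened to (N, D).

    ``'input'``/``'reshape'`` selects the raw one-hot input (D = L*4).  For an
    ensemble, the designated ``member`` (default the first) is dissected.
    Unknown layer names raise a ``KeyError`` listing the available layers.
    """
    net = _single_model(model, member)
    chunks = []
    for start in range(0, len(batch), batch_size):
        a = net.forward_to(layer_selector, batch.x[start:start + batch_size])
        chunks.append(a.reshape(a.shape[0], -1).astype(np.float64))
    name = layer_selector if isinstance(layer_selector, str) else net.layers[layer_selector].name
    return LayerActivation(layer_name=str(name), matrix=np.concatenate(chunks),
                           sample_ids=list(batch.ids), labels=batch.y)


def umap_project(
    activation: LayerActivation,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> Embedding2D:
    """Seeded 2-D UMAP of a layer activation matrix."""
    n = activation.matrix.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} samples, got {n}")
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that random_state forces 1 job
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        coords = reducer.fit_transform(activation.matrix)
    return Embedding2D(coords=np.asarray(coords, dtype=np.float64),
                       layer_name=activation.layer_name,
                       umap_params={"n_neighbors": n_neighbors,
                                    "min_dist": min_dist, "seed": seed})


def class_separation(embedding: Embedding2D, labels: Sequence[int]) -> float:
    """Silhouette score of the embedding under the class labels (in [-1, 1])."""
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(embedding.coords, np.asarray(labels)))


# -- Shapley estimators -----------------------------------------------------

def _predict_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(model, EnsembleModel):
        return lambda X: predict_proba(model, X)
    if isinstance(model, Network):
        return model.predict
    if callable(model):
        return lambda X: np.asarray(model(X), dtype=np.float64)
    raise TypeError(f"cannot predict with {type(model)!r}")


def _composite_values(f, x, background, masks, batch_size=4096) -> np.ndarray:
    """v(S) = mean_b f(x with players in S, b elsewhere) for each mask.

    Players are axis-0 slices of ``x``; ``masks`` is (n_masks, M) boolean.
    """
    B = background.shape[0]
    vals = np.empty(masks.shape[0])
    per = max(1, batch_size // B)
    for start in range(0, masks.shape[0], per):
        chunk = masks[start:start + per]
        X = np.repeat(background[None], chunk.shape[0], axis=0)  # (n, B, M, ...)
        for j, mask in enumerate(chunk):
            X[j][:, mask] = x[mask]
        flat = X.reshape(-1, *x.shape)
        out = f(flat).reshape(chunk.shape[0], B)
        vals[start:start + per] = out.mean(axis=1)
    return vals


def exact_shapley(model, x: np.ndarray, background: np.ndarray,
                  max_players: int = 16) -> tuple[np.ndarray, float]:
    """Exact Shapley values by weighted subset enumeration.

    Players are axis-0 entries of ``x`` (scalar features of a 1-D vector, or
    whole positions of a 2-D one-hot window).  Cost is ``2^M`` model batches;
    refuse beyond ``max_players``.  Returns ``(phi, phi0)`` with ``phi`` one
    value per player.
    """
    f = _predict_fn(model)
    x = np.asarray(x)
    background = np.asarray(background)
    if background.ndim == x.ndim:
        background = background[None] if background.shape == x.shape else background
    if background.shape[0] == 0:
        raise ValueError("empty background")
    M = x.shape[0]
    if M > max_players:
        raise ValueError(f"{M} players exceed max_players={max_players} "
                         "(use sampling_shapley or expected_gradients)")
    masks = np.array(list(itertools.product([False, True], repeat=M)), dtype=bool)
    v = _composite_values(f, x, background, masks)
    lookup = {mask.tobytes(): val for mask, val in zip(masks, v)}
    fact = [math.factorial(k) for k in range(M + 1)]
    phi = np.zeros(M)
    for mask, val in zip(masks, v):
        for i in range(M):
            if mask[i]:
                continue
            s = int(mask.sum())
            with_i = mask.copy()
            with_i[i] = True
            weight = fact[s] * fact[M - s - 1] / fact[M]
            phi[i] += weight * (lookup[with_i.tobytes()] - val)
    phi0 = v[0]  # empty coalition: background expectation
    return phi, phi0


def sampling_shapley(model, x: np.ndarray, background: np.ndarray,
                     n_permutations: int = 200, seed: int = 0) -> tuple[np.ndarray, float]:
    """Monte-Carlo Shapley values: marginal contributions along random
    player permutations, averaged (unbiased; error ~ 1/sqrt(n))."""
    f = _predict_fn(model)
    x = np.asarray(x)
    background = np.asarray(background)
    rng = np.random.default_rng(seed)
    M = x.shape[0]
    phi = np.zeros(M)
    for _ in range(n_permutations):
        order = rng.permutation(M)
        masks = np.zeros((M + 1, M), dtype=bool)
        for k, player in enumerate(order):
            masks[k + 1] = masks[k]
            masks[k + 1, player] = True
        v = _composite_values(f, x, background, masks)
        phi[order] += np.diff(v)
    phi /= n_permutations
    phi0 = float(_composite_values(f, x, background, np.zeros((1, M), dtype=bool))[0])
    return phi, phi0


def _input_gradient(model, X: np.ndarray) -> np.ndarray:
    """Gradient of the (ensemble-mean) probability with respect to the input."""
    if isinstance(model, EnsembleModel):
        g = model.members[0].input_gradient(X).astype(np.float64)
        for m in model.members[1:]:
            g += m.input_gradient(X).astype(np.float64)
        return g / len(model.members)
    if isinstance(model, Network):
        return model.input_gradient(X).astype(np.float64)
    raise TypeError("expected gradients require a Network or EnsembleModel")


def expected_gradients(model, x: np.ndarray, background: np.ndarray,
                       n_samples: int = 64, seed: int = 0) -> tuple[np.ndarray, float]:
    """Expected-gradients Shapley estimate for differentiable models.

    Averages ``(x - b) * grad f(b + alpha (x - b))`` over background draws
    ``b`` and uniform path positions ``alpha``; converges to the Aumann-
    Shapley allocation, which coincides with the one-hot position attribution
    in expectation and keeps constant features (the centre U) at exactly zero.
    """
    x = np.asarray(x, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    rng = np.random.default_rng(seed)
    b = background[rng.integers(background.shape[0], size=n_samples)]
    alpha = rng.random(n_samples).reshape(-1, *([1] * x.ndim))
    diff = x[None] - b
    points = b + alpha * diff
    grads = _input_gradient(model, points)
    phi = (diff * grads).mean(axis=0)
    phi0 = float(_predict_fn(model)(background).mean())
    return phi, phi0


def shap_attributions(
    model,
    x: np.ndarray,
    background: EncodedBatch | np.ndarray,
    method: str = "auto",
    n_samples: int = 64,
    seed: int = 0,
    seq_id: str = "",
    max_exact_players: int = 12,
) -> AttributionMatrix:
    """Shapley attribution of one prediction against a background reference.

    ``method='auto'`` enumerates exactly when the number of players (axis-0
    entries of ``x``) is small and falls back to expected gradients for
    sequence models.  For exact/sampling estimates on a 2-D one-hot window the
    per-position value is placed on the observed base's channel.
    """
    bg = background.x if isinstance(background, EncodedBatch) else np.asarray(background)
    if bg.shape[0] == 0:
        raise ValueError("empty background")
    x = np.asarray(x)
    if method == "auto":
        method = "exact" if x.shape[0] <= max_exact_players else "expected_gradients"
    if method == "exact":
        phi, phi0 = exact_shapley(model, x, bg)
    elif method == "sampling":
        phi, phi0 = sampling_shapley(model, x, bg, n_permutations=n_samples, seed=seed)
    elif method == "expected_gradients":
        phi, phi0 = expected_gradients(model, x, bg, n_samples=n_samples, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    if phi.ndim == 1 and x.ndim == 2:
        full = np.zeros_like(x, dtype=np.float64)
        full[np.arange(x.shape[0]), x.argmax(axis=1)] = phi
        phi = full
    f_x = float(_predict_fn(model)(x[None])[0])
    residual = f_x - phi0 - float(phi.sum())
    return AttributionMatrix(phi=phi, phi0=float(phi0), f_x=f_x,
                             residual=residual, seq_id=seq_id)


# -- logo-style aggregation -------------------------------------------------

def per_base_importance(attr: AttributionMatrix, seq: str) -> np.ndarray:
    """Letter heights for a logo: phi at the observed base of each position."""
    if attr.phi.shape[0] != len(seq):
        raise ValueError("sequence length does not match attribution matrix")
    idx = [_BASE_INDEX[b] for b in seq.upper().replace("T", "U")]
    return attr.phi[np.arange(len(seq)), idx]


def normalize_and_accumulate(
    attrs: Sequence[AttributionMatrix],
    seqs: Sequence[str],
) -> NormalizedAttribution:
    """Rescale each attribution matrix to max |value| 0.25 and accumulate.

    Scaling is per sequence (``phi * 0.25 / max|phi|``; an all-zero matrix is
    left untouched) and never changes a value's sign.  The accumulated matrix
    sums scaled values position-by-observed-base over the dataset: positive
    entries mark favoured features, negative entries disfavoured ones.  A
    per-sequence sum of scaled observed-base values outside [-1, 1] is
    flagged with a warning.
    """
    if not attrs:
        raise ValueError("no attributions to accumulate")
    if len(attrs) != len(seqs):
        raise ValueError("one sequence per attribution matrix required")
    L = attrs[0].phi.shape[0]
    scaled = np.zeros((len(attrs), L, 4))
    accumulated = np.zeros((L, 4))
    sums = np.zeros(len(attrs))
    for k, (attr, seq) in enumerate(zip(attrs, seqs)):
        peak = np.abs(attr.phi).max()
        scaled[k] = attr.phi * (0.25 / peak) if peak > 0 else attr.phi
        idx = [_BASE_INDEX[b] for b in seq.upper().replace("T", "U")]
        obs = scaled[k][np.arange(L), idx]
        accumulated[np.arange(L), idx] += obs
        sums[k] = obs.sum()
    out_of_range = np.abs(sums) > 1.0 + 1e-9
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} sequence(s) have summed scaled "
            "attributions outside [-1, 1]", stacklevel=2)
    return NormalizedAttribution(scaled=scaled, accumulated=accumulated,
                                 per_sequence_sum=sums)


def attribution_table(matrix: np.ndarray):
    """41x4 matrix as a DataFrame (position, A, C, G, U) for logo tools."""
    import pandas as pd

    df = pd.DataFrame(matrix, columns=list(ALPHABET))
    df.insert(0, "position", np.arange(1, matrix.shape[0] + 1))
    return df
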