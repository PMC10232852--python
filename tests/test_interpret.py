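"""Shapley estimators against enumeration oracles; manifolds; logo accumulation."""

import itertools
import math

import numpy as np
import pytest

from conftest import tiny_spec
from m5ukit.architectures import architecture_spec, build_model
from m5ukit.interpret import (AttributionMatrix, LayerActivation, class_separation,
                              exact_shapley, expected_gradients, extract_layer_output,
                              normalize_and_accumulate, per_base_importance,
                              sampling_shapley, shap_attributions, umap_project)
from m5ukit.seqdata import one_hot_encode


def _permutation_shapley(f, x, background):
    """Oracle: average marginal contribution over all M! player orderings."""
    M = x.shape[0]

    def value(subset):
        X = background.copy().astype(float)
        idx = list(subset)
        X[:, idx] = x[idx]
        return float(f(X).mean())

    cache = {}

    def v(subset):
        key = frozenset(subset)
        if key not in cache:
            cache[key] = value(key)
        return cache[key]

    phi = np.zeros(M)
    for order in itertools.permutations(range(M)):
        seen: set = set()
        for player in order:
            phi[player] += v(seen | {player}) - v(seen)
            seen.add(player)
    return phi / math.factorial(M), v(set())


def _surrogate(M, seed):
    """A nonlinear scoring function of M features with pairwise interactions."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 1, M)
    Q = rng.normal(0, 0.5, (M, M))

    def f(X):
        X = np.atleast_2d(X)
        return 1.0 / (1.0 + np.exp(-(X @ w + np.einsum("ni,ij,nj->n", X, Q, X))))

    return f


class TestExactShapley:
    @pytest.mark.parametrize("M", [3, 5, 8])
    def test_matches_full_permutation_enumeration(self, M):
        rng = np.random.default_rng(M)
        f = _surrogate(M, seed=M)
        x = rng.normal(0, 1, M)
        background = rng.normal(0, 1, (6, M))
        phi, phi0 = exact_shapley(f, x, background)
        phi_oracle, phi0_oracle = _permutation_shapley(f, x, background)
        assert np.abs(phi - phi_oracle).max() < 1e-10
        assert abs(phi0 - phi0_oracle) < 1e-12

    def test_additivity_exact(self):
        f = _surrogate(6, seed=1)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 6)
        background = rng.normal(0, 1, (8, 6))
        phi, phi0 = exact_shapley(f, x, background)
        assert abs(float(f(x[None])[0]) - phi0 - phi.sum()) < 1e-10

    def test_null_player_gets_zero(self):
        f = _surrogate(5, seed=3)
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 5)
        background = rng.normal(0, 1, (7, 5))
        background[:, 2] = x[2]  # feature 2 constant across x and background
        phi, _ = exact_shapley(f, x, background)
        assert phi[2] == 0.0

    def test_refuses_large_player_count(self):
        with pytest.raises(ValueError, match="max_players"):
            exact_shapley(lambda X: X.sum(1), np.zeros(20), np.zeros((2, 20)))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty background"):
            shap_attributions(lambda X: X.sum(1), np.zeros(4), np.zeros((0, 4)))


class TestSamplingShapley:
    def test_converges_to_exact(self):
        f = _surrogate(6, seed=5)
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 6)
        background = rng.normal(0, 1, (5, 6))
        phi_exact, _ = exact_shapley(f, x, background)
        phi_mc, _ = sampling_shapley(f, x, background, n_permutations=400, seed=0)
        assert np.abs(phi_mc - phi_exact).max() < 0.05


@pytest.fixture(scope="module")
def trained_tiny(small_split):
    from m5ukit.training import TrainingConfig, train_once

    model, _ = train_once(tiny_spec(), small_split,
                          TrainingConfig(epochs=6, repeats=1, seed=21))
    return model


class TestExpectedGradients:
    def test_constant_center_feature_is_null(self, trained_tiny, small_split):
        batch = one_hot_encode(small_split.train[:50])
        x = batch.x[0]
        phi, _ = expected_gradients(trained_tiny, x, batch.x[1:], n_samples=32, seed=0)
        assert np.all(phi[20] == 0.0)  # centre U identical in x and background

    def test_additivity_within_monte_carlo_tolerance(self, trained_tiny, small_split):
        batch = one_hot_encode(small_split.train[:80])
        x = batch.x[0]
        phi, phi0 = expected_gradients(trained_tiny, x, batch.x[1:], n_samples=512,
                                       seed=1)
        f_x = float(trained_tiny.predict(x[None])[0])
        assert abs(f_x - phi0 - phi.sum()) < 0.05

    def test_shap_attributions_wraps_and_records_residual(self, trained_tiny,
                                                          small_split):
        batch = one_hot_encode(small_split.train[:40])
        attr = shap_attributions(trained_tiny, batch.x[0], batch.x[1:],
                                 n_samples=64, seed=2, seq_id="s0")
        assert attr.phi.shape == (41, 4)
        assert attr.seq_id == "s0"
        assert np.isclose(attr.residual, attr.f_x - attr.phi0 - attr.phi.sum())


class TestAutoDispatch:
    def test_small_vector_goes_exact(self):
        f = _surrogate(4, seed=7)
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 4)
        background = rng.normal(0, 1, (5, 4))
        attr = shap_attributions(f, x, background, method="auto")
        phi_exact, _ = exact_shapley(f, x, background)
        assert np.allclose(attr.phi, phi_exact)
        attr.check_additivity(tol=1e-8)


@pytest.fixture(scope="module")
def cnn_bilstm():
    return build_model(architecture_spec("CNN_BiLSTM"), seed=0)


class TestLayerExtraction:
    def test_input_layer_dimension(self, cnn_bilstm, small_split):
        batch = one_hot_encode(small_split.test[:10])
        act = extract_layer_output(cnn_bilstm, "input", batch)
        assert act.matrix.shape == (10, 164)

    def test_pooling_layer_dimension(self, cnn_bilstm, small_split):
        batch = one_hot_encode(small_split.test[:10])
        act = extract_layer_output(cnn_bilstm, "maxpool1d", batch)
        assert act.matrix.shape == (10, 7 * 250)

    def test_last_hidden_dense_dimension(self, cnn_bilstm, small_split):
        batch = one_hot_encode(small_split.test[:10])
        act = extract_layer_output(cnn_bilstm, "dense", batch)
        assert act.matrix.shape == (10, 256)

    def test_unknown_layer_lists_available(self, cnn_bilstm, small_split):
        batch = one_hot_encode(small_split.test[:4])
        with pytest.raises(KeyError, match="conv1d"):
            extract_layer_output(cnn_bilstm, "nonexistent", batch)


class TestManifold:
    def _two_cluster_activation(self, n=120, sep=30.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n // 2, 20))
        b = rng.normal(sep, 1, (n // 2, 20))
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        return LayerActivation("toy", np.vstack([a, b]),
                               [f"s{i}" for i in range(n)], labels)

    def test_embedding_shape_and_determinism(self):
        act = self._two_cluster_activation()
        e1 = umap_project(act, seed=3)
        e2 = umap_project(act, seed=3)
        assert e1.coords.shape == (120, 2)
        assert np.array_equal(e1.coords, e2.coords)

    def test_separated_clusters_keep_high_silhouette(self):
        act = self._two_cluster_activation()
        emb = umap_project(act, seed=4)
        assert class_separation(emb, act.labels) > 0.5

    def test_shuffled_labels_near_zero_silhouette(self):
        act = self._two_cluster_activation()
        emb = umap_project(act, seed=5)
        rng = np.random.default_rng(6)
        assert abs(class_separation(emb, rng.permutation(act.labels))) < 0.2

    def test_too_few_samples_rejected(self):
        act = LayerActivation("toy", np.zeros((5, 3)), list("abcde"))
        with pytest.raises(ValueError, match="n_neighbors"):
            umap_project(act, n_neighbors=15)


class TestLogoAccumulation:
    def _attr(self, phi):
        return AttributionMatrix(phi=phi, phi0=0.0, f_x=0.0, residual=0.0)

    def test_scaling_rule_and_zero_matrix(self):
        phi = np.zeros((41, 4))
        phi[5, 2] = 0.5
        norm = normalize_and_accumulate([self._attr(phi)], ["A" * 20 + "U" + "G" * 20])
        assert np.abs(norm.scaled).max() == 0.25
        zero = normalize_and_accumulate([self._attr(np.zeros((41, 4)))],
                                        ["A" * 20 + "U" + "A" * 20])
        assert np.all(zero.scaled == 0.0)

    def test_scaling_preserves_signs(self):
        import warnings as _warnings

        rng = np.random.default_rng(7)
        phi = rng.normal(0, 1, (41, 4))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # dense random phi can exceed [-1, 1]
            norm = normalize_and_accumulate([self._attr(phi)], ["ACGU" * 10 + "A"])
        assert np.array_equal(np.sign(norm.scaled[0]), np.sign(phi))

    def test_accumulation_restricted_to_observed_base(self):
        phi = np.zeros((41, 4))
        phi[0, 0] = 0.25   # A channel, observed
        phi[0, 1] = -0.25  # C channel, not observed at position 0
        seq = "A" * 20 + "U" + "A" * 20
        norm = normalize_and_accumulate([self._attr(phi)], [seq])
        assert norm.accumulated[0, 0] == 0.25
        assert norm.accumulated[0, 1] == 0.0

    def test_out_of_range_sequence_sum_flagged(self):
        phi = np.full((41, 4), 0.5)
        with pytest.warns(UserWarning, match="outside"):
            normalize_and_accumulate([self._attr(phi)], ["A" * 20 + "U" + "A" * 20])

    def test_per_base_importance_picks_observed_channel(self):
        phi = np.zeros((41, 4))
        phi[3, 1] = 0.7  # C channel
        seq = "AAAC" + "A" * 16 + "U" + "A" * 20
        heights = per_base_importance(self._attr(phi), seq)
        assert heights.shape == (41,)
        assert heights[3] == 0.7
        assert per_base_importance(self._attr(np.zeros((41, 4))), seq).sum() == 0.0
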