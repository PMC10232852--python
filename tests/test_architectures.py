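"""Published architecture stacks, shape arithmetic, builders and grid search."""

import numpy as np
import pytest

from m5ukit.architectures import (FAMILIES, ArchitectureSpec, GridSearchSpace,
                                  LayerSpec, architecture_spec, build_model,
                                  conv_output_length, grid_search, shape_trace)
from m5ukit.seqdata import three_way_split
from m5ukit.synthdata import SyntheticConfig, generate_dataset


class TestPublishedStacks:
    def test_cnn_bilstm_first_conv(self):
        layer = architecture_spec("CNN_BiLSTM").layers[0]
        assert layer.kind == "conv1d"
        assert layer.params == {"filters": 250, "kernel_size": 7, "stride": 1,
                                "activation": "relu"}

    def test_cnn_bilstm_recurrent_units_per_direction(self):
        spec = architecture_spec("cnn-bilstm")  # CLI spelling accepted
        (rec,) = [l for l in spec.layers if l.kind == "bilstm"]
        assert rec.params["units"] == 64

    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_stack_ends_in_sigmoid_unit(self, family):
        last = architecture_spec(family).layers[-1]
        assert last.kind == "output"
        assert last.params == {"units": 1, "activation": "sigmoid"}

    def test_cnn_uses_kernel_11_pool_10(self):
        spec = architecture_spec("CNN")
        kinds = [l.kind for l in spec.layers]
        assert kinds[:3] == ["conv1d", "conv1d", "maxpool1d"]
        assert spec.layers[0].params["kernel_size"] == 11
        assert spec.layers[2].params == {"pool_size": 10, "stride": 10}

    def test_dense_block_shared_by_all(self):
        for family in FAMILIES:
            tail = architecture_spec(family).layers[-4:]
            assert [l.kind for l in tail] == ["dense", "dropout", "activation", "output"]
            assert tail[0].params["units"] == 256
            assert tail[1].params["rate"] == 0.2

    def test_unknown_family_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            architecture_spec("transformer")

    def test_template_round_trip(self, tmp_path):
        spec = architecture_spec("CNN_BiGRU")
        path = tmp_path / "spec.json"
        spec.save(path)
        loaded = ArchitectureSpec.load(path)
        assert loaded.name == spec.name
        assert loaded.layers == spec.layers


class TestShapeArithmetic:
    @pytest.mark.parametrize("args, expected", [
        ((41, 11, 1), 31),
        ((41, 7, 1), 35),
        ((35, 7, 1), 29),
        ((29, 4, 4), 7),
        ((21, 10, 10), 2),
    ])
    def test_valid_convolution_lengths(self, args, expected):
        assert conv_output_length(*args) == expected

    def test_kernel_longer_than_input_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            conv_output_length(5, 7)

    def test_symbolic_traces(self):
        assert shape_trace(architecture_spec("CNN")) == [41, 31, 21, 2]
        assert shape_trace(architecture_spec("CNN_BiLSTM")) == [41, 35, 29, 7]
        assert shape_trace(architecture_spec("CNN_BiGRU")) == [41, 31, 3]


class TestBuildModel:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_builds_and_outputs_probabilities(self, family):
        net = build_model(architecture_spec(family), seed=0)
        x = np.random.default_rng(0).random((6, 41, 4)).astype(np.float32)
        p = net.forward(x)
        assert p.shape == (6,)
        assert ((p >= 0) & (p <= 1)).all()

    @pytest.mark.parametrize("family", FAMILIES)
    def test_built_layers_match_symbolic_trace(self, family):
        spec = architecture_spec(family)
        net = build_model(spec, seed=0)
        x = np.random.default_rng(1).random((3, 41, 4)).astype(np.float32)
        trace = shape_trace(spec)
        observed = [41]
        for layer in net.layers:
            if layer.name.startswith(("conv1d", "maxpool1d")):
                observed.append(net.forward_to(layer.name, x).shape[1])
        assert observed == trace

    def test_batch_order_preserved(self):
        net = build_model(architecture_spec("CNN"), seed=0)
        x = np.random.default_rng(2).random((5, 41, 4)).astype(np.float32)
        batch = net.predict(x)
        singles = np.concatenate([net.predict(x[i:i + 1]) for i in range(5)])
        assert np.allclose(batch, singles, atol=1e-6)

    def test_infeasible_shape_chain_names_layer(self):
        spec = ArchitectureSpec(name="CNN", layers=[
            LayerSpec("conv1d", {"filters": 4, "kernel_size": 30}),
            LayerSpec("conv1d", {"filters": 4, "kernel_size": 30}),
            LayerSpec("output", {"units": 1, "activation": "sigmoid"}),
        ])
        with pytest.raises(ValueError, match="conv1d"):
            build_model(spec)


@pytest.fixture(scope="module")
def tiny_split():
    records = generate_dataset(SyntheticConfig(n_pos=80, n_neg=80, seed=8))
    return three_way_split(records, seed=8)


class TestGridSearch:
    def test_single_configuration_returned(self, tiny_split):
        space = GridSearchSpace(conv_layers=(1,), kernel_size=(5,), filters=(8,),
                                pool_size=(4,))
        best, table = grid_search(space, tiny_split, "CNN", epochs=1, seed=0)
        assert best.layers[0].params["kernel_size"] == 5
        assert len(table) == 1

    def test_table_covers_all_configurations_and_argmax(self, tiny_split):
        space = GridSearchSpace(conv_layers=(1,), kernel_size=(5, 7), filters=(8,),
                                pool_size=(4,))
        best, table = grid_search(space, tiny_split, "CNN", epochs=2, seed=0)
        assert len(table) == 2
        winner = table.loc[table["val_acc"].idxmax()]
        assert best.layers[0].params["kernel_size"] == winner["kernel_size"]

    def test_infeasible_configuration_marked(self, tiny_split):
        space = GridSearchSpace(conv_layers=(3,), kernel_size=(15,), filters=(4,),
                                pool_size=(2,))
        best, table = grid_search(
            GridSearchSpace(conv_layers=(1, 3), kernel_size=(15,), filters=(4,),
                            pool_size=(2,)),
            tiny_split, "CNN", epochs=1, seed=0)
        assert (table["status"] == "infeasible").sum() == 1
        assert best.layers[0].params["kernel_size"] == 15

    def test_budget_subsamples(self, tiny_split):
        space = GridSearchSpace(conv_layers=(1,), kernel_size=(3, 5, 7), filters=(8,),
                                pool_size=(2, 4))
        _, table = grid_search(space, tiny_split, "CNN", budget=2, epochs=1, seed=1)
        assert len(table) == 2
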