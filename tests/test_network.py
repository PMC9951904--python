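"""Network graph: structure audit, parameter accounting, shape conservation."""

import numpy as np
import pytest

from aimunet.config import ConfigurationError, IMPSpec, NetworkConfig
from aimunet.network import Network, build_aim_unet, count_parameters
from aimunet.network.runtime import InferenceError

from _oracles import expected_network_totals


def _imp_layers(net, level):
    prefix = f"imp{level}_"
    return [r for r in net.layers if r.name.startswith(prefix)]


class TestStructure:
    def test_imp_audit_per_skip_level(self, tiny_network_config):
        """Each skip level holds one IMP with exactly 16 convs, 2 concats and
        one stride-1 pool per repetition."""
        net = build_aim_unet(tiny_network_config)
        for level in (1, 2, 3, 4):
            recs = _imp_layers(net, level)
            kinds = [r.kind for r in recs]
            assert kinds.count("conv") == 16
            assert kinds.count("concat") == 2
            assert kinds.count("max_pool") == 2
            pools = [r for r in recs if r.kind == "max_pool"]
            assert all(p.stride == 1 for p in pools)

    def test_imp_preserves_spatial_dims(self, tiny_network_config):
        net = build_aim_unet(tiny_network_config)
        for level, side in zip((1, 2, 3, 4), (32, 16, 8, 4)):
            for rec in _imp_layers(net, level):
                assert rec.output_shape[:2] == (side, side)

    def test_output_matches_input_dims(self):
        for side in (32, 64):
            cfg = NetworkConfig(input_height=side, input_width=side, base_filters=2)
            net = build_aim_unet(cfg)
            assert net.layers[-1].output_shape == (side, side, 1)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ConfigurationError):
            build_aim_unet(NetworkConfig(input_height=100, input_width=100))

    def test_acyclic_single_input_output(self, tiny_network_config):
        net = build_aim_unet(tiny_network_config)
        seen = set()
        for rec in net.layers:  # topological order by construction
            assert all(src in seen for src in rec.inputs)
            seen.add(rec.name)
        assert net.layers[0].kind == "input"
        assert net.layers[-1].kind == "output"


class TestParameterAccounting:
    def test_single_conv_and_bn_counts(self, tiny_network_config):
        net = build_aim_unet(NetworkConfig(input_height=32, input_width=32,
                                           base_filters=8))
        enc1a = net["enc1a"]
        assert enc1a.n_trainable == 3 * 3 * 1 * 8 + 8 == 80
        bn = net["imp1_r1_b1_bn"]
        c = net["imp1_r1_b1"].output_shape[2]
        assert bn.n_trainable == 2 * c
        assert bn.n_non_trainable == 2 * c

    def test_total_is_trainable_plus_non_trainable(self, tiny_network_config):
        net = build_aim_unet(tiny_network_config)
        total, trainable, non_trainable = count_parameters(net)
        assert total == trainable + non_trainable

    def test_non_trainable_is_twice_bn_channels(self, tiny_network_config):
        net = build_aim_unet(tiny_network_config)
        bn_channels = sum(r.output_shape[2] for r in net.layers if r.kind == "batch_norm")
        assert count_parameters(net)[2] == 2 * bn_channels

    def test_totals_invariant_to_input_size(self):
        a = build_aim_unet(NetworkConfig(input_height=64, input_width=64))
        b = build_aim_unet(NetworkConfig(input_height=256, input_width=256))
        assert count_parameters(a) == count_parameters(b)
        assert a.n_layers == b.n_layers

    @pytest.mark.parametrize("seed", range(6))
    def test_closed_form_oracle_on_randomized_reduced_configs(self, seed):
        """count_parameters agrees with an independent per-layer summation."""
        rng = np.random.default_rng(seed)
        depth = int(rng.integers(2, 4))
        base = int(rng.integers(2, 9))
        specs = tuple(
            IMPSpec.uniform(int(rng.integers(1, 13)), int(rng.integers(1, 17)))
            for _ in range(depth)
        )
        scopes = [("imp",), ("imp", "decoder"), ("imp", "encoder", "base"),
                  ("imp", "decoder", "upsample"),
                  ("imp", "encoder", "base", "decoder", "upsample")]
        cfg = NetworkConfig(
            input_height=16 * 2**depth // 2, input_width=16 * 2**depth // 2,
            depth=depth, base_filters=base, imp_specs=specs,
            bn_scope=scopes[seed % len(scopes)],
            upsample_mode="transposed_conv" if seed % 2 == 0 else "upsample_then_conv",
        )
        net = build_aim_unet(cfg)
        total, trainable, non_trainable, n_layers = expected_network_totals(cfg)
        assert count_parameters(net) == (total, trainable, non_trainable)
        assert net.n_layers == n_layers


class TestRuntime:
    def test_untrained_outputs_strictly_inside_unit_interval(self, tiny_network_config):
        net = Network.from_config(tiny_network_config, seed=0)
        x = np.random.default_rng(0).random((2, 32, 32, 1)).astype(np.float32)
        y = net.predict(x)
        assert y.shape == (2, 32, 32, 1)
        assert np.all(y > 0.0) and np.all(y < 1.0)

    def test_256_input_gives_256_single_channel_map(self):
        cfg = NetworkConfig(input_height=256, input_width=256, base_filters=2)
        net = Network.from_config(cfg, seed=0)
        x = np.random.default_rng(1).random((1, 256, 256, 1)).astype(np.float32)
        y = net.predict(x)
        assert y.shape == (1, 256, 256, 1)

    def test_batch_order_preserved(self, tiny_network_config):
        net = Network.from_config(tiny_network_config, seed=0)
        x = np.random.default_rng(2).random((4, 32, 32, 1)).astype(np.float32)
        batched = net.predict(x, batch_size=2)
        singles = np.concatenate([net.predict(x[i:i + 1]) for i in range(4)])
        assert np.allclose(batched, singles, atol=1e-6)

    def test_dimension_mismatch_raises(self, tiny_network_config):
        net = Network.from_config(tiny_network_config, seed=0)
        with pytest.raises(InferenceError):
            net.predict(np.zeros((1, 64, 64, 1), dtype=np.float32))

    def test_weight_state_round_trip(self, tiny_network_config):
        net = Network.from_config(tiny_network_config, seed=0)
        x = np.random.default_rng(3).random((1, 32, 32, 1)).astype(np.float32)
        y1 = net.predict(x)
        state = net.get_weights()
        net2 = Network.from_config(tiny_network_config, seed=99)
        net2.set_weights(state)
        assert np.allclose(net2.predict(x), y1)
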