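"""Architecture contracts: shapes, parameter inventory, determinism,
checkpointing and mask prediction."""

import numpy as np
import pytest

from follikit.attention import effective_reduction
from follikit.network import (HarmonicAttentionUNet, NetworkConfig,
                              build_network, load_checkpoint, predict_mask,
                              save_checkpoint)
from follikit.nn import Tensor


def expected_parameter_count(base: int, f: int = 3, in_ch: int = 1,
                             out_ch: int = 1, ha_reduction: int = 16,
                             use_ha: bool = True) -> int:
    """Closed-form layer-by-layer parameter inventory of the architecture."""
    w = [base * 2 ** k for k in range(5)]

    def hconv(cin, cout):               # DCT-combination weights + bias
        return cout * cin * f * f + cout

    def bn(c):                          # gamma + beta
        return 2 * c

    def fact(c):                        # 3x1 conv + BN, 1x3 conv + BN
        return 2 * (c * c * 3 + c) + 2 * bn(c)

    def ha(c):
        if not use_ha:
            return 0
        r = effective_reduction(c, ha_reduction)
        h = c // r
        return (h * c + h) + (c * h + c)    # squeeze + excite 1x1 convs

    def up(cin, cout):                  # 2x2 transpose conv + bias
        return cin * cout * 4 + cout

    total = 0
    # encoder
    total += hconv(in_ch, w[0]) + bn(w[0]) + fact(w[0])
    total += hconv(w[0], w[1]) + bn(w[1]) + fact(w[1]) + ha(w[1])
    total += hconv(w[1], w[2]) + bn(w[2]) + ha(w[2])
    total += hconv(w[2], w[3]) + bn(w[3]) + ha(w[3])
    total += hconv(w[3], w[4]) + bn(w[4]) + ha(w[4])
    # decoder
    total += up(w[4], w[3]) + hconv(2 * w[3], w[3]) + bn(w[3]) + ha(w[3])
    total += up(w[3], w[2]) + hconv(2 * w[2], w[2]) + bn(w[2]) + ha(w[2])
    total += up(w[2], w[1]) + hconv(2 * w[1], w[1]) + bn(w[1]) + fact(w[1]) + ha(w[1])
    total += up(w[1], w[0]) + hconv(2 * w[0], w[0]) + bn(w[0]) + fact(w[0])
    # 1x1 sigmoid head
    total += w[0] * out_ch + out_ch
    return total


class TestArchitecture:
    def test_output_shape_and_range(self, rng):
        model = build_network(NetworkConfig(base_width=8, seed=0)).eval()
        out = model(Tensor(rng.random((1, 1, 96, 96)))).data
        assert out.shape == (1, 1, 96, 96)
        assert out.min() > 0.0 and out.max() < 1.0

    @pytest.mark.parametrize("use_ha", [True, False])
    def test_parameter_count_matches_layer_inventory(self, use_ha):
        cfg = NetworkConfig(base_width=8, use_ha=use_ha, seed=0)
        model = build_network(cfg)
        actual = sum(p.data.size for p in model.parameters())
        assert actual == expected_parameter_count(8, use_ha=use_ha)

    def test_baseline_flag_removes_attention_parameters(self):
        full = build_network(NetworkConfig(base_width=8, seed=0))
        bl = build_network(NetworkConfig(base_width=8, use_ha=False, seed=0))
        n_full = sum(p.data.size for p in full.parameters())
        n_bl = sum(p.data.size for p in bl.parameters())
        assert n_bl < n_full

    def test_eval_forward_is_deterministic(self, rng):
        model = build_network(NetworkConfig(base_width=8, seed=3)).eval()
        x = Tensor(rng.random((1, 1, 32, 32)))
        a = model(x).data
        b = model(x).data
        assert np.array_equal(a, b)

    def test_indivisible_input_rejected_with_required_multiple(self, rng):
        model = build_network(NetworkConfig(base_width=8, seed=0))
        with pytest.raises(ValueError, match="16"):
            model(Tensor(rng.random((1, 1, 50, 50))))

    def test_channel_width_doubles_per_level(self):
        cfg = NetworkConfig(base_width=8)
        assert cfg.widths == [8, 16, 32, 64, 128]

    def test_depth_other_than_five_rejected(self):
        with pytest.raises(ValueError):
            HarmonicAttentionUNet(NetworkConfig(base_width=8, depth=4))


class _ConstantModel:
    """Stub emitting a constant probability map (threshold-semantics tests)."""

    def __init__(self, value):
        self.value = value
        self.training = False

    def eval(self):
        return self

    def train(self):
        return self

    def __call__(self, x):
        return Tensor(np.full_like(x.data, self.value))


class TestPredictMask:
    def test_probabilities_below_threshold_give_empty_mask(self, rng):
        mask, prob = predict_mask(_ConstantModel(0.49), rng.random((32, 32)))
        assert mask.sum() == 0
        assert np.allclose(prob, 0.49)

    def test_probabilities_above_threshold_give_full_mask(self, rng):
        mask, _ = predict_mask(_ConstantModel(0.51), rng.random((32, 32)))
        assert mask.all()

    def test_mask_returned_at_input_resolution(self, rng):
        model = build_network(NetworkConfig(base_width=8, seed=0)).eval()
        mask, prob = predict_mask(model, rng.random((60, 70)), input_size=32)
        assert mask.shape == (60, 70)
        assert prob.shape == (32, 32)
        assert set(np.unique(mask)) <= {0, 1}

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            predict_mask(_ConstantModel(0.5), np.zeros((3, 4, 5)))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        model = build_network(NetworkConfig(base_width=8, seed=7)).eval()
        x = Tensor(rng.random((1, 1, 32, 32)))
        before = model(x).data
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path).eval()
        after = restored(x).data
        assert np.array_equal(before, after)
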