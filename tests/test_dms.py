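"""DMS layer algebra: splits, kernels, shuffle, chaining, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dms_eeg import (DMSConfig, channel_shuffle, channel_split, dms_layer,
                     dms_module, dynamic_kernel_sizes)
from dms_eeg.dms import (init_layer_weights, init_module_weights,
                         shuffle_permutation, split_channel_counts)
from dms_eeg.reference import conv2d_direct


class TestChannelSplit:
    def test_equal_split(self, rng):
        F = rng.standard_normal((8, 8, 16))
        parts = channel_split(F, 4)
        assert [p.shape for p in parts] == [(8, 8, 4)] * 4

    def test_single_split_is_identity(self, rng):
        F = rng.standard_normal((3, 4, 5))
        (only,) = channel_split(F, 1)
        assert np.array_equal(only, F)

    def test_remainder_goes_to_last_submap(self):
        assert split_channel_counts(10, 4) == [2, 2, 2, 4]

    def test_concat_restores_input_exactly(self, rng):
        F = rng.standard_normal((4, 5, 11))
        assert np.array_equal(np.concatenate(channel_split(F, 3), axis=-1), F)

    def test_more_splits_than_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_split(rng.standard_normal((2, 2, 3)), 4)


class TestKernelSizes:
    @pytest.mark.parametrize("d,expected", [
        (16, (15, 7, 3)), (4, (3, 1, 1)), (1, (1, 1, 1)),
        (7, (7, 3, 1)), (2, (1, 1, 1))])
    def test_rule(self, d, expected):
        assert dynamic_kernel_sizes(d) == expected

    def test_sizes_are_odd_and_bounded_by_d(self):
        for d in range(1, 40):
            for k in dynamic_kernel_sizes(d):
                assert k % 2 == 1 and 1 <= k <= d

    def test_custom_rule_honoured(self):
        assert dynamic_kernel_sizes(9, rule=lambda d: (3, 3, 3)) == (3, 3, 3)


class TestChannelShuffle:
    def test_groups_one_is_identity(self, rng):
        F = rng.standard_normal((2, 2, 6))
        assert np.array_equal(channel_shuffle(F, 1), F)

    def test_two_group_transpose_order(self):
        F = np.arange(4)[None, None, :] * np.ones((1, 1, 4))
        assert list(channel_shuffle(F, 2)[0, 0]) == [0, 2, 1, 3]

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_shuffle(rng.standard_normal((2, 2, 5)), 2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.sampled_from([(4, 2), (8, 2), (8, 4), (12, 3), (12, 4), (6, 6)]))
    def test_permutation_preserves_channel_multiset(self, cg):
        c, g = cg
        perm = shuffle_permutation(c, g)
        assert sorted(perm) == list(range(c))
        F = np.random.default_rng(c * 100 + g).standard_normal((3, 3, c))
        shuffled = channel_shuffle(F, g)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(c)
        assert np.array_equal(shuffled[..., inv], F)


class TestDMSModule:
    def test_zero_weights_give_zero_output(self, rng):
        s = rng.standard_normal((5, 6, 4))
        cfg = DMSConfig(n_splits=1)
        w = init_module_weights(4, dynamic_kernel_sizes(5),
                                cfg.enabled_branches, rng=None)
        assert np.abs(dms_module(s, cfg, w)).max() == 0.0

    def test_output_shape_equals_input_shape(self, rng):
        for shape in [(4, 4, 2), (7, 3, 5), (2, 9, 1)]:
            s = rng.standard_normal(shape)
            cfg = DMSConfig(n_splits=1)
            w = init_module_weights(shape[-1],
                                    dynamic_kernel_sizes(min(shape[:2])),
                                    cfg.enabled_branches, rng=rng)
            assert dms_module(s, cfg, w).shape == shape

    def test_single_1x1_branch_matches_direct_oracle(self, rng):
        s = rng.standard_normal((6, 6, 3))
        cfg = DMSConfig(n_splits=1, enabled_branches=("Conv3",))
        w = init_module_weights(3, (5, 3, 1), ("Conv3",), rng=rng)
        got = dms_module(s, cfg, w)
        mid = np.maximum(conv2d_direct(s, w["branches"]["Conv3"]["kernel"],
                                       w["branches"]["Conv3"]["bias"]), 0.0)
        ref = np.maximum(conv2d_direct(mid, w["fuse"]["kernel"],
                                       w["fuse"]["bias"]), 0.0)
        assert np.abs(got - ref).max() < 1e-6

    def test_missing_branch_weights_named_in_error(self, rng):
        s = rng.standard_normal((4, 4, 2))
        cfg = DMSConfig(n_splits=1)
        w = init_module_weights(2, (3, 1, 1), ("Conv1",), rng=rng)
        with pytest.raises(ValueError, match="Conv2"):
            dms_module(s, cfg, w)


class TestDMSLayer:
    @pytest.mark.parametrize("shape,n", [
        ((8, 8, 16), 4), ((5, 7, 10), 4), ((4, 4, 6), 3), ((3, 3, 4), 1),
        ((6, 2, 5), 5), ((2, 2, 6), 6)])
    def test_shape_conservation(self, rng, shape, n):
        F = rng.standard_normal(shape)
        cfg = DMSConfig(n_splits=n)
        w = init_layer_weights(shape[-1], min(shape[:2]), cfg, rng=rng)
        assert dms_layer(F, cfg, w).shape == shape

    def test_zero_weights_collapse_through_full_chain(self, rng):
        F = rng.standard_normal((6, 6, 8))
        cfg = DMSConfig(n_splits=4)
        w = init_layer_weights(8, 6, cfg, rng=None)
        assert np.abs(dms_layer(F, cfg, w)).max() == 0.0

    def test_single_split_single_branch_matches_oracle_pipeline(self, rng):
        F = rng.standard_normal((5, 5, 2))
        cfg = DMSConfig(n_splits=1, enabled_branches=("Conv3",))
        w = init_layer_weights(2, 5, cfg, rng=rng)
        got = dms_layer(F, cfg, w)
        mid = np.maximum(conv2d_direct(F, w[0]["branches"]["Conv3"]["kernel"],
                                       w[0]["branches"]["Conv3"]["bias"]), 0.0)
        ref = np.maximum(conv2d_direct(mid, w[0]["fuse"]["kernel"],
                                       w[0]["fuse"]["bias"]), 0.0)
        assert np.abs(got - ref).max() < 1e-6

    def test_additive_chain_feeds_previous_output_forward(self, rng):
        """With 2 equal splits, z2 must differ from the unchained module
        output M2(s2) whenever z1 is nonzero."""
        F = rng.standard_normal((4, 4, 4))
        cfg = DMSConfig(n_splits=2)
        w = init_layer_weights(4, 4, cfg, rng=rng)
        chained = dms_layer(F, cfg, w)
        s1, s2 = channel_split(F, 2)
        z1 = dms_module(s1, cfg, w[0])
        z2_unchained = dms_module(s2, cfg, w[1])
        z2_chained = dms_module(s2 + z1, cfg, w[1])
        expected = channel_shuffle(np.concatenate([z1, z2_chained], axis=-1), 2)
        assert np.allclose(chained, expected, atol=1e-9)
        assert not np.allclose(z2_chained, z2_unchained)

    def test_unequal_splits_skip_chain_and_shuffle(self, rng):
        """C=5, n=2 -> splits (2, 3): the addition is shape-mismatched and
        must be skipped, and the shuffle must fall back to identity."""
        F = rng.standard_normal((4, 4, 5))
        cfg = DMSConfig(n_splits=2)
        w = init_layer_weights(5, 4, cfg, rng=rng)
        got = dms_layer(F, cfg, w)
        s1, s2 = channel_split(F, 2)
        z1 = dms_module(s1, cfg, w[0])
        z2 = dms_module(s2, cfg, w[1])
        assert np.allclose(got, np.concatenate([z1, z2], axis=-1), atol=1e-9)


def test_config_validation():
    with pytest.raises(ValueError):
        DMSConfig(n_splits=0)
    with pytest.raises(ValueError):
        DMSConfig(enabled_branches=())
    with pytest.raises(ValueError):
        DMSConfig(enabled_branches=("Conv9",))
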