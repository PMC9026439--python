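"""Architecture and forward-pass tests: inventory of the canonical
depth-9 network, agreement with a nested-loop oracle across every
sharing x fusion combination, fusion algebra, branch isolation and
shape conservation."""

import numpy as np
import pytest

from dbnn.model import (ModelConfig, DBNNModel, SingleBranchCNN, build_model,
                        summarize)
from dbnn.nn import autograd as ag
from dbnn.errors import ValidationError, ContractError
from conftest import tiny_config
from naive_net import naive_forward


class TestConfig:
    def test_default_depth9_layout(self):
        cfg = ModelConfig()
        assert cfg.block_layout == [2, 2, 3, 2]
        assert cfg.sharing_layers == {2, 4, 6, 9}
        assert cfg.pool_layers == {2, 4, 7, 9}
        assert cfg.channel_sequence == [64, 64, 128, 128, 256, 256, 256, 512, 512]

    @pytest.mark.parametrize("depth,layout", [(8, [2, 2, 2, 2]), (10, [2, 2, 3, 3]),
                                              (11, [2, 3, 3, 3]), (12, [3, 3, 3, 3])])
    def test_depth_variants_have_block_end_defaults(self, depth, layout):
        cfg = ModelConfig(depth=depth)
        assert cfg.block_layout == layout
        ends = set(np.cumsum(layout).tolist())
        assert cfg.pool_layers == ends and cfg.sharing_layers == ends

    @pytest.mark.parametrize("bad", [
        dict(depth=9, block_layout=[2, 2, 2, 2]),           # sums to 8
        dict(alpha=0.5, beta=0.6, fusion="weighted"),       # alpha+beta != 1
        dict(sharing="avg"),
        dict(pool_layers={2, 4, 7}),                        # needs 4 pools
        dict(sharing_layers={0, 2}),
        dict(image_size=100),                               # not divisible by 16
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValidationError):
            ModelConfig(**bad)


class TestInventory:
    def test_canonical_network_inventory(self):
        s = summarize(build_model(ModelConfig(), seed=0))
        assert s.conv_layer_count == 9
        assert s.pool_count == 4
        assert s.per_layer_channels == [64, 64, 128, 128, 256, 256, 256, 512, 512]
        assert s.per_layer_channels[-1] == 512
        assert s.fused_feature_dim == 1024

    def test_depth_12_inventory(self):
        s = summarize(build_model(ModelConfig(depth=12), seed=0))
        assert s.conv_layer_count == 12

    def test_concat_fusion_doubles_fused_dim(self):
        s = summarize(build_model(tiny_config(fusion="concat"), seed=0))
        assert s.fused_feature_dim == 12  # 2 * fc_width

    def test_same_seed_identical_parameters(self, tiny_cfg):
        a = build_model(tiny_cfg, seed=5)
        b = build_model(tiny_cfg, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)
        c = build_model(tiny_cfg, seed=6)
        assert any(not np.array_equal(pa.data, pc.data)
                   for pa, pc in zip(a.parameters(), c.parameters()))

    def test_branches_are_not_tied(self, tiny_cfg):
        m = build_model(tiny_cfg, seed=0)
        assert not np.array_equal(m.branch_pre.conv1.weight.data,
                                  m.branch_post.conv1.weight.data)


SHARING = ["none", "sum", "concat"]
FUSION = [("concat", {}), ("sum", {}),
          ("weighted", dict(alpha=0.2, beta=0.8)),
          ("weighted", dict(alpha=1.0, beta=0.0))]


class TestForwardOracle:
    @pytest.mark.parametrize("sharing", SHARING)
    @pytest.mark.parametrize("fusion,extra", FUSION)
    def test_forward_matches_nested_loop_oracle(self, sharing, fusion, extra, rng):
        cfg = tiny_config(sharing=sharing, fusion=fusion, **extra)
        m = build_model(cfg, seed=7)
        # nudge BN buffers off their init so the eval path is non-trivial
        for br in (m.branch_pre, m.branch_post):
            for i in range(1, cfg.depth + 1):
                bn = getattr(br, f"bn{i}")
                bn.running_mean += rng.normal(0, 0.05, bn.running_mean.shape)
                bn.running_var += rng.uniform(0, 0.1, bn.running_var.shape)
        pre = rng.random((16, 16))
        post = rng.random((16, 16))
        got = m.forward(pre[None], post[None])[0]
        want = naive_forward(m, pre, post)
        assert np.allclose(got, want, atol=1e-5)
        assert np.isclose(got.sum(), 1.0, atol=1e-6)

    def test_probabilities_sum_to_one_on_random_batch(self, tiny_cfg, rng):
        m = build_model(tiny_cfg, seed=0)
        p = m.forward(rng.random((32, 16, 16)), rng.random((32, 16, 16)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestFusionAndBranches:
    def test_weighted_half_half_equals_half_of_sum_fusion(self, rng):
        """The (0.5, 0.5) weighting and plain sum fusion are genuinely
        different models: their fused vectors differ exactly by the 0.5
        factor."""
        cfg_w = tiny_config(sharing="sum", fusion="weighted", alpha=0.5, beta=0.5)
        m = build_model(cfg_w, seed=3)
        pre, post = rng.random((2, 16, 16)), rng.random((2, 16, 16))
        fa, fb = m._features(m._check_batch(pre), m._check_batch(post),
                             train=False, rng=None)
        weighted = m.fuse(fa, fb).data
        assert np.allclose(weighted, 0.5 * (fa.data + fb.data), atol=1e-6)

    def test_dead_branch_when_beta_zero_and_no_sharing(self, rng):
        cfg = tiny_config(sharing="none", fusion="weighted", alpha=1.0, beta=0.0)
        m = build_model(cfg, seed=1)
        pre = rng.random((3, 16, 16))
        p1 = m.forward(pre, rng.random((3, 16, 16)))
        p2 = m.forward(pre, rng.random((3, 16, 16)))
        assert np.allclose(p1, p2, atol=1e-12)

    def test_dead_branch_gradients_exactly_zero(self, rng):
        cfg = tiny_config(sharing="none", fusion="weighted", alpha=1.0, beta=0.0)
        m = build_model(cfg, seed=1)
        y = np.array([[1.0, 0.0]])
        loss = ag.softmax_cross_entropy(
            m.logits(rng.random((1, 16, 16)), rng.random((1, 16, 16)), train=False), y)
        loss.backward()
        post_params = m.branch_post.parameters() + m.fc_post.parameters()
        assert all(p.grad is None or not p.grad.any() for p in post_params)
        assert any(p.grad is not None and p.grad.any()
                   for p in m.branch_pre.parameters())

    def test_symmetric_branches_give_equal_features(self, rng):
        """With identical branch parameters, identical inputs and sum
        sharing, F(X) == F(Y) by symmetry."""
        cfg = tiny_config(sharing="sum")
        m = build_model(cfg, seed=2)
        state = m.branch_pre.state_arrays()
        m.branch_post.load_state_arrays({k: v.copy() for k, v in state.items()})
        m.fc_post.load_state_arrays({k: v.copy() for k, v in
                                     m.fc_pre.state_arrays().items()})
        img = rng.random((1, 16, 16))
        fa, fb = m._features(m._check_batch(img), m._check_batch(img),
                             train=False, rng=None)
        assert np.allclose(fa.data, fb.data, atol=1e-6)

    def test_branch_features_length_and_companion_contract(self, tiny_cfg, rng):
        m = build_model(tiny_cfg, seed=0)
        img = rng.random((1, 16, 16))
        f = m.branch_features(img, "pre", companion_image=rng.random((1, 16, 16)))
        assert f.shape == (1, tiny_cfg.fc_width)
        with pytest.raises(ContractError):
            m.branch_features(img, "post")     # sharing=sum needs a companion


class TestShapes:
    def test_spatial_size_halves_at_each_pool(self, rng):
        cfg = ModelConfig(channels_per_block=[2, 2, 2, 2], fc_width=4,
                          dropout_rate=0.0)
        m = build_model(cfg, seed=0)
        sizes = []
        a = ag.Tensor(rng.random((1, 1, 128, 128)))
        for i in range(1, cfg.depth + 1):
            conv, bn = m.branch_pre.layer(i)
            a = ag.relu(bn(conv(a), False))
            if i in cfg.pool_layers:
                a = ag.maxpool2(a)
                sizes.append(a.data.shape[-1])
        assert sizes == [64, 32, 16, 8]

    def test_shape_mismatch_rejected(self, tiny_cfg, rng):
        m = build_model(tiny_cfg, seed=0)
        with pytest.raises(ContractError):
            m.forward(rng.random((2, 16, 16)), rng.random((3, 16, 16)))
        with pytest.raises(ContractError):
            m.forward(rng.random((2, 8, 8)), rng.random((2, 8, 8)))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tiny_cfg, tmp_path, rng):
        m = build_model(tiny_cfg, seed=9)
        pre, post = rng.random((2, 16, 16)), rng.random((2, 16, 16))
        want = m.forward(pre, post)
        m.save(tmp_path / "ckpt")
        m2 = DBNNModel.load(tmp_path / "ckpt")
        assert np.allclose(m2.forward(pre, post), want, atol=1e-12)
        assert m2.config.to_dict() == tiny_cfg.to_dict()


class TestSingleBranch:
    def test_single_branch_reads_only_its_stage(self, tiny_cfg, rng):
        m = SingleBranchCNN(tiny_cfg, "pre", seed=0)
        pre = rng.random((2, 16, 16))
        p1 = m.forward(pre, rng.random((2, 16, 16)))
        p2 = m.forward(pre, rng.random((2, 16, 16)))
        assert np.allclose(p1, p2)
        assert np.allclose(p1.sum(axis=1), 1.0)
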