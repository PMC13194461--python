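import numpy as np
import pytest

from seedling3d.autograd import Adam, Tensor
from seedling3d.network import (
    GlobalContext,
    ModelConfig,
    MSResBlock,
    MultiScaleConv,
    SEBlock,
    StageConfig,
    ablation_grid,
    ball_group,
    build_model,
    build_scene_plan,
    cross_entropy,
    farthest_point_sampling,
    interpolate_features,
    stack_plans,
)
from _oracles import direct_conv1d

RNG = np.random.default_rng(0)


def tiny_config(**toggles):
    return ModelConfig(
        stages=(
            StageConfig(64, 0.25, 8, (16, 16)),
            StageConfig(16, 0.6, 8, (32, 32)),
        ),
        fp_channels=(32, 16),
        **toggles,
    )


def toy_scene(n=256, seed=0):
    """Separable two-class toy: a vertical rod and a horizontal disc."""
    rng = np.random.default_rng(seed)
    n_rod = n // 3
    rod = np.column_stack([
        0.05 * np.cos(rng.uniform(0, 2 * np.pi, n_rod)),
        0.05 * np.sin(rng.uniform(0, 2 * np.pi, n_rod)),
        rng.uniform(0, 1.0, n_rod),
    ])
    n_disc = n - n_rod
    r = np.sqrt(rng.uniform(0, 1, n_disc))
    phi = rng.uniform(0, 2 * np.pi, n_disc)
    disc = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                            np.full(n_disc, 1.0)])
    coords = np.vstack([rod, disc])
    normals = np.vstack([
        np.column_stack([rod[:, 0] / 0.05, rod[:, 1] / 0.05, np.zeros(n_rod)]),
        np.tile([0.0, 0.0, 1.0], (n_disc, 1)),
    ])
    labels = np.concatenate([np.full(n_rod, 1), np.full(n_disc, 2)])
    return coords, normals, labels


class TestMultiScaleConv:
    def test_shape_contract_preserves_points(self):
        ms = MultiScaleConv(RNG, 4, 6)
        out = ms(Tensor(np.random.default_rng(1).normal(size=(5, 10, 4))))
        assert out.shape == (5, 10, 6)

    def test_zero_weights_give_zero_output(self):
        ms = MultiScaleConv(RNG, 3, 4)
        for p in ms.parameters():
            p.data = np.zeros_like(p.data)
        out = ms(Tensor(np.ones((7, 3))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_branches_match_direct_convolution(self):
        x = np.random.default_rng(2).normal(size=(6, 2))
        ms = MultiScaleConv(RNG, 2, 3)
        for conv, k in zip(ms.branches, (1, 3, 5)):
            conv.w.data = conv.w.data.astype(np.float64)
            conv.b.data = conv.b.data.astype(np.float64)
            got = conv(Tensor(x)).data
            want = direct_conv1d(x, conv.w.data, conv.b.data)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_short_sequence_fallback_runs(self):
        ms = MultiScaleConv(RNG, 2, 3)
        out = ms(Tensor(np.ones((1, 3, 2))))
        assert out.shape == (1, 3, 3)
        assert np.all(np.isfinite(out.data))


class TestSEBlock:
    def test_zero_weights_halve_the_input(self):
        se = SEBlock(RNG, 4)
        for p in se.parameters():
            p.data = np.zeros_like(p.data)
        x = np.random.default_rng(3).normal(size=(6, 4))
        np.testing.assert_allclose(se(Tensor(x)).data, 0.5 * x, atol=1e-12)

    def test_constant_channels_pool_to_constants(self):
        x = np.tile([1.0, -2.0, 3.0], (5, 1))
        z = Tensor(x).mean(axis=-2)
        np.testing.assert_allclose(z.data, [1.0, -2.0, 3.0], atol=1e-12)

    def test_two_channel_hand_case(self):
        se = SEBlock(RNG, 2, reduction=2)
        W1 = np.array([[0.5], [-0.25]])
        W2 = np.array([[1.0, -1.0]])
        se.W1.data, se.W2.data = W1, W2
        x = np.array([[2.0, 4.0], [0.0, 2.0]])   # channel means 1, 3
        z = x.mean(axis=0)
        hidden = np.maximum(0.0, z @ W1)
        s = 1.0 / (1.0 + np.exp(-(hidden @ W2)))
        np.testing.assert_allclose(se(Tensor(x)).data, x * s, atol=1e-9)

    def test_gate_between_zero_and_one(self):
        se = SEBlock(RNG, 8)
        x = np.random.default_rng(4).normal(size=(20, 8)) * 10
        out = se(Tensor(x)).data
        ratio = np.abs(out) / np.maximum(np.abs(x), 1e-12)
        assert np.all(ratio <= 1.0 + 1e-9)


class TestResidual:
    def test_zero_main_branch_is_identity(self):
        block = MSResBlock(RNG, 4, 4, use_se=False)
        for p in block.ms.parameters():
            p.data = np.zeros_like(p.data)
        x = np.random.default_rng(5).normal(size=(9, 4))
        np.testing.assert_array_equal(block(Tensor(x)).data, x)

    def test_mismatched_dims_project_shortcut(self):
        block = MSResBlock(RNG, 3, 5, use_se=True)
        out = block(Tensor(np.ones((7, 3))))
        assert out.shape == (7, 5)

    def test_jacobian_contains_identity_component(self):
        block = MSResBlock(RNG, 2, 2, use_se=False)
        for p in block.ms.parameters():
            p.data = np.zeros_like(p.data)
        x = Tensor(np.random.default_rng(6).normal(size=(3, 2)),
                   requires_grad=True)
        block(x).sum().backward()
        np.testing.assert_allclose(x.grad, np.ones((3, 2)), atol=1e-12)


class TestGlobalContext:
    def test_zero_recovery_layer_is_identity(self):
        gc = GlobalContext(RNG, 4)
        gc.Wu.data = np.zeros_like(gc.Wu.data)
        x = np.random.default_rng(7).normal(size=(11, 4))
        np.testing.assert_array_equal(gc(Tensor(x)).data, x)

    def test_pooling_is_permutation_invariant(self):
        gc = GlobalContext(RNG, 3)
        x = np.random.default_rng(8).normal(size=(10, 3))
        perm = np.random.default_rng(9).permutation(10)
        out = gc(Tensor(x)).data
        out_perm = gc(Tensor(x[perm])).data
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-6)

    def test_four_point_hand_case(self):
        gc = GlobalContext(RNG, 2, reduction=2)
        Wd = np.array([[1.0], [0.5]])
        Wu = np.array([[2.0, -1.0]])
        gc.Wd.data, gc.Wu.data = Wd, Wu
        x = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0], [1.0, 1.0]])
        g = x.mean(axis=0)
        u = np.maximum(0.0, g @ Wd) @ Wu
        np.testing.assert_allclose(gc(Tensor(x)).data, x + u, atol=1e-9)


class TestInterpolation:
    def test_coincident_query_copies_exactly(self):
        src = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        feats = np.array([[1.0], [2.0], [3.0]])
        out = interpolate_features(src, feats, np.array([[1.0, 0, 0]]))
        np.testing.assert_array_equal(out, [[2.0]])

    def test_single_source_broadcasts(self):
        out = interpolate_features(
            np.array([[0.0, 0, 0]]), np.array([[5.0, 7.0]]),
            np.random.default_rng(0).normal(size=(4, 3)),
        )
        np.testing.assert_allclose(out, np.tile([5.0, 7.0], (4, 1)))

    def test_inverse_square_weights_hand_case(self):
        src = np.array([[1.0, 0, 0], [2.0, 0, 0], [50.0, 0, 0]])
        feats = np.array([[1.0], [0.0], [0.0]])
        out = interpolate_features(src, feats, np.array([[0.0, 0, 0]]), k=2)
        # distances 1 and 2: weights 1 and 1/4 -> 4/5 on the nearer point
        np.testing.assert_allclose(out, [[0.8]], atol=1e-12)


class TestModel:
    @pytest.mark.parametrize("name", list(ablation_grid()))
    def test_all_ablation_configs_forward(self, name):
        toggles = ablation_grid()[name]
        config = tiny_config(**toggles)
        model = build_model(config)
        coords, normals, labels = toy_scene(128, seed=1)
        pred = model.predict_scene(coords, normals)
        assert pred.shape == (128,)
        assert set(pred) <= {0, 1, 2}

    def test_parameter_count_increases_with_each_module(self):
        base = build_model(tiny_config(use_ms=False, use_se=False,
                                       use_gc=False, use_improved_fp=False))
        for toggle in ("use_ms", "use_se", "use_gc", "use_improved_fp"):
            extended = build_model(
                tiny_config(**{"use_ms": False, "use_se": False,
                               "use_gc": False, "use_improved_fp": False,
                               toggle: True})
            )
            assert extended.n_parameters > base.n_parameters, toggle

    def test_improved_fp_off_matches_plain_mlp(self):
        from seedling3d.network import FeaturePropagation
        rng = np.random.default_rng(11)
        fp = FeaturePropagation(rng, 4, 3, 5, improved=False, use_se=False,
                                se_reduction=4)
        feats_low = np.random.default_rng(12).normal(size=(1, 4, 4))
        skip = np.random.default_rng(13).normal(size=(1, 9, 3))
        idx = np.random.default_rng(14).integers(0, 4, (1, 9, 3))
        w = np.full((1, 9, 3), 1 / 3)
        out = fp(Tensor(feats_low), Tensor(skip), idx, w).data
        interp = (feats_low[0][idx[0]] * w[0][..., None]).sum(axis=1)
        h = np.concatenate([interp, skip[0]], axis=-1)
        for layer in fp.mlp:
            h = np.maximum(0.0, h @ layer.W.data + layer.b.data)
        np.testing.assert_allclose(out[0], h, rtol=1e-5, atol=1e-6)

    def test_strictly_decreasing_stage_sizes_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(
                stages=(StageConfig(64, 0.2, 8, (16,)),
                        StageConfig(64, 0.4, 8, (32,))),
                fp_channels=(16, 16),
            ).validate()

    @pytest.mark.parametrize("name", ["Baseline", "Full_model"])
    def test_loss_decreases_on_separable_toy(self, name):
        config = tiny_config(**ablation_grid()[name])
        model = build_model(config)
        coords, normals, labels = toy_scene(192, seed=2)
        plan = stack_plans([build_scene_plan(coords, config)])
        feats = model.features_from_cloud(coords, normals)[None]
        opt = Adam(model.parameters(), lr=1e-3)
        losses = []
        for _ in range(5):
            loss = cross_entropy(model.forward(plan, feats), labels[None])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < losses[0]


class TestSampling:
    def test_fps_spreads_points(self):
        coords = np.array([[0.0, 0, 0], [0.01, 0, 0], [1.0, 0, 0],
                           [0.5, 0, 0]])
        idx = farthest_point_sampling(coords, 3)
        assert idx[0] == 0
        assert idx[1] == 2      # farthest from the start
        assert idx[2] == 3      # then the midpoint

    def test_ball_group_pads_with_nearest(self):
        coords = np.array([[0.0, 0, 0], [0.05, 0, 0], [5.0, 0, 0]])
        idx = ball_group(coords, coords[:1], radius=0.1, k=4)
        assert idx.shape == (1, 4)
        assert 2 not in idx            # far point excluded by the radius


class TestCrossEntropy:
    def test_uniform_logits_give_log3(self):
        logits = np.zeros((10, 3))
        labels = np.random.default_rng(15).integers(0, 3, 10)
        assert float(cross_entropy(logits, labels).data) == pytest.approx(
            np.log(3.0), abs=1e-12
        )

    def test_confident_correct_prediction_drives_loss_to_zero(self):
        logits = np.full((4, 3), -50.0)
        labels = np.array([0, 1, 2, 0])
        logits[np.arange(4), labels] = 50.0
        assert float(cross_entropy(logits, labels).data) < 1e-8

    def test_two_point_hand_case(self):
        logits = np.array([[1.0, 2.0, 0.5], [0.0, -1.0, 1.0]])
        labels = np.array([1, 2])
        want = -np.mean([
            logits[0, 1] - np.log(np.exp(logits[0]).sum()),
            logits[1, 2] - np.log(np.exp(logits[1]).sum()),
        ])
        assert float(cross_entropy(logits, labels).data) == pytest.approx(
            want, abs=1e-9
        )

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.zeros((2, 3)), np.array([0, 3]))
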