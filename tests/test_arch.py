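"""Architecture calculus, model construction, gradients, and features."""

import numpy as np
import pytest

import ccecg
from ccecg.arch import ConvNet, HPConfig, _conv_forward
from ccecg.exceptions import InvalidParameterError, ShapeInfeasibleError
from ccecg.search import sample_hp


class TestShapeTrace:
    def test_preset_conv_and_pool_lengths(self):
        trace = ccecg.shape_trace(ccecg.cnn3_preset())
        assert trace.conv_lens == (1241, 601, 281)
        assert trace.pool_lens == (620, 300, 140)
        assert trace.gmp_len == 50

    def test_depth_seven_minimal_kernels_end_at_five(self):
        hp = HPConfig(7, (5,) * 7, (5,) * 7)
        assert ccecg.shape_trace(hp).pool_lens[-1] == 5

    def test_infeasible_configuration_raises(self):
        # after six blocks of heavy shrinkage the kernel no longer fits
        hp = HPConfig(7, (5,) * 7, (100, 100, 100, 5, 5, 5, 5))
        with pytest.raises(ShapeInfeasibleError):
            ccecg.shape_trace(hp)

    def test_pool_lengths_strictly_decrease(self):
        for seed in range(40):
            trace = ccecg.shape_trace(sample_hp(seed))
            assert all(np.diff(trace.pool_lens) < 0)


class TestCountParams:
    def test_preset_block_counts_and_total(self):
        hp = ccecg.cnn3_preset()
        assert ccecg.block_param_counts(hp) == [55, 2525, 25050, 51]
        assert ccecg.count_params(hp) == 27681

    def test_hand_evaluated_two_block_case(self):
        # 5*(5*1+1) + 5*(5*5+1) + (5+1) = 30 + 130 + 6 = 166
        assert ccecg.count_params(HPConfig(2, (5, 5), (5, 5))) == 166

    def test_grid_membership_enforced(self):
        with pytest.raises(InvalidParameterError):
            HPConfig(2, (7, 5), (5, 5))
        with pytest.raises(InvalidParameterError):
            HPConfig(2, (5, 5), (5, 42))
        with pytest.raises(InvalidParameterError):
            HPConfig(2, (5, 5, 5), (5, 5))


class TestModel:
    def test_introspected_params_equal_closed_form(self):
        for seed in range(30):
            hp = sample_hp(seed)
            model = ccecg.build_model(hp, init_seed=seed)
            assert model.num_params == ccecg.count_params(hp)

    def test_activation_shapes_follow_trace(self):
        hp = ccecg.cnn3_preset()
        model = ccecg.build_model(hp, init_seed=1)
        strip = ccecg.gen_vf(10, 0)
        acts = model.layer_activations(strip)
        trace = ccecg.shape_trace(hp)
        for i in range(hp.n_blocks):
            assert acts["conv"][i].shape == (trace.conv_lens[i], hp.filters[i])
            assert acts["pool"][i].shape == (trace.pool_lens[i], hp.filters[i])
        assert acts["gmp"].shape == (hp.filters[-1],)

    def test_output_is_probability_and_init_deterministic(self, rng):
        model_a = ccecg.build_model(ccecg.cnn3_preset(), init_seed=5)
        model_b = ccecg.build_model(ccecg.cnn3_preset(), init_seed=5)
        for pa, pb in zip(model_a.parameters, model_b.parameters):
            np.testing.assert_array_equal(pa, pb)
        x = rng.normal(0, 400, (4, 1250))
        p = model_a.predict_proba(x)
        assert np.all((p >= 0) & (p <= 1))

    def test_build_rejects_infeasible(self):
        hp = HPConfig(7, (5,) * 7, (100, 100, 100, 5, 5, 5, 5))
        with pytest.raises(ShapeInfeasibleError):
            ccecg.build_model(hp, init_seed=0)

    def test_dropout_only_in_training(self, rng):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=2)
        x = rng.normal(0, 400, (3, 1250))
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))
        p_train_a = model.forward(x, training=True, dropout_rng=np.random.default_rng(1))
        p_train_b = model.forward(x, training=True, dropout_rng=np.random.default_rng(2))
        assert not np.array_equal(p_train_a, p_train_b)

    @pytest.mark.parametrize(
        "hp", [HPConfig(2, (5, 5), (5, 5)), HPConfig(2, (25, 25), (5, 5))],
        ids=["thin-channels", "wide-channels"],
    )
    def test_gradients_match_finite_differences(self, hp):
        """Backpropagation is exact for both convolution strategies."""
        net = ConvNet(hp, init_seed=1, input_len=60, dtype=np.float64)
        gen = np.random.default_rng(0)
        x = gen.normal(0, 1, (4, 60))
        y = np.array([0, 1, 1, 0])
        _, grads, _ = net.loss_and_gradients(x, y, training=False)
        eps = 1e-6
        for pi, p in enumerate(net.parameters):
            flat = p.reshape(-1)
            for idx in gen.choice(flat.size, size=min(flat.size, 6), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                up, _, _ = net.loss_and_gradients(x, y, training=False)
                flat[idx] = old - eps
                down, _, _ = net.loss_and_gradients(x, y, training=False)
                flat[idx] = old
                numeric = (up - down) / (2 * eps)
                assert grads[pi].reshape(-1)[idx] == pytest.approx(
                    numeric, rel=1e-3, abs=1e-9
                )

    def test_conv_strategies_agree(self, rng):
        """im2col (thin channels) and tap-loop products give identical maps."""
        x = rng.normal(0, 1, (3, 80, 20))
        w = rng.normal(0, 0.1, (7, 20, 6))
        b = rng.normal(0, 0.1, 6)
        thin = _conv_forward(x[:, :, :8].copy(), w[:, :8], b)
        # brute-force reference
        ref = np.zeros_like(thin)
        for j in range(80 - 7 + 1):
            ref[:, j, :] = np.tensordot(x[:, j:j + 7, :8], w[:, :8], axes=([1, 2], [0, 1]))
        np.testing.assert_allclose(thin, ref + b, rtol=1e-10, atol=1e-10)
        wide = _conv_forward(x, w, b)
        ref_w = np.zeros_like(wide)
        for j in range(80 - 7 + 1):
            ref_w[:, j, :] = np.tensordot(x[:, j:j + 7, :], w, axes=([1, 2], [0, 1]))
        np.testing.assert_allclose(wide, ref_w + b, rtol=1e-10, atol=1e-10)


class TestClassifyAndFeatures:
    def test_boundary_probability_is_shockable(self):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=3)
        strip = ccecg.gen_vf(10, 1)
        p = float(model.predict_proba(strip.samples)[0])
        assert ccecg.classify(model, strip.samples[None, :], pthr=p)[0] == "Sh"

    def test_high_threshold_yields_no_shocks(self):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=3)
        ds = ccecg.make_dataset({"VF": 2, "OR": 2, "ASYSTOLE": 2}, seed=1)
        assert list(ccecg.classify(model, ds, pthr=1 - 1e-12)) == ["NSh"] * 6

    def test_invalid_threshold(self):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=3)
        with pytest.raises(InvalidParameterError):
            ccecg.classify(model, np.zeros((1, 1250)), pthr=0.0)

    def test_gmp_equals_bruteforce_max_of_final_activation(self):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=4)
        strip = ccecg.gen_or(10, 2)
        features, _ = ccecg.extract_gmp_features(model, strip)
        acts = model.layer_activations(strip)
        np.testing.assert_allclose(features, acts["pool"][-1].max(axis=0), rtol=1e-6)
        assert features.shape == (50,)

    def test_filter_order_sorts_classifier_weights(self):
        model = ccecg.build_model(ccecg.cnn3_preset(), init_seed=4)
        model.dense_w[:3] = [+1.0, -2.0, +0.5]
        model.dense_w[3:] = np.linspace(2, 3, 47)
        order = ccecg.gmp_filter_order(model)
        assert list(order[:3]) == [1, 2, 0]
        assert np.all(np.diff(model.dense_w[order]) >= 0)
        # it is a true permutation: composing with its inverse is the identity
        inverse = np.argsort(order)
        np.testing.assert_array_equal(order[inverse], np.arange(50))
        np.testing.assert_array_equal(np.sort(order), np.arange(50))
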