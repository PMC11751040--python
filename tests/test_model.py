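import numpy as np
import pytest

import cyspred as cp
from cyspred.encoding import as_sequence_features, encode_dataset
from cyspred.model import additive_attention, build_model


def attention_oracle(O, H, w1, w2, v):
    """Step-by-step scalar recomputation of the additive-attention equations."""
    n, t, d = O.shape
    a = w1.shape[1]
    scores = np.zeros((n, t))
    for b in range(n):
        for step in range(t):
            pre = np.zeros(a)
            for k in range(a):
                s1 = sum(O[b, step, i] * w1[i, k] for i in range(d))
                s2 = sum(H[b, i] * w2[i, k] for i in range(H.shape[1]))
                pre[k] = np.tanh(s1 + s2)
            scores[b, step] = sum(pre[k] * v[k, 0] for k in range(a))
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    weights = e / e.sum(axis=1, keepdims=True)
    context = np.einsum("nt,ntd->nd", weights, O)
    return context, weights


class TestAdditiveAttention:
    def test_matches_scalar_recomputation(self):
        rng = np.random.default_rng(0)
        O = rng.normal(size=(2, 3, 4))
        H = rng.normal(size=(2, 4))
        w1 = rng.normal(size=(4, 3)) * 0.5
        w2 = rng.normal(size=(4, 3)) * 0.5
        v = rng.normal(size=(3, 1))
        C, scores = additive_attention(O, H, w1, w2, v)
        C_ref, scores_ref = attention_oracle(O, H, w1, w2, v)
        assert np.allclose(scores, scores_ref, atol=1e-12)
        assert np.allclose(C, C_ref, atol=1e-12)

    def test_single_timestep_gets_full_weight(self):
        rng = np.random.default_rng(1)
        O = rng.normal(size=(3, 1, 5))
        H = rng.normal(size=(3, 5))
        w1, w2, v = rng.normal(size=(5, 4)), rng.normal(size=(5, 4)), rng.normal(size=(4, 1))
        C, scores = additive_attention(O, H, w1, w2, v)
        assert np.allclose(scores, 1.0)
        assert np.allclose(C, O[:, 0, :])

    def test_identical_timesteps_share_weight(self):
        rng = np.random.default_rng(2)
        row = rng.normal(size=(1, 1, 5))
        O = np.repeat(row, 2, axis=1)
        H = rng.normal(size=(1, 5))
        w1, w2, v = rng.normal(size=(5, 4)), rng.normal(size=(5, 4)), rng.normal(size=(4, 1))
        _, scores = additive_attention(O, H, w1, w2, v)
        assert np.allclose(scores, 0.5)

    def test_constant_score_shift_invariance(self):
        """Softmax weights are unchanged by adding a constant to all scores,
        which for additive attention follows from shifting v's bias-free
        projection uniformly."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(2, 6))
        from cyspred import nn

        w_a = nn.softmax(nn.Tensor(scores), axis=1).data
        w_b = nn.softmax(nn.Tensor(scores + 7.3), axis=1).data
        assert np.allclose(w_a, w_b, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            additive_attention(rng.normal(size=(2, 3, 4)), rng.normal(size=(2, 4)),
                               rng.normal(size=(5, 3)), rng.normal(size=(4, 3)),
                               rng.normal(size=(3, 1)))


class TestBuildModel:
    def test_seeded_init_is_identical(self, tiny_model_config):
        a = build_model(tiny_model_config, L=11, feature_dim=20, seed=5)
        b = build_model(tiny_model_config, L=11, feature_dim=20, seed=5)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    def test_too_short_input_names_minimum(self, tiny_model_config):
        with pytest.raises(ValueError, match=str(tiny_model_config.min_input_length())):
            build_model(tiny_model_config, L=3, feature_dim=20)

    def test_parameter_count_deterministic(self, tiny_model_config):
        a = build_model(tiny_model_config, L=11, feature_dim=20, seed=0)
        b = build_model(tiny_model_config, L=11, feature_dim=20, seed=99)
        assert a.num_parameters() == b.num_parameters()

    @pytest.mark.parametrize("flags", [
        dict(use_cnn=False), dict(use_bilstm=False), dict(use_attention=False),
        dict(use_cnn=False, use_bilstm=False, use_attention=False),
    ])
    def test_ablations_run_from_config(self, flags):
        cfg = cp.ModelConfig(conv_channels=(4, 6), kernel_sizes=(3, 3), pool_size=2,
                             lstm_hidden=6, attention_dim=5, fc_sizes=(8, 6),
                             dropout=0.0, **flags)
        model = build_model(cfg, L=11, feature_dim=20, seed=0)
        probs = model.predict_proba(np.random.default_rng(0).normal(size=(4, 11, 20)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestForward:
    def test_probabilities_and_attention_normalized(self, tiny_model_config):
        model = build_model(tiny_model_config, L=11, feature_dim=20, seed=0)
        X = np.random.default_rng(1).normal(size=(7, 11, 20))
        probs, attn = model.predict_proba(X, return_attention=True)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert np.all(attn >= 0)
        assert np.allclose(attn.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_bitwise_deterministic(self, tiny_model_config):
        model = build_model(tiny_model_config, L=11, feature_dim=20, seed=0)
        X = np.random.default_rng(2).normal(size=(5, 11, 20))
        assert np.array_equal(model.predict_proba(X), model.predict_proba(X))

    def test_batch_permutation_permutes_outputs(self, tiny_model_config):
        model = build_model(tiny_model_config, L=11, feature_dim=20, seed=0)
        X = np.random.default_rng(3).normal(size=(6, 11, 20))
        perm = np.array([3, 0, 5, 1, 4, 2])
        assert np.allclose(model.predict_proba(X)[perm], model.predict_proba(X[perm]),
                           atol=1e-12)

    def test_wrong_shape_rejected(self, tiny_model_config):
        model = build_model(tiny_model_config, L=11, feature_dim=20, seed=0)
        with pytest.raises(ValueError, match="shape"):
            model.predict_proba(np.zeros((2, 13, 20)))


class TestPredict:
    def test_untrained_model_needs_override(self, separable_dataset):
        cfg = cp.ModelConfig(conv_channels=(4, 6), kernel_sizes=(3, 3), pool_size=2,
                             lstm_hidden=6, attention_dim=5, fc_sizes=(8, 6))
        model = build_model(cfg, L=11, feature_dim=20, seed=0)
        with pytest.raises(ValueError, match="untrained"):
            cp.predict(model, separable_dataset)
        scores, attn = cp.predict(model, separable_dataset, allow_untrained=True)
        assert scores.shape == (len(separable_dataset),)
        assert attn.shape[0] == len(separable_dataset)

    def test_duplicate_windows_score_identically(self, separable_dataset,
                                                 tiny_model_config):
        model = build_model(tiny_model_config, L=11, feature_dim=20, seed=0)
        X = as_sequence_features(
            encode_dataset(separable_dataset, "bwe", cp.EncodingConfig(L=11))
        )
        X2 = np.concatenate([X, X[:1]])
        probs = model.predict_proba(X2)
        assert np.array_equal(probs[0], probs[-1])


def test_checkpoint_roundtrip(tmp_path, tiny_model_config):
    model = build_model(tiny_model_config, L=11, feature_dim=20, seed=8)
    model.trained = True
    X = np.random.default_rng(5).normal(size=(4, 11, 20))
    before = model.predict_proba(X)
    model.save(tmp_path / "ckpt")
    loaded = cp.SitePredictor.load(tmp_path / "ckpt")
    assert loaded.trained
    assert loaded.config == model.config
    assert np.array_equal(loaded.predict_proba(X), before)
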