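"""TFDS covariance descriptor: stage oracles, invariants, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigcough import (TfdsConfig, ValidationError, adaptive_pool,
                      flatten_concat, init_tfds_params, project_subbands,
                      spectral_covariance, temporal_covariance, tfds_backward,
                      tfds_forward)
from pigcough.tfds import TfdsParams, pooling_matrix

SMALL = TfdsConfig(subbands=5, t_max=4, s_max=3, hidden_dim=6, n_mels=7)


def _loop_project(x, w, b):
    out = np.zeros((x.shape[0], w.shape[0], x.shape[2]))
    for bi in range(x.shape[0]):
        for t in range(x.shape[2]):
            out[bi, :, t] = w @ x[bi, :, t] + b
    return out


class TestProjectSubbands:
    def test_default_shape_and_nonnegativity(self, rng):
        params = init_tfds_params(TfdsConfig(), seed=0)
        z = project_subbands(rng.standard_normal((8, 64, 62)), params)
        assert z.shape == (8, 32, 62)
        assert np.all(z >= 0)

    def test_identity_like_weights(self, rng):
        """With unit rows selecting the first 5 mel bins and batch-norm
        bypassed (identity statistics), the output is ReLU of those rows."""
        params = init_tfds_params(SMALL, seed=0)
        params.conv_w = np.eye(5, 7)
        params.conv_b = np.zeros(5)
        params.bn_mean[:] = 0.0
        params.bn_var[:] = 1.0 - 1e-5  # cancel the stability epsilon
        x = rng.standard_normal((2, 7, 9))
        z = project_subbands(x, params, training=False)
        assert np.allclose(z, np.maximum(x[:, :5, :], 0.0))

    def test_matches_loop_oracle(self, rng):
        params = init_tfds_params(SMALL, seed=1)
        x = rng.standard_normal((3, 7, 9))
        pre = _loop_project(x, params.conv_w, params.conv_b)
        mu, var = params.bn_mean, params.bn_var
        expected = np.maximum(
            params.bn_gamma[None, :, None]
            * (pre - mu[None, :, None]) / np.sqrt(var + 1e-5)[None, :, None]
            + params.bn_beta[None, :, None], 0.0)
        z = project_subbands(x, params, training=False)
        assert np.allclose(z, expected)

    def test_channel_mismatch_rejected(self, rng):
        params = init_tfds_params(SMALL, seed=0)
        with pytest.raises(ValidationError):
            project_subbands(rng.standard_normal((2, 9, 9)), params)


class TestCovariances:
    def test_zero_input(self):
        z = np.zeros((2, 3, 4))
        assert np.all(temporal_covariance(z) == 0)
        assert np.all(spectral_covariance(z) == 0)

    def test_single_subband_rank_one(self, rng):
        row = rng.standard_normal(6)
        z = row[None, None, :]
        ct = temporal_covariance(z)[0]
        assert np.allclose(ct, np.outer(row, row))
        assert np.linalg.matrix_rank(ct) <= 1

    def test_orthogonal_rows_give_scaled_identity(self):
        z = np.zeros((1, 3, 4))
        z[0, 0, 0] = z[0, 1, 1] = z[0, 2, 2] = 2.0
        cf = spectral_covariance(z)[0]
        assert np.allclose(cf, 4.0 * np.eye(3))

    def test_triple_loop_oracle(self, rng):
        z = rng.standard_normal((2, 3, 4))
        ct, cf = temporal_covariance(z), spectral_covariance(z)
        for b in range(2):
            for i in range(4):
                for j in range(4):
                    assert np.isclose(ct[b, i, j],
                                      sum(z[b, s, i] * z[b, s, j]
                                          for s in range(3)))
            for a in range(3):
                for c in range(3):
                    assert np.isclose(cf[b, a, c],
                                      sum(z[b, a, t] * z[b, c, t]
                                          for t in range(4)))

    def test_symmetry_and_psd(self, rng):
        """Gram matrices are symmetric and positive semi-definite."""
        for _ in range(20):
            z = rng.standard_normal((2, 5, 8)) * rng.uniform(0.1, 10)
            for c in (temporal_covariance(z), spectral_covariance(z)):
                assert np.allclose(c, c.transpose(0, 2, 1), atol=1e-12)
                for b in range(c.shape[0]):
                    assert np.linalg.eigvalsh(c[b]).min() >= -1e-8

    def test_quadratic_scaling(self, rng):
        z = rng.standard_normal((2, 4, 6))
        assert np.allclose(temporal_covariance(3.0 * z),
                           9.0 * temporal_covariance(z))
        assert np.allclose(spectral_covariance(3.0 * z),
                           9.0 * spectral_covariance(z))


def _pool_oracle(c, m):
    n = c.shape[0]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            r0, r1 = (i * n) // m, -(-((i + 1) * n) // m)
            c0, c1 = (j * n) // m, -(-((j + 1) * n) // m)
            out[i, j] = c[r0:r1, c0:c1].mean()
    return out


class TestAdaptivePool:
    def test_identity_when_m_equals_n(self, rng):
        c = rng.standard_normal((5, 5))
        assert np.allclose(adaptive_pool(c, 5), c)

    def test_constant_matrix(self):
        assert np.allclose(adaptive_pool(np.full((7, 7), 3.3), 3), 3.3)

    def test_quadrant_means(self):
        c = np.arange(1, 17, dtype=float).reshape(4, 4)
        assert np.allclose(adaptive_pool(c, 2),
                           [[3.5, 5.5], [11.5, 13.5]])

    def test_m_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            adaptive_pool(np.eye(3), 4)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(min_value=1, max_value=12),
           st.integers(min_value=1, max_value=12), st.integers(0, 2 ** 31 - 1))
    def test_matches_region_mean_oracle(self, n, m, seed):
        if m > n:
            return
        c = np.random.default_rng(seed).standard_normal((n, n))
        assert np.allclose(adaptive_pool(c, m), _pool_oracle(c, m))

    def test_grand_mean_preserved_when_m_divides_n(self, rng):
        c = rng.standard_normal((12, 12))
        pooled = adaptive_pool(c, 4)
        assert np.isclose(pooled.mean(), c.mean())

    def test_pooling_matrix_regions_cover(self):
        p = pooling_matrix(62, 25)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.all(p.sum(axis=0) > 0)  # every source index used


class TestFlattenConcat:
    def test_default_length_881(self, rng):
        cfg = TfdsConfig()
        flat = flatten_concat(rng.standard_normal((2, 25, 25)),
                              rng.standard_normal((2, 16, 16)), cfg)
        assert flat.shape == (2, 881)

    def test_tiny_sizes(self, rng):
        cfg = TfdsConfig(t_max=2, s_max=2)
        assert flatten_concat(np.zeros((1, 2, 2)), np.zeros((1, 2, 2)),
                              cfg).shape == (1, 8)

    def test_temporal_block_comes_first_row_major(self, rng):
        cfg = TfdsConfig(t_max=2, s_max=2)
        ct = np.arange(4, dtype=float).reshape(1, 2, 2)
        flat = flatten_concat(ct, np.zeros((1, 2, 2)), cfg)
        assert np.array_equal(flat[0, :4], [0, 1, 2, 3])

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            flatten_concat(np.zeros((1, 3, 3)), np.zeros((1, 16, 16)),
                           TfdsConfig())


class TestForward:
    def test_default_output_shape_nonneg(self, rng):
        cfg = TfdsConfig()
        params = init_tfds_params(cfg, seed=0)
        g = tfds_forward(rng.standard_normal((8, 64, 62)), cfg, params)
        assert g.shape == (8, 128)
        assert np.all(g >= 0)

    def test_zero_input_zero_bias_gives_zero(self):
        cfg = TfdsConfig()
        params = init_tfds_params(cfg, seed=0)
        params.bn_beta[:] = 0.0
        g = tfds_forward(np.zeros((2, 64, 62)), cfg, params)
        assert np.allclose(g, 0.0)

    def test_matches_stage_composition(self, rng):
        cfg = SMALL
        params = init_tfds_params(cfg, seed=2)
        x = rng.standard_normal((3, 7, 9))
        z = project_subbands(x, params, training=False)
        flat = flatten_concat(adaptive_pool(temporal_covariance(z), cfg.t_max),
                              adaptive_pool(spectral_covariance(z), cfg.s_max),
                              cfg)
        expected = np.maximum(flat @ params.w_proj.T + params.b_proj, 0.0)
        assert np.allclose(tfds_forward(x, cfg, params), expected)

    def test_batch_permutation_covariance(self, rng):
        cfg = SMALL
        params = init_tfds_params(cfg, seed=3)
        x = rng.standard_normal((4, 7, 9))
        perm = np.array([2, 0, 3, 1])
        assert np.allclose(tfds_forward(x, cfg, params)[perm],
                           tfds_forward(x[perm], cfg, params))


class TestBackward:
    @pytest.mark.parametrize("training", [False, True])
    def test_matches_central_differences(self, rng, training):
        """All six trainable tensors, including through training-mode
        batch-norm statistics."""
        cfg = SMALL
        params = init_tfds_params(cfg, seed=4)
        x = rng.standard_normal((3, 7, 9))
        w_out = rng.standard_normal((6,))
        bn0 = (params.bn_mean.copy(), params.bn_var.copy())

        def loss():
            params.bn_mean, params.bn_var = bn0[0].copy(), bn0[1].copy()
            return float((tfds_forward(x, cfg, params, training=training)
                          * w_out).sum())

        cache = {}
        params.bn_mean, params.bn_var = bn0[0].copy(), bn0[1].copy()
        g = tfds_forward(x, cfg, params, training=training, cache=cache)
        dg = np.tile(w_out, (3, 1))
        grads = tfds_backward(dg, cfg, params, cache)
        for name in TfdsParams.TRAINABLE:
            arr = getattr(params, name)
            it = np.nditer(arr, flags=["multi_index"])
            num = np.zeros_like(arr)
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + 1e-6
                lp = loss()
                arr[i] = old - 1e-6
                lm = loss()
                arr[i] = old
                num[i] = (lp - lm) / 2e-6
            assert np.max(np.abs(num - grads[name])) < 1e-6, name
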