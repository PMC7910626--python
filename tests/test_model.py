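"""Network architecture, forward pass, gradients, training, decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionlab import corpus as C
from motionlab import model as M


def loop_correlation(batch, kernels, offsets):
    """Brute-force six-nested-loop valid correlation oracle (per frame
    window), written independently of the vectorised implementation."""
    n, H, W, T = batch.shape
    K, ky, kx, kt = kernels.shape
    oh, ow, ot = H - ky + 1, W - kx + 1, T - kt + 1
    out = np.zeros((n, K, oh, ow, ot))
    for s in range(n):
        for k in range(K):
            for i in range(oh):
                for j in range(ow):
                    for t in range(ot):
                        acc = 0.0
                        for a in range(ky):
                            for b in range(kx):
                                for c in range(kt):
                                    acc += batch[s, i + a, j + b, t + c] * kernels[k, a, b, c]
                        out[s, k, i, j, t] = acc + offsets[k]
    return np.maximum(out, 0.0)


class TestArchitecture:
    def test_default_parameter_and_connection_counts(self):
        counts = M.count_connections(M.ArchConfig())
        assert counts["v1"]["parameters"] == 13_888
        assert counts["v1"]["connections"] == 64 * 27 * 27 * 6 * 6 * 6 == 10_077_696
        assert counts["output"]["connections"] == 128
        assert counts["output"]["parameters"] == 130
        # pure valid convolution, no pooling: 64 maps of 27x27 V1 units
        assert M.ArchConfig().n_v1_units == 64 * 27 * 27

    def test_degenerate_single_connection(self):
        arch = M.ArchConfig(n_kernels=1, kernel_size=(1, 1, 1),
                            input_size=(1, 1, 1), n_mt_units=1, n_outputs=1)
        counts = M.count_connections(arch)
        assert counts["v1"] == {"connections": 1, "parameters": 2}

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            M.ArchConfig(kernel_size=(40, 6, 6))


class TestInit:
    def test_kernel_noise_scale_and_zero_offsets(self):
        params = M.init_model(seed=0)
        sd = params.v1_kernels.std()
        assert 0.0009 <= sd <= 0.0011
        assert np.all(params.v1_offsets == 0)
        assert np.all(params.mt_offsets == 0)
        assert np.all(params.out_offsets == 0)

    def test_deterministic_per_seed(self):
        a = M.init_model(seed=3)
        b = M.init_model(seed=3)
        assert np.array_equal(a.v1_kernels, b.v1_kernels)
        assert np.array_equal(a.mt_weights, b.mt_weights)
        c = M.init_model(seed=4)
        assert not np.array_equal(a.v1_kernels, c.v1_kernels)

    def test_zero_hidden_init_available(self):
        params = M.init_model(seed=0, hidden_init="zero")
        assert np.all(params.mt_weights == 0)
        assert np.all(params.out_weights == 0)


class TestForward:
    def test_matches_loop_oracle(self, tiny_arch, rng):
        for _ in range(10):
            params = M.init_model(tiny_arch, seed=int(rng.integers(1 << 16)))
            params.v1_kernels = rng.standard_normal(params.v1_kernels.shape)
            params.v1_offsets = rng.standard_normal(params.v1_offsets.shape) * 0.1
            batch = rng.standard_normal((2, *tiny_arch.input_size))
            expect = loop_correlation(batch, params.v1_kernels, params.v1_offsets)
            v1_flat, mt, out = M.forward_batch(params, batch)
            h, w, t = tiny_arch.map_size
            got = v1_flat.reshape(2, tiny_arch.n_kernels, h, w, t)
            np.testing.assert_allclose(got, expect, atol=1e-6)
            # dense stages are plain affine maps of the rectified maps
            expect_mt = np.maximum(
                expect.reshape(2, -1) @ params.mt_weights.T + params.mt_offsets, 0)
            np.testing.assert_allclose(mt, expect_mt, atol=1e-6)
            np.testing.assert_allclose(
                out, expect_mt @ params.out_weights.T + params.out_offsets, atol=1e-6)

    def test_zero_input_yields_rectified_offsets(self, tiny_arch):
        params = M.init_model(tiny_arch, seed=0)
        params.v1_offsets = np.array([0.5, -0.3])
        acts = M.forward(params, np.zeros(tiny_arch.input_size))
        assert np.allclose(acts.v1[0], 0.5)
        assert np.allclose(acts.v1[1], 0.0)

    def test_rectification_nonnegative(self, tiny_arch, rng):
        params = M.init_model(tiny_arch, seed=1)
        params.v1_kernels = rng.standard_normal(params.v1_kernels.shape)
        acts = M.forward(params, rng.standard_normal(tiny_arch.input_size))
        assert np.all(acts.v1 >= 0)
        assert np.all(acts.mt >= 0)

    def test_shape_mismatch_rejected(self, tiny_arch):
        params = M.init_model(tiny_arch, seed=0)
        with pytest.raises(ValueError, match="extent"):
            M.forward_batch(params, np.zeros((1, 5, 5, 2)))


class TestGradients:
    def test_analytic_matches_finite_differences(self, tiny_arch, rng):
        params = M.init_model(tiny_arch, seed=0)
        params.v1_kernels = rng.standard_normal(params.v1_kernels.shape) * 0.3
        params.v1_offsets = rng.standard_normal(2) * 0.1
        params.mt_offsets = rng.standard_normal(4) * 0.1
        params.out_offsets = rng.standard_normal(2) * 0.1
        batch = rng.standard_normal((3, *tiny_arch.input_size))
        labels = rng.standard_normal((3, 2))
        loss, grads = M._loss_and_grads(params, batch, labels)
        eps = 1e-5
        for name in grads:
            arr = getattr(params, name)
            flat = arr.ravel()
            g = grads[name].ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = M._loss_and_grads(params, batch, labels)
                flat[i] = orig - eps
                lm, _ = M._loss_and_grads(params, batch, labels)
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(g[i]), 1e-8)
                assert abs(fd - g[i]) / denom < 1e-4, f"{name}[{i}]: {fd} vs {g[i]}"


class TestTraining:
    def _constant_corpus(self, tiny_arch, n=256):
        frames = np.ones(tiny_arch.input_size) * 0.5
        seqs = [C.MotionSequence(frames=frames.copy(), v_x=0.0, v_y=0.0)
                for _ in range(n)]
        return C.Corpus(train=seqs[: 3 * n // 4], test=seqs[3 * n // 4:], seed=0)

    def test_constant_target_regression_converges(self, tiny_arch):
        corp = self._constant_corpus(tiny_arch)
        params = M.init_model(tiny_arch, seed=0)
        params, hist = M.train(
            params, corp,
            M.TrainConfig(learning_rate=1e-2, batch_size=32, epochs=5, seed=0))
        assert hist.train_loss[-1] < 1e-4
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_vanishing_learning_rate_is_identity(self, tiny_arch, rng):
        corp = self._constant_corpus(tiny_arch, n=8)
        params = M.init_model(tiny_arch, seed=0)
        # nonzero everywhere: a parameter at exactly 0 would pick up a
        # denormal-sized update instead of none at all
        for name in M._PARAM_DSETS:
            arr = getattr(params, name)
            arr += rng.uniform(0.1, 1.0, size=arr.shape)
        out, _ = M.train(
            params, corp,
            M.TrainConfig(learning_rate=1e-200, batch_size=4, epochs=1, seed=0),
            dtype=np.float64)
        for name in M._PARAM_DSETS:
            np.testing.assert_array_equal(getattr(out, name), getattr(params, name))

    def test_canonical_training_defaults(self):
        cfg = M.TrainConfig()
        assert cfg.learning_rate == 1.0e-4
        assert cfg.batch_size == 32
        assert cfg.epochs == 25

    def test_deterministic_per_seed(self, tiny_arch):
        corp = self._constant_corpus(tiny_arch, n=16)
        a, _ = M.train(M.init_model(tiny_arch, seed=0), corp,
                       M.TrainConfig(epochs=1, seed=5))
        b, _ = M.train(M.init_model(tiny_arch, seed=0), corp,
                       M.TrainConfig(epochs=1, seed=5))
        assert np.array_equal(a.v1_kernels, b.v1_kernels)


class TestEvaluate:
    def test_too_few_sequences(self, tiny_arch):
        params = M.init_model(tiny_arch, seed=0)
        with pytest.raises(ValueError):
            M.evaluate(params, [])

    def test_zero_variance_flagged(self, tiny_arch):
        params = M.init_model(tiny_arch, seed=0, hidden_init="zero")
        seqs = [C.MotionSequence(np.zeros(tiny_arch.input_size), v_x=1.0, v_y=0.0)
                for _ in range(4)]
        with pytest.raises(ValueError, match="zero-variance"):
            M.evaluate(params, seqs)


class TestToPolar:
    def test_diagonal_unit_velocity(self):
        est = M.to_polar(0.7071, 0.7071)
        assert est.speed == pytest.approx(1.0, abs=1e-4)
        assert est.direction == pytest.approx(45.0, abs=1e-4)

    def test_rightward(self):
        est = M.to_polar(1.0, 0.0)
        assert est.speed == 1.0
        assert est.direction == 0.0

    def test_zero_velocity_undefined_direction(self):
        est = M.to_polar(0.0, 0.0)
        assert est.speed == 0.0
        assert est.direction is None
        assert not est.direction_defined

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(speed=st.floats(0.01, 4.0), direction=st.floats(0.0, 359.999))
    def test_polar_roundtrip(self, speed, direction):
        v_x = speed * np.cos(np.radians(direction))
        v_y = speed * np.sin(np.radians(direction))
        est = M.to_polar(v_x, v_y)
        assert est.speed == pytest.approx(speed, abs=1e-9)
        assert est.direction == pytest.approx(direction, abs=1e-9)


class TestPersistence:
    def test_bit_exact_roundtrip(self, tiny_arch, tmp_path):
        params = M.init_model(tiny_arch, seed=0)
        path = tmp_path / "model.h5"
        M.persist_model(params, path)
        loaded = M.load_model(path)
        for name in M._PARAM_DSETS:
            np.testing.assert_array_equal(getattr(loaded, name), getattr(params, name))
        assert loaded.arch == params.arch
        assert loaded.seed == params.seed

    def test_truncated_file_raises(self, tiny_arch, tmp_path):
        path = tmp_path / "model.h5"
        M.persist_model(M.init_model(tiny_arch, seed=0), path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(IOError):
            M.load_model(path)

    def test_different_seeds_different_files(self, tiny_arch, tmp_path):
        p0, p1 = tmp_path / "a.h5", tmp_path / "b.h5"
        M.persist_model(M.init_model(tiny_arch, seed=0), p0)
        M.persist_model(M.init_model(tiny_arch, seed=1), p1)
        assert p0.read_bytes() != p1.read_bytes()


class TestEmergentSelectivity:
    def test_majority_of_v1_kernels_direction_selective(self, scaled_ensemble):
        """After scaled training, most V1 kernels respond at least twice
        as strongly to their preferred grating direction as to the
        opposite direction at their best spatiotemporal period."""
        v1_t, _ = scaled_ensemble.batteries[0]
        n_dir = v1_t.directions.size
        n_selective = 0
        for u in range(v1_t.n_units):
            vals = v1_t.values[u]
            idx = np.unravel_index(np.argmax(vals), vals.shape)
            anti = ((idx[0] + n_dir // 2) % n_dir, idx[1], idx[2])
            if vals[idx] >= 2.0 * vals[anti]:
                n_selective += 1
        assert n_selective >= v1_t.n_units / 2
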