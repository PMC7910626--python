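"""Tuning batteries, partial-correlation classification, spectral fits."""

import numpy as np
import pytest

from motionlab import model as M
from motionlab import probes as P
from motionlab import tuning as T


def regress_out_partial(data, pred_a, pred_b):
    """Textbook oracle: partial correlation of data with pred_a
    controlling pred_b = correlation of the residuals after regressing
    pred_b out of both."""
    def residual(y, x):
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    ra = residual(data, pred_b)
    rb = residual(pred_a, pred_b)
    return float(np.corrcoef(ra, rb)[0, 1])


class TestPartialCorrelation:
    def test_matches_regress_out_oracle(self, rng):
        for _ in range(100):
            data = rng.standard_normal(20)
            pa = rng.standard_normal(20)
            pb = 0.5 * pa + rng.standard_normal(20)
            r_p = np.corrcoef(data, pa)[0, 1]
            r_c = np.corrcoef(data, pb)[0, 1]
            r_cp = np.corrcoef(pa, pb)[0, 1]
            R_p, R_c = T.partial_correlation(r_p, r_c, r_cp)
            assert R_p == pytest.approx(regress_out_partial(data, pa, pb), abs=1e-10)
            assert R_c == pytest.approx(regress_out_partial(data, pb, pa), abs=1e-10)

    def test_uncorrelated_predictions_reduce_to_raw(self):
        R_p, _ = T.partial_correlation(0.7, 0.0, 0.0)
        assert R_p == pytest.approx(0.7)

    def test_hand_evaluated_example(self):
        R_p, _ = T.partial_correlation(0.9, 0.3, 0.5)
        assert R_p == pytest.approx((0.9 - 0.15) / np.sqrt(0.91 * 0.75), abs=1e-10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ZeroDivisionError):
            T.partial_correlation(0.5, 0.5, 1.0)
        with pytest.raises(ValueError):
            T.partial_correlation(1.5, 0.0, 0.0)


class TestDirectionClassification:
    @staticmethod
    def _tuning_curve(center_idx, width=1.5, n=16):
        idx = np.arange(n)
        d = np.minimum(np.abs(idx - center_idx), n - np.abs(idx - center_idx))
        return np.exp(-0.5 * (d / width) ** 2)

    def test_component_like_unit(self, rng):
        g = self._tuning_curve(5)
        comp = np.roll(g, 3) + np.roll(g, -3)
        noise = rng.normal(0, 0.01, 16)
        cls = T.classify_direction_selectivity(g, comp + noise)
        assert cls.label == "component"
        assert cls.index < 0

    def test_pattern_like_unit(self, rng):
        g = self._tuning_curve(5)
        noise = rng.normal(0, 0.01, 16)
        cls = T.classify_direction_selectivity(g, g + noise)
        assert cls.label == "pattern"
        assert cls.index > 0

    def test_flat_plaid_response_unclassed(self):
        g = self._tuning_curve(5)
        cls = T.classify_direction_selectivity(g, np.ones(16))
        assert cls.label == "unclassed"
        assert "zero-variance" in cls.flags

    def test_scale_invariance(self, rng):
        g = self._tuning_curve(4)
        plaid_resp = np.roll(g, 3) + np.roll(g, -3) + rng.normal(0, 0.02, 16)
        a = T.classify_direction_selectivity(g, plaid_resp)
        b = T.classify_direction_selectivity(10.0 * g, 3.0 * plaid_resp)
        assert a.label == b.label
        assert a.index == pytest.approx(b.index, rel=1e-9)

    def test_incommensurate_separation_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            T.classify_direction_selectivity(np.ones(16), np.ones(16), separation=100.0)


class TestPreferredTuning:
    @staticmethod
    def _tensor(values, dirs, sps, tps):
        return T.ResponseTensor("mt", values, np.asarray(dirs),
                                np.asarray(sps), np.asarray(tps))

    def test_frequency_arithmetic(self):
        # peak at spatial period 8 px (sf 0.125 c/px), temporal period 4
        # frames (tf 0.25 c/frame) -> preferred speed 2 px/frame
        vals = np.zeros((1, 2, 2, 2))
        vals[0, 1, 0, 0] = 1.0
        s = T.preferred_tuning(self._tensor(vals, [0, 90], [8, 16], [4, 8]), 0)
        assert s.preferred_sf == pytest.approx(0.125)
        assert s.preferred_tf == pytest.approx(0.25)
        assert s.preferred_speed == pytest.approx(2.0)
        assert s.preferred_direction == 90.0

    def test_all_zero_undefined(self):
        s = T.preferred_tuning(self._tensor(np.zeros((1, 2, 2, 2)),
                                            [0, 90], [8, 16], [4, 8]), 0)
        assert not s.defined

    def test_uniform_tie_flagged(self):
        with pytest.warns(UserWarning, match="tied"):
            s = T.preferred_tuning(self._tensor(np.ones((1, 2, 2, 2)),
                                                [0, 90], [8, 16], [4, 8]), 0)
        assert s.tied


class TestGratingBattery:
    def test_ideal_gabor_kernel_recovers_construction_direction(self):
        """A V1 kernel built as a drifting sinusoid should prefer the
        direction and periods it was built from (within one grid step)."""
        arch = M.ArchConfig()
        params = M.init_model(arch, seed=0, hidden_init="zero")
        params.v1_kernels[:] = 0.0
        build_dir, build_sp, build_tp = 90.0, 12.0, 6.0
        g = P.grating(P.GratingSpec(build_dir, build_sp, build_tp,
                                    size=6, n_frames=6))
        params.v1_kernels[0] = g.frames
        v1_t, _ = T.grating_battery(
            params, n_directions=8, sf_periods=(8, 25, 4),
            tf_periods=(4, 25, 4), n_phases=8)
        s = T.preferred_tuning(v1_t, 0)
        step = 360.0 / 8
        diff = abs((s.preferred_direction - build_dir + 180) % 360 - 180)
        assert diff <= step

    def test_quadrature_shortcut_matches_explicit_phases(self, tiny_arch, rng):
        """The battery convolves only two quadrature stimuli per
        condition; the result must equal brute-force forwards of every
        phase-shifted grating."""
        params = M.init_model(tiny_arch, seed=2)
        params.v1_kernels = rng.standard_normal(params.v1_kernels.shape) * 0.5
        params.v1_offsets = rng.standard_normal(2) * 0.05
        n_phases = 8
        v1_t, mt_t = T.grating_battery(params, n_directions=4,
                                       sf_periods=(4, 8, 2),
                                       tf_periods=(2, 4, 2), n_phases=n_phases)
        h, w, t = tiny_arch.map_size
        centre = (h // 2) * w * t + (w // 2) * t
        for i_d, d in enumerate(v1_t.directions):
            for i_s, sp in enumerate(v1_t.spatial_periods):
                for i_t, tp in enumerate(v1_t.temporal_periods):
                    frames = np.stack([
                        P.grating(P.GratingSpec(d, sp, tp, phase=ph, size=8,
                                                n_frames=2)).frames
                        for ph in np.arange(n_phases) * 360.0 / n_phases
                    ])
                    v1_flat, mt, _ = M.forward_batch(params, frames)
                    v1 = v1_flat.reshape(n_phases, 2, -1)[:, :, centre].mean(axis=0)
                    np.testing.assert_allclose(
                        v1_t.values[:, i_d, i_s, i_t], v1, atol=1e-4)
                    np.testing.assert_allclose(
                        mt_t.values[:, i_d, i_s, i_t], mt.mean(axis=0), atol=1e-4)

    def test_battery_enumerates_conditions(self, tiny_arch):
        params = M.init_model(tiny_arch, seed=0)
        v1_t, mt_t = T.grating_battery(params, n_directions=4,
                                       sf_periods=(4, 8, 3),
                                       tf_periods=(2, 2, 1), n_phases=2)
        assert v1_t.values.shape == (2, 4, 3, 1)
        assert mt_t.values.shape == (4, 4, 3, 1)
        assert np.all(v1_t.values >= 0) and np.all(mt_t.values >= 0)


class TestSpectralGaussian:
    GRID = dict(spatial_periods=np.logspace(np.log10(8), np.log10(33), 6),
                temporal_periods=np.logspace(np.log10(4), np.log10(500), 6))

    def _map_from_params(self, p, A, x0, y0, theta, sx, sy, noise_sd=0.0, seed=0):
        x = np.log2(self.GRID["spatial_periods"])
        y = np.log2(self.GRID["temporal_periods"])
        X, Y = np.meshgrid(x, y, indexing="ij")
        vals = T.gaussian2d(X, Y, p, A, x0, y0, theta, sx, sy)
        if noise_sd:
            vals = vals + np.random.default_rng(seed).normal(0, noise_sd, vals.shape)
        return T.SpectralMap(0, vals, self.GRID["spatial_periods"],
                             self.GRID["temporal_periods"], 0.0)

    def test_parameter_recovery_at_one_percent_noise(self):
        truth = dict(p=0.1, A=2.0, x0=4.0, y0=5.5, theta=0.0, sx=0.8, sy=1.6)
        smap = self._map_from_params(**truth, noise_sd=0.02, seed=1)
        fit = T.fit_spectral_gaussian(smap, "cardinal")
        assert fit.converged
        assert fit.amplitude == pytest.approx(truth["A"], rel=0.10)
        assert fit.x0 == pytest.approx(truth["x0"], abs=0.1 * truth["x0"])
        assert fit.y0 == pytest.approx(truth["y0"], abs=0.1 * truth["y0"])
        assert fit.sigma_x == pytest.approx(truth["sx"], rel=0.10)
        assert fit.sigma_y == pytest.approx(truth["sy"], rel=0.10)

    def test_isotropic_axis_aligned_coefficients(self):
        a, b, c = T.gaussian_abc(0.0, 1.3, 1.3)
        assert b == 0.0
        assert a == pytest.approx(c)
        # positive definite
        assert a > 0 and c > 0

    def test_all_zero_map_degenerate(self):
        smap = T.SpectralMap(0, np.zeros((6, 6)), self.GRID["spatial_periods"],
                             self.GRID["temporal_periods"], 0.0)
        fit = T.fit_spectral_gaussian(smap, "free")
        assert fit.amplitude == 0.0
        assert not fit.converged


class TestSpeedClassification:
    GRID = TestSpectralGaussian.GRID

    def _map(self, theta):
        x = np.log2(self.GRID["spatial_periods"])
        y = np.log2(self.GRID["temporal_periods"])
        X, Y = np.meshgrid(x, y, indexing="ij")
        vals = T.gaussian2d(X, Y, 0.0, 1.0, float(x.mean()), float(y.mean()),
                            theta, 0.5, 2.0)
        return T.SpectralMap(0, vals, self.GRID["spatial_periods"],
                             self.GRID["temporal_periods"], 0.0)

    def test_diagonal_ridge_is_speed_tuned(self):
        cls = T.classify_speed_tuning(self._map(np.pi / 4))
        assert cls.label == "speed"
        assert cls.index > 0

    def test_cardinal_ridge_is_independent(self):
        cls = T.classify_speed_tuning(self._map(0.0))
        assert cls.label == "independent"
        assert cls.index < 0

    def test_separable_outer_product_is_independent(self):
        sf_curve = np.exp(-0.5 * ((np.arange(6) - 2.0) / 1.0) ** 2)
        tf_curve = np.exp(-0.5 * ((np.arange(6) - 3.0) / 1.5) ** 2)
        vals = np.outer(sf_curve, tf_curve)
        smap = T.SpectralMap(0, vals, self.GRID["spatial_periods"],
                             self.GRID["temporal_periods"], 0.0)
        cls = T.classify_speed_tuning(smap)
        assert cls.label == "independent"

    def test_noise_map_unclassed(self, rng):
        vals = 1.0 + rng.normal(0, 0.01, (6, 6))
        smap = T.SpectralMap(0, vals, self.GRID["spatial_periods"],
                             self.GRID["temporal_periods"], 0.0)
        cls = T.classify_speed_tuning(smap)
        assert cls.label == "unclassed"


class TestPatternSpeedCorrelation:
    @staticmethod
    def _cls(axis, index, label="speed"):
        return T.SelectivityClass(axis, 0, 0.5, 0.5, 0.1, 0.5, 0.5, 1.0, 1.0,
                                  label, index)

    def test_identical_indices_perfect_correlation(self):
        d = [self._cls("direction", v) for v in [0.1, 0.5, 0.9, -0.3]]
        s = [self._cls("spectral", v) for v in [0.1, 0.5, 0.9, -0.3]]
        r, p, n = T.pattern_speed_correlation(d, s)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_independent_indices_near_zero(self, rng):
        xs = rng.standard_normal(500)
        ys = rng.standard_normal(500)
        d = [self._cls("direction", v) for v in xs]
        s = [self._cls("spectral", v) for v in ys]
        r, p, n = T.pattern_speed_correlation(d, s)
        assert abs(r) < 0.15
        assert p > 0.01

    def test_doubly_unclassed_omitted(self):
        d = [self._cls("direction", 0.5), self._cls("direction", 1.0, "unclassed")]
        s = [self._cls("spectral", 0.5), self._cls("spectral", 2.0, "unclassed")]
        with pytest.raises(ValueError, match="fewer than 3"):
            T.pattern_speed_correlation(d, s)
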