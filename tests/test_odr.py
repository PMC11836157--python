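"""Orthogonal-distance fitting: footpoints, recovery, oracle equivalence."""

import warnings

import numpy as np
import pytest

from mvtforage import (
    GainCurve,
    fit_gain_odr,
    gain,
    orthogonal_distance,
    residual_stats,
)

CURVE = GainCurve(50.0, 0.1)


def dense_orthogonal_distance(A, k, T_obs, g_obs, T_hi=None, step=1e-4):
    """Independent oracle: dense sampling of the point-to-curve distance."""
    if T_hi is None:
        T_hi = T_obs + abs(A * (1 - np.exp(-k * T_obs)) - g_obs) + 1.0
    grid = np.arange(0.0, T_hi, step)
    d2 = (grid - T_obs) ** 2 + (A * (1 - np.exp(-k * grid)) - g_obs) ** 2
    i = int(np.argmin(d2))
    return grid[i], float(np.sqrt(d2[i]))


def grid_search_fit(T, g, stages=3, n_cells=80):
    """Independent oracle: exhaustive (A, k) grid search with zoom stages.

    The asymptote valley is razor thin once the data saturate (plateau
    points cost ~(A - plateau)^2 with no slope deflation), so the A grid is
    centred on the plateau level of the data and each stage zooms in around
    the incumbent best. Footpoints inside the oracle come from dense
    sampling plus Newton refinement of the stationarity condition —
    evaluating the true distance at candidate footpoints never undershoots
    the objective.
    """
    g_max = float(np.max(g))
    lo = np.log([max(0.7 * g_max, 1.0), 0.001])
    hi = np.log([min(2.5 * g_max, 200.0), 1.0])
    T_hi = T.max() + g.max() + 5.0
    grid_T = np.linspace(0.0, T_hi, 800)

    def per_point_min_d2(A, k):
        d2 = (grid_T[None, :] - T[:, None]) ** 2 + (
            A * (1 - np.exp(-k * grid_T))[None, :] - g[:, None]
        ) ** 2
        idx = d2.argmin(axis=1)
        t = grid_T[idx].astype(float)
        for _ in range(8):
            gv = A * (1 - np.exp(-k * t))
            gp = A * k * np.exp(-k * t)
            phi = (t - T) + (gv - g) * gp
            dphi = 1.0 + gp**2 + (gv - g) * (-k * gp)
            step = np.where(np.abs(dphi) > 1e-12, phi / dphi, 0.0)
            t = np.maximum(t - np.clip(step, -1.0, 1.0), 0.0)
        d2_ref = (t - T) ** 2 + (A * (1 - np.exp(-k * t)) - g) ** 2
        return np.minimum(d2_ref, d2[np.arange(d2.shape[0]), idx])

    best = None
    for _ in range(stages):
        As = np.exp(np.linspace(lo[0], hi[0], n_cells))
        ks = np.exp(np.linspace(lo[1], hi[1], n_cells))
        for A in As:
            for k in ks:
                obj = float(per_point_min_d2(A, k).sum())
                if best is None or obj < best[2]:
                    best = (A, k, obj)
        dA = 2.0 * (hi[0] - lo[0]) / (n_cells - 1)
        dk = 2.0 * (hi[1] - lo[1]) / (n_cells - 1)
        lo = np.array([np.log(best[0]) - dA, np.log(best[1]) - dk])
        hi = np.array([np.log(best[0]) + dA, np.log(best[1]) + dk])
    return best


class TestOrthogonalDistance:
    def test_point_on_curve(self):
        T0 = 12.0
        T_star, length, signed = orthogonal_distance(CURVE, (T0, gain(CURVE, T0)))
        assert length == pytest.approx(0.0, abs=1e-9)
        assert T_star == pytest.approx(T0, abs=1e-6)
        assert signed == pytest.approx(0.0, abs=1e-9)

    def test_matches_dense_grid_oracle(self):
        T_star, length, signed = orthogonal_distance(CURVE, (10.0, 40.0))
        oracle_T, oracle_len = dense_orthogonal_distance(50.0, 0.1, 10.0, 40.0)
        vertical = 40.0 - gain(CURVE, 10.0)          # 8.394
        assert length == pytest.approx(oracle_len, abs=1e-6)
        assert T_star == pytest.approx(oracle_T, abs=1e-3)
        assert length <= vertical
        assert signed > 0                            # point above the curve

    def test_small_perturbation_bound(self):
        eps = 0.01
        _, length, _ = orthogonal_distance(CURVE, (15.0, gain(CURVE, 15.0) + eps))
        assert length <= eps + 1e-12

    @pytest.mark.parametrize("point", [(3.0, 2.0), (25.0, 55.0), (0.5, 30.0)])
    def test_oracle_agreement_various_points(self, point):
        _, length, _ = orthogonal_distance(CURVE, point)
        _, oracle_len = dense_orthogonal_distance(50.0, 0.1, *point)
        assert length == pytest.approx(oracle_len, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_distance(CURVE, (-1.0, 5.0))


class TestFitGainOdr:
    def test_noise_free_recovery(self):
        T = np.linspace(2.0, 40.0, 15)
        pts = np.c_[T, gain(CURVE, T)]
        for standardize in (True, False):
            fit = fit_gain_odr(pts, standardize=standardize)
            assert fit.A_hat == pytest.approx(50.0, rel=1e-6)
            assert fit.k_hat == pytest.approx(0.1, rel=1e-6)
            assert fit.objective == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle_on_small_instance(self):
        rng = np.random.default_rng(8)
        T = np.array([3.0, 7.0, 12.0, 20.0, 30.0])
        g = gain(GainCurve(60.0, 0.09), T) + rng.normal(0, 0.8, 5)
        fit = fit_gain_odr(np.c_[T, g], standardize=False)
        A_g, k_g, obj_g = grid_search_fit(T, g)
        assert fit.objective <= obj_g * (1 + 1e-3) + 1e-9
        assert fit.objective == pytest.approx(obj_g, rel=0.02)
        assert fit.A_hat == pytest.approx(A_g, rel=0.1)
        assert fit.k_hat == pytest.approx(k_g, rel=0.1)

    def test_beats_vertical_least_squares_on_its_own_criterion(self):
        rng = np.random.default_rng(9)
        T = np.linspace(2, 35, 20)
        g = gain(CURVE, T) + rng.normal(0, 1.0, 20)
        fit = fit_gain_odr(np.c_[T, g], standardize=False)
        from mvtforage.odr import _footpoints, _gain, _ols_start

        A_ols, k_ols = _ols_start(T, g, 1.1 * g.max(), 0.1)
        fp = _footpoints(A_ols, k_ols, T, g, n_grid=256, n_golden=60)
        obj_ols = float(
            np.sum((fp - T) ** 2 + (_gain(A_ols, k_ols, fp) - g) ** 2)
        )
        assert fit.objective <= obj_ols + 1e-9

    def test_agrees_with_odrpack_on_benign_instance(self):
        rng = np.random.default_rng(10)
        T = np.linspace(2, 35, 25)
        g = gain(CURVE, T) + rng.normal(0, 0.5, 25)
        fit = fit_gain_odr(np.c_[T, g], standardize=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DeprecationWarning)
            import scipy.odr as sodr
        model = sodr.Model(lambda B, x: B[0] * (-np.expm1(-B[1] * x)))
        out = sodr.ODR(
            sodr.Data(T, g), model, beta0=[fit.A_hat * 1.2, fit.k_hat * 0.8],
            maxit=500,
        ).run()
        assert fit.A_hat == pytest.approx(out.beta[0], rel=1e-3)
        assert fit.k_hat == pytest.approx(out.beta[1], rel=1e-3)
        assert fit.objective == pytest.approx(out.sum_square, rel=1e-4)

    def test_gain_axis_scaling_changes_raw_unit_fit(self):
        # orthogonal distances mix units: c * gain is not a c-scaled fit
        rng = np.random.default_rng(11)
        T = np.linspace(2, 35, 20)
        g = gain(CURVE, T) + rng.normal(0, 1.0, 20)
        fit1 = fit_gain_odr(np.c_[T, g], standardize=False)
        fit100 = fit_gain_odr(np.c_[T, 100.0 * g], standardize=False)
        assert fit100.k_hat != pytest.approx(fit1.k_hat, rel=1e-3)

    def test_gain_axis_scaling_equivariant_when_standardized(self):
        rng = np.random.default_rng(12)
        T = np.linspace(2, 35, 20)
        g = gain(CURVE, T) + rng.normal(0, 1.0, 20)
        fit1 = fit_gain_odr(np.c_[T, g], standardize=True)
        fit100 = fit_gain_odr(np.c_[T, 100.0 * g], standardize=True)
        assert fit100.A_hat == pytest.approx(100.0 * fit1.A_hat, rel=1e-5)
        assert fit100.k_hat == pytest.approx(fit1.k_hat, rel=1e-5)

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            fit_gain_odr(np.array([[1.0, 2.0], [3.0, 4.0]]))      # 2 points
        with pytest.raises(ValueError):
            fit_gain_odr(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        with pytest.raises(ValueError):
            fit_gain_odr(np.array([[1.0, 2.0], [3.0, np.nan], [4.0, 5.0]]))


class TestResidualStats:
    def test_all_zero(self):
        assert residual_stats([0.0, 0.0, 0.0]) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        s2, se = residual_stats([3.0, 4.0], n_params=0)
        assert s2 == pytest.approx(12.5)
        assert se == pytest.approx(np.sqrt(12.5))

    def test_se_squared_is_s2(self):
        rng = np.random.default_rng(13)
        r = rng.random(20)
        s2, se = residual_stats(r)
        assert se**2 == pytest.approx(s2, rel=1e-12)

    def test_insufficient_residuals(self):
        with pytest.raises(ValueError):
            residual_stats([1.0, 2.0], n_params=2)
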