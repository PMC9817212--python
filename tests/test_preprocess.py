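import math

import numpy as np
import pytest

from motorcpd import preprocess as pre


def make_track(x, y, missing=None, dt=0.05):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if missing is None:
        missing = np.zeros(x.size, dtype=bool)
    times = np.arange(x.size) * dt
    return pre.RawTrack2D(times=times, x=x, y=y, missing=missing, dt=dt)


def tls_slope_svd(x, y):
    """Total-least-squares slope via SVD (independent oracle)."""
    pts = np.column_stack([x - x.mean(), y - y.mean()])
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    direction = vt[0]
    return direction[1] / direction[0]


class TestFitMicrotubule:
    def test_exact_line(self):
        x = np.linspace(0, 5, 20)
        fit = pre.fit_microtubule(make_track(x, 2 * x + 1))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-10)

    def test_matches_svd_oracle_on_noisy_cloud(self):
        """Isotropic noise about a 45-degree line: orthogonal regression is
        unbiased and equals the SVD total-least-squares fit."""
        rng = np.random.default_rng(0)
        t = np.linspace(0, 4, 200)
        x = t + rng.normal(0, 0.05, t.size)
        y = t + rng.normal(0, 0.05, t.size)
        fit = pre.fit_microtubule(make_track(x, y))
        assert fit.slope == pytest.approx(tls_slope_svd(x, y), abs=1e-10)
        assert fit.slope == pytest.approx(1.0, abs=0.05)

    def test_swap_symmetry(self):
        """Swapping x and y inverts the orthogonal-regression slope."""
        rng = np.random.default_rng(1)
        t = np.linspace(0, 3, 80)
        x = t + rng.normal(0, 0.03, t.size)
        y = 0.4 * t + rng.normal(0, 0.03, t.size)
        a = pre.fit_microtubule(make_track(x, y)).slope
        b = pre.fit_microtubule(make_track(y, x)).slope
        assert a == pytest.approx(1.0 / b, rel=1e-9)

    def test_vertical_line(self):
        y = np.linspace(0, 5, 30)
        x = np.full_like(y, 2.0)
        fit = pre.fit_microtubule(make_track(x, y))
        assert fit.vertical
        assert fit.x_mean == pytest.approx(2.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            pre.fit_microtubule(make_track(np.ones(5), np.ones(5)))


class TestProjection:
    def test_track_along_x_axis_is_identity(self):
        x = np.array([0.0, 0.1, 0.25, 0.4, 0.7])
        track = make_track(x, np.zeros_like(x))
        lt = pre.project_to_longitudinal(track)
        assert np.allclose(lt.x_par, x - x[0], atol=1e-12)

    def test_inclined_line_preserves_arc_length(self):
        L = 3.0
        t = np.linspace(0, L, 40)
        x = t * math.cos(math.radians(30))
        y = t * math.sin(math.radians(30))
        lt = pre.project_to_longitudinal(make_track(x, y))
        assert abs(lt.x_par[-1]) == pytest.approx(L, rel=1e-10)
        assert lt.x_par[0] == 0.0

    @pytest.mark.parametrize("theta", [0.3, 1.2, 2.5, -0.8])
    def test_rotation_invariance_up_to_sign(self, theta):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 2, 60)
        x = t + rng.normal(0, 0.02, t.size)
        y = 0.5 * t + rng.normal(0, 0.02, t.size)
        base = pre.project_to_longitudinal(make_track(x, y)).x_par
        c, s = math.cos(theta), math.sin(theta)
        xr = c * x - s * y
        yr = s * x + c * y
        rot = pre.project_to_longitudinal(make_track(xr, yr)).x_par
        assert np.allclose(rot, base, atol=1e-8) or np.allclose(
            rot, -base, atol=1e-8
        )


class TestImputation:
    def test_no_missing_is_identity(self):
        x = np.linspace(0, 1, 11)
        lt = pre.LongitudinalTrack(
            times=np.arange(11) * 0.05,
            x_par=x,
            missing=np.zeros(11, bool),
            imputed=np.zeros(11, bool),
            dt=0.05,
        )
        out = pre.impute_missing(lt, rng=0)
        assert np.array_equal(out.x_par, x)
        assert not out.imputed.any()

    def test_single_gap_midpoint_no_noise(self):
        x = np.array([0.0, np.nan, 2.0])
        missing = np.isnan(x)
        lt = pre.LongitudinalTrack(
            times=np.arange(3) * 0.05, x_par=x, missing=missing,
            imputed=np.zeros(3, bool), dt=0.05,
        )
        out = pre.impute_missing(lt, rng=0, noise_scale=0.0)
        assert out.x_par[1] == pytest.approx(1.0)
        assert out.imputed[1]

    def test_gap_of_three_fills_quarter_fractions(self):
        """A length-3 gap interpolates at fractions 1/4, 1/2, 3/4 of the
        endpoint difference."""
        x = np.array([1.0, np.nan, np.nan, np.nan, 5.0])
        lt = pre.LongitudinalTrack(
            times=np.arange(5) * 0.05, x_par=x, missing=np.isnan(x),
            imputed=np.zeros(5, bool), dt=0.05,
        )
        out = pre.impute_missing(lt, rng=0, noise_scale=0.0)
        assert np.allclose(out.x_par, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_imputation_noise_is_unbiased(self):
        x = np.array([0.0, np.nan, 2.0] + [2.0] * 30)
        vals = []
        for seed in range(300):
            lt = pre.LongitudinalTrack(
                times=np.arange(x.size) * 0.05, x_par=x.copy(),
                missing=np.isnan(x), imputed=np.zeros(x.size, bool), dt=0.05,
            )
            vals.append(pre.impute_missing(lt, rng=seed, noise_scale=0.3).x_par[1])
        assert np.mean(vals) == pytest.approx(1.0, abs=0.06)

    def test_long_gap_truncates(self):
        x = np.concatenate([np.arange(10.0), np.full(25, np.nan), np.arange(10.0)])
        lt = pre.LongitudinalTrack(
            times=np.arange(x.size) * 0.05, x_par=x, missing=np.isnan(x),
            imputed=np.zeros(x.size, bool), dt=0.05,
        )
        out = pre.impute_missing(lt, max_gap=20, rng=0)
        assert out.x_par.size == 10
        assert not np.isnan(out.x_par).any()

    def test_edge_gaps_truncated_not_extrapolated(self):
        x = np.concatenate([[np.nan, np.nan], np.arange(8.0), [np.nan]])
        lt = pre.LongitudinalTrack(
            times=np.arange(x.size) * 0.05, x_par=x, missing=np.isnan(x),
            imputed=np.zeros(x.size, bool), dt=0.05,
        )
        out = pre.impute_missing(lt, rng=0)
        assert out.x_par.size == 8
        assert not out.imputed.any()


class TestIncrements:
    def test_constant_track(self):
        xi = pre.to_increments(np.full(20, 1.5), dt=0.05)
        assert np.allclose(xi.values, 0.0)

    def test_linear_track_slope(self):
        v, dt = 0.6, 0.05
        xi = pre.to_increments(np.arange(50) * v * dt, dt=dt)
        assert np.allclose(xi.values, v * dt)

    def test_telescoping_sum(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(0, 0.1, 40))
        xi = pre.to_increments(x, dt=0.05)
        assert xi.values.sum() == pytest.approx(x[-1] - x[0], rel=1e-12)

    def test_simulated_mean_increment(self, constant_path):
        """A 0.6 um/s path sampled at 20 fps has mean increment ~ 0.03 um."""
        xi = pre.to_increments(constant_path.obs_positions, dt=0.05)
        se = xi.values.std(ddof=1) / np.sqrt(xi.n)
        assert abs(xi.values.mean() - 0.03) < 4 * se


class TestRoundTrip:
    def test_read_track_csv_marks_missing(self, tmp_path):
        import pandas as pd

        frames = [0, 1, 2, 4, 5, 7]
        df = pd.DataFrame(
            {
                "frame": frames,
                "t": [f * 0.05 for f in frames],
                "x": np.linspace(0, 1, 6),
                "y": np.linspace(0, 2, 6),
            }
        )
        f = tmp_path / "track.csv"
        df.to_csv(f, index=False)
        track = pre.read_track_csv(f)
        assert track.x.size == 8
        assert list(np.flatnonzero(track.missing)) == [3, 6]
        assert track.dt == pytest.approx(0.05)
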