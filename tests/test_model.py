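import numpy as np
import pytest
from scipy import integrate, stats

from motorcpd.model import (
    IncrementSeries,
    MarginalLikelihood,
    SegmentModel,
    eta_umvu,
    log_likelihood,
    log_ndtr_diff,
    marginal_log_likelihood,
)

DT = 0.05


def series(values):
    return IncrementSeries(values=np.asarray(values, dtype=float), dt=DT)


class TestLogLikelihood:
    def test_zero_residual_closed_form(self):
        """Constant-drift data at the true velocity leaves only the
        normalization: log L = (N/2) log(eta / (2 pi dt))."""
        n, v, eta = 20, 0.4, 150.0
        xi = series(np.full(n, v * DT))
        m = SegmentModel((), (v,), eta)
        expected = 0.5 * n * np.log(eta / (2 * np.pi * DT))
        assert log_likelihood(xi, m) == pytest.approx(expected, rel=1e-12)

    def test_matches_per_point_normal_sum(self):
        rng = np.random.default_rng(0)
        xi = series(rng.normal(0.02, 0.03, 37))
        m = SegmentModel((10 * DT, 25 * DT), (0.1, -0.3, 0.6), 80.0)
        # independent oracle: direct per-point Normal log-pdf summation
        bounds = [0, 10, 25, 37]
        total = 0.0
        for j, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            total += stats.norm.logpdf(
                xi.values[a:b], loc=m.velocities[j] * DT, scale=np.sqrt(DT / 80.0)
            ).sum()
        assert log_likelihood(xi, m) == pytest.approx(total, rel=1e-10)

    def test_split_without_velocity_change_is_invariant(self):
        rng = np.random.default_rng(1)
        xi = series(rng.normal(0.0, 0.02, 40))
        one = SegmentModel((), (0.2,), 100.0)
        split = SegmentModel((17 * DT,), (0.2, 0.2), 100.0)
        assert log_likelihood(xi, one) == pytest.approx(
            log_likelihood(xi, split), rel=1e-12
        )

    def test_nonpositive_eta(self):
        xi = series(np.zeros(5) + 0.01)
        assert log_likelihood(xi, SegmentModel((), (0.0,), -1.0)) == -np.inf


class TestMarginalLikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_segment_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        xi = series(rng.normal(0.01, 0.02, 8))
        eta, vmax = 90.0, 2.0
        got = marginal_log_likelihood(xi, [0, 8], eta, vmax)
        val, _ = integrate.quad(
            lambda v: np.exp(log_likelihood(xi, SegmentModel((), (v,), eta)))
            / (2 * vmax),
            -vmax,
            vmax,
            epsabs=1e-14,
        )
        assert got == pytest.approx(np.log(val), rel=1e-6)

    def test_two_segment_quadrature(self):
        """The velocity-marginalized likelihood equals brute-force 2-D
        quadrature of likelihood x uniform priors."""
        rng = np.random.default_rng(3)
        xi = series(rng.normal(0.02, 0.02, 6))
        eta, vmax = 120.0, 2.0
        got = marginal_log_likelihood(xi, [0, 3, 6], eta, vmax)
        val, _ = integrate.dblquad(
            lambda v2, v1: np.exp(
                log_likelihood(xi, SegmentModel((3 * DT,), (v1, v2), eta))
            )
            / (2 * vmax) ** 2,
            -vmax,
            vmax,
            -vmax,
            vmax,
            epsabs=1e-13,
            epsrel=1e-10,
        )
        assert got == pytest.approx(np.log(val), rel=1e-6)

    def test_three_segment_quadrature(self):
        rng = np.random.default_rng(4)
        xi = series(rng.normal(0.0, 0.03, 9))
        eta, vmax = 60.0, 1.5
        got = marginal_log_likelihood(xi, [0, 3, 6, 9], eta, vmax)
        val, _ = integrate.tplquad(
            lambda v3, v2, v1: np.exp(
                log_likelihood(
                    xi, SegmentModel((3 * DT, 6 * DT), (v1, v2, v3), eta)
                )
            )
            / (2 * vmax) ** 3,
            -vmax,
            vmax,
            -vmax,
            vmax,
            -vmax,
            vmax,
            epsabs=1e-12,
            epsrel=1e-8,
        )
        assert got == pytest.approx(np.log(val), rel=1e-6)

    def test_wide_prior_limit_is_profile_marginal(self):
        """As v_max grows, 2 v_max x marginal converges to the unbounded
        Normal integral closed form."""
        rng = np.random.default_rng(5)
        xi = series(rng.normal(0.02, 0.02, 30))
        eta = 100.0
        n, mean = 30, float(xi.values.mean())
        ssd = float(np.sum((xi.values - mean) ** 2))
        # int L dv = (eta/2 pi dt)^{n/2} e^{-eta ssd/2dt} sqrt(2 pi dt/(eta n)) / dt
        closed = (
            0.5 * n * np.log(eta / (2 * np.pi * DT))
            - eta * ssd / (2 * DT)
            + 0.5 * np.log(2 * np.pi / (eta * n * DT))
        )
        got = marginal_log_likelihood(xi, [0, 30], eta, v_max=50.0)
        assert got + np.log(2 * 50.0) == pytest.approx(closed, rel=1e-9)

    def test_mean_outside_prior_support_vanishes(self):
        """A segment drifting far faster than v_max makes the marginal term
        collapse, monotonically in the excess."""
        eta = 200.0
        vals = [
            marginal_log_likelihood(series(np.full(20, v * DT)), [0, 20], eta, 1.0)
            for v in (1.5, 3.0, 5.0, 8.0)
        ]
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))

    def test_occam_penalty_on_constant_drift(self):
        """On exactly constant-drift data the marginal decreases with every
        added change (the uniform-prior volume penalty)."""
        xi = series(np.full(60, 0.03))
        eta = 150.0
        partitions = [[0, 60], [0, 30, 60], [0, 20, 40, 60], [0, 15, 30, 45, 60]]
        vals = [marginal_log_likelihood(xi, b, eta, 2.0) for b in partitions]
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))

    def test_numba_kernel_agrees_with_reference(self):
        """The jitted sampler-side marginal equals the numpy reference on
        random instances."""
        from motorcpd._stage1_kernel import _marg_loglik

        rng = np.random.default_rng(6)
        xi = series(rng.normal(0.01, 0.02, 50))
        cs = np.concatenate([[0.0], np.cumsum(xi.values)])
        cs2 = np.concatenate([[0.0], np.cumsum(xi.values**2)])
        ml = MarginalLikelihood(xi, 2.0)
        for _ in range(20):
            k = int(rng.integers(0, 4))
            ch = np.sort(rng.choice(np.arange(5, 46), size=k, replace=False))
            bounds = np.concatenate([[0], ch, [50]]).astype(int)
            eta = float(rng.uniform(20, 400))
            ref = ml(bounds, eta)
            got = _marg_loglik(
                ch.astype(np.int64), k, cs, cs2, 50, DT, 2.0, eta
            )
            assert got == pytest.approx(ref, rel=1e-9, abs=1e-9)


class TestLogNdtrDiff:
    def test_matches_direct_difference_in_easy_range(self):
        a = np.array([-1.0, -0.5, 0.2])
        b = np.array([0.5, 1.3, 2.0])
        direct = np.log(stats.norm.cdf(b) - stats.norm.cdf(a))
        assert np.allclose(log_ndtr_diff(b, a), direct, rtol=1e-12)

    def test_far_right_tail_no_cancellation(self):
        got = float(log_ndtr_diff(21.0, 20.0))
        # log(Phi(21)-Phi(20)) = log(Phi(-20)-Phi(-21)) ~ logPhi(-20)
        expected = stats.norm.logcdf(-20.0)
        assert got == pytest.approx(expected, abs=0.1)
        assert np.isfinite(got)


class TestEtaUmvu:
    def test_unit_variance_scaling(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, 400)
        vals = (vals - vals.mean()) / vals.std(ddof=1)  # exact unit variance
        xi = IncrementSeries(values=vals * np.sqrt(DT), dt=DT)
        assert eta_umvu(xi) == pytest.approx(1.0, rel=1e-10)

    def test_linear_in_dt(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 0.1, 100)
        a = eta_umvu(IncrementSeries(values=vals, dt=DT))
        b = eta_umvu(IncrementSeries(values=vals, dt=2 * DT))
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_consistency(self):
        """eta_hat -> eta as N grows for xi ~ N(0, dt/eta)."""
        eta_true = 250.0
        rng = np.random.default_rng(9)
        xi = IncrementSeries(
            values=rng.normal(0, np.sqrt(DT / eta_true), 20_000), dt=DT
        )
        assert eta_umvu(xi) == pytest.approx(eta_true, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            eta_umvu(IncrementSeries(values=np.full(10, 0.01), dt=DT))
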