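"""Piecewise-drift statistical model for increment series.

The observed longitudinal cargo position is modeled as Brownian motion with
piecewise-constant drift: over a uniform frame grid with spacing ``dt``, the
increments ``xi_n = X_{n+1} - X_n`` are independent Normal(v_j dt, dt / eta),
where v_j is the velocity of the segment containing increment n and eta is a
common precision nuisance parameter (1/eta lumps motor-stepping noise, cargo
diffusion about the motor, and localization error).

Two likelihoods are provided: the full likelihood at fixed segment velocities,
and the velocity-marginalized likelihood under independent Uniform(-v_max,
v_max) priors, in which each segment contributes a Gaussian-CDF difference.
The marginal form is what the stage-1 sampler targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

__all__ = [
    "IncrementSeries",
    "SegmentModel",
    "segment_stats",
    "log_likelihood",
    "marginal_log_likelihood",
    "MarginalLikelihood",
    "eta_umvu",
    "log_ndtr_diff",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class IncrementSeries:
    """A uniform-grid increment series; the object all inference consumes."""

    values: np.ndarray  # xi_1..xi_N, um
    dt: float  # frame interval Delta, s

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("need a 1-D series with N >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("increments must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n * self.dt


@dataclass(frozen=True)
class SegmentModel:
    """(k, tau, v, eta): a full parameterization of the piecewise model.

    Segment j (1-based) covers increments M_{j-1}+1 .. M_j, half-open on the
    left, with M_j = floor(tau_j / dt), M_0 = 0 and M_{k+1} = N.
    """

    change_times: tuple[float, ...]
    velocities: tuple[float, ...]
    eta: float

    def __post_init__(self) -> None:
        if len(self.velocities) != len(self.change_times) + 1:
            raise ValueError("need k+1 velocities for k change times")
        tau = np.asarray(self.change_times)
        if tau.size and np.any(np.diff(tau) <= 0):
            raise ValueError("change_times must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.change_times)

    def change_indices(self, dt: float) -> np.ndarray:
        return np.floor(np.asarray(self.change_times) / dt).astype(int)


def _boundaries(xi: IncrementSeries, m: SegmentModel) -> np.ndarray:
    """[0, M_1, ..., M_k, N] with validity checks."""
    mj = m.change_indices(xi.dt)
    bounds = np.concatenate([[0], mj, [xi.n]])
    if np.any(np.diff(bounds) < 1):
        raise ValueError("change indices must partition 1..N with nonempty segments")
    return bounds


def segment_stats(values: np.ndarray, bounds: np.ndarray):
    """Per-segment (count, mean, sum of squared deviations) via cumsums."""
    cs = np.concatenate([[0.0], np.cumsum(values)])
    cs2 = np.concatenate([[0.0], np.cumsum(values**2)])
    n = np.diff(bounds).astype(float)
    s1 = cs[bounds[1:]] - cs[bounds[:-1]]
    s2 = cs2[bounds[1:]] - cs2[bounds[:-1]]
    mean = s1 / n
    ssd = np.maximum(s2 - n * mean**2, 0.0)
    return n, mean, ssd


def log_likelihood(xi: IncrementSeries, m: SegmentModel) -> float:
    """Log of the piecewise-drift likelihood at fixed (tau, v, eta)."""
    if m.eta <= 0:
        return -np.inf
    bounds = _boundaries(xi, m)
    n, mean, ssd = segment_stats(xi.values, bounds)
    v = np.asarray(m.velocities, dtype=float)
    dt = xi.dt
    # sum (xi_i - v dt)^2 = ssd + n (mean - v dt)^2 per segment
    rss = float(np.sum(ssd + n * (mean - v * dt) ** 2))
    return 0.5 * xi.n * (np.log(m.eta) - np.log(dt) - _LOG_2PI) - (
        m.eta / (2.0 * dt)
    ) * rss


def log_ndtr_diff(b, a):
    """log(Phi(b) - Phi(a)) for b >= a, stable in both tails.

    When both arguments are positive the difference is computed on the
    reflected pair (-a, -b) so the complementary CDF carries the precision.
    """
    b = np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    flip = (a + b) > 0
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    lhi = log_ndtr(hi)
    llo = log_ndtr(lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = lhi + np.log1p(-np.exp(llo - lhi))
    out = np.where(llo >= lhi, -np.inf, out)
    return out


def marginal_log_likelihood(
    xi: IncrementSeries,
    bounds: np.ndarray,
    eta: float,
    v_max: float,
) -> float:
    """Log marginal likelihood with the segment velocities integrated out
    against independent Uniform(-v_max, v_max) priors.

    ``bounds`` is the ordered index set [0, M_1, ..., M_k, N].  Each of the
    k+1 segments contributes

        -log(2 v_max) + (n_j/2) log(eta/(2 pi dt)) - eta S_j / (2 dt)
        + (1/2) log(2 pi / (eta n_j dt))
        + log[ Phi(c_j (v_max - m_j/dt)) - Phi(c_j (-v_max - m_j/dt)) ]

    with m_j the segment increment mean, S_j its sum of squared deviations
    and c_j = sqrt(eta n_j dt).
    """
    if v_max <= 0:
        return -np.inf
    return MarginalLikelihood(xi, v_max)(bounds, eta)


class MarginalLikelihood:
    """Repeated-evaluation form of :func:`marginal_log_likelihood`.

    Precomputes the increment cumulative sums once so that each evaluation at
    a segmentation ``bounds`` and precision ``eta`` costs O(k) instead of
    O(N).  Used inside the stage-1 sampler loop.
    """

    def __init__(self, xi: IncrementSeries, v_max: float):
        self.xi = xi
        self.v_max = float(v_max)
        self.dt = xi.dt
        self._cs = np.concatenate([[0.0], np.cumsum(xi.values)])
        self._cs2 = np.concatenate([[0.0], np.cumsum(xi.values**2)])

    def __call__(self, bounds: np.ndarray, eta: float) -> float:
        if eta <= 0:
            return -np.inf
        bounds = np.asarray(bounds, dtype=int)
        n = np.diff(bounds).astype(float)
        if np.any(n < 1):
            return -np.inf
        s1 = self._cs[bounds[1:]] - self._cs[bounds[:-1]]
        s2 = self._cs2[bounds[1:]] - self._cs2[bounds[:-1]]
        mean = s1 / n
        ssd = np.maximum(s2 - n * mean**2, 0.0)
        dt = self.dt
        c = np.sqrt(eta * n * dt)
        vhat = mean / dt
        phi_term = log_ndtr_diff(c * (self.v_max - vhat), c * (-self.v_max - vhat))
        terms = (
            -np.log(2.0 * self.v_max)
            + 0.5 * n * (np.log(eta) - np.log(dt) - _LOG_2PI)
            - eta * ssd / (2.0 * dt)
            + 0.5 * (_LOG_2PI - np.log(eta * n * dt))
            + phi_term
        )
        return float(np.sum(terms))


def eta_umvu(xi: IncrementSeries) -> float:
    """Empirical precision estimate assuming no change points:
    eta_hat = dt / Var(xi) with the unbiased sample variance."""
    var = float(np.var(xi.values, ddof=1))
    if var < 1e-30:  # constant series up to rounding
        raise ValueError("degenerate path: increment variance is zero")
    return xi.dt / var
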