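"""Stage 2: inference of (tau, v, eta) for a fixed number of change points.

Given k (usually the stage-1 MAP), a component-wise sampler draws from the
joint posterior of the change times, segment velocities and common precision:

* each v_j by a Normal random walk (rejected outside [-v_max, v_max]),
* eta by a Gibbs draw from its conjugate Gamma full conditional,
* each tau_j by a uniform random walk on continuous time, mapped to indices
  by M_j = floor(tau_j / dt) for likelihood evaluation, rejected if a segment
  would drop below the minimum duration d.

Convergence is assessed with split R-hat and the effective sample size; the
run passes if every parameter has R-hat < 1.1 and ESS > 5 x (number of
chains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import IncrementSeries, eta_umvu

__all__ = [
    "Stage2Hyper",
    "Stage2Chain",
    "Stage2Result",
    "run_stage2",
    "check_convergence",
    "map_point_estimates",
]


@dataclass(frozen=True)
class Stage2Hyper:
    d: int = 5
    v_max: float = 2.0
    eta_shape_factor: float = 0.1  # prior shape = factor * eta_hat_map1
    eta_rate: float = 0.1
    eps_v: float = 0.5  # velocity walk sd, um/s

    def eps_tau(self, k: int, n: int, dt: float) -> float:
        """Change-time walk half-width: ceil((1+k)^-2 N) * dt."""
        return math.ceil(n / (1 + k) ** 2) * dt


@dataclass
class Stage2Chain:
    tau: np.ndarray  # (n_keep, k)
    v: np.ndarray  # (n_keep, k+1)
    eta: np.ndarray  # (n_keep,)
    log_post: np.ndarray
    seed: int | None = None


@dataclass
class Stage2Result:
    chains: list[Stage2Chain]
    k: int
    hyper: Stage2Hyper
    xi: IncrementSeries
    eta_map1: float

    def merged(self, name: str) -> np.ndarray:
        return np.concatenate([getattr(c, name) for c in self.chains])


def _seg_sums(cs, cs2, bounds):
    n = np.diff(bounds).astype(float)
    s1 = cs[bounds[1:]] - cs[bounds[:-1]]
    s2 = cs2[bounds[1:]] - cs2[bounds[:-1]]
    return n, s1, s2


def _sum_sq(n, s1, s2, v, dt):
    """sum over segments of sum_i (xi_i - v_j dt)^2."""
    return float(np.sum(s2 - 2.0 * v * dt * s1 + n * (v * dt) ** 2))


def _tau_feasible(m: np.ndarray, n: int, d: int) -> bool:
    bounds = np.concatenate([[0], m, [n]])
    return bool(np.all(np.diff(bounds) >= d))


def run_stage2(
    xi: IncrementSeries,
    k: int,
    hyper: Stage2Hyper | None = None,
    n_iter: int = 40_000,
    n_chains: int = 4,
    rng: np.random.Generator | int | None = None,
    burn_frac: float = 0.5,
    thin: int = 50,
    eta_map1: float | None = None,
    init_changes: tuple[int, ...] | None = None,
    prior_only: bool = False,
) -> Stage2Result:
    """Sample the conditional posterior given ``k`` change points.

    ``eta_map1`` is the stage-1 MAP precision used to center the eta prior;
    it falls back to the no-change empirical estimate.  ``init_changes``
    (e.g. the stage-1 MAP switch points) seeds tau; each chain jitters its
    start for overdispersed initialization.
    """
    hyper = hyper or Stage2Hyper()
    rng = np.random.default_rng(rng)
    n, dt = xi.n, xi.dt
    if k >= n / hyper.d:
        raise ValueError("k too large for the minimum segment duration")
    if eta_map1 is None:
        eta_map1 = eta_umvu(xi)
    chains = []
    for _ in range(n_chains):
        seed = int(rng.integers(2**31 - 1))
        chains.append(
            _run_one(
                xi, k, hyper, n_iter, np.random.default_rng(seed),
                burn_frac, thin, eta_map1, init_changes, prior_only, seed,
            )
        )
    return Stage2Result(chains=chains, k=k, hyper=hyper, xi=xi, eta_map1=eta_map1)


def _init_tau(k, n, dt, d, init_changes, rng):
    if k == 0:
        return np.empty(0)
    if init_changes is not None and len(init_changes) == k:
        m = np.asarray(init_changes, dtype=float)
    else:
        m = np.round(np.arange(1, k + 1) * n / (k + 1.0))
    # jitter within the feasible corridor for overdispersed starts
    for _ in range(20):
        jit = m + rng.integers(-d, d + 1, size=k)
        if _tau_feasible(np.floor(jit).astype(int), n, d) and np.all(jit >= d):
            m = jit
            break
    return (m + rng.uniform(0.0, 1.0, size=k)) * dt


_LOG_2PI = float(np.log(2.0 * np.pi))


def _run_one(
    xi, k, hyper, n_iter, rng, burn_frac, thin,
    eta_map1, init_changes, prior_only, seed,
):
    n, dt = xi.n, xi.dt
    d = hyper.d
    cs = np.concatenate([[0.0], np.cumsum(xi.values)])
    cs2 = np.concatenate([[0.0], np.cumsum(xi.values**2)])
    eta_shape = hyper.eta_shape_factor * eta_map1
    eps_tau = hyper.eps_tau(k, n, dt)

    tau = _init_tau(k, n, dt, d, init_changes, rng)
    m = np.floor(tau / dt).astype(int)
    v = rng.uniform(-hyper.v_max, hyper.v_max, size=k + 1)
    eta = max(eta_map1 * float(rng.lognormal(0.0, 0.3)), 1e-8)

    def seg_arrays(mvec):
        bounds = np.concatenate([[0], mvec, [n]]).astype(int)
        return _seg_sums(cs, cs2, bounds)

    nseg, s1, s2 = seg_arrays(m)

    def seg_rss_j(j, vj):
        return s2[j] - 2.0 * vj * dt * s1[j] + nseg[j] * (vj * dt) ** 2

    burn = int(n_iter * burn_frac)
    keep_iters = list(range(burn, n_iter, thin))
    keep_set = set(keep_iters)
    n_keep = len(keep_iters)
    out_tau = np.empty((n_keep, k))
    out_v = np.empty((n_keep, k + 1))
    out_eta = np.empty(n_keep)
    out_lp = np.empty(n_keep)
    ki = 0
    coef = 0.0 if prior_only else eta / (2.0 * dt)

    for it in range(n_iter):
        coef = 0.0 if prior_only else eta / (2.0 * dt)
        # --- segment velocities, one at a time
        for j in range(k + 1):
            vp = v[j] + hyper.eps_v * rng.standard_normal()
            if abs(vp) > hyper.v_max:
                continue
            log_a = -coef * (seg_rss_j(j, vp) - seg_rss_j(j, v[j]))
            if log_a >= 0 or math.log(rng.random()) < log_a:
                v[j] = vp
        # --- eta: conjugate Gibbs draw
        if not prior_only:
            rss = _sum_sq(nseg, s1, s2, v, dt)
            eta = float(
                rng.gamma(eta_shape + n / 2.0, 1.0 / (hyper.eta_rate + rss / (2.0 * dt)))
            )
            coef = eta / (2.0 * dt)
        # --- change times, one at a time (continuous walk)
        for j in range(k):
            tp = tau[j] + eps_tau * (2.0 * rng.random() - 1.0)
            if not (0.0 < tp < n * dt):
                continue
            mp = int(math.floor(tp / dt))
            left = m[j - 1] if j > 0 else 0
            right = m[j + 1] if j + 1 < k else n
            if not (left + d <= mp <= right - d):
                continue
            if mp == m[j]:
                tau[j] = tp  # same index partition: likelihood unchanged
                continue
            m_new = m.copy()
            m_new[j] = mp
            n2, s1_2, s2_2 = seg_arrays(m_new)
            # only segments j and j+1 change
            d_old = -coef * (seg_rss_j(j, v[j]) + seg_rss_j(j + 1, v[j + 1]))
            d_new = -coef * (
                (s2_2[j] - 2 * v[j] * dt * s1_2[j] + n2[j] * (v[j] * dt) ** 2)
                + (s2_2[j + 1] - 2 * v[j + 1] * dt * s1_2[j + 1] + n2[j + 1] * (v[j + 1] * dt) ** 2)
            )
            log_a = d_new - d_old
            if log_a >= 0 or math.log(rng.random()) < log_a:
                tau[j] = tp
                m = m_new
                nseg, s1, s2 = n2, s1_2, s2_2
        if it in keep_set:
            out_tau[ki] = tau
            out_v[ki] = v
            out_eta[ki] = eta
            out_lp[ki] = _log_posterior(
                nseg, s1, s2, v, eta, n, dt, eta_shape, hyper.eta_rate, prior_only
            )
            ki += 1
    return Stage2Chain(
        tau=out_tau, v=out_v, eta=out_eta, log_post=out_lp, seed=seed
    )


def _log_posterior(nseg, s1, s2, v, eta, n, dt, eta_shape, eta_rate, prior_only):
    if prior_only:
        return 0.0
    rss = _sum_sq(nseg, s1, s2, v, dt)
    loglik = 0.5 * n * (math.log(eta) - math.log(dt) - _LOG_2PI) - eta * rss / (
        2.0 * dt
    )
    logprior_eta = (eta_shape - 1.0) * math.log(eta) - eta_rate * eta
    return loglik + logprior_eta


def check_convergence(result: Stage2Result, rhat_max: float = 1.1):
    """Split R-hat and ESS per parameter; pass iff R-hat < 1.1 and
    ESS > 5 x n_chains for every parameter."""
    import arviz as az

    if len(result.chains) < 2:
        raise ValueError("convergence diagnostics need at least 2 chains")
    k = result.k
    data = {
        "eta": np.stack([c.eta for c in result.chains]),
    }
    for j in range(k + 1):
        data[f"v{j}"] = np.stack([c.v[:, j] for c in result.chains])
    for j in range(k):
        data[f"tau{j}"] = np.stack([c.tau[:, j] for c in result.chains])
    idata = az.convert_to_dataset(data)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    table = {
        name: (float(rhat[name].values), float(ess[name].values))
        for name in data
    }
    n_chains = len(result.chains)
    ok = all(
        r < rhat_max and e > 5 * n_chains for r, e in table.values()
    )
    return ok, table


def map_point_estimates(result: Stage2Result):
    """The retained draw with the highest evaluated log posterior; components
    reported jointly as (tau_hat, v_hat, eta_hat)."""
    best = None
    for c in result.chains:
        i = int(np.argmax(c.log_post))
        if best is None or c.log_post[i] > best[0]:
            best = (c.log_post[i], c.tau[i].copy(), c.v[i].copy(), float(c.eta[i]))
    return best[1], best[2], best[3]
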