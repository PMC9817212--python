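"""Stage 1: posterior for the number of change points.

A Metropolis--Hastings sampler over (r, lambda, eta), where r is a switch
point process -- a set of change indices in 1..N-1 subject to a minimum
segment duration of d_r observations -- lambda is the switch rate (1/s) and
eta the common precision.  The segment velocities are integrated out against
their Uniform(-v_max, v_max) priors (see ``model.MarginalLikelihood``), which
reduces the dimension of the space the chain explores and is what makes the
number of changes directly identifiable from the posterior of K_r.

Moves on r: with probability u1 an independent proposal (a fresh feasible
configuration with exactly computable density), with u2 a birth/death pair,
otherwise a single-change location shift.  lambda uses an independence Gamma
proposal; eta a Normal random walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import baselines
from .model import IncrementSeries, MarginalLikelihood, eta_umvu

__all__ = [
    "Stage1Hyper",
    "Stage1Chain",
    "Stage1Result",
    "switch_stats",
    "is_feasible",
    "log_prior_r",
    "run_stage1",
    "k_map",
]


@dataclass(frozen=True)
class Stage1Hyper:
    """Sampler hyperparameters (priors, proposal kernels, move mixture)."""

    d_r: int = 5
    v_max: float = 2.0  # um/s
    a_lam: float = (3.0 / 10.0) * 50.0
    b_lam: float = 50.0
    eta_shape_factor: float = 0.15  # prior shape = factor * eta_umvu
    eta_rate: float = 0.1
    a_prop: float = 2.5
    b_prop: float = 10.0
    u1: float = 0.25  # independent proposal
    u2: float = 0.25  # birth/death
    eta_walk_sd_factor: float = 0.25  # walk sd = factor * eta_umvu

    def __post_init__(self) -> None:
        if self.u1 + self.u2 > 1.0:
            raise ValueError("u1 + u2 must not exceed 1")
        if self.d_r < 1:
            raise ValueError("d_r must be >= 1")


def switch_stats(changes, n: int, d_r: int):
    """(K_r, A_r, bounds) for a change-index set.

    bounds is the ordered set M_r = {0, changes..., N}; A_r counts, per
    segment, the grid positions where an extra change could not be placed
    without violating the minimum duration on either side:
    A_r = sum_j max(0, M_j - (M_{j-1} + 1) - 2 (d_r - 1)).
    """
    bounds = np.concatenate([[0], np.asarray(changes, dtype=int), [n]])
    gaps = np.diff(bounds)
    k = len(changes)
    a = int(np.sum(np.maximum(0, gaps - 1 - 2 * (d_r - 1))))
    return k, a, bounds


def is_feasible(changes, n: int, d_r: int) -> bool:
    bounds = np.concatenate([[0], np.asarray(changes, dtype=int), [n]])
    return bool(np.all(np.diff(bounds) >= d_r))


def log_prior_r(changes, n: int, lam: float, dt: float, d_r: int) -> float:
    """Truncated-renewal switch point prior: (1 - e^{-lam dt})^K (e^{-lam
    dt})^A on the feasible set, -inf otherwise."""
    if not is_feasible(changes, n, d_r):
        return -np.inf
    k, a, _ = switch_stats(changes, n, d_r)
    p_step = -lam * dt
    return k * math.log1p(-math.exp(p_step)) + a * p_step if k or a else 0.0


# ---------------------------------------------------------------------------
# independent feasible-configuration proposal


def _feasible_kmax(n: int, d_r: int) -> int:
    return max(n // d_r - 1, 0)


def _log_n_configs(n: int, k: int, d_r: int) -> float:
    """log of the number of feasible configurations with exactly k changes:
    C(N - (k+1) d_r + k, k) by stars and bars over the slack gaps."""
    s = n - (k + 1) * d_r
    if s < 0:
        return -np.inf
    return float(gammaln(s + k + 1) - gammaln(k + 1) - gammaln(s + 1))


class _IndependentProposal:
    """K' ~ Poisson(lam * T) restricted to feasible K, then a uniformly
    random feasible configuration with K' changes."""

    def __init__(self, n: int, d_r: int, dt: float):
        self.n = n
        self.d_r = d_r
        self.dt = dt
        self.kmax = _feasible_kmax(n, d_r)
        self._log_nconf = np.array(
            [_log_n_configs(n, k, d_r) for k in range(self.kmax + 1)]
        )

    def _log_weights(self, lam: float) -> np.ndarray:
        mu = lam * self.n * self.dt
        ks = np.arange(self.kmax + 1)
        logw = ks * math.log(max(mu, 1e-300)) - mu - gammaln(ks + 1)
        logw -= _logsumexp(logw)
        return logw

    def sample(self, lam: float, rng: np.random.Generator) -> tuple[int, ...]:
        logw = self._log_weights(lam)
        k = int(rng.choice(self.kmax + 1, p=np.exp(logw)))
        if k == 0:
            return ()
        s = self.n - (k + 1) * self.d_r
        slots = np.sort(rng.choice(s + k, size=k, replace=False))
        # bijection slots -> non-negative slack gaps e_1..e_k
        e = np.diff(np.concatenate([[-1], slots])) - 1
        gaps = self.d_r + e
        return tuple(int(x) for x in np.cumsum(gaps))

    def log_density(self, changes, lam: float) -> float:
        k = len(changes)
        if k > self.kmax:
            return -np.inf
        logw = self._log_weights(lam)
        return float(logw[k] - self._log_nconf[k])


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


# ---------------------------------------------------------------------------
# local moves


def _birth_slots(bounds: np.ndarray, d_r: int) -> list[tuple[int, int]]:
    """Per existing gap (a, b): feasible insertion range [a+d_r, b-d_r]."""
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= 2 * d_r:
            out.append((int(a) + d_r, int(b) - d_r))
    return out


def _count_slots(ranges) -> int:
    return sum(hi - lo + 1 for lo, hi in ranges)


def propose_r(
    changes: tuple[int, ...],
    n: int,
    lam: float,
    hyper: Stage1Hyper,
    indep: _IndependentProposal,
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], float, str]:
    """One switch-point-process proposal.

    Returns (proposed changes, log proposal ratio q(r|r')/q(r'|r), move tag).
    Moves with no feasible target propose the identity (ratio 0).
    """
    d_r = hyper.d_r
    u = rng.random()
    if u < hyper.u1:
        prop = indep.sample(lam, rng)
        logratio = indep.log_density(changes, lam) - indep.log_density(prop, lam)
        return prop, logratio, "independent"
    if u < hyper.u1 + hyper.u2:
        _, _, bounds = switch_stats(changes, n, d_r)
        if rng.random() < 0.5:  # birth
            ranges = _birth_slots(bounds, d_r)
            nb = _count_slots(ranges)
            if nb == 0:
                return changes, 0.0, "birth-noop"
            pick = int(rng.integers(nb))
            for lo, hi in ranges:
                if pick < hi - lo + 1:
                    pos = lo + pick
                    break
                pick -= hi - lo + 1
            prop = tuple(sorted(changes + (pos,)))
            # forward: 0.5/nb ; reverse death: 0.5/K'
            logratio = math.log(nb) - math.log(len(prop))
            return prop, logratio, "birth"
        else:  # death
            if not changes:
                return changes, 0.0, "death-noop"
            j = int(rng.integers(len(changes)))
            prop = changes[:j] + changes[j + 1 :]
            _, _, bounds_p = switch_stats(prop, n, d_r)
            nb_rev = _count_slots(_birth_slots(bounds_p, d_r))
            logratio = math.log(len(changes)) - math.log(nb_rev)
            return prop, logratio, "death"
    # shift
    if not changes:
        return changes, 0.0, "shift-noop"
    j = int(rng.integers(len(changes)))
    _, _, bounds = switch_stats(changes, n, d_r)
    lo, hi = int(bounds[j]) + hyper.d_r, int(bounds[j + 2]) - hyper.d_r
    pos = int(rng.integers(lo, hi + 1))
    prop = tuple(sorted(changes[:j] + (pos,) + changes[j + 1 :]))
    return prop, 0.0, "shift"


# ---------------------------------------------------------------------------
# the sampler


@dataclass
class Stage1Chain:
    """Retained (post burn-in, thinned) samples of one chain."""

    k: np.ndarray
    lam: np.ndarray
    eta: np.ndarray
    changes: list[tuple[int, ...]]
    log_target: np.ndarray
    accept_rates: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass
class Stage1Result:
    chains: list[Stage1Chain]
    hyper: Stage1Hyper
    eta_umvu: float

    @property
    def k_samples(self) -> np.ndarray:
        return np.concatenate([c.k for c in self.chains])

    def map_sample(self) -> tuple[tuple[int, ...], float, float]:
        """(changes, lambda, eta) of the highest-log-target retained draw."""
        best = None
        for c in self.chains:
            i = int(np.argmax(c.log_target))
            if best is None or c.log_target[i] > best[0]:
                best = (c.log_target[i], c.changes[i], c.lam[i], c.eta[i])
        return best[1], float(best[2]), float(best[3])

    @property
    def eta_map(self) -> float:
        return self.map_sample()[2]


def _log_gamma_pdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -np.inf
    return (
        shape * math.log(rate)
        - float(gammaln(shape))
        + (shape - 1.0) * math.log(x)
        - rate * x
    )


def init_stage1(
    xi: IncrementSeries,
    hyper: Stage1Hyper,
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], float, float]:
    """Initial state: lambda, eta from their priors; k0 ~ Poisson of the
    prior-mean number of changes over the path; r set to the k0-change
    minimum-RSS segmentation, repaired to feasibility by dropping the
    closest-pair changes."""
    lam0 = float(rng.gamma(hyper.a_lam, 1.0 / hyper.b_lam))
    ehat = eta_umvu(xi)
    eta0 = float(rng.gamma(hyper.eta_shape_factor * ehat, 1.0 / hyper.eta_rate))
    k0 = int(rng.poisson((hyper.a_lam / hyper.b_lam) * xi.duration))
    changes = list(baselines.rss_changes_for_k(xi.values, k0, min_seg=hyper.d_r))
    while changes and not is_feasible(changes, xi.n, hyper.d_r):
        bounds = np.concatenate([[0], changes, [xi.n]])
        gaps = np.diff(bounds)
        j = int(np.argmin(gaps))  # drop a change bounding the tightest gap
        drop = min(j, len(changes) - 1)
        changes.pop(drop)
    return tuple(changes), lam0, eta0


def run_stage1(
    xi: IncrementSeries,
    hyper: Stage1Hyper | None = None,
    n_iter: int = 200_000,
    n_chains: int = 4,
    rng: np.random.Generator | int | None = None,
    burn_frac: float = 0.5,
    thin: int = 100,
    prior_only: bool = False,
    fixed_lam: float | None = None,
    use_numba: bool = True,
) -> Stage1Result:
    """Run ``n_chains`` independent stage-1 samplers and collect retained
    samples.

    ``prior_only`` switches the likelihood off (the chain then targets the
    joint prior -- used for kernel validation).  ``fixed_lam`` freezes the
    switch rate at a constant.  ``use_numba=False`` forces the pure-Python
    reference chain.
    """
    from ._stage1_kernel import HAVE_NUMBA

    hyper = hyper or Stage1Hyper()
    rng = np.random.default_rng(rng)
    ehat = eta_umvu(xi)
    if not np.isfinite(ehat):
        raise ValueError("degenerate increment series")
    n = xi.n
    if n < 2 * hyper.d_r:
        raise ValueError("path too short for one change at this d_r")
    lik = MarginalLikelihood(xi, hyper.v_max)
    indep = _IndependentProposal(n, hyper.d_r, xi.dt)
    eta_shape = hyper.eta_shape_factor * ehat
    eta_sd = hyper.eta_walk_sd_factor * ehat
    fast = use_numba and HAVE_NUMBA
    chains = []
    for _ in range(n_chains):
        seed = int(rng.integers(2**31 - 1))
        sub = np.random.default_rng(seed)
        if fast:
            chains.append(
                _run_one_chain_numba(
                    xi, hyper, n_iter, sub, burn_frac, thin,
                    prior_only, fixed_lam, eta_shape, eta_sd, seed,
                )
            )
        else:
            chains.append(
                _run_one_chain(
                    xi, hyper, lik, indep, n_iter, sub, burn_frac, thin,
                    prior_only, fixed_lam, eta_shape, eta_sd, seed,
                )
            )
    return Stage1Result(chains=chains, hyper=hyper, eta_umvu=ehat)


def _run_one_chain_numba(
    xi, hyper, n_iter, rng, burn_frac, thin,
    prior_only, fixed_lam, eta_shape, eta_sd, seed,
):
    from ._stage1_kernel import run_chain_numba

    n = xi.n
    changes, lam, eta = init_stage1(xi, hyper, rng)
    if fixed_lam is not None:
        lam = float(fixed_lam)
    cs = np.concatenate([[0.0], np.cumsum(xi.values)])
    cs2 = np.concatenate([[0.0], np.cumsum(xi.values**2)])
    kmax = _feasible_kmax(n, hyper.d_r)
    init_ch = np.asarray(changes, dtype=np.int64)
    kernel_seed = int(rng.integers(2**31 - 1))
    out_k, out_lam, out_eta, out_lt, out_ch, acc = run_chain_numba(
        kernel_seed,
        cs,
        cs2,
        n,
        xi.dt,
        int(n_iter),
        int(n_iter * burn_frac),
        int(thin),
        int(hyper.d_r),
        float(hyper.v_max),
        float(hyper.a_lam),
        float(hyper.b_lam),
        float(eta_shape),
        float(hyper.eta_rate),
        float(hyper.a_prop),
        float(hyper.b_prop),
        float(hyper.u1),
        float(hyper.u2),
        float(eta_sd),
        init_ch,
        len(changes),
        float(lam),
        float(eta),
        bool(prior_only),
        fixed_lam is not None,
        int(kmax),
    )
    changes_list = [
        tuple(int(c) for c in row if c >= 0) for row in out_ch
    ]
    rates = {
        "r": acc[0] / acc[1] if acc[1] else float("nan"),
        "lam": acc[2] / acc[3] if acc[3] else float("nan"),
        "eta": acc[4] / acc[5] if acc[5] else float("nan"),
    }
    return Stage1Chain(
        k=out_k,
        lam=out_lam,
        eta=out_eta,
        changes=changes_list,
        log_target=out_lt,
        accept_rates=rates,
        seed=kernel_seed,
    )


def _run_one_chain(
    xi, hyper, lik, indep, n_iter, rng, burn_frac, thin,
    prior_only, fixed_lam, eta_shape, eta_sd, seed,
):
    n = xi.n
    dt = xi.dt
    changes, lam, eta = init_stage1(xi, hyper, rng)
    if fixed_lam is not None:
        lam = float(fixed_lam)

    def loglik(ch, e):
        if prior_only:
            return 0.0
        bounds = np.concatenate([[0], ch, [n]]).astype(int)
        return lik(bounds, e)

    cur_lik = loglik(changes, eta)
    cur_prior_r = log_prior_r(changes, n, lam, dt, hyper.d_r)
    n_keep = 0
    burn = int(n_iter * burn_frac)
    keep_iters = range(burn, n_iter, thin)
    n_keep = len(keep_iters)
    out_k = np.empty(n_keep, dtype=int)
    out_lam = np.empty(n_keep)
    out_eta = np.empty(n_keep)
    out_lt = np.empty(n_keep)
    out_changes: list[tuple[int, ...]] = []
    acc = {"r": 0, "r_tries": 0, "lam": 0, "lam_tries": 0, "eta": 0, "eta_tries": 0}
    keep_set = set(keep_iters)
    ki = 0
    for it in range(n_iter):
        # --- r move
        prop, logqratio, tag = propose_r(changes, n, lam, hyper, indep, rng)
        if prop != changes:
            acc["r_tries"] += 1
            prop_prior = log_prior_r(prop, n, lam, dt, hyper.d_r)
            if np.isfinite(prop_prior):
                prop_lik = loglik(prop, eta)
                log_a = (prop_lik + prop_prior) - (cur_lik + cur_prior_r) + logqratio
                if log_a >= 0 or math.log(rng.random()) < log_a:
                    changes, cur_lik, cur_prior_r = prop, prop_lik, prop_prior
                    acc["r"] += 1
        # --- lambda move (independence Gamma proposal); likelihood free
        if fixed_lam is None:
            acc["lam_tries"] += 1
            lam_p = float(rng.gamma(hyper.a_prop, 1.0 / hyper.b_prop))
            prior_r_p = log_prior_r(changes, n, lam_p, dt, hyper.d_r)
            log_a = (
                prior_r_p
                + _log_gamma_pdf(lam_p, hyper.a_lam, hyper.b_lam)
                - cur_prior_r
                - _log_gamma_pdf(lam, hyper.a_lam, hyper.b_lam)
                + _log_gamma_pdf(lam, hyper.a_prop, hyper.b_prop)
                - _log_gamma_pdf(lam_p, hyper.a_prop, hyper.b_prop)
            )
            if log_a >= 0 or math.log(rng.random()) < log_a:
                lam = lam_p
                cur_prior_r = prior_r_p
                acc["lam"] += 1
        # --- eta move (Normal random walk; negative proposals rejected)
        acc["eta_tries"] += 1
        eta_p = eta + eta_sd * rng.standard_normal()
        if eta_p > 0:
            lik_p = loglik(changes, eta_p)
            log_a = (
                lik_p
                + _log_gamma_pdf(eta_p, eta_shape, hyper.eta_rate)
                - cur_lik
                - _log_gamma_pdf(eta, eta_shape, hyper.eta_rate)
            )
            if log_a >= 0 or math.log(rng.random()) < log_a:
                eta, cur_lik = eta_p, lik_p
                acc["eta"] += 1
        if it in keep_set:
            out_k[ki] = len(changes)
            out_lam[ki] = lam
            out_eta[ki] = eta
            out_lt[ki] = (
                cur_lik
                + cur_prior_r
                + _log_gamma_pdf(eta, eta_shape, hyper.eta_rate)
                + _log_gamma_pdf(lam, hyper.a_lam, hyper.b_lam)
            )
            out_changes.append(changes)
            ki += 1
    rates = {
        m: (acc[m] / acc[f"{m}_tries"] if acc[f"{m}_tries"] else float("nan"))
        for m in ("r", "lam", "eta")
    }
    return Stage1Chain(
        k=out_k,
        lam=out_lam,
        eta=out_eta,
        changes=out_changes,
        log_target=out_lt,
        accept_rates=rates,
        seed=seed,
    )


def k_map(result: Stage1Result | np.ndarray) -> tuple[int, dict[int, float]]:
    """MAP number of change points and the empirical posterior pmf of K_r.

    Ties are broken toward the smaller k (parsimony).
    """
    ks = result.k_samples if isinstance(result, Stage1Result) else np.asarray(result)
    if ks.size == 0:
        raise ValueError("no retained samples")
    vals, counts = np.unique(ks, return_counts=True)
    pmf = {int(v): float(c) / ks.size for v, c in zip(vals, counts)}
    best = max(pmf.items(), key=lambda kv: (kv[1], -kv[0]))
    return int(best[0]), pmf
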