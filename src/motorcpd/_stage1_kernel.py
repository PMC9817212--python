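"""Numba kernel for the stage-1 sampler.

Same algorithm as the pure-Python chain in ``stage1`` (which remains the
reference implementation and the fallback when numba is unavailable), with
the switch point process held as a fixed-capacity int array.  The kernel is
validated against enumerated prior masses by the same test as the reference
chain.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


_SQRT2 = np.sqrt(2.0)
_LOG_2PI = np.log(2.0 * np.pi)
_LOG_SQRT_PI = 0.5 * np.log(np.pi)


@njit(cache=False)
def _log_erfc(x):  # pragma: no cover - jitted
    """log(erfc(x)), stable for large positive x."""
    if x < 25.0:
        return np.log(math.erfc(x))
    # asymptotic: erfc(x) ~ exp(-x^2)/(x sqrt(pi)) (1 - 1/(2x^2) + 3/(4x^4))
    inv2 = 1.0 / (x * x)
    series = 1.0 - 0.5 * inv2 + 0.75 * inv2 * inv2
    return -x * x - np.log(x) - _LOG_SQRT_PI + np.log(series)


@njit(cache=False)
def _log_phi_diff(b, a):  # pragma: no cover
    """log(Phi(b) - Phi(a)), b >= a."""
    if a + b > 0.0:  # reflect so the small tail carries the precision
        a, b = -b, -a
    # now b <= -a; Phi(b) - Phi(a) = 0.5*(erfc(-b/sqrt2) - erfc(-a/sqrt2))
    lb = _log_erfc(-b / _SQRT2)  # log(2 Phi(b))
    la = _log_erfc(-a / _SQRT2)
    if la >= lb:
        return -np.inf
    return lb - np.log(2.0) + np.log1p(-np.exp(la - lb))


@njit(cache=False)
def _marg_loglik(ch, k, cs, cs2, n, dt, vmax, eta):  # pragma: no cover
    if eta <= 0.0:
        return -np.inf
    total = 0.0
    log_eta = np.log(eta)
    log_dt = np.log(dt)
    prev = 0
    for j in range(k + 1):
        end = ch[j] if j < k else n
        nj = float(end - prev)
        if nj < 1.0:
            return -np.inf
        s1 = cs[end] - cs[prev]
        s2 = cs2[end] - cs2[prev]
        mean = s1 / nj
        ssd = s2 - nj * mean * mean
        if ssd < 0.0:
            ssd = 0.0
        c = np.sqrt(eta * nj * dt)
        vhat = mean / dt
        phi = _log_phi_diff(c * (vmax - vhat), c * (-vmax - vhat))
        total += (
            -np.log(2.0 * vmax)
            + 0.5 * nj * (log_eta - log_dt - _LOG_2PI)
            - eta * ssd / (2.0 * dt)
            + 0.5 * (_LOG_2PI - np.log(eta * nj * dt))
            + phi
        )
        prev = end
    return total


@njit(cache=False)
def _prior_r(ch, k, n, d_r, lam, dt):  # pragma: no cover
    prev = 0
    a = 0
    for j in range(k + 1):
        end = ch[j] if j < k else n
        gap = end - prev
        if gap < d_r:
            return -np.inf
        slack = gap - 1 - 2 * (d_r - 1)
        if slack > 0:
            a += slack
        prev = end
    p_step = -lam * dt
    return k * np.log1p(-np.exp(p_step)) + a * p_step


@njit(cache=False)
def _log_gamma_pdf(x, shape, rate):  # pragma: no cover
    if x <= 0.0:
        return -np.inf
    return (
        shape * np.log(rate)
        - math.lgamma(shape)
        + (shape - 1.0) * np.log(x)
        - rate * x
    )


@njit(cache=False)
def _log_nconf(n, k, d_r):  # pragma: no cover
    s = n - (k + 1) * d_r
    if s < 0:
        return -np.inf
    return math.lgamma(s + k + 1.0) - math.lgamma(k + 1.0) - math.lgamma(s + 1.0)


@njit(cache=False)
def _indep_logweights(lam, n, dt, kmax, out):  # pragma: no cover
    mu = lam * n * dt
    if mu < 1e-300:
        mu = 1e-300
    m = -np.inf
    for k in range(kmax + 1):
        out[k] = k * np.log(mu) - mu - math.lgamma(k + 1.0)
        if out[k] > m:
            m = out[k]
    s = 0.0
    for k in range(kmax + 1):
        s += np.exp(out[k] - m)
    lz = m + np.log(s)
    for k in range(kmax + 1):
        out[k] -= lz


@njit(cache=False)
def _count_birth_slots(ch, k, n, d_r):  # pragma: no cover
    total = 0
    prev = 0
    for j in range(k + 1):
        end = ch[j] if j < k else n
        if end - prev >= 2 * d_r:
            total += end - prev - 2 * d_r + 1
        prev = end
    return total


@njit(cache=False)
def _pick_birth_slot(ch, k, n, d_r, pick):  # pragma: no cover
    prev = 0
    for j in range(k + 1):
        end = ch[j] if j < k else n
        if end - prev >= 2 * d_r:
            width = end - prev - 2 * d_r + 1
            if pick < width:
                return prev + d_r + pick
            pick -= width
        prev = end
    return -1


@njit(cache=False)
def run_chain_numba(
    seed,
    cs,
    cs2,
    n,
    dt,
    n_iter,
    burn,
    thin,
    d_r,
    vmax,
    a_lam,
    b_lam,
    eta_shape,
    eta_rate,
    a_prop,
    b_prop,
    u1,
    u2,
    eta_sd,
    init_ch,
    init_k,
    init_lam,
    init_eta,
    prior_only,
    fix_lam,
    kmax,
):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    cap = kmax + 1
    ch = np.zeros(cap + 1, dtype=np.int64)
    k = init_k
    for j in range(k):
        ch[j] = init_ch[j]
    lam = init_lam
    eta = init_eta
    logw = np.empty(kmax + 1)
    logw_lam = -1.0  # lambda the cached weights belong to
    lognconf = np.empty(kmax + 1)
    for kk in range(kmax + 1):
        lognconf[kk] = _log_nconf(n, kk, d_r)

    def loglik(chv, kv, etav):
        if prior_only:
            return 0.0
        return _marg_loglik(chv, kv, cs, cs2, n, dt, vmax, etav)

    cur_lik = loglik(ch, k, eta)
    cur_prior = _prior_r(ch, k, n, d_r, lam, dt)

    n_keep = (n_iter - burn + thin - 1) // thin
    out_k = np.empty(n_keep, dtype=np.int64)
    out_lam = np.empty(n_keep)
    out_eta = np.empty(n_keep)
    out_lt = np.empty(n_keep)
    out_ch = -np.ones((n_keep, cap), dtype=np.int64)
    acc = np.zeros(6, dtype=np.int64)  # r_acc, r_try, lam_acc, lam_try, eta_acc, eta_try

    prop = np.zeros(cap + 1, dtype=np.int64)
    ki = 0
    for it in range(n_iter):
        # ---------- r move ----------
        u = np.random.random()
        kp = -1
        logq = 0.0
        if u < u1:
            # independent proposal: K' ~ truncated Poisson(lam*T), uniform config
            if lam != logw_lam:
                _indep_logweights(lam, n, dt, kmax, logw)
                logw_lam = lam
            r = np.random.random()
            csum = 0.0
            kp = kmax
            for kk in range(kmax + 1):
                csum += np.exp(logw[kk])
                if r < csum:
                    kp = kk
                    break
            s = n - (kp + 1) * d_r
            if kp > 0:
                # sample kp distinct slots from s+kp via partial Fisher-Yates
                m_tot = s + kp
                pool = np.arange(m_tot)
                for jj in range(kp):
                    swap = jj + int(np.random.random() * (m_tot - jj))
                    tmp = pool[jj]
                    pool[jj] = pool[swap]
                    pool[swap] = tmp
                slots = np.sort(pool[:kp])
                pos = 0
                prev_slot = -1
                for jj in range(kp):
                    e = slots[jj] - prev_slot - 1
                    pos += d_r + e
                    prop[jj] = pos
                    prev_slot = slots[jj]
            logq = (logw[k] - lognconf[k]) - (logw[kp] - lognconf[kp])
        elif u < u1 + u2:
            if np.random.random() < 0.5:  # birth
                nb = _count_birth_slots(ch, k, n, d_r)
                if nb > 0 and k < kmax:
                    pick = int(np.random.random() * nb)
                    pos = _pick_birth_slot(ch, k, n, d_r, pick)
                    kp = k + 1
                    jj = 0
                    for ii in range(k):
                        if ch[ii] < pos:
                            prop[jj] = ch[ii]
                            jj += 1
                    prop[jj] = pos
                    jj += 1
                    for ii in range(k):
                        if ch[ii] > pos:
                            prop[jj] = ch[ii]
                            jj += 1
                    logq = np.log(nb) - np.log(kp)
            else:  # death
                if k > 0:
                    drop = int(np.random.random() * k)
                    kp = k - 1
                    jj = 0
                    for ii in range(k):
                        if ii != drop:
                            prop[jj] = ch[ii]
                            jj += 1
                    nb_rev = _count_birth_slots(prop, kp, n, d_r)
                    logq = np.log(k) - np.log(nb_rev)
        else:  # shift
            if k > 0:
                j = int(np.random.random() * k)
                lo = (ch[j - 1] if j > 0 else 0) + d_r
                hi = (ch[j + 1] if j + 1 < k else n) - d_r
                pos = lo + int(np.random.random() * (hi - lo + 1))
                if pos != ch[j]:
                    kp = k
                    for ii in range(k):
                        prop[ii] = ch[ii]
                    prop[j] = pos
                    # re-sort (single displaced element; neighbors bound it)
                    logq = 0.0
        if kp >= 0:
            acc[1] += 1
            p_prior = _prior_r(prop, kp, n, d_r, lam, dt)
            if p_prior > -np.inf:
                p_lik = loglik(prop, kp, eta)
                log_a = (p_lik + p_prior) - (cur_lik + cur_prior) + logq
                if log_a >= 0.0 or np.log(np.random.random()) < log_a:
                    for ii in range(kp):
                        ch[ii] = prop[ii]
                    k = kp
                    cur_lik = p_lik
                    cur_prior = p_prior
                    acc[0] += 1
        # ---------- lambda move ----------
        if not fix_lam:
            acc[3] += 1
            lam_p = np.random.gamma(a_prop, 1.0 / b_prop)
            prior_p = _prior_r(ch, k, n, d_r, lam_p, dt)
            log_a = (
                prior_p
                + _log_gamma_pdf(lam_p, a_lam, b_lam)
                - cur_prior
                - _log_gamma_pdf(lam, a_lam, b_lam)
                + _log_gamma_pdf(lam, a_prop, b_prop)
                - _log_gamma_pdf(lam_p, a_prop, b_prop)
            )
            if log_a >= 0.0 or np.log(np.random.random()) < log_a:
                lam = lam_p
                cur_prior = prior_p
                acc[2] += 1
        # ---------- eta move ----------
        acc[5] += 1
        eta_p = eta + eta_sd * np.random.standard_normal()
        if eta_p > 0.0:
            lik_p = loglik(ch, k, eta_p)
            log_a = (
                lik_p
                + _log_gamma_pdf(eta_p, eta_shape, eta_rate)
                - cur_lik
                - _log_gamma_pdf(eta, eta_shape, eta_rate)
            )
            if log_a >= 0.0 or np.log(np.random.random()) < log_a:
                eta = eta_p
                cur_lik = lik_p
                acc[4] += 1
        # ---------- record ----------
        if it >= burn and (it - burn) % thin == 0:
            out_k[ki] = k
            out_lam[ki] = lam
            out_eta[ki] = eta
            out_lt[ki] = (
                cur_lik
                + cur_prior
                + _log_gamma_pdf(eta, eta_shape, eta_rate)
                + _log_gamma_pdf(lam, a_lam, b_lam)
            )
            for ii in range(k):
                out_ch[ki, ii] = ch[ii]
            ki += 1
    return out_k, out_lam, out_eta, out_lt, out_ch, acc
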