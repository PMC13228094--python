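"""Jitted No-U-Turn sampling for the hierarchical cumulative logit.

Same algorithm as :mod:`emaconn._hmc` (slice-variant NUTS, dual-averaging
step size, windowed diagonal-metric adaptation) but compiled end-to-end with
numba and specialized to the collapsed ordinal likelihood, so one chain runs
at the cost of its gradient evaluations.  The doubling recursion is replaced
by an equivalent iterative scheme: leaves of each subtree are produced
sequentially and merged like a binary counter, performing exactly the
per-subtree no-U-turn checks and progressive candidate sampling of the
recursive formulation.

Randomness uses numba's internal generator seeded per chain, so runs are
reproducible bit-for-bit for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from emaconn._ordlik import logp_grad_cells

_MAX_DELTA_H = 1000.0


@njit(cache=True, fastmath=True)
def _kinetic(r, inv_mass):
    s = 0.0
    for i in range(r.size):
        s += r[i] * inv_mass[i] * r[i]
    return 0.5 * s


@njit(cache=True, fastmath=True)
def _dot_im(a, inv_mass, b):
    s = 0.0
    for i in range(a.size):
        s += a[i] * inv_mass[i] * b[i]
    return s


@njit(cache=True, fastmath=True)
def _leapfrog(theta, r, grad, eps, inv_mass,
              Xc, counts, pid, did, n_p, n_d, ncut, sb, st, ss):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * r1
    logp, grad1 = logp_grad_cells(
        theta1, Xc, counts, pid, did, n_p, n_d, ncut, sb, st, ss
    )
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, logp, grad1


@njit(cache=True, fastmath=True)
def _find_eps(theta, eps0, inv_mass,
              Xc, counts, pid, did, n_p, n_d, ncut, sb, st, ss):
    eps = eps0
    dim = theta.size
    r = np.empty(dim)
    for i in range(dim):
        r[i] = np.random.normal() / np.sqrt(inv_mass[i])
    logp, grad = logp_grad_cells(
        theta, Xc, counts, pid, did, n_p, n_d, ncut, sb, st, ss
    )
    h0 = logp - _kinetic(r, inv_mass)
    t1, r1, lp1, _ = _leapfrog(theta, r, grad, eps, inv_mass,
                               Xc, counts, pid, did, n_p, n_d, ncut, sb, st, ss)
    h1 = lp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        t1, r1, lp1, _ = _leapfrog(theta, r, grad, eps, inv_mass,
                                   Xc, counts, pid, did, n_p, n_d, ncut,
                                   sb, st, ss)
        h1 = lp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


@njit(cache=True, fastmath=True)
def nuts_chain(
    theta0,
    n_warmup,
    n_draws,
    seed,
    target_accept,
    max_treedepth,
    warmup_max_treedepth,
    Xc, counts, pid, did, n_p, n_d, ncut, sb, st, ss,
):
    """Run one NUTS chain; returns (draws, eps, inv_mass, n_div, acc, depth)."""
    np.random.seed(seed)
    theta = theta0.copy()
    dim = theta.size
    inv_mass = np.ones(dim)

    head = max(20, int(0.15 * n_warmup))
    tail = max(10, int(0.1 * n_warmup))
    middle = max(0, n_warmup - head - tail)
    boundaries = np.empty(32, dtype=np.int64)
    n_bound = 0
    w = 25
    remaining = middle
    acc_pos = head
    while remaining > 0:
        take = min(w, remaining)
        if remaining - take < 10 and n_bound > 0:
            acc_pos += remaining
            boundaries[n_bound - 1] = acc_pos
            remaining = 0
        else:
            acc_pos += take
            boundaries[n_bound] = acc_pos
            n_bound += 1
            remaining -= take
            w *= 2

    eps = _find_eps(theta, 1.0, inv_mass,
                    Xc, counts, pid, did, n_p, n_d, ncut, sb, st, ss)
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma = 0.05
    t0_da = 10.0
    kappa = 0.75
    adapt_count = 0

    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    accept_sum = 0.0
    depth_sum = 0.0
    total = n_warmup + n_draws

    maxd = max_treedepth + 2
    stk_first_t = np.empty((maxd, dim))
    stk_first_r = np.empty((maxd, dim))
    stk_cand = np.empty((maxd, dim))
    stk_n = np.empty(maxd, dtype=np.int64)
    stk_size = np.empty(maxd, dtype=np.int64)

    tmin = np.empty(dim)
    rmin = np.empty(dim)
    gmin = np.empty(dim)
    tmax = np.empty(dim)
    rmax = np.empty(dim)
    gmax = np.empty(dim)

    for it in range(total):
        warming = it < n_warmup
        logp, grad = logp_grad_cells(
            theta, Xc, counts, pid, did, n_p, n_d, ncut, sb, st, ss
        )
        r0 = np.empty(dim)
        for i in range(dim):
            r0[i] = np.random.normal() / np.sqrt(inv_mass[i])
        h0 = logp - _kinetic(r0, inv_mass)
        log_u = h0 + np.log(np.random.random())

        tmin[:] = theta
        rmin[:] = r0
        gmin[:] = grad
        tmax[:] = theta
        rmax[:] = r0
        gmax[:] = grad
        sample = theta.copy()
        n_tot = 1
        depth = 0
        alpha_sum = 0.0
        n_alpha = 0
        divergent_iter = False
        cap = warmup_max_treedepth if warming else max_treedepth
        if cap > max_treedepth:
            cap = max_treedepth
        keep_going = True
        while keep_going and depth < cap:
            v = 1.0 if np.random.random() < 0.5 else -1.0
            # grow a subtree of 2^depth leaves in direction v
            if v > 0:
                cur_t = tmax.copy()
                cur_r = rmax.copy()
                cur_g = gmax.copy()
            else:
                cur_t = tmin.copy()
                cur_r = rmin.copy()
                cur_g = gmin.copy()
            top = 0
            sub_valid = True
            n_leaves = 1 << depth
            for _leaf in range(n_leaves):
                cur_t, cur_r, lp1, cur_g = _leapfrog(
                    cur_t, cur_r, cur_g, v * eps, inv_mass,
                    Xc, counts, pid, did, n_p, n_d, ncut, sb, st, ss,
                )
                h1 = lp1 - _kinetic(cur_r, inv_mass)
                if not np.isfinite(h1):
                    h1 = -np.inf
                n_alpha += 1
                d_h = h1 - h0
                if d_h > 0.0:
                    alpha_sum += 1.0
                else:
                    alpha_sum += np.exp(d_h)
                if log_u >= h1 + _MAX_DELTA_H:
                    divergent_iter = True
                    sub_valid = False
                    break
                stk_first_t[top] = cur_t
                stk_first_r[top] = cur_r
                stk_cand[top] = cur_t
                stk_n[top] = 1 if log_u <= h1 else 0
                stk_size[top] = 1
                top += 1
                # binary-counter merge of equal-size sibling subtrees
                while top >= 2 and stk_size[top - 1] == stk_size[top - 2]:
                    dvec = v * (cur_t - stk_first_t[top - 2])
                    if (
                        _dot_im(dvec, inv_mass, stk_first_r[top - 2]) < 0.0
                        or _dot_im(dvec, inv_mass, cur_r) < 0.0
                    ):
                        sub_valid = False
                        break
                    nL = stk_n[top - 2]
                    nR = stk_n[top - 1]
                    if nR > 0 and np.random.random() * (nL + nR) < nR:
                        stk_cand[top - 2] = stk_cand[top - 1]
                    stk_n[top - 2] = nL + nR
                    stk_size[top - 2] *= 2
                    top -= 1
                if not sub_valid:
                    break
            if sub_valid:
                n_new = stk_n[0]
                # progressive sampling across the doubling
                if n_new > 0 and np.random.random() * n_tot < n_new:
                    sample = stk_cand[0].copy()
                n_tot += n_new
                if v > 0:
                    tmax[:] = cur_t
                    rmax[:] = cur_r
                    gmax[:] = cur_g
                else:
                    tmin[:] = cur_t
                    rmin[:] = cur_r
                    gmin[:] = cur_g
                dvec = tmax - tmin
                if (
                    _dot_im(dvec, inv_mass, rmin) < 0.0
                    or _dot_im(dvec, inv_mass, rmax) < 0.0
                ):
                    keep_going = False
            else:
                keep_going = False
            depth += 1
        theta = sample
        accept_prob = alpha_sum / max(n_alpha, 1)

        if warming:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0_da)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            in_window = it >= head and it < (n_warmup - tail)
            if in_window:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
            hit_boundary = False
            for b in range(n_bound):
                if boundaries[b] == it + 1:
                    hit_boundary = True
            if in_window and hit_boundary and welford_n > 5:
                var = welford_m2 / (welford_n - 1)
                var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                    5.0 / (welford_n + 5.0)
                )
                inv_mass = var
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                eps = _find_eps(theta, eps, inv_mass,
                                Xc, counts, pid, did, n_p, n_d, ncut,
                                sb, st, ss)
                mu = np.log(10.0 * eps)
                log_eps_bar = 0.0
                h_bar = 0.0
                adapt_count = 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            if divergent_iter:
                n_divergent += 1
            accept_sum += accept_prob
            depth_sum += depth
            draws[it - n_warmup] = theta

    return (
        draws,
        eps,
        inv_mass,
        n_divergent,
        accept_sum / max(n_draws, 1),
        depth_sum / max(n_draws, 1),
    )
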