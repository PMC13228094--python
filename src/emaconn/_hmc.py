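"""A compact No-U-Turn sampler with dual-averaging and diagonal-metric
adaptation.

This is the standard NUTS recursion (slice variant) with:

* step-size adaptation by dual averaging toward a target acceptance rate,
* a diagonal mass matrix estimated from warmup draws in an expanding-window
  schedule (fast / slow / fast phases, as in mainstream HMC samplers),
* divergence detection (energy error > 1000) and a maximum tree depth.

The target density is supplied as a callable ``theta -> (logp, grad)``; the
sampler itself is model-agnostic.  All randomness flows through one
``numpy.random.Generator``, so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["nuts_sample", "NUTSResult"]

_MAX_DELTA_H = 1000.0


@dataclass
class NUTSResult:
    draws: np.ndarray          # (n_draws, dim)
    step_size: float
    inv_mass: np.ndarray
    n_divergent: int
    mean_accept: float
    mean_treedepth: float


def _leapfrog(f, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    logp, grad = f(theta)
    r = r + 0.5 * eps * grad
    return theta, r, logp, grad


def _hamiltonian(logp, r, inv_mass):
    return logp - 0.5 * np.dot(r * inv_mass, r)


def _find_reasonable_epsilon(f, theta, rng, inv_mass, eps0=1.0):
    eps = eps0
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    logp, grad = f(theta)
    with np.errstate(over="ignore", invalid="ignore"):
        h0 = _hamiltonian(logp, r, inv_mass)
        theta1, r1, logp1, _ = _leapfrog(f, theta, r, grad, eps, inv_mass)
        h1 = _hamiltonian(logp1, r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
        for _ in range(50):
            eps *= 2.0**direction
            theta1, r1, logp1, _ = _leapfrog(f, theta, r, grad, eps, inv_mass)
            h1 = _hamiltonian(logp1, r1, inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            if direction * (h1 - h0) <= direction * np.log(0.5):
                break
    return eps


class _Tree:
    """State threaded through the NUTS doubling recursion."""

    __slots__ = ("f", "inv_mass", "rng", "log_u", "h0", "divergent")

    def __init__(self, f, inv_mass, rng, log_u, h0):
        self.f = f
        self.inv_mass = inv_mass
        self.rng = rng
        self.log_u = log_u
        self.h0 = h0
        self.divergent = False

    def build(self, theta, r, grad, v, j, eps):
        if j == 0:
            theta1, r1, logp1, grad1 = _leapfrog(
                self.f, theta, r, grad, v * eps, self.inv_mass
            )
            h1 = _hamiltonian(logp1, r1, self.inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            n1 = int(self.log_u <= h1)
            s1 = int(self.log_u < h1 + _MAX_DELTA_H)
            if not s1:
                self.divergent = True
            alpha = min(1.0, np.exp(min(0.0, h1 - self.h0)))
            return (theta1, r1, grad1, theta1, r1, grad1, theta1, n1, s1,
                    alpha, 1)
        (tm, rm, gm, tp, rp, gp, t1, n1, s1, a1, na1) = self.build(
            theta, r, grad, v, j - 1, eps
        )
        if s1:
            if v == -1:
                (tm, rm, gm, _, _, _, t2, n2, s2, a2, na2) = self.build(
                    tm, rm, gm, v, j - 1, eps
                )
            else:
                (_, _, _, tp, rp, gp, t2, n2, s2, a2, na2) = self.build(
                    tp, rp, gp, v, j - 1, eps
                )
            if n2 > 0 and self.rng.random() < n2 / max(n1 + n2, 1):
                t1 = t2
            a1 += a2
            na1 += na2
            dt = tp - tm
            s1 = (
                s2
                * int(np.dot(dt, self.inv_mass * rm) >= 0)
                * int(np.dot(dt, self.inv_mass * rp) >= 0)
            )
            n1 += n2
        return tm, rm, gm, tp, rp, gp, t1, n1, s1, a1, na1


def nuts_sample(
    f,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    warmup_max_treedepth: int = 8,
) -> NUTSResult:
    """Sample ``n_draws`` post-warmup draws of the density ``f``.

    Warmup transitions use a lower tree-depth cap: before the step size has
    adapted, trees would otherwise double to the full cap and dominate the
    cost of the run without improving adaptation.
    """
    theta = np.asarray(theta0, dtype=np.float64).copy()
    dim = theta.size
    inv_mass = np.ones(dim)

    # warmup schedule: step-size-only head/tail with expanding metric
    # windows in between
    head = max(20, int(0.15 * n_warmup))
    tail = max(10, int(0.1 * n_warmup))
    middle = max(0, n_warmup - head - tail)
    windows: list[int] = []
    w = 25
    remaining = middle
    while remaining > 0:
        take = min(w, remaining)
        # fold a too-small last window into the previous one
        if remaining - take < 10 and windows:
            windows[-1] += remaining
            remaining = 0
        else:
            windows.append(take)
            remaining -= take
            w *= 2
    boundaries = []
    acc = head
    for wlen in windows:
        acc += wlen
        boundaries.append(acc)

    eps = _find_reasonable_epsilon(f, theta, rng, inv_mass)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    accept_sum = 0.0
    depth_sum = 0.0
    total = n_warmup + n_draws
    adapt_count = 0

    for it in range(total):
        warming = it < n_warmup
        logp, grad = f(theta)
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = _hamiltonian(logp, r0, inv_mass)
        log_u = h0 + np.log(rng.random())
        tree = _Tree(f, inv_mass, rng, log_u, h0)
        tm = tp = theta
        rm = rp = r0
        gm = gp = grad
        sample = theta
        n, s, depth = 1, 1, 0
        alpha, n_alpha = 0.0, 1
        depth_cap = min(warmup_max_treedepth, max_treedepth) if warming else max_treedepth
        while s and depth < depth_cap:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                (tm, rm, gm, _, _, _, t1, n1, s1, alpha, n_alpha) = tree.build(
                    tm, rm, gm, v, depth, eps
                )
            else:
                (_, _, _, tp, rp, gp, t1, n1, s1, alpha, n_alpha) = tree.build(
                    tp, rp, gp, v, depth, eps
                )
            if s1 and rng.random() < min(1.0, n1 / n):
                sample = t1
            n += n1
            dt = tp - tm
            s = (
                s1
                * int(np.dot(dt, inv_mass * rm) >= 0)
                * int(np.dot(dt, inv_mass * rp) >= 0)
            )
            depth += 1
        theta = sample
        accept_prob = alpha / max(n_alpha, 1)

        if warming:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            in_window = it >= head and it < (n_warmup - tail)
            if in_window:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
            if in_window and (it + 1) in boundaries and welford_n > 5:
                var = welford_m2 / (welford_n - 1)
                # regularize toward unit scale as mainstream samplers do
                var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                    5.0 / (welford_n + 5.0)
                )
                inv_mass = var
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                eps = _find_reasonable_epsilon(f, theta, rng, inv_mass, eps0=eps)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
                adapt_count = 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            if tree.divergent:
                n_divergent += 1
            accept_sum += accept_prob
            depth_sum += depth
            draws[it - n_warmup] = theta

    return NUTSResult(
        draws=draws,
        step_size=eps,
        inv_mass=inv_mass,
        n_divergent=n_divergent,
        mean_accept=accept_sum / max(n_draws, 1),
        mean_treedepth=depth_sum / max(n_draws, 1),
    )
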