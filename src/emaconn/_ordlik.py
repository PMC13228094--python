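"""Log posterior and analytic gradient of the hierarchical cumulative logit.

Parameter vector layout (unconstrained):

    theta = [ beta (p) | tau_raw (ncut) | log sigma_p | log sigma_d |
              z_p (n_participants) | z_d (n_days_total) ]

Thresholds are parameterized for ordering as ``tau_1 = raw_0`` and
``tau_j = tau_{j-1} + exp(raw_j)``; random intercepts are non-centered
(``u = sigma * z`` with ``z ~ N(0,1)``), which keeps the posterior geometry
well-conditioned for Hamiltonian sampling.  Priors: ``beta ~ N(0, sd_beta)``
on the standardized-predictor scale, ``tau_j ~ N(0, sd_tau)`` independently
on the threshold scale (with the change-of-variables Jacobian), and
half-Normal(``sd_sigma``) on both random-intercept SDs.

Observations sharing a design row and grouping indices (e.g. the responses
of one participant-day to the same question type) have identical linear
predictors, so the likelihood is collapsed to unique (x, participant, day)
cells with per-category response counts before entering the jitted kernel;
the kernel is then O(n_cells) per call instead of O(n_obs).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True, fastmath=True)
def logp_grad_cells(
    theta: np.ndarray,
    Xc: np.ndarray,       # (C, p) unique design rows
    counts: np.ndarray,   # (C, K) response counts per cell
    pid: np.ndarray,      # (C,)
    did: np.ndarray,      # (C,)
    n_p: int,
    n_d: int,
    ncut: int,
    sd_beta: float,
    sd_tau: float,
    sd_sigma: float,
):
    p = Xc.shape[1]
    C = Xc.shape[0]
    K = ncut + 1
    beta = theta[:p]
    raw = theta[p : p + ncut]
    lsp = theta[p + ncut]
    lsd = theta[p + ncut + 1]
    z_p = theta[p + ncut + 2 : p + ncut + 2 + n_p]
    z_d = theta[p + ncut + 2 + n_p :]

    tau = np.empty(ncut)
    tau[0] = raw[0]
    for j in range(1, ncut):
        tau[j] = tau[j - 1] + np.exp(raw[j])
    sigma_p = np.exp(lsp)
    sigma_d = np.exp(lsd)

    grad = np.zeros_like(theta)
    g_beta = grad[:p]
    g_raw = grad[p : p + ncut]
    g_zp = grad[p + ncut + 2 : p + ncut + 2 + n_p]
    g_zd = grad[p + ncut + 2 + n_p :]
    gtau = np.zeros(ncut)
    F = np.empty(ncut)
    fpdf = np.empty(ncut)
    logp = 0.0
    s_lsp = 0.0
    s_lsd = 0.0

    for c in range(C):
        eta = sigma_p * z_p[pid[c]] + sigma_d * z_d[did[c]]
        for j in range(p):
            eta += Xc[c, j] * beta[j]
        for j in range(ncut):
            F[j] = _sigmoid(tau[j] - eta)
            fpdf[j] = F[j] * (1.0 - F[j])
        g_eta = 0.0
        for k in range(K):
            n_ck = counts[c, k]
            if n_ck == 0:
                continue
            F_hi = F[k] if k < ncut else 1.0
            f_hi = fpdf[k] if k < ncut else 0.0
            F_lo = F[k - 1] if k > 0 else 0.0
            f_lo = fpdf[k - 1] if k > 0 else 0.0
            P = F_hi - F_lo
            if P < 1e-300:
                P = 1e-300
            logp += n_ck * np.log(P)
            g_eta += n_ck * (f_lo - f_hi) / P
            if k < ncut:
                gtau[k] += n_ck * f_hi / P
            if k > 0:
                gtau[k - 1] -= n_ck * f_lo / P
        for j in range(p):
            g_beta[j] += g_eta * Xc[c, j]
        g_zp[pid[c]] += g_eta * sigma_p
        g_zd[did[c]] += g_eta * sigma_d
        s_lsp += g_eta * z_p[pid[c]]
        s_lsd += g_eta * z_d[did[c]]

    # priors
    for j in range(p):
        logp += -0.5 * beta[j] ** 2 / sd_beta**2
        g_beta[j] += -beta[j] / sd_beta**2
    for j in range(ncut):
        logp += -0.5 * tau[j] ** 2 / sd_tau**2
        gtau[j] += -tau[j] / sd_tau**2
    # half-normal on sigma with log-scale Jacobian (+log sigma)
    logp += -0.5 * sigma_p**2 / sd_sigma**2 + lsp
    logp += -0.5 * sigma_d**2 / sd_sigma**2 + lsd
    grad[p + ncut] = s_lsp * sigma_p - sigma_p**2 / sd_sigma**2 + 1.0
    grad[p + ncut + 1] = s_lsd * sigma_d - sigma_d**2 / sd_sigma**2 + 1.0
    for i in range(n_p):
        logp += -0.5 * z_p[i] ** 2
        g_zp[i] += -z_p[i]
    for i in range(n_d):
        logp += -0.5 * z_d[i] ** 2
        g_zd[i] += -z_d[i]
    # threshold ordering Jacobian: tau_j - tau_{j-1} = exp(raw_j)
    for j in range(1, ncut):
        logp += raw[j]
        g_raw[j] += 1.0
    # chain rule tau -> raw (suffix sums)
    suffix = 0.0
    for j in range(ncut - 1, 0, -1):
        suffix += gtau[j]
        g_raw[j] += np.exp(raw[j]) * suffix
    suffix += gtau[0]
    g_raw[0] += suffix
    return logp, grad


def collapse_cells(X, y, pid, did, n_categories):
    """Group identical (design row, participant, day) cells, counting
    responses per category.  Returns (Xc, counts, pid_c, did_c)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    pid = np.asarray(pid, dtype=np.int64)
    did = np.asarray(did, dtype=np.int64)
    key = np.concatenate(
        [X, pid[:, None].astype(np.float64), did[:, None].astype(np.float64)],
        axis=1,
    )
    _, first, inverse = np.unique(
        key.view([("", key.dtype)] * key.shape[1]).ravel(),
        return_index=True,
        return_inverse=True,
    )
    C = first.size
    counts = np.zeros((C, n_categories), dtype=np.float64)
    np.add.at(counts, (inverse, y), 1.0)
    return (
        np.ascontiguousarray(X[first]),
        counts,
        np.ascontiguousarray(pid[first]),
        np.ascontiguousarray(did[first]),
    )


def make_logp_grad(X, y, pid, did, n_p, n_d, ncut, sd_beta, sd_tau, sd_sigma):
    """Bind the data arrays into a ``theta -> (logp, grad)`` closure."""
    Xc, counts, pid_c, did_c = collapse_cells(X, y, pid, did, ncut + 1)

    def f(theta: np.ndarray):
        return logp_grad_cells(
            theta, Xc, counts, pid_c, did_c, n_p, n_d, ncut,
            sd_beta, sd_tau, sd_sigma,
        )

    return f
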