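"""Bayesian hierarchical cumulative-logit inference for ordinal EMA outcomes.

The model for response ``Y in {1..5}`` of one EMA observation is

    P(Y <= k) = logistic(tau_k - eta),    k = 1..4,
    eta = x' beta + u_participant + u_day(participant),

with ordered thresholds ``tau``, fixed effects ``beta`` on the (standardized)
design columns, and independent participant and day-within-participant
random intercepts.  Posterior sampling uses the package's No-U-Turn sampler
with a non-centered parameterization; convergence is checked with split-Rhat
and bulk effective sample size (via arviz) and a failed check raises unless
disabled.

Effect summaries follow the reporting conventions of ordinal regression in
clinical research: posterior-median odds ratio ``e^beta`` with an
equal-tailed 95% credible interval, probability of direction (PD, the percent
of posterior draws of the coefficient greater than zero; the symmetrized
``max(p, 100-p)`` variant is reported alongside), percent of draws inside the
region of practical equivalence ROPE = [-0.10, 0.10] on the log-odds scale
(closed interval), and a significance flag set when the odds-ratio credible
interval excludes 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from emaconn._hmc import nuts_sample
from emaconn._nuts_jit import nuts_chain
from emaconn._ordlik import collapse_cells, make_logp_grad

DIAG_GROUPS = ("BD", "MDD", "SZ")
BASE_TERMS = ["BD", "MDD", "SZ", "age_z", "gender", "question_code"]
ROPE_INTERVAL = (-0.10, 0.10)


class ConvergenceError(RuntimeError):
    """Raised when posterior diagnostics exceed the configured limits."""


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects to fit, plus prior and sampler settings."""

    terms: tuple[str, ...]
    outcome: str = "response"
    prior_sd_beta: float = 2.5
    prior_sd_tau: float = 5.0
    prior_sd_sigma: float = 1.0
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10
    rhat_max: float = 1.01
    ess_min: float = 400.0
    check_convergence: bool = True
    backend: str = "jit"  # "jit" (compiled) or "python" (reference sampler)

    @classmethod
    def diagnostic(cls, **kw) -> "ModelSpec":
        """Diagnosis + age + gender + question type."""
        return cls(terms=tuple(BASE_TERMS), **kw)

    @classmethod
    def connectivity(cls, network: str, **kw) -> "ModelSpec":
        """Within-network connectivity and PC of one network, with
        diagnosis interactions and the mean-FD covariate."""
        w, p = f"within_{network}_z", f"pc_{network}_z"
        terms = BASE_TERMS + ["fd_z", w, p]
        terms += [f"{w}:{g}" for g in DIAG_GROUPS]
        terms += [f"{p}:{g}" for g in DIAG_GROUPS]
        return cls(terms=tuple(terms), **kw)

    @classmethod
    def extent(cls, network: str, **kw) -> "ModelSpec":
        """Spatial extent (vertex count) of one network, with interactions."""
        e = f"extent_{network}_z"
        terms = BASE_TERMS + ["fd_z", e] + [f"{e}:{g}" for g in DIAG_GROUPS]
        return cls(terms=tuple(terms), **kw)

    @classmethod
    def metric(cls, column: str, interactions: bool = False, **kw) -> "ModelSpec":
        """A single metric column (already standardized) plus covariates."""
        terms = BASE_TERMS + ["fd_z", column]
        if interactions:
            terms += [f"{column}:{g}" for g in DIAG_GROUPS]
        return cls(terms=tuple(terms), **kw)


@dataclass
class PosteriorDraws:
    """Named posterior draws with convergence diagnostics.

    Coefficient draws are stored as (chains, draws) arrays on the log-odds
    scale; thresholds as (chains, draws, 4).  ``diagnostics`` holds per-term
    split-Rhat and bulk ESS plus sampler health counters.
    """

    terms: tuple[str, ...]
    beta: np.ndarray        # (chains, draws, p)
    tau: np.ndarray         # (chains, draws, ncut)
    sigma_participant: np.ndarray  # (chains, draws)
    sigma_day: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def term_draws(self, term: str) -> np.ndarray:
        """All chains' draws for one fixed-effect term, flattened."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}; have {self.terms}")
        return self.beta[:, :, self.terms.index(term)].ravel()

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]


@dataclass(frozen=True)
class EffectSummary:
    """Posterior odds-ratio summary of one term (or conditional contrast)."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    pd: float       # percent of draws > 0 (strict)
    pd_max: float   # symmetrized convention max(p, 100 - p)
    rope: float     # percent of draws in the closed ROPE interval
    significant: bool

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("CI must bracket the posterior median")


@dataclass
class _JitResult:
    draws: np.ndarray
    n_divergent: int
    mean_treedepth: float


def _encode_groups(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int, int]:
    pid, _ = pd.factorize(table["participant_id"])
    day_keys = pd.Series(list(zip(pid, table["day"])))
    did, _ = pd.factorize(day_keys)
    return pid, did, int(pid.max()) + 1, int(did.max()) + 1


def fit_cumulative_logit(table: pd.DataFrame, spec: ModelSpec) -> PosteriorDraws:
    """Sample the joint posterior of the hierarchical cumulative logit.

    ``table`` must contain the outcome (integers 1..5), every term in
    ``spec.terms``, and ``participant_id``/``day`` columns defining the
    nesting.  Runs ``spec.chains`` independent chains (seeds derived from
    ``spec.seed``); raises :class:`ConvergenceError` when split-Rhat or bulk
    ESS of any reported parameter violates the limits, unless
    ``spec.check_convergence`` is off.
    """
    if len(table) == 0:
        raise ValueError("model table is empty")
    missing = [t for t in spec.terms if t not in table.columns]
    if missing:
        raise KeyError(f"terms not in table: {missing}")
    finite = np.isfinite(table[list(spec.terms)].to_numpy(dtype=np.float64))
    row_ok = finite.all(axis=1)
    if not row_ok.all():
        dropped = table.loc[~row_ok, "participant_id"].unique()
        warnings.warn(
            f"dropping {int((~row_ok).sum())} rows from {len(dropped)} "
            "participants with missing metric predictors",
            stacklevel=2,
        )
        table = table[row_ok].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("no rows with complete predictors")
    y_raw = table[spec.outcome].to_numpy()
    if not np.isin(y_raw, [1, 2, 3, 4, 5]).all():
        raise ValueError("outcome must be integers in 1..5")
    if np.unique(y_raw).size < 2:
        raise ValueError("outcome is constant; ordinal model is unidentified")
    X = table[list(spec.terms)].to_numpy(dtype=np.float64)
    y = (y_raw - 1).astype(np.int64)
    ncut = 4
    pid, did, n_p, n_d = _encode_groups(table)
    prior = (spec.prior_sd_beta, spec.prior_sd_tau, spec.prior_sd_sigma)
    if spec.backend == "python":
        f = make_logp_grad(X, y, pid, did, n_p, n_d, ncut, *prior)
    elif spec.backend == "jit":
        cells = collapse_cells(X, y, pid, did, ncut + 1)
    else:
        raise ValueError(f"unknown backend {spec.backend!r}")
    p = X.shape[1]
    dim = p + ncut + 2 + n_p + n_d
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    beta_all = np.empty((spec.chains, spec.draws, p))
    tau_all = np.empty((spec.chains, spec.draws, ncut))
    sp_all = np.empty((spec.chains, spec.draws))
    sd_all = np.empty((spec.chains, spec.draws))
    n_div = 0
    depths = []
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        theta0 = 0.1 * rng.standard_normal(dim)
        # start thresholds spread so categories are initially occupied
        theta0[p] = -1.5
        theta0[p + 1 : p + ncut] = 0.0
        if spec.backend == "jit":
            chain_seed = int(rng.integers(2**31 - 1))
            drw, _eps, _im, ndiv_c, _acc, depth_c = nuts_chain(
                theta0, spec.warmup, spec.draws, chain_seed,
                spec.target_accept, spec.max_treedepth, 8,
                *cells, n_p, n_d, ncut, *prior,
            )
            res = _JitResult(drw, ndiv_c, depth_c)
        else:
            res = nuts_sample(
                f, theta0, spec.warmup, spec.draws, rng,
                target_accept=spec.target_accept,
                max_treedepth=spec.max_treedepth,
            )
        d = res.draws
        beta_all[c] = d[:, :p]
        raw = d[:, p : p + ncut]
        tau = np.empty_like(raw)
        tau[:, 0] = raw[:, 0]
        for j in range(1, ncut):
            tau[:, j] = tau[:, j - 1] + np.exp(raw[:, j])
        tau_all[c] = tau
        sp_all[c] = np.exp(d[:, p + ncut])
        sd_all[c] = np.exp(d[:, p + ncut + 1])
        n_div += res.n_divergent
        depths.append(res.mean_treedepth)
    draws = PosteriorDraws(
        terms=tuple(spec.terms),
        beta=beta_all,
        tau=tau_all,
        sigma_participant=sp_all,
        sigma_day=sd_all,
    )
    draws.diagnostics = _diagnose(draws, n_div, float(np.mean(depths)))
    if spec.check_convergence:
        _enforce(draws.diagnostics, spec)
    return draws


def _diagnose(draws: PosteriorDraws, n_divergent: int, mean_depth: float) -> dict:
    import arviz as az

    named = {t: draws.beta[:, :, i] for i, t in enumerate(draws.terms)}
    named["sigma_participant"] = draws.sigma_participant
    named["sigma_day"] = draws.sigma_day
    for j in range(draws.tau.shape[2]):
        named[f"tau_{j + 1}"] = draws.tau[:, :, j]
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for name, arr in named.items():
        if draws.n_chains >= 2:
            rhat[name] = float(az.rhat(arr.astype(np.float64)))
        ess[name] = float(az.ess(arr.astype(np.float64)))
    return {
        "rhat": rhat,
        "ess_bulk": ess,
        "n_divergent": n_divergent,
        "mean_treedepth": mean_depth,
    }


def _enforce(diag: dict, spec: ModelSpec) -> None:
    bad_rhat = {k: v for k, v in diag["rhat"].items() if v > spec.rhat_max}
    bad_ess = {k: v for k, v in diag["ess_bulk"].items() if v < spec.ess_min}
    if bad_rhat or bad_ess:
        raise ConvergenceError(
            f"posterior diagnostics outside limits: rhat>{spec.rhat_max}: "
            f"{bad_rhat}; ess<{spec.ess_min}: {bad_ess}"
        )
    if diag["n_divergent"] > 0.02 * spec.chains * spec.draws:
        raise ConvergenceError(
            f"{diag['n_divergent']} divergent transitions"
        )


def prob_direction(draws: np.ndarray) -> float:
    """Percent of draws strictly greater than zero."""
    draws = np.asarray(draws)
    if draws.size == 0:
        raise ValueError("need at least one draw")
    return 100.0 * float(np.mean(draws > 0))


def rope_fraction(
    draws: np.ndarray, interval: tuple[float, float] = ROPE_INTERVAL
) -> float:
    """Percent of draws inside the closed interval (default [-0.10, 0.10])."""
    lo, hi = interval
    if not lo < hi:
        raise ValueError("interval lower bound must be below upper bound")
    draws = np.asarray(draws)
    return 100.0 * float(np.mean((draws >= lo) & (draws <= hi)))


def summarize_draws(name: str, b: np.ndarray) -> EffectSummary:
    """Summarize raw log-odds draws as an odds-ratio effect."""
    b = np.asarray(b, dtype=float).ravel()
    med = float(np.median(b))
    lo, hi = np.percentile(b, [2.5, 97.5])
    pd_val = prob_direction(b)
    return EffectSummary(
        term=name,
        odds_ratio=float(np.exp(med)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        pd=pd_val,
        pd_max=max(pd_val, 100.0 - pd_val),
        rope=rope_fraction(b),
        significant=bool(np.exp(lo) > 1.0 or np.exp(hi) < 1.0),
    )


def summarize_effect(draws: PosteriorDraws, term: str) -> EffectSummary:
    """Posterior summary of one fixed-effect term."""
    return summarize_draws(term, draws.term_draws(term))


def simple_slopes(
    draws: PosteriorDraws,
    metric_term: str,
    groups: tuple[str, ...] = ("CON",) + DIAG_GROUPS,
) -> dict[str, EffectSummary]:
    """Per-group conditional effect of a metric with diagnosis interactions.

    The reference group's conditional effect is the main effect itself; for
    each other group the per-draw conditional coefficient is
    ``beta_metric + beta_metric:group``.
    """
    main = draws.term_draws(metric_term)
    out: dict[str, EffectSummary] = {}
    for g in groups:
        if g == "CON":
            cond = main
        else:
            inter = f"{metric_term}:{g}"
            if inter not in draws.terms:
                raise KeyError(f"missing interaction term {inter!r}")
            cond = main + draws.term_draws(inter)
        out[g] = summarize_draws(f"{metric_term}|{g}", cond)
    return out


def secondary_between_model(
    table: pd.DataFrame,
    predictors: list[str],
    covariate_terms: tuple[str, ...] = ("age_z", "gender", "question_code", "fd_z"),
    notable_pd: float = 90.0,
    **spec_kw,
) -> dict[str, EffectSummary]:
    """Joint model of many between-network predictors on one subgroup.

    ``table`` should already be restricted to one diagnostic group; all
    ``predictors`` (standardized between-network connectivity columns) enter
    one model together with the covariates.  Returns one summary per
    predictor; summaries whose symmetrized PD exceeds ``notable_pd`` carry a
    ``notable`` attribute (PD > 90 marks notable effects even when the
    credible interval includes 1).  Warns when the predictor block is
    ill-conditioned.
    """
    if len(table) == 0:
        raise ValueError("subgroup table is empty")
    missing = [c for c in predictors if c not in table.columns]
    if missing:
        raise KeyError(f"predictors not in table: {missing}")
    P = table[predictors].to_numpy(dtype=float)
    cond = np.linalg.cond(P - P.mean(axis=0))
    if cond > 1e4:
        warnings.warn(
            f"between-network predictor block is ill-conditioned "
            f"(condition number {cond:.3g})",
            stacklevel=2,
        )
    terms = tuple(list(covariate_terms) + list(predictors))
    spec = ModelSpec(terms=terms, **spec_kw)
    draws = fit_cumulative_logit(table, spec)
    out: dict[str, EffectSummary] = {}
    for pcol in predictors:
        s = summarize_effect(draws, pcol)
        object.__setattr__(s, "notable", bool(s.pd_max > notable_pd))
        out[pcol] = s
    return out
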