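"""Generative model for ordinal EMA responses.

Responses follow a hierarchical cumulative-logit model: for observation with
linear predictor eta,

    P(Y <= k) = logistic(tau_k - eta),   k = 1..4,  Y in {1..5},
    eta = x' beta + u_participant + u_day(participant),

with participant and day-within-participant random intercepts.  The design
vector x is assembled from participant covariates (diagnosis dummies with the
control group as reference, standardized age, gender code, standardized mean
framewise displacement), the question-type code (0 = motivation,
1 = pleasure), and optional standardized per-participant network-metric
columns with diagnosis-interaction terms.

The EMA protocol emulated is 4 prompts/day for 14 days; at every prompt the
participant answers a motivation and a pleasure question for each of the
anticipatory and consummatory constructs (4 ordinal responses per prompt).
Missingness is independent Bernoulli per prompt (missing completely at
random): a skipped prompt drops all four of its responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONSTRUCTS = ("anticipatory", "consummatory")
QUESTIONS = ("motivation", "pleasure")
DIAGNOSES = ("CON", "BD", "MDD", "SZ")


def _default_beta() -> dict[str, float]:
    # log-odds per unit (per SD for numeric terms); SZ and age positive and a
    # pleasure > motivation offset, echoing the diagnostic-group findings the
    # generator is meant to emulate
    return {
        "BD": 0.0,
        "MDD": 0.0,
        "SZ": 0.7,
        "age": 0.15,
        "gender": 0.0,
        "question": 0.3,
        "fd": 0.0,
    }


@dataclass(frozen=True)
class EMASimConfig:
    """Configuration of the ordinal EMA response generator.

    ``thresholds`` are the four ordered cutpoints on the latent logit scale;
    ``beta`` maps term names to log-odds effects (numeric predictors are
    standardized across participants before entering the linear predictor, so
    effects are per SD).  A key of the form ``"<metric>:<GROUP>"`` denotes a
    diagnosis-by-metric interaction.
    """

    thresholds: tuple[float, float, float, float] = (-2.0, -0.5, 0.5, 2.0)
    beta: dict[str, float] = field(default_factory=_default_beta)
    sigma_participant: float = 0.5
    sigma_day: float = 0.3
    prompts_per_day: int = 4
    n_days: int = 14
    miss_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        tau = np.asarray(self.thresholds, dtype=float)
        if tau.size != 4 or not np.all(np.diff(tau) > 0):
            raise ValueError("thresholds must be four strictly increasing values")
        if self.sigma_participant < 0 or self.sigma_day < 0:
            raise ValueError("random-intercept SDs must be nonnegative")
        if not 0 <= self.miss_prob < 1:
            raise ValueError("miss_prob must be in [0, 1)")
        if self.prompts_per_day < 1 or self.n_days < 1:
            raise ValueError("prompts_per_day and n_days must be positive")


def category_probs(eta: np.ndarray | float, thresholds) -> np.ndarray:
    """Category probabilities P(Y = k), k = 1..K, of the cumulative logit.

    ``eta`` may be a scalar or array; the result has one trailing axis of
    length ``len(thresholds) + 1`` and sums to 1 along it.
    """
    eta = np.asarray(eta, dtype=float)
    tau = np.asarray(thresholds, dtype=float)
    if not np.all(np.diff(tau) > 0):
        raise ValueError("thresholds must be strictly increasing")
    cum = 1.0 / (1.0 + np.exp(-(tau - eta[..., None])))
    cum = np.concatenate(
        [np.zeros(eta.shape + (1,)), cum, np.ones(eta.shape + (1,))], axis=-1
    )
    return np.diff(cum, axis=-1)


def _standardize(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def participant_design(
    covariates: pd.DataFrame, metrics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Participant-level design columns used by the generative model.

    Returns one row per participant with diagnosis dummies (``BD``, ``MDD``,
    ``SZ``; CON is the reference), standardized ``age`` and ``fd``, the raw
    ``gender`` code, and standardized copies of any metric columns, plus all
    diagnosis-by-metric interaction columns named ``"<metric>:<GROUP>"``.
    """
    cov = covariates.set_index("participant_id")
    bad = set(cov["diagnosis"]) - set(DIAGNOSES)
    if bad:
        raise ValueError(f"unknown diagnosis values: {sorted(bad)}")
    design = pd.DataFrame(index=cov.index)
    for g in ("BD", "MDD", "SZ"):
        design[g] = (cov["diagnosis"] == g).astype(float)
    design["age"] = _standardize(cov["age"].astype(float))
    design["gender"] = cov["gender"].astype(float)
    design["fd"] = _standardize(cov["mean_fd"].astype(float))
    if metrics is not None:
        met = metrics.set_index("participant_id").reindex(cov.index)
        if met.isna().any().any():
            missing = met.index[met.isna().any(axis=1)].tolist()
            raise ValueError(f"metrics missing for participants: {missing}")
        for col in met.columns:
            design[col] = _standardize(met[col].astype(float))
            for g in ("BD", "MDD", "SZ"):
                design[f"{col}:{g}"] = design[col] * design[g]
    return design


def simulate_ema(
    covariates: pd.DataFrame,
    cfg: EMASimConfig,
    metrics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw a long-format EMA response table from the generative model.

    ``covariates`` needs columns ``participant_id, diagnosis, age, gender,
    mean_fd``; ``metrics`` (optional) is participant-level with a
    ``participant_id`` column and one column per network metric referenced by
    ``cfg.beta``.  Output columns: ``participant_id, day, prompt, construct,
    question, response`` with ``day`` in 1..n_days, ``prompt`` in
    1..prompts_per_day, and ``response`` in 1..5.  Deterministic under
    ``cfg.seed``.
    """
    design = participant_design(covariates, metrics)
    q_beta = cfg.beta.get("question", 0.0)
    base = np.zeros(len(design))
    for name, b in cfg.beta.items():
        if name == "question" or b == 0.0:
            continue
        if name not in design.columns:
            raise KeyError(f"beta term {name!r} not resolvable from covariates/metrics")
        base += b * design[name].to_numpy()

    rng = np.random.default_rng(cfg.seed)
    tau = np.asarray(cfg.thresholds, dtype=float)
    rows: list[tuple] = []
    for pid, eta_p in zip(design.index, base):
        u_p = cfg.sigma_participant * rng.standard_normal()
        for day in range(1, cfg.n_days + 1):
            u_d = cfg.sigma_day * rng.standard_normal()
            for prompt in range(1, cfg.prompts_per_day + 1):
                missed = rng.random() < cfg.miss_prob
                # draw the full prompt regardless so the random stream (and
                # thus all other responses) is invariant to the miss pattern
                for construct in CONSTRUCTS:
                    for q_code, question in enumerate(QUESTIONS):
                        eta = eta_p + q_beta * q_code + u_p + u_d
                        cum = 1.0 / (1.0 + np.exp(-(tau - eta)))
                        resp = 1 + int(np.sum(rng.random() > cum))
                        if not missed:
                            rows.append(
                                (pid, day, prompt, construct, question, resp)
                            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "day",
            "prompt",
            "construct",
            "question",
            "response",
        ],
    )
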