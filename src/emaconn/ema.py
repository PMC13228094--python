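"""EMA data cleaning and model-table assembly.

Responsibilities: the per-participant compliance filter (respond to at least
33% of issued prompts), coding of construct and question type, and the join
of observation-level EMA rows to participant-level covariates and network
metrics with the standardization and dummy/interaction coding the ordinal
models expect.

Question-type coding: 0 = motivation ("How interested are you in this
activity?"), 1 = pleasure ("How much are you enjoying this activity?"), with
the anticipatory analogues coded the same way.
"""

from __future__ import annotations

import pandas as pd

from emaconn.emasim import CONSTRUCTS, QUESTIONS

#: Map from the literal EMA question text to (construct, question) codes.
QUESTION_TEXT = {
    "How much are you enjoying this activity?": ("consummatory", "pleasure"),
    "How interested are you in this activity?": ("consummatory", "motivation"),
    "How much do you think you will enjoy this activity?": (
        "anticipatory",
        "pleasure",
    ),
    "How interested do you think you will be in this activity?": (
        "anticipatory",
        "motivation",
    ),
}

QUESTION_CODE = {"motivation": 0, "pleasure": 1}


def compliance_filter(
    records: pd.DataFrame,
    prompts_issued: dict[str, int] | int,
    threshold: float = 0.33,
) -> tuple[list[str], list[str]]:
    """Split participants by the responded/issued >= threshold rule.

    A prompt counts as responded when at least one record exists for its
    (day, prompt) slot.  ``prompts_issued`` is either one count applying to
    every participant or a per-participant mapping; every participant keyed
    there is classified, including those with zero responses.  Records for a
    participant not keyed in a mapping raise.
    """
    if isinstance(prompts_issued, int):
        if prompts_issued <= 0:
            raise ValueError("prompts_issued must be positive")
        issued = {p: prompts_issued for p in records["participant_id"].unique()}
    else:
        issued = dict(prompts_issued)
        if any(v <= 0 for v in issued.values()):
            raise ValueError("prompts_issued must be positive")
        unknown = set(records["participant_id"].unique()) - set(issued)
        if unknown:
            raise ValueError(
                f"records contain unknown participants: {sorted(unknown)}"
            )
    responded = (
        records.drop_duplicates(["participant_id", "day", "prompt"])
        .groupby("participant_id")
        .size()
    )
    included, excluded = [], []
    for pid, n_issued in issued.items():
        frac = responded.get(pid, 0) / n_issued
        (included if frac >= threshold else excluded).append(pid)
    return included, excluded


def encode_observations(records: pd.DataFrame) -> pd.DataFrame:
    """Validate responses and attach the numeric question-type code.

    ``records`` may carry a literal ``question_text`` column instead of the
    ``construct``/``question`` pair; the text is mapped through
    :data:`QUESTION_TEXT`.  Responses outside 1..5 raise with a row report.
    """
    out = records.copy()
    if "question_text" in out.columns and "question" not in out.columns:
        decoded = out["question_text"].map(QUESTION_TEXT)
        if decoded.isna().any():
            bad = out.loc[decoded.isna(), "question_text"].unique().tolist()
            raise ValueError(f"unrecognized question text: {bad}")
        out["construct"] = decoded.str[0]
        out["question"] = decoded.str[1]
        out = out.drop(columns=["question_text"])
    bad_rows = ~out["response"].isin([1, 2, 3, 4, 5])
    if bad_rows.any():
        raise ValueError(
            "responses outside 1..5 at rows "
            f"{out.index[bad_rows].tolist()[:20]}"
        )
    if not out["construct"].isin(CONSTRUCTS).all():
        raise ValueError("construct must be anticipatory or consummatory")
    if not out["question"].isin(QUESTIONS).all():
        raise ValueError("question must be motivation or pleasure")
    out["question_code"] = out["question"].map(QUESTION_CODE).astype(int)
    return out


def decode_observations(encoded: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`encode_observations` (drops the numeric code)."""
    return encoded.drop(columns=["question_code"])


def split_constructs(encoded: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """One analysis table per construct (anticipatory, consummatory)."""
    return {
        c: encoded[encoded["construct"] == c].reset_index(drop=True)
        for c in CONSTRUCTS
    }


def _zscore_participant_level(
    table: pd.DataFrame, col: str, per_participant: pd.Series
) -> pd.Series:
    """Standardize using one value per participant, broadcast to rows."""
    mu = per_participant.mean()
    sd = per_participant.std(ddof=0)
    z = (per_participant - mu) / sd if sd > 0 else per_participant - mu
    return table["participant_id"].map(z)


def build_model_table(
    encoded: pd.DataFrame,
    covariates: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    metric_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Join observations to covariates/metrics and code the design columns.

    Adds diagnosis dummies (``BD``, ``MDD``, ``SZ``; CON reference),
    participant-level standardized ``age_z`` and ``fd_z``, the ``gender``
    code, standardized metric columns (suffix ``_z``) and their
    diagnosis-interaction columns (``<metric>_z:BD`` etc.).  Standardization
    uses one value per participant so participants with more observations do
    not dominate the scale.  Participants lacking covariates (or metrics,
    when metrics are requested) are dropped with a log entry in the returned
    table's ``attrs["dropped"]``.
    """
    cov = covariates.set_index("participant_id")
    pids = encoded["participant_id"].unique()
    have = [p for p in pids if p in cov.index]
    dropped = sorted(set(pids) - set(have))
    if metrics is not None:
        met = metrics.set_index("participant_id")
        cols = metric_cols or [c for c in met.columns]
        missing_met = [p for p in have if p not in met.index]
        dropped += missing_met
        have = [p for p in have if p in met.index]
    table = encoded[encoded["participant_id"].isin(have)].copy()
    cov = cov.loc[have]
    diag = table["participant_id"].map(cov["diagnosis"])
    for g in ("BD", "MDD", "SZ"):
        table[g] = (diag == g).astype(float)
    table["age_z"] = _zscore_participant_level(table, "age", cov["age"])
    table["fd_z"] = _zscore_participant_level(table, "mean_fd", cov["mean_fd"])
    table["gender"] = table["participant_id"].map(cov["gender"]).astype(float)
    if metrics is not None:
        met = met.loc[have]
        for c in cols:
            zc = f"{c}_z"
            table[zc] = _zscore_participant_level(table, c, met[c])
            for g in ("BD", "MDD", "SZ"):
                table[f"{zc}:{g}"] = table[zc] * table[g]
    table = table.reset_index(drop=True)
    table.attrs["dropped"] = dropped
    return table
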