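"""End-to-end pipeline: simulate -> map networks -> metrics -> EMA -> fit.

One :class:`RunConfig` drives every stage; all randomness derives from one
master seed, and a manifest records the derived stage seeds plus the row and
participant counts surviving each filter, so a run can be reproduced
byte-identically.  Every analysis constant (top-connection fraction 0.05,
30 mm^2 patch rule, the 1-25% tie-density grid with the first 10 averaged,
the 33% compliance threshold, the 375-frame inclusion rule, and the
[-0.10, 0.10] ROPE) is surfaced as a named config key with that default.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from emaconn.bold import BOLDSimConfig
from emaconn.cohort import CohortBundle, simulate_cohort
from emaconn.ema import build_model_table, compliance_filter, encode_observations, split_constructs
from emaconn.emasim import EMASimConfig
from emaconn.mapping import (
    assign_vertices,
    clean_timeseries,
    parcellate,
    remove_small_patches,
    vertex_connectivity,
)
from emaconn.metrics import metrics_table
from emaconn.ordinal import (
    ModelSpec,
    fit_cumulative_logit,
    simple_slopes,
    summarize_effect,
)

log = logging.getLogger("emaconn")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    n_per_group: tuple[int, int, int, int] = (40, 38, 37, 29)
    surface_shape: tuple[int, int] = (40, 40)
    n_networks: int = 8
    swap_frac: float = 0.1
    bold: dict = field(default_factory=dict)
    ema: dict = field(default_factory=dict)
    top_fraction: float = 0.05
    min_patch_area: float = 30.0
    min_frames: int = 375
    compliance_threshold: float = 0.33
    clean: bool = True
    band: tuple[float, float] = (0.01, 0.1)
    fits: list[dict] = field(default_factory=list)
    sampler: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.n_per_group = tuple(cfg.n_per_group)  # type: ignore[assignment]
        cfg.surface_shape = tuple(cfg.surface_shape)  # type: ignore[assignment]
        cfg.band = tuple(cfg.band)  # type: ignore[assignment]
        cfg.validate()
        return cfg

    def validate(self) -> None:
        from emaconn.templates import DEFAULT_NETWORKS

        if self.n_networks < 2:
            raise ValueError("n_networks must be >= 2")
        if self.n_networks <= len(DEFAULT_NETWORKS):
            valid = set(DEFAULT_NETWORKS[: self.n_networks])
        else:
            valid = {f"NET{k}" for k in range(self.n_networks)}
        for fit in self.fits:
            kind = fit.get("kind")
            if kind not in {"diagnostic", "connectivity", "extent", "secondary"}:
                raise ValueError(f"unknown fit kind {kind!r}")
            if kind in {"connectivity", "extent"}:
                net = fit.get("network")
                if net not in valid:
                    raise ValueError(
                        f"fit references unknown network {net!r}; valid: {sorted(valid)}"
                    )
            if fit.get("construct") not in {"anticipatory", "consummatory"}:
                raise ValueError("fit construct must be anticipatory|consummatory")

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _map_participants(bundle: CohortBundle, cfg: RunConfig) -> dict:
    """Template-match every participant; returns pid -> (ts, assignment, parcellation)."""
    out = {}
    for pid, ts in bundle.timeseries.items():
        if cfg.clean:
            ts = clean_timeseries(ts, band=cfg.band)
        conn = vertex_connectivity(ts)
        assignment = assign_vertices(conn, bundle.templates, fraction=cfg.top_fraction)
        assignment = remove_small_patches(
            assignment, bundle.surface, min_area=cfg.min_patch_area
        )
        parcellation = parcellate(assignment, bundle.surface)
        out[pid] = (ts, assignment, parcellation)
    return out


def _fit_spec(fit: dict, cfg: RunConfig, fit_seed: int) -> ModelSpec:
    kw = dict(cfg.sampler)
    kw["seed"] = fit_seed
    kind = fit["kind"]
    if kind == "diagnostic":
        return ModelSpec.diagnostic(**kw)
    if kind == "connectivity":
        return ModelSpec.connectivity(fit["network"], **kw)
    if kind == "extent":
        return ModelSpec.extent(fit["network"], **kw)
    raise ValueError(f"unsupported fit kind {kind!r}")


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the run manifest (also written to disk).

    Stage order: simulate cohort, map networks per participant, build the
    metric table with frame QC, compliance-filter and encode the EMA records,
    assemble model tables, run the requested fits, and write Table-4-shaped
    effect TSVs (plus Table-5-shaped simple-slopes TSVs for models with
    interactions).  A stage failure leaves a ``FAILED`` marker naming the
    stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "version": _pkg_version(),
        "seed": cfg.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        bold = BOLDSimConfig(**cfg.bold) if cfg.bold else BOLDSimConfig()
        ema_kw = dict(cfg.ema)
        if "thresholds" in ema_kw:
            ema_kw["thresholds"] = tuple(ema_kw["thresholds"])
        ema = EMASimConfig(**ema_kw) if ema_kw else EMASimConfig()
        bundle = simulate_cohort(
            cfg.n_per_group,
            surface_shape=cfg.surface_shape,
            n_networks=cfg.n_networks,
            swap_frac=cfg.swap_frac,
            bold=bold,
            ema=ema,
            seed=cfg.seed,
        )
        manifest["stages"]["simulate"] = {
            "participants": len(bundle.participant_ids),
            "ema_rows": int(len(bundle.ema)),
            "seeds": bundle.manifest["seeds"],
        }

        stage = "map_networks"
        mapped = _map_participants(bundle, cfg)
        manifest["stages"]["map_networks"] = {
            "participants": len(mapped),
            "parcels": {p: mapped[p][2].n_parcels for p in mapped},
        }

        stage = "metrics"
        mean_fd = dict(
            zip(bundle.covariates["participant_id"], bundle.covariates["mean_fd"])
        )
        mtable, qc = metrics_table(mapped, mean_fd=mean_fd, min_frames=cfg.min_frames)
        mtable.to_csv(out / "metrics.tsv", sep="\t", index=False)
        (out / "qc_report.json").write_text(json.dumps(qc, indent=2))
        manifest["stages"]["metrics"] = {
            "included": qc["included"],
            "excluded": len(qc["excluded"]),
        }

        stage = "ema"
        n_issued = (
            bundle.manifest["configs"]["ema"]["n_days"]
            * bundle.manifest["configs"]["ema"]["prompts_per_day"]
        )
        included, excluded = compliance_filter(
            bundle.ema, n_issued, threshold=cfg.compliance_threshold
        )
        records = bundle.ema[bundle.ema["participant_id"].isin(included)]
        encoded = encode_observations(records)
        tables = split_constructs(encoded)
        metric_cols = [c for c in mtable.columns if c not in ("participant_id", "mean_fd")]
        model_tables = {
            c: build_model_table(
                t, bundle.covariates, metrics=mtable, metric_cols=metric_cols
            )
            for c, t in tables.items()
        }
        manifest["stages"]["ema"] = {
            "compliant": len(included),
            "noncompliant": len(excluded),
            "rows": {c: int(len(t)) for c, t in model_tables.items()},
        }

        stage = "fit"
        fit_root = np.random.SeedSequence(cfg.seed).spawn(1)[0].spawn(
            max(len(cfg.fits), 1)
        )
        fit_results = []
        for i, fit in enumerate(cfg.fits):
            fit_seed = int(fit_root[i].generate_state(1)[0] % (2**31))
            spec = _fit_spec(fit, cfg, fit_seed)
            table = model_tables[fit["construct"]]
            draws = fit_cumulative_logit(table, spec)
            rows = [summarize_effect(draws, t) for t in spec.terms]
            name = f"{fit['kind']}_{fit.get('network', 'all')}_{fit['construct']}"
            eff = pd.DataFrame(
                {
                    "term": [r.term for r in rows],
                    "odds_ratio": [r.odds_ratio for r in rows],
                    "ci_low": [r.ci_low for r in rows],
                    "ci_high": [r.ci_high for r in rows],
                    "pd": [r.pd for r in rows],
                    "pd_max": [r.pd_max for r in rows],
                    "rope": [r.rope for r in rows],
                    "significant": [r.significant for r in rows],
                }
            )
            eff.to_csv(out / f"effects_{name}.tsv", sep="\t", index=False)
            slope_terms = sorted(
                {t.split(":")[0] for t in spec.terms if ":" in t}
            )
            for metric_term in slope_terms:
                ss = simple_slopes(draws, metric_term)
                srows = pd.DataFrame(
                    {
                        "group": list(ss),
                        "odds_ratio": [s.odds_ratio for s in ss.values()],
                        "ci_low": [s.ci_low for s in ss.values()],
                        "ci_high": [s.ci_high for s in ss.values()],
                        "significant": [s.significant for s in ss.values()],
                    }
                )
                srows.to_csv(
                    out / f"slopes_{name}_{metric_term.replace(':', '_')}.tsv",
                    sep="\t",
                    index=False,
                )
            fit_results.append(
                {"fit": name, "diagnostics": draws.diagnostics, "seed": fit_seed}
            )
        manifest["stages"]["fit"] = fit_results
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def report(results_dir: str | Path) -> str:
    """Render the fitted effect tables as a human-readable summary.

    Terms whose 95% credible interval for the odds ratio excludes 1 are
    marked significant (``**`` around the estimate), mirroring the reporting
    rule of the effect tables.
    """
    res = Path(results_dir)
    effect_files = sorted(res.glob("effects_*.tsv"))
    lines = []
    if not effect_files:
        return "report: zero fits found in " + str(res)
    for f in effect_files:
        tab = pd.read_csv(f, sep="\t")
        lines.append(f"== {f.stem[len('effects_'):]} ==")
        for _, r in tab.iterrows():
            est = f"{r.odds_ratio:.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}]"
            if bool(r.significant):
                est = f"**{est}**"
            lines.append(
                f"  {r.term:<28s} e^b = {est}  PD = {r.pd_max:.1f}%  "
                f"ROPE = {r.rope:.1f}%"
            )
    for f in sorted(res.glob("slopes_*.tsv")):
        tab = pd.read_csv(f, sep="\t")
        lines.append(f"== {f.stem} (conditional effects) ==")
        for _, r in tab.iterrows():
            est = f"{r.odds_ratio:.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}]"
            if bool(r.significant):
                est = f"**{est}**"
            lines.append(f"  {r.group:<6s} {est}")
    return "\n".join(lines)


def _pkg_version() -> str:
    import emaconn

    return emaconn.__version__
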