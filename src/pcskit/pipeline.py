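"""End-to-end orchestration: simulate -> fc -> score -> analyses -> report.

Stages hand data off through plain files under one output directory so every
intermediate is inspectable, and the fc stage re-reads the simulated time
series from disk through the same readers a real cohort would use.  All
randomness funnels through the seed in the simulation config; re-running a
stage with unchanged inputs reproduces its outputs byte for byte (the run
manifest records a timestamp, result tables do not).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome_fc import EdgeVector, compute_fc, edge_index_pairs, read_timeseries, vectorize_fc, write_timeseries
from .exceptions import ConfigError, PCSKitError
from .pcs_scoring import CSSTemplate, batch_score, load_template, save_template
from .stats_models import (
    AssociationResult,
    ModerationResult,
    ancova_group_compare,
    bonferroni_adjust,
    compute_change_scores,
    fit_association,
    fit_moderation,
    tertile_split,
)
from .synthetic_data import (
    COG_SUBSCALES,
    CovariateParams,
    OutcomeParams,
    SimulationConfig,
    TemplateSpec,
    alternative_template,
    generate_clinical_cohort,
    generate_cohort,
)

ALL_STAGES = (
    "simulate",
    "fc",
    "score",
    "baseline",
    "longitudinal",
    "sensitivity",
    "exploratory",
    "report",
)

ALTERNATIVE_TEMPLATES = ("anxiety_like", "bipolar_like", "scz_like")

EMOTIONAL = ["anxiety", "depression"]


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    for key, cls in (
        ("template_spec", TemplateSpec),
        ("outcome_params", OutcomeParams),
        ("covariate_params", CovariateParams),
    ):
        if key in data and isinstance(data[key], dict):
            data[key] = cls(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in data[key].items()
            })
    return SimulationConfig(**data)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML/JSON simulation config."""
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    return config_from_dict(data)


def config_hash(config: SimulationConfig) -> str:
    """Stable hash of the canonical JSON serialization."""
    def default(o):
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))

    blob = json.dumps(config_to_dict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[str] = field(default_factory=list)
    row_counts: dict[str, int] = field(default_factory=dict)
    formulas: list[str] = field(default_factory=list)
    convergence: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _register(manifest: RunManifest, out_dir: Path, *paths: Path) -> None:
    for p in paths:
        rel = str(p.relative_to(out_dir))
        if rel not in manifest.outputs:
            manifest.outputs.append(rel)


# ---------------------------------------------------------------------------
# Result flattening
# ---------------------------------------------------------------------------

def _assoc_row(block: str, template_id: str, r: AssociationResult) -> dict:
    return {
        "block": block,
        "template_id": template_id,
        "outcome": r.outcome,
        "predictor": r.predictor,
        "moderator": "",
        "engine": r.engine,
        "beta": r.beta,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "p": r.p,
        "p_adjusted": r.p_adjusted,
        "significant": r.significant,
        "delta_r2": np.nan,
        "slope_low": np.nan,
        "slope_high": np.nan,
        "n_obs": r.n_obs,
        "converged": r.converged,
    }


def _mod_row(block: str, template_id: str, r: ModerationResult) -> dict:
    return {
        "block": block,
        "template_id": template_id,
        "outcome": r.outcome,
        "predictor": r.predictor,
        "moderator": r.moderator,
        "engine": r.engine,
        "beta": r.interaction_beta,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "p": r.p,
        "p_adjusted": r.p_adjusted,
        "significant": r.significant,
        "delta_r2": r.delta_r2,
        "slope_low": r.slope_low.slope,
        "slope_high": r.slope_high.slope,
        "n_obs": r.n_obs,
        "converged": r.converged,
    }


def _write_tidy(rows: list[dict], path: Path) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise ConfigError(
            f"missing input {path.name}; run the '{producing_stage}' stage first"
        )
    return path


def _stage_simulate(config: SimulationConfig, out: Path, manifest: RunManifest) -> None:
    cohort = generate_cohort(config, with_timeseries=True)
    clinical = generate_clinical_cohort(config, with_timeseries=True)

    (out / "timeseries").mkdir(exist_ok=True)
    (out / "templates").mkdir(exist_ok=True)
    for ts in cohort.timeseries + clinical.timeseries:
        write_timeseries(ts, out / "timeseries" / f"{ts.subject_id}.tsv")

    save_template(cohort.template, out / "templates" / "mdd_like.tsv")
    for i, name in enumerate(ALTERNATIVE_TEMPLATES):
        save_template(
            alternative_template(config, name, i), out / "templates" / f"{name}.tsv"
        )

    cohort.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    clinical.phenotypes.to_csv(out / "clinical_phenotypes.csv", index=False)
    pd.concat([cohort.repair_log, clinical.repair_log]).to_csv(
        out / "repair_log.csv", index=False
    )

    manifest.row_counts["phenotype_rows"] = len(cohort.phenotypes)
    manifest.row_counts["clinical_rows"] = len(clinical.phenotypes)
    manifest.row_counts["subjects"] = cohort.truth.shape[0]
    _register(
        manifest,
        out,
        out / "phenotypes.csv",
        out / "truth.csv",
        out / "clinical_phenotypes.csv",
        out / "repair_log.csv",
        out / "templates" / "mdd_like.tsv",
    )


def _stage_fc(config: SimulationConfig, out: Path, manifest: RunManifest, strict: bool) -> None:
    ts_dir = _require(out / "timeseries", "simulate")
    policy = "strict" if strict else "lenient"
    rows = []
    subject_ids = []
    for path in sorted(ts_dir.glob("*.tsv")):
        ts = read_timeseries(path)
        edges = vectorize_fc(compute_fc(ts, degenerate_policy=policy))
        rows.append(edges.values)
        subject_ids.append(ts.subject_id)
    if not rows:
        raise ConfigError("no time-series files found; run the 'simulate' stage first")
    n_edges = rows[0].size
    df = pd.DataFrame(
        np.vstack(rows), columns=[f"e{k:05d}" for k in range(n_edges)]
    )
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(out / "edges.csv", index=False, float_format="%.8g")
    manifest.row_counts["fc_subjects"] = len(df)
    _register(manifest, out, out / "edges.csv")


def _load_edges(out: Path) -> list[EdgeVector]:
    df = pd.read_csv(_require(out / "edges.csv", "fc"))
    values = df.drop(columns="subject_id").to_numpy(dtype=float)
    p = int(round((1 + np.sqrt(1 + 8 * values.shape[1])) / 2))
    pairs = edge_index_pairs(p)
    return [
        EdgeVector(subject_id=sid, values=row, edge_index=pairs)
        for sid, row in zip(df["subject_id"], values)
    ]


def _load_templates(out: Path) -> list[CSSTemplate]:
    tdir = _require(out / "templates", "simulate")
    return [load_template(p) for p in sorted(tdir.glob("*.tsv"))]


def _stage_score(config: SimulationConfig, out: Path, manifest: RunManifest, strict: bool) -> None:
    edges = _load_edges(out)
    templates = _load_templates(out)
    scores = batch_score(edges, templates, strict=strict)
    scores.to_csv(out / "pcs.csv", index=False, float_format="%.10g")
    manifest.row_counts["pcs_rows"] = len(scores)
    _register(manifest, out, out / "pcs.csv")


def _scored_phenotypes(out: Path, which: str = "phenotypes") -> pd.DataFrame:
    """Phenotype table with one pcs_<template> column per template."""
    pheno = pd.read_csv(_require(out / f"{which}.csv", "simulate"))
    scores = pd.read_csv(_require(out / "pcs.csv", "score"))
    wide = scores.pivot(index="subject_id", columns="template_id", values="pcs")
    wide.columns = [f"pcs_{c}" for c in wide.columns]
    return pheno.merge(wide.reset_index(), on="subject_id", how="left")


PRIMARY_PCS = "pcs_synthetic_mdd_like_p{p}"


def _pcs_col(config: SimulationConfig) -> str:
    return PRIMARY_PCS.format(p=config.atlas_p)


def _stage_baseline(config: SimulationConfig, out: Path, manifest: RunManifest) -> None:
    pheno = _scored_phenotypes(out)
    base = pheno[pheno["timepoint"] == "baseline"]
    pcs = _pcs_col(config)
    rows = []

    # stress -> emotional symptoms / cognition (age + sex, family intercept)
    emo = [fit_association(base, o, "stress", ["age", "sex"]) for o in EMOTIONAL]
    cog = [fit_association(base, o, "stress", ["age", "sex"]) for o in COG_SUBSCALES]
    rows += [_assoc_row("baseline_stress", "", r) for r in bonferroni_adjust(emo, 2)]
    rows += [_assoc_row("baseline_stress", "", r) for r in bonferroni_adjust(cog, 6)]

    # PCS -> outcomes (age + sex + motion)
    emo = [fit_association(base, o, pcs, ["age", "sex", "mean_fd"]) for o in EMOTIONAL]
    cog = [fit_association(base, o, pcs, ["age", "sex", "mean_fd"]) for o in COG_SUBSCALES]
    rows += [_assoc_row("baseline_pcs", pcs, r) for r in bonferroni_adjust(emo, 2)]
    rows += [_assoc_row("baseline_pcs", pcs, r) for r in bonferroni_adjust(cog, 6)]

    # moderation: stress x PCS
    emo_m = [
        fit_moderation(base, o, "stress", pcs, ["age", "sex", "mean_fd"])
        for o in EMOTIONAL
    ]
    cog_m = [
        fit_moderation(base, o, "stress", pcs, ["age", "sex", "mean_fd"])
        for o in COG_SUBSCALES
    ]
    rows += [_mod_row("baseline_moderation", pcs, r) for r in bonferroni_adjust(emo_m, 2)]
    rows += [_mod_row("baseline_moderation", pcs, r) for r in bonferroni_adjust(cog_m, 6)]

    df = _write_tidy(rows, out / "baseline_models.tsv")
    manifest.row_counts["baseline_models"] = len(df)
    manifest.convergence["baseline_nonconverged"] = int((~df["converged"]).sum())
    manifest.formulas.append(
        "baseline: outcome ~ predictor(+moderator) + covariates + (1 | family_id)"
    )
    _register(manifest, out, out / "baseline_models.tsv")


def _stage_longitudinal(config: SimulationConfig, out: Path, manifest: RunManifest) -> None:
    pheno = _scored_phenotypes(out)
    pcs = _pcs_col(config)
    change = compute_change_scores(pheno)
    change.table.to_csv(out / "change_scores.csv", index=False, float_format="%.10g")

    ch = change.table
    rows = []
    d_emo = [f"delta_{o}" for o in EMOTIONAL]
    d_cog = [f"delta_{c}" for c in COG_SUBSCALES]

    emo = [
        fit_association(ch, o, "delta_stress", ["sex", "followup_duration"])
        for o in d_emo
    ]
    cog = [
        fit_association(ch, o, "delta_stress", ["sex", "followup_duration"])
        for o in d_cog
    ]
    rows += [_assoc_row("change_stress", "", r) for r in bonferroni_adjust(emo, 2)]
    rows += [_assoc_row("change_stress", "", r) for r in bonferroni_adjust(cog, 6)]

    emo_m = [
        fit_moderation(ch, o, "delta_stress", pcs, ["followup_duration", "sex", "mean_fd"])
        for o in d_emo
    ]
    cog_m = [
        fit_moderation(ch, o, "delta_stress", pcs, ["followup_duration", "sex", "mean_fd"])
        for o in d_cog
    ]
    rows += [_mod_row("change_moderation", pcs, r) for r in bonferroni_adjust(emo_m, 2)]
    rows += [_mod_row("change_moderation", pcs, r) for r in bonferroni_adjust(cog_m, 6)]

    # baseline PCS -> follow-up outcomes (baseline covariates)
    fup = pheno[pheno["timepoint"] == "followup"].drop(
        columns=["age", "sex", "mean_fd"], errors="ignore"
    )
    base_cov = pheno[pheno["timepoint"] == "baseline"][
        ["subject_id", "age", "sex", "mean_fd", "family_id"]
    ]
    fup = fup.drop(columns=["family_id"], errors="ignore").merge(base_cov, on="subject_id")
    emo = [fit_association(fup, o, pcs, ["age", "sex", "mean_fd"]) for o in EMOTIONAL]
    cog = [fit_association(fup, o, pcs, ["age", "sex", "mean_fd"]) for o in COG_SUBSCALES]
    rows += [_assoc_row("prospective_pcs", pcs, r) for r in bonferroni_adjust(emo, 2)]
    rows += [_assoc_row("prospective_pcs", pcs, r) for r in bonferroni_adjust(cog, 6)]

    df = _write_tidy(rows, out / "longitudinal_models.tsv")
    manifest.row_counts["change_rows"] = len(ch)
    manifest.row_counts["change_excluded"] = change.n_excluded
    manifest.row_counts["longitudinal_models"] = len(df)
    manifest.convergence["longitudinal_nonconverged"] = int((~df["converged"]).sum())
    manifest.formulas.append(
        "longitudinal: delta_outcome ~ delta_stress(x pcs) + covariates + (1 | family_id)"
    )
    _register(manifest, out, out / "change_scores.csv", out / "longitudinal_models.tsv")


def _stage_sensitivity(config: SimulationConfig, out: Path, manifest: RunManifest) -> None:
    pheno = _scored_phenotypes(out)
    change = compute_change_scores(pheno).table
    fup = pheno[pheno["timepoint"] == "followup"].drop(
        columns=["age", "sex", "mean_fd"], errors="ignore"
    )
    base_cov = pheno[pheno["timepoint"] == "baseline"][
        ["subject_id", "age", "sex", "mean_fd", "family_id"]
    ]
    fup = fup.drop(columns=["family_id"], errors="ignore").merge(base_cov, on="subject_id")

    templates = [_pcs_col(config)] + [f"pcs_{n}" for n in ALTERNATIVE_TEMPLATES]
    rows = []
    for tpl in templates:
        for o in EMOTIONAL:
            mod = fit_moderation(
                change,
                f"delta_{o}",
                "delta_stress",
                tpl,
                ["followup_duration", "sex", "mean_fd"],
            )
            rows.append(_mod_row("sensitivity_moderation", tpl, mod))
            assoc = fit_association(fup, o, tpl, ["age", "sex", "mean_fd"])
            rows.append(_assoc_row("sensitivity_prospective", tpl, assoc))
    df = _write_tidy(rows, out / "sensitivity_models.tsv")
    manifest.row_counts["sensitivity_models"] = len(df)
    _register(manifest, out, out / "sensitivity_models.tsv")


def _stage_exploratory(config: SimulationConfig, out: Path, manifest: RunManifest) -> None:
    clin = _scored_phenotypes(out, which="clinical_phenotypes")
    pcs = _pcs_col(config)
    rows = []

    # clinical arm: plain regressions, no family clustering
    rows.append(
        _assoc_row(
            "clinical", "", fit_association(clin, "depression", "stress", ["sex", "age"], engine="ols")
        )
    )
    rows.append(
        _assoc_row(
            "clinical",
            pcs,
            fit_association(clin, "depression", pcs, ["sex", "age", "mean_fd"], engine="ols"),
        )
    )
    rows.append(
        _mod_row(
            "clinical_moderation",
            pcs,
            fit_moderation(clin, "depression", "stress", pcs, ["sex", "age", "mean_fd"], engine="ols"),
        )
    )

    # balanced vulnerability subgroups
    labels, bounds = tertile_split(clin[pcs].to_numpy())
    clin = clin.assign(pcs_group=labels)
    for grp in ("low", "medium", "high"):
        sub = clin[clin["pcs_group"] == grp]
        rows.append(
            _assoc_row(
                f"subgroup_{grp}",
                pcs,
                fit_association(sub, "depression", "stress", ["sex", "age"], engine="ols"),
            )
        )

    df = _write_tidy(rows, out / "exploratory_models.tsv")

    # ANCOVA: community vs clinical PCS after age/sex adjustment
    pheno = _scored_phenotypes(out)
    base = pheno[pheno["timepoint"] == "baseline"][["subject_id", "age", "sex", pcs]]
    both = pd.concat(
        [
            base.assign(cohort="community"),
            clin[["subject_id", "age", "sex", pcs]].assign(cohort="clinical"),
        ],
        ignore_index=True,
    )
    anc = ancova_group_compare(both, pcs, "cohort", ["age", "sex"])
    pd.DataFrame(
        [
            {
                "response": anc.response,
                "group": anc.group,
                "f_stat": anc.f_stat,
                "p": anc.p,
                "df_between": anc.df_between,
                "df_resid": anc.df_resid,
                "n_obs": anc.n_obs,
                **{f"adj_mean_{k}": v for k, v in anc.adjusted_means.items()},
            }
        ]
    ).to_csv(out / "ancova.tsv", sep="\t", index=False, float_format="%.10g")

    manifest.row_counts["exploratory_models"] = len(df)
    manifest.row_counts["subgroup_sizes_max_diff"] = int(
        max(bounds["sizes"].values()) - min(bounds["sizes"].values())
    )
    _register(manifest, out, out / "exploratory_models.tsv", out / "ancova.tsv")


def _stage_report(config: SimulationConfig, out: Path, manifest: RunManifest) -> None:
    n_subjects = manifest.row_counts.get("subjects")
    if n_subjects is None and (out / "truth.csv").exists():
        n_subjects = len(pd.read_csv(out / "truth.csv"))
    n_change = manifest.row_counts.get("change_rows")
    if n_change is None and (out / "change_scores.csv").exists():
        n_change = len(pd.read_csv(out / "change_scores.csv"))
    lines = [
        "# Pipeline summary",
        "",
        f"- config hash: {manifest.config_hash}",
        f"- seed: {config.seed}",
        f"- subjects: {n_subjects if n_subjects is not None else 'n/a'}",
        f"- change rows: {n_change if n_change is not None else 'n/a'}",
        "",
    ]
    for name in ("baseline_models", "longitudinal_models", "sensitivity_models", "exploratory_models"):
        path = out / f"{name}.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            lines.append(f"## {name}")
            sig = df[df.get("significant") == True]  # noqa: E712
            lines.append(f"- models fitted: {len(df)}")
            if "significant" in df:
                lines.append(f"- significant after correction: {len(sig)}")
            for _, r in sig.iterrows():
                what = f"{r['outcome']} ~ {r['predictor']}"
                if isinstance(r.get("moderator"), str) and r["moderator"]:
                    what += f" x {r['moderator']}"
                lines.append(
                    f"  - [{r['block']}] {what}: beta={r['beta']:.3f} "
                    f"(95% CI {r['ci_low']:.3f}, {r['ci_high']:.3f}), p={r['p']:.3g}"
                )
            lines.append("")
    (out / "summary.md").write_text("\n".join(lines))
    _register(manifest, out, out / "summary.md")


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

_STAGE_FUNCS = {
    "simulate": lambda cfg, out, man, strict: _stage_simulate(cfg, out, man),
    "fc": _stage_fc,
    "score": _stage_score,
    "baseline": lambda cfg, out, man, strict: _stage_baseline(cfg, out, man),
    "longitudinal": lambda cfg, out, man, strict: _stage_longitudinal(cfg, out, man),
    "sensitivity": lambda cfg, out, man, strict: _stage_sensitivity(cfg, out, man),
    "exploratory": lambda cfg, out, man, strict: _stage_exploratory(cfg, out, man),
    "report": lambda cfg, out, man, strict: _stage_report(cfg, out, man),
}


def run_pipeline(
    config: SimulationConfig | str | Path,
    stages: tuple[str, ...] | list[str] = ALL_STAGES,
    out_dir: str | Path = "results/run",
    strict: bool = True,
) -> RunManifest:
    """Run the requested stages in canonical order and write a manifest.

    Stage inputs must either exist in ``out_dir`` from a previous run or be
    produced by an earlier requested stage; a missing input raises an error
    naming the producing stage.  Completed outputs survive a later failure.
    """
    if not isinstance(config, SimulationConfig):
        config = load_config(config)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s) {sorted(unknown)}; choose from {ALL_STAGES}")
    ordered = [s for s in ALL_STAGES if s in set(stages)]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config), seed=config.seed, version=__version__
    )
    for stage in ordered:
        _STAGE_FUNCS[stage](config, out, manifest, strict)
        manifest.stages.append(stage)

    manifest.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    missing = [f for f in manifest.outputs if not (out / f).exists()]
    if missing:  # pragma: no cover - internal consistency guard
        raise PCSKitError(f"manifest lists missing outputs: {missing}")
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest
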