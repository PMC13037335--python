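"""Synthetic twin-family cohorts with planted, recoverable ground truth.

The generator emulates the statistical skeleton of a two-wave twin cohort:

* a sparse, signed connectome template with block structure over a network
  partition (negative within one designated network, positive between a
  designated network pair — the motif characteristic of depression-related
  connectivity maps);
* per-subject parcel time series drawn from a multivariate normal whose
  correlation is the base matrix shifted along the template pattern in
  proportion to a latent vulnerability ``v`` — so the polyconnectomic score
  computed from the simulated series increases with ``v`` by construction;
* family-clustered phenotypes in which symptom change follows
  ``delta = b0 + b1*delta_stress + b2*v + b3*delta_stress*v + u_family + eps``
  with an analogous cross-sectional model at baseline, cognition subscales
  nearly decoupled from stress, and random or deterministic follow-up
  attrition.

Latent variables live on a standardized (unit-ish variance) scale and are
mapped linearly onto instrument-like ranges, so standardized coefficients
recovered downstream are directly comparable to the planted ``b`` values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectome_fc import ParcelTimeSeries, compute_fc, edge_index_pairs, vectorize_fc
from .exceptions import ConfigError
from .pcs_scoring import CSSTemplate, compute_pcs

# Instrument-like scales for the questionnaire and cognition columns
# (location, scale, lower clip, upper clip for the discretized mode).
SCALES: dict[str, tuple[float, float, float, float]] = {
    "stress": (22.10, 11.63, 0, 60),
    "anxiety": (24.79, 13.94, 0, 114),
    "depression": (4.25, 3.47, 0, 26),
    "cog_flanker": (98.27, 15.47, 40, 160),
    "cog_card_sort": (100.87, 19.84, 40, 160),
    "cog_pattern_comparison": (98.55, 21.25, 40, 160),
    "cog_picture_sequence": (101.37, 16.16, 40, 160),
    "cog_picture_vocabulary": (103.72, 13.56, 40, 160),
    "cog_oral_reading": (106.18, 15.97, 40, 160),
}
COG_SUBSCALES = [k for k in SCALES if k.startswith("cog_")]


@dataclass
class TemplateSpec:
    """Shape of the synthetic connectome template."""

    fraction_nonzero: float = 0.30
    weight_scale: float = 0.30  # Cohen's d units
    networks: tuple[str, ...] = (
        "visual",
        "somatomotor",
        "dorsal_attention",
        "salience",
    )
    negative_within: str = "somatomotor"
    positive_between: tuple[str, str] = ("somatomotor", "salience")


@dataclass
class OutcomeParams:
    """Coefficients of the planted symptom model (standardized scale)."""

    b0: float = 0.20  # symptom-change intercept (symptoms drift up)
    b1: float = 0.50  # stress main effect
    b2: float = 0.20  # vulnerability main effect
    b3: float = 0.15  # stress x vulnerability interaction
    family_intercept_sd: float = 0.45
    residual_sd: float = 0.66
    cog_stress_coupling: float = 0.05  # near-null cognitive coupling
    cog_residual_sd: float = 0.89


@dataclass
class CovariateParams:
    age_range: tuple[float, float] = (9.0, 13.0)
    female_ratio: float = 197 / 407
    left_handed_ratio: float = 72 / 407
    mean_fd_loc: float = 0.15
    mean_fd_scale: float = 0.05
    followup_years_mean: float = 20 / 12
    followup_years_sd: float = 0.25


@dataclass
class SimulationConfig:
    """Everything the generator needs; identical configs give bit-identical cohorts."""

    seed: int = 0
    n_families: int = 204
    twins_per_family: int = 2
    n_subjects: int | None = 407  # roster truncated to this count if set
    followup_rate: float = 298 / 407
    deterministic_followup: bool = True
    atlas_p: int = 20
    series_length: int = 600
    vulnerability_sd: float = 1.0
    vulnerability_clip: float = 3.0  # truncate v at this many SD
    fc_coupling: float = 0.30  # alpha: covariance shift per unit v
    distortion_bound: float = 0.05
    discretize: bool = False
    template_spec: TemplateSpec = field(default_factory=TemplateSpec)
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)
    covariate_params: CovariateParams = field(default_factory=CovariateParams)

    def __post_init__(self) -> None:
        if not (0 < self.followup_rate <= 1):
            raise ConfigError("followup_rate must lie in (0, 1]")
        if not (0 < self.template_spec.fraction_nonzero <= 1):
            raise ConfigError("fraction_nonzero must lie in (0, 1]")
        for name, val in (
            ("vulnerability_sd", self.vulnerability_sd),
            ("family_intercept_sd", self.outcome_params.family_intercept_sd),
            ("residual_sd", self.outcome_params.residual_sd),
        ):
            if val <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.atlas_p < 2 or self.series_length < 3:
            raise ConfigError("atlas_p >= 2 and series_length >= 3 required")
        if self.n_families < 1 or self.twins_per_family < 1:
            raise ConfigError("need at least one family with one member")

    @property
    def roster_size(self) -> int:
        total = self.n_families * self.twins_per_family
        if self.n_subjects is None:
            return total
        if self.n_subjects > total:
            raise ConfigError(
                f"n_subjects={self.n_subjects} exceeds roster "
                f"{self.n_families} x {self.twins_per_family}"
            )
        return self.n_subjects


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    template: CSSTemplate
    phenotypes: pd.DataFrame  # long format, one row per subject x timepoint
    truth: pd.DataFrame  # per-subject latent ground truth
    timeseries: list[ParcelTimeSeries] | None = None
    repair_log: pd.DataFrame | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generation stage."""
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------

def _partition(p: int, networks: tuple[str, ...]) -> list[str]:
    """Contiguous, near-equal blocks of parcels per network."""
    k = len(networks)
    sizes = [p // k + (1 if i < p % k else 0) for i in range(k)]
    out: list[str] = []
    for net, size in zip(networks, sizes):
        out.extend([net] * size)
    return out


def generate_template(config: SimulationConfig) -> CSSTemplate:
    """Sparse signed template with designated within/between network blocks.

    Within-``negative_within`` edges get negative weights, edges between
    the ``positive_between`` pair get positive weights, and the remaining
    non-zero budget is drawn symmetrically about zero.
    """
    spec = config.template_spec
    rng = _rng(config, 1)
    p = config.atlas_p
    labels = [f"roi{i:04d}" for i in range(p)]
    nets = _partition(p, spec.networks)
    pairs = edge_index_pairs(p)
    e = len(pairs)

    neg_idx = [
        k
        for k, (i, j) in enumerate(pairs)
        if nets[i] == spec.negative_within and nets[j] == spec.negative_within
    ]
    pos_pair = set(spec.positive_between)
    pos_idx = [
        k
        for k, (i, j) in enumerate(pairs)
        if {nets[i], nets[j]} == pos_pair and nets[i] != nets[j]
    ]

    n_target = max(int(round(spec.fraction_nonzero * e)), len(neg_idx) + len(pos_idx))
    n_target = min(n_target, e)
    designated = set(neg_idx) | set(pos_idx)
    remaining = np.array(sorted(set(range(e)) - designated))
    n_extra = n_target - len(designated)
    extra = rng.choice(remaining, size=n_extra, replace=False) if n_extra > 0 else []

    s = spec.weight_scale
    weights = np.zeros(e)
    weights[neg_idx] = -np.abs(rng.normal(s, s / 3, size=len(neg_idx)))
    weights[pos_idx] = np.abs(rng.normal(s, s / 3, size=len(pos_idx)))
    if len(extra):
        w = rng.normal(0.0, s, size=len(extra))
        w[w == 0] = s  # zero draws have measure zero, but keep the contract exact
        weights[np.asarray(extra)] = w

    return CSSTemplate(
        template_id=f"synthetic_mdd_like_p{p}",
        atlas_id=f"synthetic_atlas_p{p}",
        weights=weights,
        edge_index=pairs,
        parcel_labels=labels,
        network_partition=dict(zip(labels, nets)),
    )


def alternative_template(config: SimulationConfig, name: str, stream: int) -> CSSTemplate:
    """A disorder-alternative template on the same atlas.

    Alternatives draw independent weights AND rotate the designated block
    structure to a different network pair, so each map targets a distinct
    connectivity motif rather than re-labelling the primary one.
    """
    base = config.template_spec
    primary_pos = set(base.positive_between)
    candidates = [
        (n, m)
        for n in base.networks
        for m in base.networks
        if n != m and n != base.negative_within and {n, m} != primary_pos
    ]
    neg, pos_partner = candidates[stream % len(candidates)]
    spec = replace(base, negative_within=neg, positive_between=(neg, pos_partner))
    alt_seed = int(
        np.random.SeedSequence((config.seed, 90, stream)).generate_state(1)[0] % (2**31)
    )
    alt = replace(config, seed=alt_seed, template_spec=spec)
    tpl = generate_template(alt)
    tpl.template_id = name
    tpl.atlas_id = f"synthetic_atlas_p{config.atlas_p}"
    return tpl


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def base_covariance(p: int, rho: float = 0.05) -> np.ndarray:
    """Well-conditioned base correlation: constant off-diagonal ``rho``."""
    return np.full((p, p), rho) + (1 - rho) * np.eye(p)


def _normalized_weight_matrix(template: CSSTemplate) -> np.ndarray:
    w = template.weight_matrix()
    norm = np.max(np.abs(np.linalg.eigvalsh(w)))
    return w / norm if norm > 0 else w


def subject_covariance(
    v: float, w_tilde: np.ndarray, config: SimulationConfig
) -> tuple[np.ndarray, float]:
    """Sigma(v) = Sigma0 + alpha * v * W~, ridge-repaired to a valid correlation.

    Returns the (possibly repaired) matrix and the relative Frobenius
    distortion introduced by the repair (0.0 when none was needed).
    """
    p = w_tilde.shape[0]
    sigma = base_covariance(p) + config.fc_coupling * v * w_tilde
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig > 1e-10:
        return sigma, 0.0
    lam = abs(min_eig) + 1e-6
    repaired = (sigma + lam * np.eye(p)) / (1 + lam)
    distortion = float(
        np.linalg.norm(repaired - sigma) / np.linalg.norm(sigma)
    )
    if distortion > config.distortion_bound:
        raise ConfigError(
            f"covariance repair distortion {distortion:.3f} exceeds "
            f"{config.distortion_bound}; reduce fc_coupling or the v range"
        )
    return repaired, distortion


def generate_subject_timeseries(
    v: float,
    template: CSSTemplate,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "sub",
    w_tilde: np.ndarray | None = None,
) -> tuple[ParcelTimeSeries, float]:
    """T zero-mean multivariate-normal draws with covariance Sigma(v)."""
    if w_tilde is None:
        w_tilde = _normalized_weight_matrix(template)
    sigma, distortion = subject_covariance(v, w_tilde, config)
    chol = np.linalg.cholesky(sigma)
    data = rng.standard_normal((config.series_length, sigma.shape[0])) @ chol.T
    ts = ParcelTimeSeries(
        subject_id=subject_id, data=data, parcel_labels=list(template.parcel_labels)
    )
    return ts, distortion


def population_pcs(v: float, template: CSSTemplate, config: SimulationConfig) -> float:
    """The infinite-T score: PCS of Sigma(v)'s off-diagonal itself."""
    w_tilde = _normalized_weight_matrix(template)
    sigma, _ = subject_covariance(v, w_tilde, config)
    p = sigma.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    from .connectome_fc import EdgeVector  # local import to avoid cycle at module load

    edges = EdgeVector(
        subject_id="population", values=sigma[iu, ju], edge_index=edge_index_pairs(p)
    )
    return compute_pcs(edges, template).score


# ---------------------------------------------------------------------------
# Phenotypes and outcomes
# ---------------------------------------------------------------------------

def _to_scale(z: np.ndarray, name: str, discretize: bool) -> np.ndarray:
    loc, scale, lo, hi = SCALES[name]
    x = loc + scale * z
    if discretize:
        x = np.clip(np.round(x), lo, hi)
    return x


def generate_vulnerabilities(config: SimulationConfig) -> np.ndarray:
    """Latent vulnerability v, normal truncated at +/- ``vulnerability_clip`` SD.

    Truncation keeps every subject's shifted covariance inside the valid
    correlation cone at the default coupling, so ridge repair stays a
    safety net rather than a routine step.
    """
    rng = _rng(config, 2)
    v = rng.normal(0.0, config.vulnerability_sd, size=config.roster_size)
    lim = config.vulnerability_clip * config.vulnerability_sd
    return np.clip(v, -lim, lim)


def generate_outcomes(
    vulnerabilities: np.ndarray, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort phenotype table (baseline + follow-up rows) plus ground truth.

    The symptom model on the latent standardized scale is
    ``delta = b0 + b1*dstress + b2*v + b3*dstress*v + u_family + eps`` with
    the analogous cross-sectional form at baseline; cognition couples to
    stress only weakly.  Attrition keeps ``followup_rate`` of subjects —
    exactly (rounded) under deterministic thinning, in expectation otherwise.
    """
    v = np.asarray(vulnerabilities, dtype=float)
    n = v.size
    if n != config.roster_size:
        raise ConfigError(f"{n} vulnerabilities for roster of {config.roster_size}")
    op, cp = config.outcome_params, config.covariate_params
    rng = _rng(config, 3)

    fam_of = np.arange(n) // config.twins_per_family
    n_fam = int(fam_of.max()) + 1
    subject_id = [f"sub{i:04d}" for i in range(n)]
    family_id = [f"fam{f:04d}" for f in fam_of]

    # covariates (age and follow-up interval shared within family)
    fam_age = rng.uniform(*cp.age_range, size=n_fam)
    age_b = fam_age[fam_of]
    sex = (rng.random(n) < cp.female_ratio).astype(int)  # 1 = female
    handedness = (rng.random(n) < cp.left_handed_ratio).astype(int)  # 1 = left
    mean_fd = np.maximum(0.02, rng.normal(cp.mean_fd_loc, cp.mean_fd_scale, size=n))
    fam_dur = np.maximum(0.75, rng.normal(cp.followup_years_mean, cp.followup_years_sd, size=n_fam))
    duration = fam_dur[fam_of]

    stress_b = rng.standard_normal(n)
    dstress = rng.normal(0.25, 1.0, size=n)

    def symptom(stress_term: np.ndarray, intercept: float) -> np.ndarray:
        u = rng.normal(0.0, op.family_intercept_sd, size=n_fam)[fam_of]
        eps = rng.normal(0.0, op.residual_sd, size=n)
        return intercept + op.b1 * stress_term + op.b2 * v + op.b3 * stress_term * v + u + eps

    emotional_b = {o: symptom(stress_b, 0.0) for o in ("anxiety", "depression")}
    emotional_d = {o: symptom(dstress, op.b0) for o in ("anxiety", "depression")}

    def cognition(stress_term: np.ndarray) -> np.ndarray:
        u = rng.normal(0.0, op.family_intercept_sd, size=n_fam)[fam_of]
        eps = rng.normal(0.0, op.cog_residual_sd, size=n)
        return op.cog_stress_coupling * stress_term + u + eps

    cog_b = {c: cognition(stress_b) for c in COG_SUBSCALES}
    cog_d = {c: cognition(dstress) * 0.3 for c in COG_SUBSCALES}  # quiet drift

    # attrition
    rng_att = _rng(config, 4)
    k = int(round(config.followup_rate * n))
    if config.deterministic_followup:
        keep = np.zeros(n, dtype=bool)
        keep[rng_att.permutation(n)[:k]] = True
    else:
        keep = rng_att.random(n) < config.followup_rate

    disc = config.discretize
    base = pd.DataFrame(
        {
            "subject_id": subject_id,
            "family_id": family_id,
            "timepoint": "baseline",
            "age": np.round(age_b, 2),
            "sex": sex,
            "handedness": handedness,
            "mean_fd": np.round(mean_fd, 4),
            "stress": _to_scale(stress_b, "stress", disc),
            "anxiety": _to_scale(emotional_b["anxiety"], "anxiety", disc),
            "depression": _to_scale(emotional_b["depression"], "depression", disc),
        }
    )
    for c in COG_SUBSCALES:
        base[c] = _to_scale(cog_b[c], c, disc)

    fup = base[keep].copy()
    fup["timepoint"] = "followup"
    fup["age"] = np.round(age_b[keep] + duration[keep], 2)
    fup["stress"] = _to_scale((stress_b + dstress)[keep], "stress", disc)
    for o in ("anxiety", "depression"):
        fup[o] = _to_scale((emotional_b[o] + emotional_d[o])[keep], o, disc)
    for c in COG_SUBSCALES:
        fup[c] = _to_scale((cog_b[c] + cog_d[c])[keep], c, disc)

    phenotypes = pd.concat([base, fup], ignore_index=True)
    truth = pd.DataFrame(
        {
            "subject_id": subject_id,
            "family_id": family_id,
            "v": v,
            "stress_baseline_z": stress_b,
            "delta_stress_z": dstress,
            "has_followup": keep,
        }
    )
    return phenotypes, truth


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimulationConfig, with_timeseries: bool = True
) -> SimulatedCohort:
    """Template + vulnerabilities + phenotypes (+ per-subject time series)."""
    template = generate_template(config)
    v = generate_vulnerabilities(config)
    phenotypes, truth = generate_outcomes(v, config)

    timeseries = None
    repair_log = None
    if with_timeseries:
        w_tilde = _normalized_weight_matrix(template)
        rng = _rng(config, 5)
        timeseries = []
        distortions = []
        for sid, vi in zip(truth["subject_id"], v):
            ts, dist = generate_subject_timeseries(
                vi, template, config, rng, subject_id=sid, w_tilde=w_tilde
            )
            timeseries.append(ts)
            distortions.append(dist)
        repair_log = pd.DataFrame(
            {"subject_id": truth["subject_id"], "repair_distortion": distortions}
        )
    return SimulatedCohort(
        config=config,
        template=template,
        phenotypes=phenotypes,
        truth=truth,
        timeseries=timeseries,
        repair_log=repair_log,
    )


def score_cohort(cohort: SimulatedCohort, template: CSSTemplate | None = None) -> pd.DataFrame:
    """FC -> edge vector -> PCS for every simulated subject (strict mode)."""
    if cohort.timeseries is None:
        raise ConfigError("cohort was generated without time series")
    template = template or cohort.template
    rows = []
    for ts in cohort.timeseries:
        edges = vectorize_fc(compute_fc(ts, degenerate_policy="strict"))
        res = compute_pcs(edges, template)
        rows.append((res.subject_id, res.template_id, res.score, res.n_nonzero))
    return pd.DataFrame(rows, columns=["subject_id", "template_id", "pcs", "n_nonzero"])


# ---------------------------------------------------------------------------
# Clinical validation arm
# ---------------------------------------------------------------------------

def generate_clinical_cohort(
    config: SimulationConfig,
    n: int = 80,
    v_shift: float = 0.5,
    with_timeseries: bool = True,
) -> SimulatedCohort:
    """A small cross-sectional clinical-like sample with elevated vulnerability.

    Older, mostly-female, unrelated subjects whose latent vulnerability is
    shifted upward by ``v_shift`` SD; depressive severity follows the same
    stress x vulnerability structure (no family clustering — singleton
    families), measured on clinical-instrument-like scales.
    """
    op = config.outcome_params
    rng = _rng(config, 7)
    v = rng.normal(v_shift, config.vulnerability_sd, size=n)
    stress_z = rng.standard_normal(n)
    eps = rng.normal(0.0, op.residual_sd, size=n)
    dep_z = op.b1 * stress_z + op.b2 * v + op.b3 * stress_z * v + eps

    df = pd.DataFrame(
        {
            "subject_id": [f"cln{i:04d}" for i in range(n)],
            "family_id": [f"cfam{i:04d}" for i in range(n)],
            "timepoint": "baseline",
            "age": np.round(rng.uniform(12.0, 18.0, size=n), 2),
            "sex": (rng.random(n) < 61 / 80).astype(int),
            "mean_fd": np.round(
                np.maximum(0.02, rng.normal(0.15, 0.05, size=n)), 4
            ),
            "stress": 54.48 + 10.0 * stress_z,  # PSS-14-like
            "depression": 29.03 + 6.0 * dep_z,  # MADRS-like
        }
    )
    truth = pd.DataFrame(
        {"subject_id": df["subject_id"], "family_id": df["family_id"], "v": v}
    )

    template = generate_template(config)
    timeseries = None
    repair_log = None
    if with_timeseries:
        w_tilde = _normalized_weight_matrix(template)
        rng_ts = _rng(config, 8)
        timeseries, distortions = [], []
        for sid, vi in zip(df["subject_id"], v):
            ts, dist = generate_subject_timeseries(
                vi, template, config, rng_ts, subject_id=sid, w_tilde=w_tilde
            )
            timeseries.append(ts)
            distortions.append(dist)
        repair_log = pd.DataFrame(
            {"subject_id": df["subject_id"], "repair_distortion": distortions}
        )
    return SimulatedCohort(
        config=config,
        template=template,
        phenotypes=df,
        truth=truth,
        timeseries=timeseries,
        repair_log=repair_log,
    )
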