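"""Family-clustered association and moderation models.

The inference layer mirrors a twin-cohort analysis plan: standardized
linear mixed-effects models with a family random intercept (clustered
siblings are not independent), moderation via a product term with
conditional simple slopes at moderator mean +/- 1 SD and a fixed-effects
ΔR², change scores (follow-up minus baseline), Bonferroni correction,
balanced tertile subgrouping, and a covariate-adjusted group ANCOVA.

Conventions
-----------
* Continuous variables are z-scored (n-1 denominator) inside each fit, so
  reported coefficients are standardized betas; binary covariates (two
  distinct values) are left untouched.
* Mixed models use Wald z inference on the fixed effects; OLS uses t.
* ΔR² is defined on the fixed-effects predictions: the squared correlation
  between X @ beta_fixed and the observed outcome, differenced between the
  full (with interaction) and reduced models.  This is engine-agnostic and
  reduces to the usual ΔR² under OLS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .exceptions import DataIntegrityError, DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

ENGINES = ("lmm_random_intercept", "ols")


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n_obs: int
    converged: bool
    engine: str
    p_adjusted: float | None = None
    significant: bool | None = None


@dataclass
class ConditionalSlope:
    """Simple slope of the predictor at a fixed moderator value."""

    at: float
    slope: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class ModerationResult:
    outcome: str
    predictor: str
    moderator: str
    interaction_beta: float
    ci_low: float
    ci_high: float
    p: float
    delta_r2: float
    slope_low: ConditionalSlope
    slope_high: ConditionalSlope
    n_obs: int
    converged: bool
    engine: str
    moderator_sd: float = 1.0
    p_adjusted: float | None = None
    significant: bool | None = None


@dataclass
class AncovaResult:
    response: str
    group: str
    f_stat: float
    p: float
    df_between: float
    df_resid: float
    adjusted_means: dict[str, float]
    n_obs: int


@dataclass
class ChangeScores:
    table: pd.DataFrame
    n_excluded: int = 0
    excluded_subjects: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def is_binary(series: pd.Series) -> bool:
    return series.dropna().nunique() <= 2


def standardize_center(
    table: pd.DataFrame, variables: list[str], mode: str = "zscore"
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center or z-score the named continuous columns.

    Returns the transformed copy and a map variable -> (mean, sd) so the
    transform can be inverted.  SD uses the n-1 denominator.  A zero-variance
    variable under ``zscore`` raises :class:`DegenerateInputError`.
    """
    if mode not in ("center", "zscore"):
        raise ValueError(f"mode must be 'center' or 'zscore', got {mode!r}")
    out = table.copy()
    params: dict[str, tuple[float, float]] = {}
    for var in variables:
        if var not in out.columns:
            raise ValidationError(f"variable {var!r} not in table")
        x = out[var].astype(float)
        mu = float(x.mean())
        sd = float(x.std(ddof=1))
        if mode == "zscore":
            if not np.isfinite(sd) or sd == 0:
                raise DegenerateInputError(f"variable {var!r} has zero variance")
            out[var] = (x - mu) / sd
        else:
            out[var] = x - mu
        params[var] = (mu, sd)
    return out, params


def _prepare(
    table: pd.DataFrame,
    continuous: list[str],
    passthrough: list[str],
) -> pd.DataFrame:
    """Complete-case subset with continuous columns z-scored in place."""
    cols = list(dict.fromkeys(continuous + passthrough))
    d = table.dropna(subset=cols).copy()
    if d.empty:
        raise DegenerateInputError("no complete cases for the requested model")
    d, _ = standardize_center(d, continuous, mode="zscore")
    return d


def _split_covariates(table: pd.DataFrame, covariates: list[str]) -> tuple[list[str], list[str]]:
    cont = [c for c in covariates if not is_binary(table[c])]
    binary = [c for c in covariates if is_binary(table[c])]
    return cont, binary


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

def _fit_engine(y: pd.Series, x: pd.DataFrame, groups, engine: str):
    """Fit OLS or a random-intercept mixed model; never raises on
    non-convergence — returns (result, converged)."""
    if engine == "ols":
        return sm.OLS(np.asarray(y, dtype=float), x).fit(), True
    if engine != "lmm_random_intercept":
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    if groups is None:
        raise ValidationError("lmm engine requires a cluster column")
    if pd.Series(groups).nunique() < 2:
        raise ValidationError("lmm engine requires >= 2 families")
    model = sm.MixedLM(np.asarray(y, dtype=float), x, groups=np.asarray(groups))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
            return res, bool(res.converged)
        except (np.linalg.LinAlgError, ValueError):
            pass
        try:
            res = model.fit(reml=True, method="powell", maxiter=500)
            return res, bool(res.converged)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed model failed (%s); falling back to OLS estimates", exc)
            return sm.OLS(np.asarray(y, dtype=float), x).fit(), False


def _wald(result, name: str, engine: str) -> tuple[float, float, float, float]:
    """(beta, ci_low, ci_high, p) for one named fixed effect."""
    beta = float(result.params[name])
    se = float(result.bse[name])
    if engine == "ols":
        df = float(result.df_resid)
        crit = sps.t.ppf(0.975, df)
        p = float(2 * sps.t.sf(abs(beta / se), df)) if se > 0 else 0.0
    else:
        crit = sps.norm.ppf(0.975)
        p = float(2 * sps.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return beta, beta - crit * se, beta + crit * se, p


def _fixed_r2(result, x: pd.DataFrame, y: np.ndarray) -> float:
    """Squared correlation between fixed-effect predictions and the outcome."""
    fe = np.asarray([result.params[c] for c in x.columns], dtype=float)
    pred = x.to_numpy(dtype=float) @ fe
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def fit_association(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: list[str] | tuple[str, ...] = (),
    cluster: str = "family_id",
    engine: str = "lmm_random_intercept",
) -> AssociationResult:
    """Standardized association of outcome on predictor with covariates.

    ``lmm_random_intercept`` adds a per-cluster (family) random intercept;
    ``ols`` omits it (single-site clinical arm).  Continuous variables are
    z-scored so ``beta`` is a standardized coefficient with a Wald 95% CI.
    """
    covariates = list(covariates)
    cont_cov, bin_cov = _split_covariates(table, covariates)
    passthrough = bin_cov + ([cluster] if engine == "lmm_random_intercept" else [])
    d = _prepare(table, [outcome, predictor] + cont_cov, passthrough)

    x = sm.add_constant(d[[predictor] + covariates].astype(float), has_constant="add")
    groups = d[cluster] if engine == "lmm_random_intercept" else None
    result, converged = _fit_engine(d[outcome], x, groups, engine)
    used_engine = engine if converged or engine == "ols" else "ols"
    beta, lo, hi, p = _wald(result, predictor, used_engine)
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        beta=beta,
        ci_low=lo,
        ci_high=hi,
        p=p,
        n_obs=len(d),
        converged=converged,
        engine=engine,
    )


# ---------------------------------------------------------------------------
# Moderation
# ---------------------------------------------------------------------------

def fit_moderation(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    moderator: str,
    covariates: list[str] | tuple[str, ...] = (),
    cluster: str = "family_id",
    engine: str = "lmm_random_intercept",
) -> ModerationResult:
    """Moderated regression Y ~ X + W + X*W (+ covariates, + family intercept).

    The interaction coefficient is reported on the standardized scale, with
    ΔR² (fixed-effects) from a reduced fit without the product term, and the
    conditional slopes of X at W = mean -/+ 1 SD via the delta method on the
    fitted covariance of the estimates.
    """
    covariates = list(covariates)
    cont_cov, bin_cov = _split_covariates(table, covariates)
    passthrough = bin_cov + ([cluster] if engine == "lmm_random_intercept" else [])
    d = _prepare(table, [outcome, predictor, moderator] + cont_cov, passthrough)

    inter = f"{predictor}:{moderator}"
    d[inter] = d[predictor] * d[moderator]

    x_full = sm.add_constant(
        d[[predictor, moderator, inter] + covariates].astype(float), has_constant="add"
    )
    x_red = sm.add_constant(
        d[[predictor, moderator] + covariates].astype(float), has_constant="add"
    )
    groups = d[cluster] if engine == "lmm_random_intercept" else None
    y = d[outcome].to_numpy(dtype=float)

    full, conv_full = _fit_engine(d[outcome], x_full, groups, engine)
    red, conv_red = _fit_engine(d[outcome], x_red, groups, engine)
    converged = conv_full and conv_red
    used_engine = engine if (conv_full or engine == "ols") else "ols"

    beta, lo, hi, p = _wald(full, inter, used_engine)

    raw_delta = _fixed_r2(full, x_full, y) - _fixed_r2(red, x_red, y)
    delta_r2 = max(0.0, raw_delta)

    # conditional slopes: dY/dX = b_x + w0 * b_xw, evaluated at W mean -/+ 1 SD
    w = d[moderator].to_numpy(dtype=float)
    w_mean, w_sd = float(np.mean(w)), float(np.std(w, ddof=1))
    cov = full.cov_params()
    var_x = float(cov.loc[predictor, predictor])
    var_xw = float(cov.loc[inter, inter])
    cov_x_xw = float(cov.loc[predictor, inter])
    b_x = float(full.params[predictor])
    b_xw = float(full.params[inter])

    def slope_at(w0: float) -> ConditionalSlope:
        s = b_x + w0 * b_xw
        var = var_x + w0 ** 2 * var_xw + 2 * w0 * cov_x_xw
        se = float(np.sqrt(max(var, 0.0)))
        if used_engine == "ols":
            df = float(full.df_resid)
            crit = sps.t.ppf(0.975, df)
            pv = float(2 * sps.t.sf(abs(s / se), df)) if se > 0 else 0.0
        else:
            crit = sps.norm.ppf(0.975)
            pv = float(2 * sps.norm.sf(abs(s / se))) if se > 0 else 0.0
        return ConditionalSlope(at=w0, slope=s, ci_low=s - crit * se, ci_high=s + crit * se, p=pv)

    return ModerationResult(
        outcome=outcome,
        predictor=predictor,
        moderator=moderator,
        interaction_beta=beta,
        ci_low=lo,
        ci_high=hi,
        p=p,
        delta_r2=delta_r2,
        slope_low=slope_at(w_mean - w_sd),
        slope_high=slope_at(w_mean + w_sd),
        n_obs=len(d),
        converged=converged,
        engine=engine,
        moderator_sd=w_sd,
    )


# ---------------------------------------------------------------------------
# Change scores
# ---------------------------------------------------------------------------

def compute_change_scores(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    carry: list[str] | None = None,
) -> ChangeScores:
    """Follow-up minus baseline deltas for subjects observed at both waves.

    ``variables`` default to stress / anxiety / depression plus every
    ``cog_*`` column present.  Baseline values of ``carry`` columns (family,
    sex, motion, PCS columns by default) are attached, along with
    ``followup_duration`` in years.  Subjects lacking a follow-up row are
    excluded and counted; a follow-up age not exceeding the baseline age is a
    data-integrity error.
    """
    required = {"subject_id", "timepoint", "age"}
    if not required.issubset(table.columns):
        raise ValidationError(f"cohort table needs columns {sorted(required)}")

    if variables is None:
        candidates = ["stress", "anxiety", "depression"]
        variables = [v for v in candidates if v in table.columns]
        variables += sorted(c for c in table.columns if c.startswith("cog_"))
    if carry is None:
        carry = [
            c
            for c in ("family_id", "sex", "mean_fd", "handedness")
            if c in table.columns
        ]
        carry += sorted(c for c in table.columns if c.startswith("pcs"))

    base = table[table["timepoint"] == "baseline"].set_index("subject_id")
    fup = table[table["timepoint"] == "followup"].set_index("subject_id")
    if base.index.has_duplicates or fup.index.has_duplicates:
        raise ValidationError("a subject has more than one row per timepoint")

    orphans = fup.index.difference(base.index)
    if len(orphans):
        raise ValidationError(f"follow-up rows without baseline: {list(orphans)[:5]}")

    both = base.index.intersection(fup.index)
    excluded = base.index.difference(fup.index)

    bad_age = both[fup.loc[both, "age"].to_numpy() <= base.loc[both, "age"].to_numpy()]
    if len(bad_age):
        raise DataIntegrityError(
            f"follow-up age <= baseline age for subject(s) {list(bad_age)[:5]}"
        )

    out = pd.DataFrame(index=both)
    for var in variables:
        out[f"delta_{var}"] = fup.loc[both, var] - base.loc[both, var]
    out["followup_duration"] = fup.loc[both, "age"] - base.loc[both, "age"]
    for col in carry:
        out[col] = base.loc[both, col]
    out = out.reset_index().rename(columns={"index": "subject_id"})
    if len(excluded):
        logger.info("change scores: excluded %d subject(s) without follow-up", len(excluded))
    return ChangeScores(
        table=out, n_excluded=len(excluded), excluded_subjects=list(excluded)
    )


# ---------------------------------------------------------------------------
# Multiple comparisons, subgrouping, ANCOVA
# ---------------------------------------------------------------------------

def bonferroni_adjust(results: list, family_size: int | None = None, alpha: float = 0.05) -> list:
    """Bonferroni adjustment in place: p_adjusted = min(1, m * p)."""
    m = family_size if family_size is not None else len(results)
    if m < 1:
        raise ValueError("family_size must be >= 1")
    for r in results:
        r.p_adjusted = min(1.0, m * r.p)
        r.significant = r.p_adjusted < alpha
    return results


def tertile_split(scores) -> tuple[np.ndarray, dict]:
    """Split scores into three balanced ordered groups (low/medium/high).

    Group sizes differ by at most one (the lower groups absorb the
    remainder); ties are broken by stable input order.  Returns the label
    array aligned to the input and a dict with group sizes and score
    boundaries.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 3:
        raise ValueError(f"need at least 3 scores to form tertiles, got {n}")
    if np.ptp(scores) == 0:
        logger.warning("tertile split on constant scores: assignment by input order")
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if g < rem else 0) for g in range(3)]
    labels = np.empty(n, dtype=object)
    names = ["low", "medium", "high"]
    start = 0
    boundaries: dict = {"sizes": dict(zip(names, sizes))}
    for name, size in zip(names, sizes):
        members = order[start : start + size]
        labels[members] = name
        boundaries[name] = (float(scores[members].min()), float(scores[members].max()))
        start += size
    return labels, boundaries


def ancova_group_compare(
    table: pd.DataFrame,
    response: str,
    group: str,
    covariates: list[str] | tuple[str, ...] = ("age", "sex"),
) -> AncovaResult:
    """Covariate-adjusted group comparison (ANCOVA).

    Fits ``response ~ C(group) + covariates`` by OLS and reports the group
    F test (type-II sum of squares) plus covariate-adjusted group means
    (predictions at the grand covariate means).
    """
    covariates = list(covariates)
    d = table.dropna(subset=[response, group] + covariates).copy()
    counts = d[group].value_counts()
    if len(counts) < 2:
        raise ValidationError(f"ANCOVA needs >= 2 groups, got {len(counts)}")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"group(s) with < 2 observations: {small}")

    cont = [c for c in covariates if not is_binary(d[c])]
    if cont:
        d, _ = standardize_center(d, cont, mode="center")

    formula = f"{response} ~ C({group})" + "".join(f" + {c}" for c in covariates)
    fit = smf.ols(formula, data=d).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    row = anova.loc[f"C({group})"]

    grid = pd.DataFrame({group: sorted(d[group].unique())})
    for c in covariates:
        grid[c] = float(d[c].mean())
    adjusted = dict(zip(grid[group], (float(v) for v in fit.predict(grid))))

    return AncovaResult(
        response=response,
        group=group,
        f_stat=float(row["F"]),
        p=float(row["PR(>F)"]),
        df_between=float(row["df"]),
        df_resid=float(anova.loc["Residual", "df"]),
        adjusted_means=adjusted,
        n_obs=len(d),
    )
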