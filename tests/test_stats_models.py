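"""Inference layer: standardized (mixed) models, moderation, change scores,
multiple-comparison correction, tertiles and ANCOVA."""

import numpy as np
import pandas as pd
import pytest

from pcskit.exceptions import DataIntegrityError, DegenerateInputError, ValidationError
from pcskit.stats_models import (
    AssociationResult,
    ancova_group_compare,
    bonferroni_adjust,
    compute_change_scores,
    fit_association,
    fit_moderation,
    standardize_center,
    tertile_split,
)


def _clustered(seed, n_fam=200, per_fam=2, beta=0.6, fam_sd=0.5, resid_sd=None):
    """Outcome = beta * predictor + family effect + noise, total variance ~ 1."""
    rng = np.random.default_rng(seed)
    n = n_fam * per_fam
    fam = np.repeat(np.arange(n_fam), per_fam)
    x = rng.standard_normal(n)
    if resid_sd is None:
        resid_sd = np.sqrt(max(1 - beta**2 - fam_sd**2, 1e-3))
    y = beta * x + (rng.standard_normal(n_fam) * fam_sd)[fam] + rng.standard_normal(n) * resid_sd
    return pd.DataFrame({"y": y, "x": x, "family_id": [f"f{i}" for i in fam]})


class TestStandardize:
    def test_center(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, params = standardize_center(df, ["a"], mode="center")
        assert list(out["a"]) == [-1.0, 0.0, 1.0]
        assert params["a"] == (2.0, 1.0)

    def test_zscore_uses_sample_sd(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out, params = standardize_center(df, ["a"], mode="zscore")
        assert list(out["a"]) == [-1.0, 0.0, 1.0]
        assert params["a"][1] == 2.0

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        with pytest.raises(DegenerateInputError):
            standardize_center(df, ["a"], mode="zscore")


class TestFitAssociation:
    def test_identity_regression(self):
        df = pd.DataFrame({"y": np.linspace(0, 10, 50)})
        df["x"] = df["y"]
        res = fit_association(df, "y", "x", engine="ols")
        assert res.beta == pytest.approx(1.0, abs=1e-8)
        assert res.p < 1e-10

    def test_standardized_beta_equals_pearson_r(self, rng):
        x = rng.standard_normal(120)
        y = 0.4 * x + rng.standard_normal(120)
        df = pd.DataFrame({"y": y, "x": x})
        res = fit_association(df, "y", "x", engine="ols")
        assert res.beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-8)

    def test_single_fit_recovers_planted_effect(self):
        res = fit_association(_clustered(seed=5), "y", "x")
        assert res.converged
        assert res.ci_low < 0.6 < res.ci_high

    def test_replicate_mean_is_unbiased(self):
        betas = [fit_association(_clustered(seed=s), "y", "x").beta for s in range(200)]
        assert -0.03 < np.mean(betas) - 0.6 < 0.03

    def test_type_i_error_is_nominal(self):
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(500):
            df = pd.DataFrame(
                {"y": rng.standard_normal(200), "x": rng.standard_normal(200)}
            )
            hits += fit_association(df, "y", "x", engine="ols").p < 0.05
        assert 0.025 < hits / 500 < 0.075

    def test_degenerate_cluster_limit_matches_ols(self):
        df = _clustered(seed=11, n_fam=150, per_fam=1)
        lmm = fit_association(df, "y", "x", engine="lmm_random_intercept")
        ols = fit_association(df, "y", "x", engine="ols")
        assert lmm.beta == pytest.approx(ols.beta, abs=1e-4)

    def test_lmm_requires_multiple_families(self):
        df = _clustered(seed=1, n_fam=1, per_fam=10)
        with pytest.raises(ValidationError, match="families"):
            fit_association(df, "y", "x", engine="lmm_random_intercept")


def _moderated(seed, n_fam=200, b3=0.15, fam_sd=0.45, resid_sd=0.66):
    rng = np.random.default_rng(seed)
    n = n_fam * 2
    fam = np.repeat(np.arange(n_fam), 2)
    x, w = rng.standard_normal(n), rng.standard_normal(n)
    y = (
        0.5 * x
        + 0.2 * w
        + b3 * x * w
        + (rng.standard_normal(n_fam) * fam_sd)[fam]
        + rng.standard_normal(n) * resid_sd
    )
    return pd.DataFrame({"y": y, "x": x, "w": w, "family_id": [f"f{i}" for i in fam]})


def _zscore(a):
    return (a - a.mean()) / a.std(ddof=1)


def delta_r2_oracle(y, x, w):
    """Two independent OLS fits; ΔR² as squared prediction-outcome correlation."""
    zy, zx, zw = _zscore(y), _zscore(x), _zscore(w)
    ones = np.ones_like(zy)

    def r2(design):
        coef, *_ = np.linalg.lstsq(design, zy, rcond=None)
        return np.corrcoef(design @ coef, zy)[0, 1] ** 2

    full = np.column_stack([ones, zx, zw, zx * zw])
    red = np.column_stack([ones, zx, zw])
    return r2(full) - r2(red)


class TestFitModeration:
    def test_interaction_recovery_and_slope_identity(self):
        res = fit_moderation(_moderated(seed=2), "y", "x", "w")
        assert res.converged
        assert res.ci_low < 0.15 < res.ci_high
        gap = res.slope_high.slope - res.slope_low.slope
        assert gap == pytest.approx(2 * res.moderator_sd * res.interaction_beta, abs=1e-8)

    def test_noiseless_interaction_matches_two_fit_oracle(self, rng):
        x, w = rng.standard_normal(80), rng.standard_normal(80)
        y = x + x * w
        df = pd.DataFrame({"y": y, "x": x, "w": w})
        res = fit_moderation(df, "y", "x", "w", engine="ols")
        assert res.interaction_beta > 0
        assert res.delta_r2 == pytest.approx(delta_r2_oracle(y, x, w), abs=1e-10)

    def test_delta_r2_invariant_to_affine_rescaling(self, rng):
        df = _moderated(seed=8)
        res = fit_moderation(df, "y", "x", "w", engine="ols")
        df2 = df.assign(x=3.0 * df["x"] - 7.0, w=-0.5 * df["w"] + 2.0)
        res2 = fit_moderation(df2, "y", "x", "w", engine="ols")
        assert res2.delta_r2 == pytest.approx(res.delta_r2, abs=1e-10)

    def test_null_interaction_delta_r2_is_small(self):
        vals = [
            fit_moderation(_moderated(seed=s, b3=0.0), "y", "x", "w").delta_r2
            for s in range(20)
        ]
        assert np.mean(vals) < 0.005

    def test_conditional_slopes_bracket_the_main_effect(self):
        res = fit_moderation(_moderated(seed=3), "y", "x", "w")
        assert res.slope_low.slope < 0.5 < res.slope_high.slope


class TestChangeScores:
    @staticmethod
    def _cohort():
        return pd.DataFrame(
            {
                "subject_id": ["s1", "s1", "s2"],
                "family_id": ["f1", "f1", "f2"],
                "timepoint": ["baseline", "followup", "baseline"],
                "age": [10.0, 11.5, 12.0],
                "sex": [1, 1, 0],
                "stress": [20.0, 27.0, 30.0],
                "anxiety": [10.0, 12.0, 15.0],
                "depression": [3.0, 5.0, 4.0],
            }
        )

    def test_delta_is_followup_minus_baseline(self):
        ch = compute_change_scores(self._cohort())
        row = ch.table.set_index("subject_id").loc["s1"]
        assert row["delta_stress"] == 7.0
        assert row["followup_duration"] == pytest.approx(1.5)

    def test_baseline_only_subjects_are_excluded_and_counted(self):
        ch = compute_change_scores(self._cohort())
        assert len(ch.table) == 1
        assert ch.n_excluded == 1
        assert ch.excluded_subjects == ["s2"]

    def test_nonpositive_followup_interval_is_integrity_error(self):
        df = self._cohort()
        df.loc[1, "age"] = 10.0
        with pytest.raises(DataIntegrityError, match="s1"):
            compute_change_scores(df)


class TestBonferroni:
    @staticmethod
    def _res(p):
        return AssociationResult(
            outcome="y", predictor="x", beta=0.0, ci_low=0, ci_high=0,
            p=p, n_obs=10, converged=True, engine="ols",
        )

    @pytest.mark.parametrize(
        "p,m,expected,significant",
        [(0.02, 2, 0.04, True), (0.04, 2, 0.08, False), (0.9, 8, 1.0, False)],
    )
    def test_adjustment_arithmetic(self, p, m, expected, significant):
        (out,) = bonferroni_adjust([self._res(p)], family_size=m)
        assert out.p_adjusted == pytest.approx(expected)
        assert out.significant is significant


class TestTertiles:
    def test_perfect_split(self):
        labels, bounds = tertile_split(np.arange(1, 10))
        assert bounds["sizes"] == {"low": 3, "medium": 3, "high": 3}
        assert list(labels[:3]) == ["low"] * 3

    def test_sizes_balanced_at_n_80(self, rng):
        labels, bounds = tertile_split(rng.standard_normal(80))
        sizes = bounds["sizes"]
        assert sum(sizes.values()) == 80
        assert max(sizes.values()) - min(sizes.values()) <= 1

    def test_constant_scores_split_by_stable_order(self):
        labels, bounds = tertile_split(np.ones(7))
        assert bounds["sizes"] == {"low": 3, "medium": 2, "high": 2}
        assert list(labels[:3]) == ["low"] * 3

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            tertile_split([1.0, 2.0])


class TestAncova:
    @staticmethod
    def _groups(seed, shift=0.5, age_shift=0.0, n1=400, n2=80):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "pcs": np.r_[rng.standard_normal(n1), rng.standard_normal(n2) + shift],
                "cohort": ["a"] * n1 + ["b"] * n2,
                "age": np.r_[
                    rng.uniform(9, 13, n1), rng.uniform(9, 13, n2) + age_shift
                ],
                "sex": rng.integers(0, 2, n1 + n2),
            }
        )

    def test_power_for_half_sd_difference(self):
        hits = sum(
            ancova_group_compare(self._groups(seed=s), "pcs", "cohort").p < 0.05
            for s in range(200)
        )
        assert hits / 200 >= 0.80

    def test_null_calibration(self):
        hits = sum(
            ancova_group_compare(self._groups(seed=s, shift=0.0), "pcs", "cohort").p
            < 0.05
            for s in range(500)
        )
        assert 0.025 < hits / 500 < 0.075

    def test_age_confounded_difference_is_adjusted_away(self):
        rng = np.random.default_rng(12)
        n1, n2 = 300, 300
        age = np.r_[rng.normal(10, 1, n1), rng.normal(13, 1, n2)]
        pcs = 0.5 * (age - age.mean()) + rng.normal(0, 0.3, n1 + n2)
        df = pd.DataFrame(
            {
                "pcs": pcs,
                "cohort": ["a"] * n1 + ["b"] * n2,
                "age": age,
                "sex": rng.integers(0, 2, n1 + n2),
            }
        )
        from scipy import stats as sps

        unadjusted_p = sps.ttest_ind(pcs[:n1], pcs[n1:]).pvalue
        adjusted = ancova_group_compare(df, "pcs", "cohort", ["age", "sex"])
        assert unadjusted_p < 1e-6
        assert adjusted.p > 0.05

    def test_adjusted_means_reported_per_group(self):
        res = ancova_group_compare(self._groups(seed=0), "pcs", "cohort")
        assert set(res.adjusted_means) == {"a", "b"}
        assert res.adjusted_means["b"] > res.adjusted_means["a"]

    def test_single_group_rejected(self):
        df = self._groups(seed=0).assign(cohort="a")
        with pytest.raises(ValidationError):
            ancova_group_compare(df, "pcs", "cohort")
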