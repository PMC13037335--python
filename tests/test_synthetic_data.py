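"""The cohort generator: planted template, covariance shift, outcome model."""

import numpy as np
import pandas as pd
import pytest

from pcskit.css_contributions import network_aggregate
from pcskit.exceptions import ConfigError
from pcskit.stats_models import fit_association
from pcskit.synthetic_data import (
    SimulationConfig,
    TemplateSpec,
    generate_clinical_cohort,
    generate_cohort,
    generate_outcomes,
    generate_subject_timeseries,
    generate_template,
    generate_vulnerabilities,
    population_pcs,
    score_cohort,
    subject_covariance,
    _normalized_weight_matrix,
    _rng,
)


class TestTemplate:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=5)
        a, b = generate_template(cfg), generate_template(cfg)
        assert np.array_equal(a.weights, b.weights)
        assert a.network_partition == b.network_partition

    def test_full_density_has_no_zero_weights(self):
        cfg = SimulationConfig(seed=5)
        cfg.template_spec.fraction_nonzero = 1.0
        tpl = generate_template(cfg)
        assert np.all(tpl.weights != 0)

    def test_designated_block_signs_via_aggregation(self):
        tpl = generate_template(SimulationConfig(seed=9))
        block = network_aggregate(tpl, statistic="mean").to_frame()
        assert block.loc["somatomotor", "somatomotor"] < 0
        assert block.loc["somatomotor", "salience"] > 0

    def test_zero_density_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, template_spec=TemplateSpec(fraction_nonzero=0.0))

    def test_400_parcel_seven_network_smoke(self):
        cfg = SimulationConfig(
            seed=2,
            atlas_p=400,
            series_length=60,
            n_families=1,
            n_subjects=1,
            template_spec=TemplateSpec(
                networks=(
                    "visual",
                    "somatomotor",
                    "dorsal_attention",
                    "ventral_attention",
                    "limbic",
                    "frontoparietal",
                    "default",
                ),
                positive_between=("somatomotor", "ventral_attention"),
            ),
        )
        tpl = generate_template(cfg)
        assert tpl.n_edges == 400 * 399 // 2
        ts, _ = generate_subject_timeseries(1.0, tpl, cfg, _rng(cfg, 5))
        assert ts.data.shape == (60, 400)


class TestCovarianceShift:
    def test_population_pcs_matches_sample_mean_at_v_zero(self):
        cfg = SimulationConfig(seed=21, n_families=100, n_subjects=200)
        tpl = generate_template(cfg)
        expected = population_pcs(0.0, tpl, cfg)
        rng = _rng(cfg, 5)
        w = _normalized_weight_matrix(tpl)
        from pcskit.connectome_fc import compute_fc, vectorize_fc
        from pcskit.pcs_scoring import compute_pcs

        scores = []
        for i in range(200):
            ts, _ = generate_subject_timeseries(0.0, tpl, cfg, rng, w_tilde=w)
            scores.append(compute_pcs(vectorize_fc(compute_fc(ts)), tpl).score)
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(np.mean(scores) - expected) < 3 * se

    def test_score_monotone_in_vulnerability(self):
        cfg = SimulationConfig(seed=4, series_length=2000, fc_coupling=0.3)
        tpl = generate_template(cfg)
        rng = _rng(cfg, 5)
        from pcskit.connectome_fc import compute_fc, vectorize_fc
        from pcskit.pcs_scoring import compute_pcs

        lo, _ = generate_subject_timeseries(-2.0, tpl, cfg, rng, subject_id="lo")
        hi, _ = generate_subject_timeseries(+2.0, tpl, cfg, rng, subject_id="hi")
        s_lo = compute_pcs(vectorize_fc(compute_fc(lo)), tpl).score
        s_hi = compute_pcs(vectorize_fc(compute_fc(hi)), tpl).score
        assert s_hi > s_lo

    def test_pcs_recovers_planted_vulnerability(self):
        cfg = SimulationConfig(
            seed=6, n_families=200, n_subjects=400, series_length=1000
        )
        cohort = generate_cohort(cfg)
        scores = score_cohort(cohort)
        r = np.corrcoef(scores["pcs"], cohort.truth["v"])[0, 1]
        assert r > 0.3

    def test_repair_engages_only_outside_valid_cone_and_is_logged(self):
        cfg = SimulationConfig(seed=1)
        tpl = generate_template(cfg)
        w = _normalized_weight_matrix(tpl)
        _, dist0 = subject_covariance(2.0, w, cfg)
        assert dist0 == 0.0
        # far beyond the truncation range the shift leaves the PSD cone
        cfg_loose = SimulationConfig(seed=1, distortion_bound=0.5)
        sigma, dist = subject_covariance(5.0, w, cfg_loose)
        assert dist > 0
        assert np.linalg.eigvalsh(sigma)[0] > 0
        assert np.allclose(np.diag(sigma), 1.0)

    def test_excessive_distortion_raises_config_error(self):
        cfg = SimulationConfig(seed=1, distortion_bound=0.01)
        tpl = generate_template(cfg)
        w = _normalized_weight_matrix(tpl)
        with pytest.raises(ConfigError, match="fc_coupling"):
            subject_covariance(8.0, w, cfg)

    def test_default_cohort_needs_no_repair(self):
        cfg = SimulationConfig(seed=13, n_families=100, n_subjects=200)
        cohort = generate_cohort(cfg)
        assert (cohort.repair_log["repair_distortion"] == 0).all()


class TestOutcomes:
    def test_cohort_is_bit_reproducible(self):
        cfg = SimulationConfig(seed=8, n_families=50, n_subjects=100, series_length=50)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert all(
            np.array_equal(x.data, y.data) for x, y in zip(a.timeseries, b.timeseries)
        )

    def test_deterministic_attrition_hits_exact_count(self):
        cfg = SimulationConfig(seed=3)  # default 407 baseline, rate 298/407
        v = generate_vulnerabilities(cfg)
        pheno, truth = generate_outcomes(v, cfg)
        assert (pheno["timepoint"] == "baseline").sum() == 407
        assert (pheno["timepoint"] == "followup").sum() == 298
        assert truth["has_followup"].sum() == 298

    def test_family_clustering_recovered(self):
        cfg = SimulationConfig(
            seed=17, n_families=500, n_subjects=1000, followup_rate=1.0
        )
        v = generate_vulnerabilities(cfg)
        pheno, truth = generate_outcomes(v, cfg)
        base = pheno[pheno["timepoint"] == "baseline"].merge(
            truth[["subject_id", "v"]], on="subject_id"
        )
        # residual ICC after the planted fixed effects, via one-way family ANOVA
        import statsmodels.api as sm

        d = base.copy()
        z = lambda s: (s - s.mean()) / s.std(ddof=1)
        resid = sm.OLS(
            z(d["anxiety"]),
            sm.add_constant(
                np.column_stack([z(d["stress"]), d["v"], z(d["stress"]) * d["v"]])
            ),
        ).fit().resid
        d["resid"] = resid
        grp = d.groupby("family_id")["resid"]
        k = 2.0
        ms_between = k * grp.mean().var(ddof=1)
        ms_within = grp.apply(lambda s: s.var(ddof=1)).mean()
        icc = (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)
        op = cfg.outcome_params
        truth_icc = op.family_intercept_sd**2 / (
            op.family_intercept_sd**2 + op.residual_sd**2
        )
        assert icc > 0
        assert abs(icc - truth_icc) < 0.1

    def test_cognition_is_nearly_decoupled_from_stress(self):
        cfg = SimulationConfig(seed=23, n_families=400, n_subjects=800)
        v = generate_vulnerabilities(cfg)
        pheno, _ = generate_outcomes(v, cfg)
        base = pheno[pheno["timepoint"] == "baseline"]
        res = fit_association(base, "cog_flanker", "stress", ["age", "sex"])
        assert abs(res.beta) < 0.15

    def test_discretized_scores_respect_instrument_ranges(self):
        cfg = SimulationConfig(seed=31, n_families=100, n_subjects=200, discretize=True)
        v = generate_vulnerabilities(cfg)
        pheno, _ = generate_outcomes(v, cfg)
        assert pheno["stress"].between(0, 60).all()
        assert pheno["depression"].between(0, 26).all()
        assert (pheno["stress"] == pheno["stress"].round()).all()

    def test_roster_cannot_exceed_family_capacity(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, n_families=10, n_subjects=100).roster_size


class TestClinicalCohort:
    def test_elevated_vulnerability_and_size(self):
        cfg = SimulationConfig(seed=10)
        clin = generate_clinical_cohort(cfg, n=80, v_shift=0.5, with_timeseries=False)
        assert len(clin.phenotypes) == 80
        assert clin.truth["v"].mean() > 0.2

    def test_families_are_singletons(self):
        cfg = SimulationConfig(seed=10)
        clin = generate_clinical_cohort(cfg, n=40, with_timeseries=False)
        assert clin.phenotypes["family_id"].nunique() == 40
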