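"""Tests of the SAEM fitter, likelihood machinery and covariate search."""

import numpy as np
import pandas as pd
import pytest

from dalbapk import (
    CohortConfig,
    CovariateModel,
    ModelSpec,
    SAEMSettings,
    VAD_TYPICAL,
    covariate_search,
    fit,
    generate_cohort,
    impute_bql,
    log_likelihood,
    standard_errors,
)
from dalbapk.estimation import FitResult
from dalbapk.model import conc_many

from conftest import dose_row, make_dataset, obs_row


def dense_noise_free_dataset(n_subjects=10, b=1e-3, seed=0):
    """Dense single-dose sampling from the typical subject, near-zero noise."""
    rng = np.random.default_rng(seed)
    times = np.array([1.0, 4, 12, 24, 48, 96, 168, 336, 504, 672, 840, 1008])
    p = VAD_TYPICAL
    f = conc_many(p.CL, p.V1, p.Q, p.V2, np.array([0.0]), np.array([1500.0]),
                  np.array([0.5]), times)[0]
    rows = []
    for sid in range(1, n_subjects + 1):
        rows.append(dose_row(sid))
        y = f * (1 + b * rng.standard_normal(f.shape))
        rows.extend(obs_row(sid, t, yv) for t, yv in zip(times, y))
    return make_dataset(rows)


class TestModelSpec:
    def test_fixed_q_excluded_from_free_count(self):
        spec = ModelSpec()  # Q fixed at 0.476
        assert spec.n_free == 7  # 3 typical + 3 omega + 1 error
        free_q = ModelSpec(fixed=(), iiv=("CL", "V1", "Q", "V2"))
        assert free_q.n_free == 9

    def test_free_parameter_without_iiv_rejected(self):
        with pytest.raises(ValueError, match="IIV"):
            ModelSpec(fixed=(), iiv=("CL", "V1", "V2"))

    def test_fixed_with_iiv_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(fixed=(("Q", 0.476),), iiv=("CL", "V1", "Q", "V2"))

    def test_three_compartment_not_supported(self):
        with pytest.raises(NotImplementedError):
            ModelSpec(n_compartments=3)


class TestFit:
    def test_noise_free_dense_recovery(self):
        # omega ~ 0, b -> 0, dense design: degenerates to least squares
        d = dense_noise_free_dataset()
        fr = fit(d, ModelSpec(), seed=0)
        for name, truth in (("CL", 0.050), ("V1", 6.5), ("V2", 15.4)):
            assert fr.estimates[name] == pytest.approx(truth, rel=1e-3)
        assert fr.error["b"] < 0.005
        assert fr.converged

    def test_subject_order_invariance(self, study_cohort):
        d = study_cohort["imputed"]
        blocks = [d.records[d.records["ID"] == sid] for sid in reversed(d.subjects)]
        reordered = pd.concat(blocks, ignore_index=True)
        from dalbapk import PKDataset

        fr1 = fit(d, ModelSpec(), seed=3, settings=SAEMSettings.fast())
        fr2 = fit(PKDataset(reordered), ModelSpec(), seed=3, settings=SAEMSettings.fast())
        for k in fr1.estimates:
            assert fr1.estimates[k] == pytest.approx(fr2.estimates[k], rel=1e-10)

    def test_seed_determinism(self, study_cohort):
        fr1 = fit(study_cohort["imputed"], ModelSpec(), seed=11, settings=SAEMSettings.fast())
        fr2 = fit(study_cohort["imputed"], ModelSpec(), seed=11, settings=SAEMSettings.fast())
        assert fr1.estimates == fr2.estimates
        assert fr1.omega == fr2.omega

    def test_fit_json_round_trip(self, study_fit):
        payload = study_fit.to_json_dict()
        again = FitResult.from_json_dict(payload)
        assert again.estimates == study_fit.estimates
        assert again.spec == study_fit.spec

    def test_summary_table_mentions_fixed_q(self, study_fit):
        table = study_fit.summary_table()
        assert "Q (fixed)" in table
        assert "omega_CL" in table


class TestLogLikelihood:
    def test_importance_matches_gauss_hermite_oracle(self):
        # 1 subject, 1 random effect: oracle = probabilists' Gauss-Hermite
        rows = [dose_row(1), obs_row(1, 1.0, 210.0), obs_row(1, 168.0, 40.0),
                obs_row(1, 1008.0, 14.0)]
        d = make_dataset(rows)
        spec = ModelSpec(fixed=(("Q", 0.476), ("V1", 6.5), ("V2", 15.4)), iiv=("CL",))
        fr = FitResult(
            spec=spec, estimates={"CL": 0.05, "V1": 6.5, "Q": 0.476, "V2": 15.4},
            omega={"CL": 0.3}, error={"b": 0.15}, betas={}, cov_medians={},
            converged=True, trajectory=None, ebe=None, seed=None, settings=None,
            n_free=spec.n_free,
        )
        lik = log_likelihood(fr, d, n_mc=50_000, seed=3)

        from numpy.polynomial.hermite_e import hermegauss

        nodes, weights = hermegauss(80)
        y = np.array([210.0, 40.0, 14.0])
        t = np.array([1.0, 168.0, 1008.0])
        ll = []
        for z in nodes:
            fv = conc_many(0.05 * np.exp(0.3 * z), 6.5, 0.476, 15.4,
                           np.array([0.0]), np.array([1500.0]), np.array([0.5]), t)[0]
            sd = 0.15 * fv
            ll.append(np.sum(-0.5 * ((y - fv) / sd) ** 2 - np.log(sd)
                             - 0.5 * np.log(2 * np.pi)))
        ll = np.array(ll)
        m = ll.max()
        marginal = np.log(np.sum(weights * np.exp(ll - m))) + m - 0.5 * np.log(2 * np.pi)
        assert lik.ofv == pytest.approx(-2.0 * marginal, abs=0.1)

    def test_mc_error_shrinks_with_more_draws(self, study_fit, study_cohort):
        small = log_likelihood(study_fit, study_cohort["imputed"], n_mc=500, seed=4)
        big = log_likelihood(study_fit, study_cohort["imputed"], n_mc=4000, seed=4)
        assert big.mc_se < small.mc_se
        assert abs(big.ofv - small.ofv) < 6 * (small.mc_se + big.mc_se)

    def test_aic_bic_consistent_with_free_count(self, study_fit, study_cohort):
        lik = log_likelihood(study_fit, study_cohort["imputed"], method="laplace")
        assert lik.aic == pytest.approx(lik.ofv + 2 * 7)
        assert lik.bic == pytest.approx(lik.ofv + 7 * np.log(13))

    def test_unknown_method_rejected(self, study_fit, study_cohort):
        with pytest.raises(ValueError):
            log_likelihood(study_fit, study_cohort["imputed"], method="vb")


class TestStandardErrors:
    def test_fim_rse_on_study_replica(self, study_fit, study_cohort):
        rse = standard_errors(study_fit, study_cohort["imputed"], method="fim")
        # structural parameters well determined; residual error poorly, as
        # expected for a 13-subject, 3-samples-per-subject design
        for key in ("theta_CL", "theta_V1", "theta_V2"):
            assert 0 < rse[key] < 30.0
        assert rse["error_b"] > 30.0

    def test_rse_dimensionless_under_unit_rescaling(self, study_fit):
        # log-scale SEs: RSE of V1 in litres would equal RSE of V1 in mL
        assert study_fit.rse is not None
        assert all(v > 0 for v in study_fit.rse.values())


class TestCovariateSearch:
    def test_missing_covariate_reported_per_subject(self, study_cohort):
        d = study_cohort["imputed"]
        broken = d.records.copy()
        broken.loc[broken["ID"] == 3, "CRCL"] = np.nan
        from dalbapk import PKDataset

        with pytest.raises(ValueError, match=r"CRCL.*3"):
            covariate_search(PKDataset(broken), ModelSpec(), covariate_columns=("CRCL",),
                             params=("CL",), seed=0)

    def test_strong_true_effect_selected_and_recovered(self):
        cfg = CohortConfig(
            n_subjects=100,
            covariate_model=CovariateModel(effects=(("CL", "CRCL", 0.75),)),
        )
        d, _ = generate_cohort(cfg, seed=11)
        imputed, _ = impute_bql(d)
        res = covariate_search(imputed, ModelSpec(), covariate_columns=("CRCL",),
                               params=("CL",), seed=0)
        assert res.selected == (("CL", "CRCL"),)
        assert res.final_fit.betas["CL~CRCL"] == pytest.approx(0.75, abs=0.25)

    def test_study_size_replica_selects_nothing(self, study_cohort):
        res = covariate_search(
            study_cohort["imputed"], ModelSpec(),
            covariate_columns=("WT", "BSA", "AGE", "CRCL", "ALB"),
            params=("CL",), seed=0,
        )
        assert res.selected == ()
        assert (res.trace["phase"] == "forward").all()
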