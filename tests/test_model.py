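"""Model-fitting contracts: determinism, identifiability, out-of-sample Z
inference, and mortality-curve behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cohoprior import (
    GeneratorConfig,
    ModelSpec,
    PreSpawnMortalityModel,
    fit_psm_model,
    generate_dataset,
    infer_z_for_new_subbasins,
    predict_mortality_curve,
)
from cohoprior.model import ValidationError
from cohoprior.synthetic import ConfigurationError, covariate_columns
from tests.conftest import make_posterior

FAST = dict(chains=2, draws_per_chain=150, warmup=400)


@pytest.fixture(scope="module")
def quick_fit(small_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_psm_model(small_table, ModelSpec(seed=3, **FAST))


class TestFit:
    def test_same_seed_identical_draws(self, small_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_psm_model(small_table, ModelSpec(seed=42, **FAST))
            b = fit_psm_model(small_table, ModelSpec(seed=42, **FAST))
        np.testing.assert_array_equal(a.slope, b.slope)
        np.testing.assert_array_equal(a.z_cur, b.z_cur)
        np.testing.assert_array_equal(a.loadings, b.loadings)

    def test_identifiability_constraints_hold(self, quick_fit):
        assert (quick_fit.slope > 0).all()
        assert (quick_fit.loadings[:, 0] > 0).all()
        assert (quick_fit.noise_sd > 0).all()
        assert (quick_fit.intercept_sd > 0).all()

    def test_posterior_z_tracks_truth(self, small_table, quick_fit):
        truth = small_table.set_index("subbasin_id")["z_true"]
        zmean = quick_fit.z_cur.mean(axis=0)
        r = np.corrcoef(zmean, truth[quick_fit.subbasin_ids])[0, 1]
        assert r > 0.9

    def test_null_slope_data_yields_smaller_slope(self, small_table):
        null = generate_dataset(
            GeneratorConfig(n_subbasins=60, n_surveyed=60, slope=0.0, seed=7))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_null = fit_psm_model(null, ModelSpec(seed=3, **FAST))
            p_alt = fit_psm_model(small_table, ModelSpec(seed=3, **FAST))
        assert np.median(p_null.slope) < np.median(p_alt.slope)
        assert np.median(p_null.slope) < 0.5  # mass near the positivity boundary

    def test_too_few_surveyed_rejected(self, small_table):
        t = small_table.copy()
        t["spawners_observed"] = 0
        with pytest.raises(ValidationError):
            fit_psm_model(t, ModelSpec(seed=0, **FAST))

    def test_diagnostics_populated(self, quick_fit):
        assert set(quick_fit.diagnostics["rhat"]) >= {"slope", "z", "intercept_sd"}
        assert quick_fit.diagnostics["max_rhat"] >= 1.0
        assert quick_fit.chains * quick_fit.draws_per_chain == quick_fit.n_draws

    def test_modelspec_invariants(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(chains=1)
        with pytest.raises(ConfigurationError):
            ModelSpec(draws_per_chain=50)

    def test_estimator_params_roundtrip(self):
        est = PreSpawnMortalityModel(chains=2, draws_per_chain=150, seed=9)
        params = est.get_params()
        assert params["chains"] == 2 and params["seed"] == 9
        est.set_params(seed=10)
        assert est.seed == 10


class TestInferZ:
    def test_noise_free_covariates_recover_truth(self, quick_fit):
        # a new subbasin whose covariates equal loading * z exactly
        lam = quick_fit.loadings.mean(axis=0)
        z_true = 1.3
        row = {"subbasin_id": "NEW1", "spawners_observed": 0, "deaths_observed": 0}
        for k, l in enumerate(lam):
            row[f"cov_{k + 1}"] = l * z_true
        post = infer_z_for_new_subbasins(quick_fit, pd.DataFrame([row]), seed=0)
        zhat = post.z_draws("NEW1")
        assert abs(zhat.mean() - z_true) < 3 * zhat.std()
        assert abs(zhat.mean() - z_true) < 0.35

    def test_zero_covariates_give_centered_z(self, quick_fit):
        row = {"subbasin_id": "NEW0", "spawners_observed": 0, "deaths_observed": 0}
        for k in range(quick_fit.loadings.shape[1]):
            row[f"cov_{k + 1}"] = 0.0
        post = infer_z_for_new_subbasins(quick_fit, pd.DataFrame([row]), seed=0)
        assert abs(post.z_draws("NEW0").mean()) < 0.2

    def test_uninformative_measurements_recover_prior_sd(self):
        # noise-sd draws so large the covariates carry no information
        post = make_posterior(np.zeros(400), np.ones(400))
        post.noise_sd[:] = 1e4
        row = {"subbasin_id": "NEWX", "cov_1": 0.7, "cov_2": -0.2,
               "spawners_observed": 0, "deaths_observed": 0}
        out = infer_z_for_new_subbasins(post, pd.DataFrame([row]), seed=1)
        z = out.z_draws("NEWX")
        assert abs(z.std() - 1.0) < 0.15
        assert abs(z.mean()) < 0.2

    def test_covariate_mismatch_rejected(self, quick_fit):
        row = {"subbasin_id": "BAD", "cov_1": 0.0,
               "spawners_observed": 0, "deaths_observed": 0}
        with pytest.raises(ValidationError):
            infer_z_for_new_subbasins(quick_fit, pd.DataFrame([row]))

    def test_inferred_marked_out_of_sample(self, posterior300):
        assert posterior300.in_sample.sum() == 60
        assert (~posterior300.in_sample).sum() == 240


class TestMortalityCurve:
    def test_degenerate_draw_logistic_values(self):
        post = make_posterior([0.0], 1.0)
        curve = predict_mortality_curve(post, "T0", np.array([-20.0, 0.0]))
        assert curve["median"].iloc[1] == pytest.approx(0.5)
        assert curve["median"].iloc[0] < 1e-8

    def test_median_curve_non_decreasing(self, quick_fit):
        grid = np.linspace(-4, 4, 41)
        sid = quick_fit.subbasin_ids[0]
        curve = predict_mortality_curve(quick_fit, sid, grid)
        assert (np.diff(curve["median"]) >= 0).all()
        assert (curve["lower"] <= curve["median"]).all()
        assert (curve["median"] <= curve["upper"]).all()

    def test_unknown_subbasin_requires_marginalize(self, quick_fit):
        with pytest.raises(ValidationError):
            predict_mortality_curve(quick_fit, "NOPE", np.array([0.0]))
        curve = predict_mortality_curve(quick_fit, "NOPE", np.array([0.0]),
                                        marginalize=True, seed=1)
        assert 0 < curve["median"].iloc[0] < 1
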