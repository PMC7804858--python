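"""Shared fixtures: synthetic tables, a session-scoped fitted posterior, and
a constructor for small hand-built posteriors used by the threshold oracles."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cohoprior import (
    GeneratorConfig,
    ModelSpec,
    PosteriorSamples,
    fit_psm_model,
    infer_z_for_new_subbasins,
    generate_dataset,
)


def make_posterior(intercepts, slopes, z_draws=None, subbasin_ids=None,
                   n_covariates=2) -> PosteriorSamples:
    """Hand-built posterior with given per-draw intercepts and slopes.

    ``intercepts`` has shape (S,) for a single subbasin or (S, J); ``z_draws``
    defaults to zeros.  Loadings/noise draws are filled with benign constants.
    """
    intercepts = np.asarray(intercepts, dtype=float)
    if intercepts.ndim == 1:
        intercepts = intercepts.reshape(-1, 1)  # (S,) -> single subbasin
    S, J = intercepts.shape
    slopes = np.broadcast_to(np.asarray(slopes, dtype=float), (S,)).copy()
    if z_draws is None:
        z_draws = np.zeros((S, J))
    z_draws = np.asarray(z_draws, dtype=float).reshape(S, J)
    if subbasin_ids is None:
        subbasin_ids = [f"T{j}" for j in range(J)]
    return PosteriorSamples(
        loadings=np.ones((S, n_covariates)),
        noise_sd=np.full((S, n_covariates), 0.5),
        slope=slopes,
        intercept_mean=intercepts.mean(axis=1),
        intercept_sd=np.full(S, 0.5),
        subbasin_ids=list(subbasin_ids),
        z_cur=z_draws,
        intercepts=intercepts,
        in_sample=np.ones(J, dtype=bool),
        chains=1,
        draws_per_chain=S,
        converged=True,
        diagnostics={"max_rhat": 1.0},
    )


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(n_subbasins=300, n_surveyed=60, seed=11)


@pytest.fixture(scope="session")
def table300(gen_config):
    return generate_dataset(gen_config)


@pytest.fixture(scope="session")
def posterior300(table300):
    """Posterior fitted on the 60 surveyed subbasins of table300 and extended
    to the remaining mapped-only subbasins.  MCMC settings are sized for the
    test session; threshold/prioritization properties hold for any draws, so
    dependent tests pass force=True rather than requiring convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit_psm_model(
            table300,
            ModelSpec(chains=2, draws_per_chain=600, warmup=1800, seed=5))
        return infer_z_for_new_subbasins(post, table300, seed=5)


@pytest.fixture(scope="session")
def small_table():
    return generate_dataset(GeneratorConfig(n_subbasins=60, n_surveyed=60, seed=7))
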