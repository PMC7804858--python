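"""Hierarchical Bayesian urbanization–mortality model.

A reduced structural equation model linking landscape covariates to coho
pre-spawn mortality through a one-dimensional latent urbanization factor Z:

    x_jk  ~ Normal(lambda_k * z_j, sigma_k)        measurement model
    d_j   ~ Binomial(n_j, logistic(a_j + b z_j))   mortality model
    a_j   ~ Normal(mu_a, tau)                      subbasin random intercept
    z_j   ~ Normal(0, 1)                           latent urbanization

with b > 0 and lambda_1 > 0 for identifiability.  Fitting is exposed both as
a scikit-learn style estimator (:class:`PreSpawnMortalityModel`) and as the
function :func:`fit_psm_model`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .sampler import PriorSpec, _PsmPosterior, run_chain
from .synthetic import ConfigurationError, covariate_columns

RHAT_THRESHOLD = 1.05


class ValidationError(ValueError):
    """Raised when input data violate the model's preconditions."""


class ConvergenceError(RuntimeError):
    """Raised when an unconverged posterior is used without being forced."""


@dataclass(frozen=True)
class ModelSpec:
    """MCMC configuration for the mortality model fit."""

    priors: PriorSpec = field(default_factory=PriorSpec)
    chains: int = 4
    draws_per_chain: int = 1500
    warmup: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ConfigurationError("chains must be >= 2 for convergence diagnostics")
        if self.draws_per_chain < 100:
            raise ConfigurationError("draws_per_chain must be >= 100")
        if self.warmup < 1:
            raise ConfigurationError("warmup must be positive")


@dataclass
class PosteriorSamples:
    """Joint posterior draws, flattened across chains (S = chains x draws).

    Per-subbasin arrays cover both fitted subbasins (their own intercept
    draws) and subbasins added later by :func:`infer_z_for_new_subbasins`
    (intercepts drawn per-posterior-draw from the population distribution).
    """

    loadings: np.ndarray        # (S, K)
    noise_sd: np.ndarray        # (S, K)
    slope: np.ndarray           # (S,)
    intercept_mean: np.ndarray  # (S,)
    intercept_sd: np.ndarray    # (S,)
    subbasin_ids: list[str]
    z_cur: np.ndarray           # (S, J)
    intercepts: np.ndarray      # (S, J)
    in_sample: np.ndarray       # (J,) bool
    chains: int
    draws_per_chain: int
    converged: bool
    diagnostics: dict

    def __post_init__(self) -> None:
        S = self.slope.shape[0]
        for name in ("loadings", "noise_sd", "intercept_mean", "intercept_sd",
                     "z_cur", "intercepts"):
            if getattr(self, name).shape[0] != S:
                raise ValidationError(f"draw count mismatch in {name}")
        if np.any(self.slope <= 0):
            raise ValidationError("slope draws must be positive")
        if np.any(self.noise_sd <= 0) or np.any(self.intercept_sd <= 0):
            raise ValidationError("sd draws must be positive")
        self._index = {sid: j for j, sid in enumerate(self.subbasin_ids)}

    @property
    def n_draws(self) -> int:
        return int(self.slope.shape[0])

    def __contains__(self, subbasin_id: str) -> bool:
        return subbasin_id in self._index

    def _col(self, subbasin_id: str) -> int:
        try:
            return self._index[subbasin_id]
        except KeyError:
            raise ValidationError(f"unknown subbasin_id {subbasin_id!r}") from None

    def z_draws(self, subbasin_id: str) -> np.ndarray:
        return self.z_cur[:, self._col(subbasin_id)]

    def intercept_draws(self, subbasin_id: str) -> np.ndarray:
        return self.intercepts[:, self._col(subbasin_id)]

    def with_subbasins(self, ids: list[str], z: np.ndarray, a: np.ndarray,
                       in_sample: bool = False) -> "PosteriorSamples":
        """New object with extra subbasin columns appended."""
        clash = set(ids) & set(self.subbasin_ids)
        if clash:
            raise ValidationError(f"subbasins already present: {sorted(clash)[:5]}")
        return PosteriorSamples(
            loadings=self.loadings, noise_sd=self.noise_sd, slope=self.slope,
            intercept_mean=self.intercept_mean, intercept_sd=self.intercept_sd,
            subbasin_ids=list(self.subbasin_ids) + list(ids),
            z_cur=np.concatenate([self.z_cur, z], axis=1),
            intercepts=np.concatenate([self.intercepts, a], axis=1),
            in_sample=np.concatenate(
                [self.in_sample, np.full(len(ids), bool(in_sample))]),
            chains=self.chains, draws_per_chain=self.draws_per_chain,
            converged=self.converged, diagnostics=self.diagnostics,
        )


def _chain_seeds(seed: int, chains: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(chains)]


def _diagnostics(chain_draws: list[dict], var_names: list[str]) -> dict:
    """Classic split-R-hat and bulk ESS per parameter block."""
    stacked = {
        name: np.stack([c[name] for c in chain_draws]) for name in var_names
    }
    idata = az.from_dict(posterior=stacked)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata, method="split")
        ess = az.ess(idata)
    diag: dict = {"rhat": {}, "ess_bulk": {}}
    for name in var_names:
        diag["rhat"][name] = float(np.max(rhat[name].values))
        diag["ess_bulk"][name] = float(np.min(ess[name].values))
    diag["max_rhat"] = max(diag["rhat"].values())
    diag["min_ess_bulk"] = min(diag["ess_bulk"].values())
    return diag


class PreSpawnMortalityModel(BaseEstimator):
    """Scikit-learn style estimator for the urbanization–mortality SEM.

    Parameters mirror :class:`ModelSpec`.  After :meth:`fit`, the joint
    posterior is available as ``posterior_`` and convergence diagnostics as
    ``diagnostics_``.

    Examples
    --------
    >>> model = PreSpawnMortalityModel(chains=2, draws_per_chain=200, seed=1)
    >>> model.fit(table)                                   # doctest: +SKIP
    >>> model.posterior_.slope.mean()                      # doctest: +SKIP
    """

    def __init__(self, priors: PriorSpec | None = None, chains: int = 4,
                 draws_per_chain: int = 1500, warmup: int = 3000, seed: int = 0):
        self.priors = priors
        self.chains = chains
        self.draws_per_chain = draws_per_chain
        self.warmup = warmup
        self.seed = seed

    def _spec(self) -> ModelSpec:
        return ModelSpec(priors=self.priors or PriorSpec(), chains=self.chains,
                         draws_per_chain=self.draws_per_chain,
                         warmup=self.warmup, seed=self.seed)

    def fit(self, table: pd.DataFrame, y=None) -> "PreSpawnMortalityModel":
        """Fit on the surveyed subbasins of a SubbasinTable.

        Rows with ``spawners_observed > 0`` enter the likelihood; the table
        must contain at least two of them.
        """
        spec = self._spec()
        cov_cols = covariate_columns(table)
        if not cov_cols:
            raise ValidationError("no covariate columns (cov_*) found")
        obs = table[table["spawners_observed"] > 0]
        if len(obs) < 2:
            raise ValidationError("need >= 2 subbasins with spawner counts > 0")
        deaths = obs["deaths_observed"].to_numpy(dtype=float)
        spawners = obs["spawners_observed"].to_numpy(dtype=float)
        if np.any(deaths > spawners) or np.any(deaths < 0):
            raise ValidationError("deaths must satisfy 0 <= deaths <= spawners")

        X = obs[cov_cols].to_numpy(dtype=float)
        post = _PsmPosterior(X, deaths, spawners, spec.priors)
        chain_draws = [
            run_chain(post, spec.draws_per_chain, spec.warmup, rng)
            for rng in _chain_seeds(spec.seed, spec.chains)
        ]

        var_names = ["loadings", "noise_sd", "slope", "intercept_mean",
                     "intercept_sd", "z", "intercept"]
        diag = _diagnostics(chain_draws, var_names)
        converged = diag["max_rhat"] <= RHAT_THRESHOLD
        if not converged:
            warnings.warn(
                f"MCMC not converged: max split-R-hat {diag['max_rhat']:.3f} "
                f"> {RHAT_THRESHOLD}; increase warmup/draws", RuntimeWarning)

        flat = {name: np.concatenate([c[name] for c in chain_draws])
                for name in var_names}
        self.posterior_ = PosteriorSamples(
            loadings=flat["loadings"], noise_sd=flat["noise_sd"],
            slope=flat["slope"], intercept_mean=flat["intercept_mean"],
            intercept_sd=flat["intercept_sd"],
            subbasin_ids=list(obs["subbasin_id"]),
            z_cur=flat["z"], intercepts=flat["intercept"],
            in_sample=np.ones(len(obs), dtype=bool),
            chains=spec.chains, draws_per_chain=spec.draws_per_chain,
            converged=converged, diagnostics=diag,
        )
        self.diagnostics_ = diag
        self.converged_ = converged
        self.covariate_columns_ = cov_cols
        return self

    def infer_z(self, table: pd.DataFrame, seed: int | None = None) -> PosteriorSamples:
        """Posterior of Z for mapped-only subbasins; see module function."""
        return infer_z_for_new_subbasins(self.posterior_, table, seed=seed)


def fit_psm_model(table: pd.DataFrame, spec: ModelSpec | None = None) -> PosteriorSamples:
    """Fit the hierarchical model and return posterior draws."""
    spec = spec or ModelSpec()
    est = PreSpawnMortalityModel(priors=spec.priors, chains=spec.chains,
                                 draws_per_chain=spec.draws_per_chain,
                                 warmup=spec.warmup, seed=spec.seed)
    return est.fit(table).posterior_


def infer_z_for_new_subbasins(posterior: PosteriorSamples, table: pd.DataFrame,
                              seed: int | None = None) -> PosteriorSamples:
    """Add posterior Z draws for subbasins with covariates but no counts.

    For each posterior draw the measurement model alone gives the conditional
    Z | covariates: with prior Z ~ N(0, 1),

        v = 1 / (1 + sum_k lambda_k^2 / sigma_k^2)
        m = v * sum_k lambda_k x_k / sigma_k^2

    and a Z value is sampled from N(m, v) so measurement uncertainty is
    retained.  Mortality predictions for these subbasins marginalise the
    random intercept: each draw gets an intercept sampled from that draw's
    population Normal(mu_a, tau).
    """
    cov_cols = covariate_columns(table)
    K = posterior.loadings.shape[1]
    if len(cov_cols) != K:
        raise ValidationError(
            f"covariate count mismatch: table has {len(cov_cols)}, model has {K}")
    new = table[~table["subbasin_id"].isin(posterior.subbasin_ids)]
    if len(new) == 0:
        return posterior
    X = new[cov_cols].to_numpy(dtype=float)  # (J_new, K)

    lam, sig = posterior.loadings, posterior.noise_sd  # (S, K)
    w = lam / sig**2
    v = 1.0 / (1.0 + np.sum(lam * w, axis=1))          # (S,)
    mean = (X @ w.T) * v[None, :]                      # (J_new, S)

    rng = np.random.default_rng(
        np.random.SeedSequence([0 if seed is None else int(seed), 2]))
    z = (mean + np.sqrt(v)[None, :] * rng.standard_normal(mean.shape)).T
    a = (posterior.intercept_mean[:, None]
         + posterior.intercept_sd[:, None]
         * rng.standard_normal((posterior.n_draws, len(new))))
    return posterior.with_subbasins(list(new["subbasin_id"]), z, a, in_sample=False)


def predict_mortality_curve(posterior: PosteriorSamples, subbasin_id: str | None,
                            z_grid: np.ndarray, marginalize: bool = False,
                            seed: int | None = None,
                            interval: float = 0.90) -> pd.DataFrame:
    """Posterior summaries of mortality M over a grid of urbanization values.

    Returns a DataFrame with columns ``z``, ``median``, ``lower``, ``upper``
    (central credible interval).  ``subbasin_id=None`` with
    ``marginalize=True`` gives the population-level curve.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    if not np.all(np.isfinite(z_grid)):
        raise ValidationError("z_grid must be finite")
    if subbasin_id is not None and subbasin_id in posterior:
        a = posterior.intercept_draws(subbasin_id)
    elif marginalize:
        rng = np.random.default_rng(
            np.random.SeedSequence([0 if seed is None else int(seed), 3]))
        a = (posterior.intercept_mean
             + posterior.intercept_sd * rng.standard_normal(posterior.n_draws))
    else:
        raise ValidationError(
            f"unknown subbasin_id {subbasin_id!r}; pass marginalize=True for a "
            "population-level curve")
    m = expit(a[:, None] + posterior.slope[:, None] * z_grid[None, :])
    lo = 0.5 - interval / 2.0
    hi = 0.5 + interval / 2.0
    return pd.DataFrame({
        "z": z_grid,
        "median": np.median(m, axis=0),
        "lower": np.quantile(m, lo, axis=0),
        "upper": np.quantile(m, hi, axis=0),
    })
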