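"""Seeded synthetic subbasin datasets.

Emulates the statistical structure the downstream analysis assumes: landscape
covariates driven by a one-dimensional latent urbanization factor ``Z``,
binomial spawner-mortality counts with a logistic link and subbasin random
intercepts, right-skewed stream-habitat metrics (a widespread coho metric with
a sparser, weakly correlated Chinook subset), and imperviousness mapped
monotonically from ``Z`` together with three future development scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

SCENARIOS = ("status_quo", "managed_growth", "unconstrained_growth")

#: Fixed column order used when a SubbasinTable is written to CSV.
SUBBASIN_COLUMNS_FIXED = [
    "subbasin_id",
    "spawners_observed",
    "deaths_observed",
    "habitat_km_coho",
    "habitat_km_chinook",
    "impervious_pct_current",
    "impervious_pct_status_quo",
    "impervious_pct_managed_growth",
    "impervious_pct_unconstrained_growth",
    "area_km2",
    "supports_coho",
]


class ConfigurationError(ValueError):
    """Raised when a generator or pipeline configuration is invalid."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic subbasin generator.

    The defaults describe a Puget-Sound-scale study system: ~1,400 analysis
    subbasins of which a small surveyed subset (``n_surveyed``) carries
    spawner mortality counts, five landscape covariates loading on a single
    latent urbanization factor, and three imperviousness growth scenarios
    whose multipliers are ordered managed < status quo < unconstrained.
    """

    n_subbasins: int = 1400
    n_surveyed: int = 60
    n_covariates: int = 5
    loadings: Sequence[float] | None = None  # default set per n_covariates
    covariate_noise_sd: float = 0.5
    intercept_mean: float = -2.0  # logit scale; ~12% mortality at Z = 0
    intercept_sd: float = 0.5
    slope: float = 1.5  # effect of Z on logit mortality
    surveys_per_subbasin: int = 1
    spawners_per_survey: int = 50
    habitat_log_mean: float = 2.5  # lognormal habitat-km, median ~12 km
    habitat_log_sd: float = 1.0
    chinook_presence_prob: float = 0.5
    chinook_correlation: float = 0.3  # log-scale correlation with coho habitat
    area_log_mean: float = 2.0  # lognormal km^2, median ~7.4 km^2
    area_log_sd: float = 0.6
    impervious_center: float = 2.0  # Z at which imperviousness = 50%
    impervious_scale: float = 1.0
    scenario_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "status_quo": 1.5,
            "managed_growth": 1.15,
            "unconstrained_growth": 2.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subbasins <= 0 or self.n_covariates <= 0:
            raise ConfigurationError("n_subbasins and n_covariates must be positive")
        if not 0 <= self.n_surveyed <= self.n_subbasins:
            raise ConfigurationError("n_surveyed must be in [0, n_subbasins]")
        for name in ("covariate_noise_sd", "intercept_sd", "habitat_log_sd",
                     "area_log_sd", "impervious_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.slope < 0:
            raise ConfigurationError("slope must be >= 0")
        if self.surveys_per_subbasin <= 0 or self.spawners_per_survey <= 0:
            raise ConfigurationError("survey counts must be positive")
        if not 0.0 <= self.chinook_presence_prob <= 1.0:
            raise ConfigurationError("chinook_presence_prob must be in [0, 1]")
        if set(self.scenario_multipliers) != set(SCENARIOS):
            raise ConfigurationError(f"scenario_multipliers must have keys {SCENARIOS}")
        if any(m <= 0 for m in self.scenario_multipliers.values()):
            raise ConfigurationError("scenario multipliers must be > 0")
        if self.loadings is not None and len(self.loadings) != self.n_covariates:
            raise ConfigurationError("loadings length must equal n_covariates")

    def resolved_loadings(self) -> np.ndarray:
        if self.loadings is not None:
            return np.asarray(self.loadings, dtype=float)
        base = np.array([1.0, 0.8, 0.6, 0.9, 0.7])
        reps = int(np.ceil(self.n_covariates / base.size))
        return np.tile(base, reps)[: self.n_covariates]

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


def _impervious_from_z(z: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    # monotone logistic squashing of the latent scale onto [0, 100] percent
    return 100.0 * expit((z - config.impervious_center) / config.impervious_scale)


def generate_landscape(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic subbasin table (without habitat metrics).

    The latent urbanization ``z_true`` of each subbasin is standard normal;
    covariate ``k`` is ``loading_k * z_true`` plus Gaussian noise; mortality
    follows a logistic regression on ``z_true`` with a subbasin random
    intercept; deaths are binomial. Only the first ``n_surveyed`` subbasins
    (chosen at random) receive spawner surveys — the rest have zero counts and
    stand in for mapped-only subbasins.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subbasins
    lam = config.resolved_loadings()

    z_true = rng.standard_normal(n)
    noise = rng.normal(0.0, config.covariate_noise_sd, size=(n, lam.size))
    covariates = z_true[:, None] * lam[None, :] + noise

    intercepts = rng.normal(config.intercept_mean, config.intercept_sd, size=n)
    mortality = expit(intercepts + config.slope * z_true)

    surveyed = np.zeros(n, dtype=bool)
    surveyed[rng.choice(n, size=config.n_surveyed, replace=False)] = True
    spawners = np.where(
        surveyed, config.surveys_per_subbasin * config.spawners_per_survey, 0
    )
    deaths = rng.binomial(spawners, mortality)

    impervious = _impervious_from_z(z_true, config)

    width = len(str(n))
    table = pd.DataFrame({"subbasin_id": [f"SB{i:0{width}d}" for i in range(n)]})
    for k in range(lam.size):
        table[f"cov_{k + 1}"] = covariates[:, k]
    table["spawners_observed"] = spawners
    table["deaths_observed"] = deaths
    table["impervious_pct_current"] = impervious
    for scenario in SCENARIOS:
        mult = config.scenario_multipliers[scenario]
        table[f"impervious_pct_{scenario}"] = np.minimum(100.0, impervious * mult)
    table["area_km2"] = rng.lognormal(config.area_log_mean, config.area_log_sd, size=n)
    table["supports_coho"] = True
    table["z_true"] = z_true
    table["intercept_true"] = intercepts
    return table


def generate_habitat_metrics(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Attach habitat-km metrics for coho and a sparser Chinook subset.

    Coho habitat is drawn for every coho-supporting subbasin from a lognormal
    (a free right-skewed choice; the marginal shape is not constrained by the
    analysis). Chinook habitat is positive only on a Bernoulli subset of coho
    subbasins and is only weakly correlated with coho habitat on the log
    scale, so the Chinook analysis population is strictly smaller and ranks
    under the two metrics can genuinely differ.
    """
    if len(table) == 0:
        raise ConfigurationError("subbasin table is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = table.copy()
    n = len(out)
    coho_mask = out["supports_coho"].to_numpy(dtype=bool)

    log_coho = rng.normal(config.habitat_log_mean, config.habitat_log_sd, size=n)
    out["habitat_km_coho"] = np.where(coho_mask, np.exp(log_coho), 0.0)

    present = coho_mask & (rng.random(n) < config.chinook_presence_prob)
    rho = config.chinook_correlation
    log_std = (log_coho - config.habitat_log_mean) / config.habitat_log_sd
    log_chin = (
        config.habitat_log_mean
        + config.habitat_log_sd
        * (rho * log_std + np.sqrt(1 - rho**2) * rng.standard_normal(n))
        - 0.7  # Chinook streams are shorter on average
    )
    out["habitat_km_chinook"] = np.where(present, np.exp(log_chin), 0.0)
    return out


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Full synthetic SubbasinTable: landscape + habitat metrics."""
    return generate_habitat_metrics(generate_landscape(config), config)


def covariate_columns(table: pd.DataFrame) -> list[str]:
    """Names of the landscape covariate columns, in order."""
    cols = [c for c in table.columns if c.startswith("cov_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def synthetic_grid_geojson(table: pd.DataFrame, cell_deg: float = 0.02) -> dict:
    """Square-grid GeoJSON polygons keyed by subbasin_id, for map smoke tests.

    Geometry is decorative: a row-major grid of square cells near Puget Sound
    coordinates. It never affects any computation.
    """
    n = len(table)
    ncol = int(np.ceil(np.sqrt(n)))
    lon0, lat0 = -123.0, 47.0
    features = []
    for i, sid in enumerate(table["subbasin_id"]):
        r, c = divmod(i, ncol)
        x0, y0 = lon0 + c * cell_deg, lat0 + r * cell_deg
        ring = [
            [x0, y0],
            [x0 + cell_deg, y0],
            [x0 + cell_deg, y0 + cell_deg],
            [x0, y0 + cell_deg],
            [x0, y0],
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"subbasin_id": sid},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {"type": "FeatureCollection", "features": features}
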