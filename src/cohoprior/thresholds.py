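"""Critical urbanization levels, ΔZ, and the (M_crit, α) sensitivity surface.

For each subbasin the logistic mortality regression is inverted over the
posterior: the critical urbanization Z_crit solves

    P(M >= M_crit | Z_crit, data) = 1 - alpha,

with the posterior CDF approximated by the MCMC draws.  Because every draw's
mortality curve is increasing in Z, each draw i crosses M_crit at a unique
point z*_i = (logit(M_crit) - a_i) / b_i, and Z_crit is the (1 - alpha)
empirical quantile of those crossing points.  ΔZ is then Z_crit minus the
alpha-quantile of the subbasin's current urbanization Z_cur, so that

    P(Z_cur + ΔZ <= Z_crit | data) = alpha

holds up to the empirical step-function resolution.  ΔZ < 0 marks a
restoration subbasin (effort required), ΔZ >= 0 a preservation subbasin
(resilience in hand); the ΔZ = 0 boundary is assigned to preservation by
default since no restoration effort is required there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model import ConvergenceError, PosteriorSamples
from .synthetic import ConfigurationError

RESTORATION = "restoration"
PRESERVATION = "preservation"

#: Empirical quantile rule: inverse empirical CDF (type 1), so the two
#: defining probability statements hold exactly in the step-function sense.
QUANTILE_METHOD = "inverted_cdf"


@dataclass(frozen=True)
class ThresholdSpec:
    """The (M_crit, alpha) pair governing threshold inversion.

    Defaults: M_crit = 0.3 (a mortality level tied to ~70-year extinction
    horizons for otherwise healthy coho populations) and alpha = 0.95.
    """

    m_crit: float = 0.3
    alpha: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.m_crit < 1.0:
            raise ConfigurationError("m_crit must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class DeltaZResult:
    subbasin_id: str
    m_crit: float
    alpha: float
    z_crit: float
    z_cur_alpha_quantile: float
    delta_z: float
    category: str

    def __post_init__(self) -> None:
        for v in (self.z_crit, self.z_cur_alpha_quantile, self.delta_z):
            if not np.isfinite(v):
                raise ValueError("DeltaZResult values must be finite")


def require_converged(posterior: PosteriorSamples, force: bool = False) -> None:
    """Refuse to consume an unconverged posterior unless explicitly forced."""
    if not posterior.converged and not force:
        raise ConvergenceError(
            "posterior flagged as unconverged "
            f"(max split-R-hat {posterior.diagnostics.get('max_rhat', float('nan')):.3f}); "
            "pass force=True to proceed anyway")


def crossing_points(posterior: PosteriorSamples, subbasin_id: str,
                    m_crit: float) -> np.ndarray:
    """Per-draw urbanization level at which mortality reaches m_crit."""
    a = posterior.intercept_draws(subbasin_id)
    return (logit(m_crit) - a) / posterior.slope


def exceedance_probability(posterior: PosteriorSamples, subbasin_id: str,
                           z: float, m_crit: float) -> float:
    """Posterior probability that mortality at urbanization z meets m_crit.

    Direct draw count: (1/S) * #{i : logistic(a_i + b_i z) >= m_crit}.
    Non-decreasing in z, with limits 0 and 1.
    """
    if posterior.n_draws == 0:
        raise ValueError("empty posterior")
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    a = posterior.intercept_draws(subbasin_id)
    m = expit(a + posterior.slope * z)
    return float(np.mean(m >= m_crit))


def solve_z_crit(posterior: PosteriorSamples, subbasin_id: str,
                 spec: ThresholdSpec) -> float:
    """Critical urbanization: exceedance probability equals 1 - alpha.

    Closed form: the (1 - alpha) empirical quantile (inverse-CDF rule) of the
    per-draw crossing points.  If 1 - alpha falls below the 1/S resolution of
    the draws, the boundary (smallest) crossing point is returned with a
    warning.
    """
    q = 1.0 - spec.alpha
    x = crossing_points(posterior, subbasin_id, spec.m_crit)
    if q < 1.0 / x.size:
        warnings.warn(
            f"requested exceedance level {q:.4g} is below the 1/S = "
            f"{1.0 / x.size:.4g} resolution of the posterior; returning the "
            "boundary crossing point", RuntimeWarning)
        return float(np.min(x))
    return float(np.quantile(x, q, method=QUANTILE_METHOD))


def solve_z_crit_bisection(posterior: PosteriorSamples, subbasin_id: str,
                           spec: ThresholdSpec, lo: float = -60.0,
                           hi: float = 60.0, tol: float = 1e-10) -> float:
    """Independent solver: bisection on the empirical exceedance step function.

    Finds the smallest z with P(M >= m_crit | z) >= 1 - alpha.  Kept as a
    cross-check of the closed-form quantile path.
    """
    target = 1.0 - spec.alpha
    if exceedance_probability(posterior, subbasin_id, lo, spec.m_crit) >= target:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if exceedance_probability(posterior, subbasin_id, mid, spec.m_crit) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def compute_delta_z(posterior: PosteriorSamples, subbasin_id: str,
                    spec: ThresholdSpec,
                    boundary_category: str = PRESERVATION) -> DeltaZResult:
    """ΔZ = Z_crit - Q_alpha(Z_cur draws), with its restoration/preservation call."""
    z_crit = solve_z_crit(posterior, subbasin_id, spec)
    z_cur_q = float(np.quantile(posterior.z_draws(subbasin_id), spec.alpha,
                                method=QUANTILE_METHOD))
    delta = z_crit - z_cur_q
    if delta < 0:
        category = RESTORATION
    elif delta > 0:
        category = PRESERVATION
    else:
        category = boundary_category
    return DeltaZResult(subbasin_id=subbasin_id, m_crit=spec.m_crit,
                        alpha=spec.alpha, z_crit=z_crit,
                        z_cur_alpha_quantile=z_cur_q, delta_z=delta,
                        category=category)


def delta_z_table(posterior: PosteriorSamples, subbasin_ids: Sequence[str],
                  spec: ThresholdSpec, force: bool = False) -> pd.DataFrame:
    """Vectorised ΔZ over many subbasins; one row per subbasin."""
    require_converged(posterior, force=force)
    if len(subbasin_ids) == 0:
        raise ValueError("no subbasins requested")
    cols = np.array([posterior._col(sid) for sid in subbasin_ids])
    a = posterior.intercepts[:, cols]                       # (S, J)
    x = (logit(spec.m_crit) - a) / posterior.slope[:, None]  # crossing points
    q = 1.0 - spec.alpha
    S = posterior.n_draws
    if q < 1.0 / S:
        warnings.warn("alpha exceeds posterior resolution; using boundary "
                      "crossing points", RuntimeWarning)
        z_crit = np.min(x, axis=0)
    else:
        z_crit = np.quantile(x, q, axis=0, method=QUANTILE_METHOD)
    z_cur_q = np.quantile(posterior.z_cur[:, cols], spec.alpha, axis=0,
                          method=QUANTILE_METHOD)
    delta = z_crit - z_cur_q
    return pd.DataFrame({
        "subbasin_id": list(subbasin_ids),
        "m_crit": spec.m_crit,
        "alpha": spec.alpha,
        "z_crit": z_crit,
        "z_cur_q": z_cur_q,
        "delta_z": delta,
        "category": np.where(delta < 0, RESTORATION, PRESERVATION),
        "in_sample": posterior.in_sample[cols],
    })


def sensitivity_grid(posterior: PosteriorSamples, subbasin_ids: Sequence[str],
                     m_crit_values: Sequence[float],
                     alpha_values: Sequence[float],
                     force: bool = False) -> pd.DataFrame:
    """Full factorial ΔZ surface over (M_crit, alpha), long format."""
    if len(m_crit_values) == 0 or len(alpha_values) == 0:
        raise ValueError("sensitivity grids must be non-empty")
    frames = [
        delta_z_table(posterior, subbasin_ids,
                      ThresholdSpec(m_crit=m, alpha=al), force=force)
        for m in m_crit_values for al in alpha_values
    ]
    return pd.concat(frames, ignore_index=True)
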