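"""Future-development risk flagging under imperviousness growth scenarios.

A subbasin is flagged as at risk under a scenario when it is currently in
good condition — imperviousness below the impairment threshold (10% by
default, the level above which streams are generally considered impacted)
and predicted spawner mortality below the mortality screen (0.10) — but the
scenario's projected imperviousness reaches the threshold.  Current condition
uses strict ``<`` and the projection uses ``>=``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import PosteriorSamples
from .synthetic import SCENARIOS

IMPERVIOUS_THRESHOLD = 10.0
MORTALITY_SCREEN = 0.10


def predicted_mortality(posterior: PosteriorSamples,
                        subbasin_ids) -> pd.Series:
    """Posterior median mortality at each subbasin's posterior median Z_cur."""
    cols = np.array([posterior._col(sid) for sid in subbasin_ids])
    z_med = np.median(posterior.z_cur[:, cols], axis=0)          # (J,)
    eta = posterior.intercepts[:, cols] + posterior.slope[:, None] * z_med[None, :]
    m = np.median(expit(eta), axis=0)
    return pd.Series(m, index=list(subbasin_ids), name="predicted_mortality")


def flag_future_risk(table: pd.DataFrame, mortality: pd.Series,
                     impervious_threshold: float = IMPERVIOUS_THRESHOLD,
                     mortality_screen: float = MORTALITY_SCREEN,
                     scenarios=SCENARIOS) -> pd.DataFrame:
    """Per subbasin x scenario flag table (long format).

    flagged iff current imperviousness < threshold, predicted mortality <
    mortality_screen, and the scenario's future imperviousness >= threshold.
    The rule is a pure function of its row, so the output is invariant to row
    order and to repeated application.
    """
    for scenario in scenarios:
        if f"impervious_pct_{scenario}" not in table.columns:
            raise KeyError(f"missing scenario column impervious_pct_{scenario}")
    mort = table["subbasin_id"].map(mortality)
    if mort.isna().any():
        missing = table.loc[mort.isna(), "subbasin_id"].tolist()
        raise ValueError(f"no mortality prediction for subbasins {missing[:5]}")
    frames = []
    current = table["impervious_pct_current"].to_numpy()
    good_now = (current < impervious_threshold) & (mort.to_numpy() < mortality_screen)
    for scenario in scenarios:
        future = table[f"impervious_pct_{scenario}"].to_numpy()
        frames.append(pd.DataFrame({
            "subbasin_id": table["subbasin_id"].to_numpy(),
            "scenario": scenario,
            "current_impervious_pct": current,
            "future_impervious_pct": future,
            "predicted_mortality": mort.to_numpy(),
            "flagged": good_now & (future >= impervious_threshold),
            "area_km2": table["area_km2"].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


def summarize_area_at_risk(flags: pd.DataFrame,
                           eligible_ids=None) -> pd.DataFrame:
    """Per-scenario flagged area and flagged fraction of eligible area.

    ``eligible_ids`` defines the denominator universe (typically preservation
    subbasins with ΔZ > 0 and current imperviousness below threshold); by
    default every subbasin in ``flags`` is eligible.  A zero eligible area
    yields a NaN fraction rather than a failure.
    """
    df = flags
    if eligible_ids is not None:
        df = flags[flags["subbasin_id"].isin(set(eligible_ids))]
    rows = []
    for scenario, grp in df.groupby("scenario", sort=False):
        eligible_area = float(grp["area_km2"].sum())
        flagged_area = float(grp.loc[grp["flagged"], "area_km2"].sum())
        rows.append({
            "scenario": scenario,
            "eligible_area_km2": eligible_area,
            "flagged_area_km2": flagged_area,
            "flagged_fraction": (flagged_area / eligible_area
                                 if eligible_area > 0 else np.nan),
            "n_flagged": int(grp["flagged"].sum()),
        })
    cols = ["scenario", "eligible_area_km2", "flagged_area_km2",
            "flagged_fraction", "n_flagged"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows, columns=cols)
    order = [s for s in SCENARIOS if s in set(out["scenario"])]
    return out.set_index("scenario").loc[order].reset_index()
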