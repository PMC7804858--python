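"""Conservation prioritization: scoring and ranking subbasins.

A subbasin's priority score is its Euclidean distance, in the (ΔZ, metric)
plane, from the ideal point (0, metric_max): a site needing no change in
urbanization and holding the most habitat.  Lower score = higher priority.
Restoration (ΔZ < 0) and preservation (ΔZ >= 0) subbasins are ranked
separately; metric_max is taken over the whole analysis population.

Because ΔZ (latent units) and habitat (km) are on incommensurate scales, the
default "scaled" axis mode divides ΔZ by the population maximum |ΔZ| and the
metric by metric_max before measuring distance, which keeps the ideal point
fixed at (0, 1).  The "raw" mode applies the distance to the unscaled axes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .thresholds import PRESERVATION, RESTORATION

METRIC_COLUMNS = {
    "coho_habitat_km": "habitat_km_coho",
    "chinook_habitat_km": "habitat_km_chinook",
}

AXIS_MODES = ("scaled", "raw")


def select_analysis_population(table: pd.DataFrame, metric_name: str) -> pd.DataFrame:
    """Subbasins entering the analysis for a given conservation metric.

    Keeps coho-supporting subbasins with a positive value of the chosen
    metric.  The Chinook population is therefore a subset of the coho one
    whenever Chinook habitat only occurs on coho streams.
    """
    col = METRIC_COLUMNS.get(metric_name, metric_name)
    if col not in table.columns:
        raise KeyError(
            f"unknown metric {metric_name!r}; expected one of "
            f"{sorted(METRIC_COLUMNS)} or an existing column name")
    out = table[table["supports_coho"] & (table[col] > 0)].copy()
    if len(out) == 0:
        warnings.warn(f"metric {metric_name!r} selects an empty analysis "
                      "population", RuntimeWarning)
    return out


def priority_score(axis_delta_z, axis_metric, axis_metric_max):
    """Euclidean distance to the ideal point (ΔZ = 0, metric = metric_max)."""
    axis_delta_z = np.asarray(axis_delta_z, dtype=float)
    axis_metric = np.asarray(axis_metric, dtype=float)
    return np.hypot(axis_delta_z, axis_metric - axis_metric_max)


def _prepare_axes(delta_z: np.ndarray, metric: np.ndarray, axis_mode: str):
    if axis_mode not in AXIS_MODES:
        raise ValueError(f"axis_mode must be one of {AXIS_MODES}")
    metric_max = float(np.max(metric))
    if axis_mode == "raw":
        return delta_z, metric, metric_max
    dz_scale = float(np.max(np.abs(delta_z)))
    dz_scale = dz_scale if dz_scale > 0 else 1.0
    m_scale = metric_max if metric_max > 0 else 1.0
    return delta_z / dz_scale, metric / m_scale, metric_max / m_scale


def rank_subbasins(delta_z_results: pd.DataFrame, metric_values: pd.Series,
                   axis_mode: str = "scaled") -> pd.DataFrame:
    """Build a PriorityTable from ΔZ results and a metric series.

    ``delta_z_results`` needs columns ``subbasin_id``, ``delta_z``,
    ``category``; ``metric_values`` is indexed by subbasin_id.  Scores use
    metric_max over the full population (both categories); each category is
    ranked separately, ascending in score, ties broken by subbasin_id.
    """
    df = delta_z_results[["subbasin_id", "delta_z", "category"]].copy()
    df["metric_value"] = df["subbasin_id"].map(metric_values)
    if df["metric_value"].isna().any():
        missing = df.loc[df["metric_value"].isna(), "subbasin_id"].tolist()
        raise ValueError(f"no metric value for subbasins {missing[:5]}")

    axis_dz, axis_metric, axis_max = _prepare_axes(
        df["delta_z"].to_numpy(), df["metric_value"].to_numpy(), axis_mode)
    df["axis_delta_z"] = axis_dz
    df["axis_metric"] = axis_metric
    df["score"] = priority_score(axis_dz, axis_metric, axis_max)
    df["axis_mode"] = axis_mode

    df = df.sort_values(["category", "score", "subbasin_id"],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = df.groupby("category").cumcount() + 1
    return df[["subbasin_id", "category", "metric_value", "axis_delta_z",
               "axis_metric", "score", "rank", "axis_mode"]]


def compare_rankings(ranking_a: pd.DataFrame, ranking_b: pd.DataFrame):
    """Per-subbasin priority-rank changes between two PriorityTables.

    The comparison is restricted to subbasins present in both rankings;
    change = rank_b - rank_a.  Returns ``(per_subbasin, summary)`` where the
    summary reports both the mean signed and the mean absolute change.
    """
    a = ranking_a.set_index("subbasin_id")
    b = ranking_b.set_index("subbasin_id")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("rankings share no subbasins")
    per = pd.DataFrame({
        "subbasin_id": common,
        "rank_a": a.loc[common, "rank"].to_numpy(),
        "rank_b": b.loc[common, "rank"].to_numpy(),
        "category_a": a.loc[common, "category"].to_numpy(),
        "category_b": b.loc[common, "category"].to_numpy(),
    })
    per["rank_change"] = per["rank_b"] - per["rank_a"]
    summary = {
        "n_common": int(len(common)),
        "n_category_changed": int((per["category_a"] != per["category_b"]).sum()),
        "mean_signed_change": float(per["rank_change"].mean()),
        "mean_absolute_change": float(per["rank_change"].abs().mean()),
    }
    return per, summary


def category_counts(priority_table: pd.DataFrame) -> dict[str, int]:
    counts = priority_table["category"].value_counts()
    return {RESTORATION: int(counts.get(RESTORATION, 0)),
            PRESERVATION: int(counts.get(PRESERVATION, 0))}
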