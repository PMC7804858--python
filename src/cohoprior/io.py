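"""Readers and writers for subbasin tables, posterior draws, and GeoJSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PosteriorSamples, ValidationError
from .synthetic import SUBBASIN_COLUMNS_FIXED, covariate_columns

REQUIRED_COLUMNS = [
    "subbasin_id", "spawners_observed", "deaths_observed",
    "habitat_km_coho", "habitat_km_chinook", "impervious_pct_current",
    "area_km2", "supports_coho",
]


def validate_subbasin_table(table: pd.DataFrame) -> None:
    """Enforce the SubbasinTable invariants; errors name offending CSV rows.

    Row numbers reported are 1-based CSV line numbers (header = line 1).
    """
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if not covariate_columns(table):
        raise ValidationError("no covariate columns (cov_*) found")

    def lines(mask) -> list[int]:
        return [int(i) + 2 for i in np.flatnonzero(np.asarray(mask))]

    dup = table["subbasin_id"].duplicated(keep=False)
    if dup.any():
        ids = sorted(table.loc[dup, "subbasin_id"].unique())
        problems.append(f"duplicate subbasin_id {ids[:5]} on rows {lines(dup)[:10]}")
    bad = table["deaths_observed"] > table["spawners_observed"]
    if bad.any():
        problems.append(f"deaths_observed > spawners_observed on rows {lines(bad)}")
    neg = (table["deaths_observed"] < 0) | (table["spawners_observed"] < 0)
    if neg.any():
        problems.append(f"negative counts on rows {lines(neg)}")
    imp_cols = [c for c in table.columns if c.startswith("impervious_pct")]
    for c in imp_cols:
        out = (table[c] < 0) | (table[c] > 100)
        if out.any():
            problems.append(f"{c} outside [0, 100] on rows {lines(out)}")
    nonpos = table["area_km2"] <= 0
    if nonpos.any():
        problems.append(f"area_km2 <= 0 on rows {lines(nonpos)}")
    chin = (table["habitat_km_chinook"] > 0) & (table["habitat_km_coho"] <= 0)
    if chin.any():
        problems.append("Chinook habitat without coho habitat on rows "
                        f"{lines(chin)}")
    if problems:
        raise ValidationError("invalid subbasin table:\n  " + "\n  ".join(problems))


def read_subbasin_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "supports_coho" in table.columns:
        table["supports_coho"] = table["supports_coho"].astype(bool)
    validate_subbasin_table(table)
    return table


def write_subbasin_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write with the documented fixed column order (covariates after id)."""
    cov = covariate_columns(table)
    lead = ["subbasin_id"] + cov
    rest = [c for c in SUBBASIN_COLUMNS_FIXED if c != "subbasin_id" and c in table.columns]
    extra = [c for c in table.columns if c not in lead + rest]
    table[lead + rest + extra].to_csv(path, index=False)


# --- posterior persistence -------------------------------------------------

def save_posterior(posterior: PosteriorSamples, csv_path: str | Path,
                   json_path: str | Path, thin: int = 1) -> None:
    """Flat long-format CSV (chain, draw, parameter, value) + JSON sidecar.

    ``thin > 1`` keeps every thin-th draw per chain, which bounds the artifact
    size for posteriors with many mapped subbasins.
    """
    if thin < 1:
        raise ValueError("thin must be >= 1")
    D_full = posterior.draws_per_chain
    if thin > 1:
        kept = np.arange(0, D_full, thin)
        keep = np.concatenate(
            [c * D_full + kept for c in range(posterior.chains)])
        posterior = PosteriorSamples(
            loadings=posterior.loadings[keep], noise_sd=posterior.noise_sd[keep],
            slope=posterior.slope[keep],
            intercept_mean=posterior.intercept_mean[keep],
            intercept_sd=posterior.intercept_sd[keep],
            subbasin_ids=posterior.subbasin_ids,
            z_cur=posterior.z_cur[keep], intercepts=posterior.intercepts[keep],
            in_sample=posterior.in_sample, chains=posterior.chains,
            draws_per_chain=len(kept), converged=posterior.converged,
            diagnostics=posterior.diagnostics)
    S = posterior.n_draws
    D = posterior.draws_per_chain
    chain = np.repeat(np.arange(posterior.chains), D)
    draw = np.tile(np.arange(D), posterior.chains)

    names: list[str] = []
    cols: list[np.ndarray] = []
    K = posterior.loadings.shape[1]
    for k in range(K):
        names.append(f"loading[{k + 1}]")
        cols.append(posterior.loadings[:, k])
        names.append(f"noise_sd[{k + 1}]")
        cols.append(posterior.noise_sd[:, k])
    names += ["slope", "intercept_mean", "intercept_sd"]
    cols += [posterior.slope, posterior.intercept_mean, posterior.intercept_sd]
    for j, sid in enumerate(posterior.subbasin_ids):
        names.append(f"z[{sid}]")
        cols.append(posterior.z_cur[:, j])
        names.append(f"intercept[{sid}]")
        cols.append(posterior.intercepts[:, j])

    long = pd.DataFrame({
        "chain": np.tile(chain, len(names)),
        "draw": np.tile(draw, len(names)),
        "parameter": np.repeat(names, S),
        "value": np.concatenate(cols),
    })
    long.to_csv(csv_path, index=False, float_format="%.8g")

    meta = {
        "chains": posterior.chains,
        "draws_per_chain": posterior.draws_per_chain,
        "n_covariates": K,
        "subbasin_ids": list(posterior.subbasin_ids),
        "in_sample": [bool(v) for v in posterior.in_sample],
        "converged": bool(posterior.converged),
        "diagnostics": posterior.diagnostics,
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def load_posterior(csv_path: str | Path, json_path: str | Path) -> PosteriorSamples:
    meta = json.loads(Path(json_path).read_text())
    long = pd.read_csv(csv_path)
    wide = long.pivot_table(index=["chain", "draw"], columns="parameter",
                            values="value", sort=False).sort_index()
    S = meta["chains"] * meta["draws_per_chain"]
    if len(wide) != S:
        raise ValidationError("posterior CSV draw count disagrees with sidecar")
    K = meta["n_covariates"]
    ids = meta["subbasin_ids"]
    return PosteriorSamples(
        loadings=np.column_stack([wide[f"loading[{k + 1}]"] for k in range(K)]),
        noise_sd=np.column_stack([wide[f"noise_sd[{k + 1}]"] for k in range(K)]),
        slope=wide["slope"].to_numpy(),
        intercept_mean=wide["intercept_mean"].to_numpy(),
        intercept_sd=wide["intercept_sd"].to_numpy(),
        subbasin_ids=ids,
        z_cur=np.column_stack([wide[f"z[{sid}]"] for sid in ids]),
        intercepts=np.column_stack([wide[f"intercept[{sid}]"] for sid in ids]),
        in_sample=np.asarray(meta["in_sample"], dtype=bool),
        chains=meta["chains"],
        draws_per_chain=meta["draws_per_chain"],
        converged=meta["converged"],
        diagnostics=meta["diagnostics"],
    )


def read_geojson(path: str | Path) -> dict:
    gj = json.loads(Path(path).read_text())
    if gj.get("type") != "FeatureCollection":
        raise ValidationError("expected a GeoJSON FeatureCollection")
    return gj


def write_geojson(gj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(gj))
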