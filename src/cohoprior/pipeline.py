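"""End-to-end orchestration: simulate → fit → infer → thresholds →
prioritize → sensitivity → scenarios, with a reproducibility manifest.

All randomness flows from a single root seed, split per stage with
``numpy.random.SeedSequence`` so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .model import ModelSpec, fit_psm_model, infer_z_for_new_subbasins
from .prioritize import category_counts, compare_rankings, rank_subbasins, select_analysis_population
from .scenarios import flag_future_risk, predicted_mortality, summarize_area_at_risk
from .synthetic import ConfigurationError, GeneratorConfig, generate_dataset
from .thresholds import PRESERVATION, ThresholdSpec, delta_z_table, sensitivity_grid

from .prioritize import METRIC_COLUMNS

STAGES = ("simulate", "fit", "infer", "thresholds", "prioritize",
          "sensitivity", "scenarios")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the root seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(root_seed).spawn(len(STAGES))[idx]
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    outdir: str = "cohoprior_output"
    input_table: str | None = None      # None -> simulate synthetic data
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    m_crit_grid: tuple = (0.20, 0.25, 0.30, 0.35, 0.40)
    alpha_grid: tuple = (0.80, 0.90, 0.95, 0.99)
    metrics: tuple = ("coho_habitat_km", "chinook_habitat_km")
    axis_mode: str = "scaled"
    impervious_threshold: float = 10.0
    mortality_screen: float = 0.10
    sensitivity_max_subbasins: int = 200  # cap for the grid artifact
    posterior_max_saved_draws: int = 100  # per chain, caps the CSV artifact
    fit_retries: int = 2                  # doubled-budget refits on non-convergence
    allow_unconverged: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorConfig(**kwargs["generator"])
        if "model" in kwargs:
            kwargs["model"] = ModelSpec(**kwargs["model"])
        if "threshold" in kwargs:
            kwargs["threshold"] = ThresholdSpec(**kwargs["threshold"])
        for key in ("m_crit_grid", "alpha_grid", "metrics"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def validate(self) -> None:
        for v in list(self.m_crit_grid) + list(self.alpha_grid):
            if not 0.0 < v < 1.0:
                raise ConfigurationError("grid values must lie in (0, 1)")
        ThresholdSpec(self.threshold.m_crit, self.threshold.alpha)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["scenario_multipliers"] = dict(
            d["generator"]["scenario_multipliers"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of in-memory results + paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- data ------------------------------------------------------------
    if config.input_table is not None:
        table = io.read_subbasin_table(config.input_table)
    else:
        gen = config.generator.with_seed(stage_seed(config.seed, "simulate"))
        table = generate_dataset(gen)
    io.write_subbasin_table(table, outdir / "subbasins.csv")

    # --- fit on surveyed subbasins --------------------------------------
    # marginal non-convergence is retried with a doubled budget (bounded,
    # deterministic: the retry seeds derive from the root seed)
    fit_seed = stage_seed(config.seed, "fit")
    for attempt in range(config.fit_retries + 1):
        spec = dataclasses.replace(
            config.model, seed=fit_seed + attempt,
            warmup=config.model.warmup * 2**attempt,
            draws_per_chain=config.model.draws_per_chain * 2**attempt)
        posterior = fit_psm_model(table, spec)
        if posterior.converged:
            break
    if not posterior.converged and not config.allow_unconverged:
        raise RuntimeError(
            "stage 'fit' failed: posterior unconverged (max split-R-hat "
            f"{posterior.diagnostics['max_rhat']:.3f}) after "
            f"{config.fit_retries + 1} attempts; increase warmup/draws or "
            "set allow_unconverged")

    # --- infer Z for mapped-only subbasins -------------------------------
    posterior = infer_z_for_new_subbasins(
        posterior, table, seed=stage_seed(config.seed, "infer"))
    thin = max(1, -(-posterior.draws_per_chain // config.posterior_max_saved_draws))
    io.save_posterior(posterior, outdir / "posterior.csv",
                      outdir / "posterior_diagnostics.json", thin=thin)

    # --- thresholds ------------------------------------------------------
    coho_pop = select_analysis_population(table, "coho_habitat_km")
    delta = delta_z_table(posterior, list(coho_pop["subbasin_id"]),
                          config.threshold, force=config.allow_unconverged)
    delta.to_csv(outdir / "delta_z.csv", index=False)

    # --- prioritization per metric ---------------------------------------
    priorities: dict[str, pd.DataFrame] = {}
    for metric in config.metrics:
        pop = select_analysis_population(table, metric)
        sub = delta[delta["subbasin_id"].isin(set(pop["subbasin_id"]))]
        metric_col = METRIC_COLUMNS.get(metric, metric)
        values = pop.set_index("subbasin_id")[metric_col]
        pt = rank_subbasins(sub, values, axis_mode=config.axis_mode)
        pt.to_csv(outdir / f"priority_{metric}.csv", index=False)
        priorities[metric] = pt

    rank_summary = None
    if len(priorities) >= 2:
        names = list(priorities)
        _, rank_summary = compare_rankings(priorities[names[0]], priorities[names[1]])
        (outdir / "rank_comparison.json").write_text(
            json.dumps({"metric_a": names[0], "metric_b": names[1],
                        **rank_summary}, indent=2))

    # --- sensitivity surface ---------------------------------------------
    sens_ids = list(coho_pop["subbasin_id"][: config.sensitivity_max_subbasins])
    sens = sensitivity_grid(posterior, sens_ids, config.m_crit_grid,
                            config.alpha_grid, force=config.allow_unconverged)
    sens.to_csv(outdir / "sensitivity.csv", index=False)

    # --- future scenarios ------------------------------------------------
    mort = predicted_mortality(posterior, list(table["subbasin_id"]))
    flags = flag_future_risk(table, mort,
                             impervious_threshold=config.impervious_threshold,
                             mortality_screen=config.mortality_screen)
    flags.to_csv(outdir / "scenario_flags.csv", index=False)
    eligible = delta[
        (delta["category"] == PRESERVATION) & (delta["delta_z"] > 0)
    ].merge(table[["subbasin_id", "impervious_pct_current"]], on="subbasin_id")
    eligible_ids = eligible.loc[
        eligible["impervious_pct_current"] < config.impervious_threshold,
        "subbasin_id"]
    summary = summarize_area_at_risk(flags, eligible_ids)
    (outdir / "scenario_summary.json").write_text(
        summary.set_index("scenario").to_json(indent=2))

    # --- manifest ---------------------------------------------------------
    artifacts = sorted(p.name for p in outdir.iterdir()
                       if p.suffix in {".csv", ".json"} and p.name != "manifest.json")
    config_json = json.dumps(config.to_jsonable(), sort_keys=True)
    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "converged": bool(posterior.converged),
        "max_rhat": posterior.diagnostics["max_rhat"],
        "category_counts": {m: category_counts(t) for m, t in priorities.items()},
        "runtime_s": round(time.time() - t0, 2),
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "table": table, "posterior": posterior, "delta_z": delta,
        "priorities": priorities, "sensitivity": sens, "scenario_flags": flags,
        "scenario_summary": summary, "rank_summary": rank_summary,
        "manifest": manifest, "outdir": outdir,
    }
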