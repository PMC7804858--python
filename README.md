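# cohoprior

Threshold-based conservation prioritization of watershed subbasins from a
hierarchical Bayesian urbanization–mortality model.

## The problem

Urban stormwater runoff kills adult coho salmon (*Oncorhynchus kisutch*)
before they can spawn; in heavily developed watersheds this pre-spawn
mortality is high enough to drive otherwise healthy populations to local
extinction within decades. Managers who must decide *where* to spend
restoration or preservation money need to know, for every subbasin:

1. how close current urbanization is to the level at which mortality risk
   becomes unacceptable, and
2. how much habitat is at stake there.

`cohoprior` implements that analysis end to end: it fits a reduced
hierarchical Bayesian structural equation model linking landscape covariates
to coho pre-spawn mortality through a one-dimensional latent urbanization
factor *Z*, inverts the posterior to find each subbasin's critical
urbanization level, converts the gap into a restoration/preservation
classification, ranks subbasins by a cost-effectiveness score, and
stress-tests the ranking against threshold choices, conservation metrics and
future development scenarios. A seeded synthetic-data module generates
subbasin tables with the same statistical structure, so the whole pipeline is
testable without any GIS downloads.

## The model and statistics

For surveyed subbasin *j* with covariates *x*<sub>jk</sub>, spawner count
*n*<sub>j</sub> and observed deaths *d*<sub>j</sub>:

```
x_jk ~ Normal(λ_k z_j, σ_k)            measurement model
d_j  ~ Binomial(n_j, logistic(a_j + b z_j))   mortality model
a_j  ~ Normal(μ_a, τ)                  subbasin random intercept
z_j  ~ Normal(0, 1)                    latent urbanization
```

with *b* > 0 and λ₁ > 0 for identifiability. Sampling is by an adaptive
Metropolis-within-Gibbs scheme (see `docs/methods.md`); subbasins without
survey data get posterior *Z* draws from the measurement model alone.

Downstream quantities, per subbasin and per posterior draw set:

- **Z_crit** solves `P(M ≥ M_crit | Z_crit, data) = 1 − α`: the urbanization
  level at which mortality risk *M* exceeds the critical level *M*_crit
  (default 0.3) with probability 1 − α (default α = 0.95). Because each
  draw's mortality curve is increasing in *Z*, Z_crit is the (1 − α)
  empirical quantile of the per-draw crossing points
  `(logit(M_crit) − a_i) / b_i`.
- **ΔZ = Z_crit − Q_α(Z_cur)**: negative ΔZ means restoration effort is
  required; positive ΔZ measures preservation resilience.
- **Priority score** = Euclidean distance from (ΔZ, metric) to the ideal
  point (0, metric_max), where the metric is stream-km of coho (or Chinook)
  habitat. Lower score = higher priority; restoration and preservation are
  ranked separately.
- **Future risk flags**: subbasins currently below 10% imperviousness and
  below 10% predicted mortality, but projected to reach ≥ 10% imperviousness
  under a growth scenario (status quo / managed / unconstrained).

## Worked example

```python
from cohoprior import (GeneratorConfig, ThresholdSpec, generate_dataset,
                       PreSpawnMortalityModel, delta_z_table, rank_subbasins,
                       select_analysis_population)

table = generate_dataset(GeneratorConfig(n_subbasins=300, n_surveyed=60, seed=11))
model = PreSpawnMortalityModel(seed=2)   # default: 4 chains, 1500 draws, 3000 warmup
model.fit(table)
posterior = model.infer_z(table, seed=2)
print("converged:", model.converged_,
      " max split-R-hat:", round(model.diagnostics_["max_rhat"], 3))
print("slope (posterior mean):", round(posterior.slope.mean(), 2))

pop = select_analysis_population(table, "coho_habitat_km")
delta = delta_z_table(posterior, list(pop["subbasin_id"]),
                      ThresholdSpec(m_crit=0.3, alpha=0.95))
print(delta["category"].value_counts().to_dict())

ranking = rank_subbasins(delta, pop.set_index("subbasin_id")["habitat_km_coho"])
print(ranking[ranking["category"] == "preservation"].nsmallest(3, "rank")
      [["subbasin_id", "metric_value", "score", "rank"]].to_string(index=False))
```

prints

```
converged: True  max split-R-hat: 1.023
slope (posterior mean): 1.51
{'restoration': 187, 'preservation': 113}
subbasin_id  metric_value    score  rank
      SB279    227.661320 0.030045     1
      SB121    160.918430 0.365895     2
      SB044     96.435419 0.589893     3
```

The generating slope was 1.5, recovered as 1.51. Of 300 coho subbasins, 187
sit beyond their critical urbanization level (restoration) and 113 retain
resilience (preservation). The top preservation pick, SB279, combines a ΔZ
very close to the threshold with the largest habitat stock, hence a score
near zero.

The same analysis is available from the shell:

```bash
cohoprior simulate --n-subbasins 300 --n-surveyed 60 --seed 11 --out subbasins.csv
cohoprior run-all --outdir results/ --seed 2
```

`run-all` writes the subbasin table, thinned posterior draws + diagnostics,
the ΔZ table, one priority table per metric, the (M_crit, α) sensitivity
surface, scenario flags/summary and a manifest with per-stage seeds and
artifact hashes.

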