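# dicascade

Bayesian phylogenetic analysis of the **dental inhibitory cascade**
(DIC) model of molar size patterning, aimed at evolutionary
morphologists and phylogenetic comparative methods users.

The DIC model proposes that the relative areas of the three lower
molars follow from a single activator/inhibitor balance *a/i*
established during development:

    M1 = 1,   M2 = a/i,   M3 = 2(a/i) − 1

so species should fall on the line *M3/M1 = 2(M2/M1) − 1* in
molar-proportion morphospace, M2 should be one third of total molar
area, and M3 should be lost when *M2/M1* < 0.5.  `dicascade` provides
everything needed to confront these predictions with specimen-level
tooth measurements on a phylogeny:

- **`dic_core`** — the model geometry: areas from *a/i*, morphospace
  region classification, the agenesis threshold, perpendicular
  deviation from the model line.
- **`morphometrics`** — crown areas from lengths and breadths, the
  ellipse/rectangle shape correction calibrated on outline areas,
  study-design exclusion rules, sex-pooled species means,
  small-sample coefficients of variation.
- **`phylo`** — Newick/NEXUS ultrametric trees (via dendropy), the
  scaled Brownian covariance Σ, Pagel's λ from variance components.
- **`pglmm`** — a from-scratch Gibbs/Metropolis sampler for Bayesian
  phylogenetic generalized linear mixed models (Gaussian and
  Bernoulli-logit families, between/within-species predictor
  splitting, parameter-expanded random-effect priors), with HDI and
  ROPE summaries and Heidelberger–Welch convergence diagnostics.
  Models follow the statsmodels pattern: build with
  `PGLMM.from_dataframe(...)`, call `.fit(schedule, seed)`, inspect a
  `PGLMMResults` via `.summary()`, `.hdi()`, `.rope()`.
- **`analyses`** — the study regressions as one-call pipeline stages:
  morphospace summary, proportion regression, relative-M2 model,
  posterior-draw mediation, body-mass/deviation, CV comparison,
  agenesis models, diet logistic model, area-correction validation.
- **`synthetic`** — generators for phylogenies and specimen tables
  with known ground truth for every recoverable parameter.

A thin `dic` command-line wrapper (`dic simulate`, `dic prepare`,
`dic fit`, `dic report`) covers the common batch workflow.

## Worked example

Simulate a 30-species study under the cascade model, prepare it, and
test whether the morphospace line is recovered:

```python
from dicascade import analyses, synthetic
from dicascade.pglmm import MCMCSchedule

sim = synthetic.simulate_dataset(
    synthetic.SimulationConfig(n_species=30, n_specimens_per_species=10, seed=7)
)
specimens, summaries, log = analyses.prepare_specimens(sim.specimens)

space = analyses.summarize_morphospace(summaries)
print(f"{space.percent_consistent:.1f}% of {space.n_species} species "
      f"consistent with the cascade; regions: {space.region_counts}")

res = analyses.run_proportion_regression(
    specimens, sim.tree, schedule=MCMCSchedule(4000, 1000, 3), seed=5
)
print(f"slope {res.slope_between.posterior_mean:.3f} "
      f"HDI {tuple(round(v, 3) for v in res.slope_between.hdi95)} "
      f"P(in ROPE) {res.slope_between.posterior_probability:.2f}")
print(f"intercept {res.intercept.posterior_mean:.3f}")
```

Output:

```
96.4% of 28 species consistent with the cascade; regions: {'INCREASING': 1, 'DECREASING': 26, 'M2_PEAK': 1, 'M2_TROUGH': 0, 'ON_LINE': 0, 'EQUAL': 0}
slope 1.926 HDI (1.842, 2.014) P(in ROPE) 0.74
intercept -0.945
```

The between-species slope and intercept sit on the generative values 2
and −1 (this short demonstration chain at 30 species leaves some
posterior mass outside the ROPE `[1.90, 2.10]`; the full-scale
schedule at 100 species centres tightly on 2, as the acceptance run
below shows).  Two of the thirty species were dropped by the
at-least-four-specimens-of-both-sexes filter, and because the data
were simulated exactly on the model line, nearly all centroids land in
cascade-consistent regions, one pushed into the M2-peak region by
specimen noise.

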