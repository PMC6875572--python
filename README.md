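# isonich

Isotopic-niche and trait-change analysis for plankton time series.

`isonich` is for ecologists quantifying how a zooplankton community's diet,
trophic niche and body-size structure respond to environmental change —
e.g. the transition from the cold, fully mixed to the warm, stratified
season of a monomictic reservoir. It implements the complete quantitative
chain on δ¹³C/δ¹⁵N consumer data:

* **Diet-source mixing** — an a-priori Monte-Carlo mixing-polygon screen
  (consumers outside the 95% confidence region of the simulated source
  polygon are removed), then a Bayesian mixing model with trophic
  enrichment factors (0.4 ± 1.3 ‰ for δ¹³C, 3.4 ± 1.0 ‰ for δ¹⁵N),
  a flat Dirichlet prior on diet proportions `p` and a residual error term:
  `x_jk ~ N(Σ_s p_s(µ_sk + f_k), Σ_s p_s²(σ_sk² + τ_k²) + ε_k²)`,
  sampled by adaptive Metropolis with split-R̂/ESS diagnostics.
* **Isotopic-niche metrics** — Layman community-wide metrics (CR, NR, CD,
  MNND, SDNND, hull area TA), the standard ellipse area `SEA = π√det S`,
  its small-sample correction `SEA_C = SEA·(n−1)/(n−2)`, the Bayesian
  posterior `SEA_B` from a vague conjugate bivariate-normal model, and
  numerical ellipse overlap.
* **Price-equation partition** — the change in a community-weighted trait
  `Δz̄ = Σq′z′ − Σqz` split exactly into taxa sorting
  `TS = Σ z_i(q_i′ − q_i)`, intrataxonomic variation
  `ITV = Σ q_i′(z_i′ − z_i)` and turnover `TT` (gain − loss), with
  percentage contributions and Spearman linkage of those contributions to
  environmental change.
* **Environment statistics** — one-factor PERMANOVA (pseudo-F, R²,
  permutation p), Spearman collinearity pruning (|ρ| > 0.7, p < 0.05) and
  VIF < 10 predictor filtering.
* **PLS path modeling** — reflective latent blocks (temperature,
  physicochemistry, nutrients, chlorophyll, community responses), loading
  < 0.7 pruning, path coefficients, R² and `GoF = √(communality · R²)`,
  with bootstrap significance at α = 0.10.
* **Synthetic reservoir generator** — a 21-date, two-period survey with six
  taxon groups and six POM sources, with full ground truth for recovery
  tests.

## Worked example

Run the full pipeline on one synthetic reservoir realization:

```python
from isonich.pipeline import run_synthetic_pipeline

s = run_synthetic_pipeline(seed=1)
print(f"CWM body size   mixing {s.cwm_body_size_mixing:.2f} ug/ind, "
      f"stratification {s.cwm_body_size_stratification:.2f} ug/ind")
print(f"body-size change   TS {s.body_size_partition.rel_TS:.1f}% "
      f"ITV {s.body_size_partition.rel_ITV:.1f}%")
print(f"niche-breadth change  TS {s.niche_partition.rel_TS:.1f}% "
      f"ITV {s.niche_partition.rel_ITV:.1f}%")
print(f"community SEA_B   mixing {s.sea_b_mixing.mode:.2f}, "
      f"stratification {s.sea_b_stratification.mode:.2f} permil^2")
print(f"PERMANOVA period   R2 {s.permanova.r_squared:.3f}  p {s.permanova.p_value:.3f}")
```

prints

```
CWM body size   mixing 2.30 ug/ind, stratification 1.38 ug/ind
body-size change   TS 83.0% ITV 17.0%
niche-breadth change  TS 3.2% ITV 96.8%
community SEA_B   mixing 4.70, stratification 1.79 permil^2
PERMANOVA period   R2 0.710  p 0.001
```

Read: the community-weighted mean body size drops from the mixing to the
stratified period, and that drop is dominated by *taxa sorting* (83%) — a
shift in relative abundances toward small-bodied taxa — while the
contraction of the community isotopic niche (SEA_B 4.70 → 1.79 ‰²) is
dominated by *intrataxonomic variation* (97%): each group narrows its own
niche as the water warms. The period factor explains 71% of the
multivariate environmental variance.

The same stages are available from the shell:

```bash
isonich synth --out data/ --seed 1          # generate a dataset bundle
isonich niche --consumers data/consumers.csv --out niche.csv --by group
isonich mix   --consumers data/consumers.csv --sources data/sources.csv --out mix/
isonich price --snapshots data/snapshots.csv --env data/env.csv --out price/
isonich env   --env data/env.csv --snapshots data/snapshots.csv --out env/
isonich run   --seed 1 --out summary.json   # full pipeline in one step
```

See `docs/methods.md` for the models, priors, defaults and their rationale.

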