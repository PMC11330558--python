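# eurysize

Phylogenetic comparative analysis of body-size macroevolution on fossil
time trees — built around the question of how giant body sizes (≥ 0.5 m)
evolved repeatedly in eurypterids ("sea scorpions"), Palaeozoic aquatic
chelicerates whose fossil record spans the Ordovician to the Permian.

The package is for comparative biologists and palaeobiologists who want to

- fit and rank **eleven continuous trait-evolution models** on
  non-ultrametric (fossil-tip) time trees: Brownian motion (BM), a
  directional trend, early burst (EB), Pagel's kappa (Κ), single-peak
  Ornstein–Uhlenbeck (OU), a **pulsed** model (BM plus compound-Poisson
  jumps), OU with an optimum tracking an environmental curve (temperature
  or dissolved O₂), and multi-peak OU (OUM) on habitat or extinction-crisis
  regime paintings;
- reconstruct **discrete habitat evolution** (marine / marginal marine /
  continental) by maximum likelihood, stochastic character mapping, and
  reversible-jump MCMC over transition-rate structures (including
  structural zeros);
- run the downstream comparative tests: GLS ancestral size with CI,
  counts of convergent origins of large size, counts of continental
  colonizations, phylogenetic regression (PGLS) of size on palaeolatitude,
  a permutational ecospace ANOVA, and rule-based predator/prey tallies.

A first-class synthetic-data module generates study-shaped data — trees
from a fossilized birth–death (FBD) forward simulation, traits drawn
exactly from each model, habitat histories, environmental curves and
community tables — so the entire pipeline is testable end to end.

## The models in brief

Body size is analysed as `x = ln(length in cm)` evolving along a
time-calibrated tree with branch lengths in Myr. All models except the
pulsed one are Gaussian: the tip vector is multivariate normal with a
model-specific mean and covariance, evaluated exactly. In standard
notation (`z0` root state, `σ²` diffusion rate, `α` pull, `θ` optimum):

| model | structure |
|---|---|
| BM | `Cov(i,j) = σ² t_ij` (shared root-to-MRCA time `t_ij`) |
| TREND | BM mean shifted by `μ·(root-to-tip time)` |
| EB | rate `σ² e^{r t}` integrated along shared history |
| KAPPA | branch lengths transformed to `ℓ^Κ` before BM (`Κ=0` punctuational, `Κ=1` BM) |
| OU | fixed-root OU: `Cov(i,j) = σ²/2α · e^{-α d_ij}(1 - e^{-2α t_ij})` |
| PULSED | BM + jumps: per branch `Poisson(λ_J ℓ)` jumps of variance `δ²`; likelihood by pruning over Gaussian-mixture messages |
| ENV_OU | OU with `θ(t) = θ₀ + β·E(t)` for a spline-smoothed curve `E` |
| OUM | per-regime `θ_k` (optionally `σ²_k, α_k`) switching at painted breakpoints |

Models are compared with AICc weights per tree, summarized by the median
weight across a posterior tree sample.

## Worked example

```python
import pandas as pd
from eurysize import models
from eurysize.selection import rank_models
from eurysize.simulate import ScenarioConfig, eurypterid_scenario

scenario = eurypterid_scenario(config=ScenarioConfig(seed=1, n_trees=2))
sizes = scenario["traits"].set_index("taxon")["log_size"]

rows = []
for i, tree in enumerate(scenario["trees"]):
    x = sizes.reindex(tree.tip_labels).to_numpy()
    for name in ("BM", "KAPPA", "PULSED"):
        fit = models.fit_model(tree, x, name, n_restarts=2, seed=0)
        rows.append({"tree": i, "model": name, "aicc": fit.aicc, "k": fit.k})
print(rank_models(pd.DataFrame(rows))[["median_waicc", "rank"]])
```

prints (seed 1):

```
        median_waicc  rank
model
PULSED      0.973599     1
KAPPA       0.013400     2
BM          0.013001     3
```

The data were simulated under the pulsed process, and the pulsed model
absorbs ~97% of the AICc weight, with the remainder split between the
kappa transform and gradual Brownian motion. The `examples/` directory has one short script per
capability (scenario simulation, fitting/ranking, habitat mapping, origin
counts and root size, ecology tests), and `eurysize simulate` /
`eurysize run-all --config cfg.yaml` drive the same pipeline from a shell.

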