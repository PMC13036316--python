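# traitscape

Trait-informed species co-occurrence modelling and spatial conservation
prioritization for gridded landscapes.

Most tropical plant species are known from a handful of herbarium records —
far too few to fit per-species distribution models, yet conservation plans
have to rank land anyway.  `traitscape` implements a workflow that pools the
information those sparse records do carry: all species enter one joint
Gaussian mixed model whose fixed effects are a trait, three environmental
covariates and their interactions, and whose random effects absorb
phylogenetic relatedness among species and spatial autocorrelation among
planning units.  The modeled occurrence probabilities feed Hill-number
diversity layers (coverage-extrapolated species and functional-entity
richness, Jaccard-type beta dissimilarity), which in turn feed a
budget-constrained minimum-shortfall site selection with a boundary
penalty, and scenario-ensemble importance scores that classify each
planning unit as a *trait* or *species* conservation priority.

The model, per species *s* and unit *m*:

    Y_sm = α + βx_s + γg_m + δd_m + ωw_m + θ x_s·(g,d,w)_m
           + a_s + b_s + c_m + d_m + ε_sm
    a ~ N(0, σ_a² I),  b ~ N(0, σ_b² Σ_spp),  c ~ N(0, σ_c² I),
    d ~ N(0, σ_d² Σ_m),  ε ~ N(0, σ_e² I)

with Σ_spp the Brownian-motion phylogenetic correlation and
Σ_m = exp(−d/d_max) on unit centroids.  Fitting is exact maximum likelihood
through a Woodbury decomposition (no dense n × n algebra), with 10-fold
cross-validated RMSE and leave-one-out CPO for model comparison against a
trait-free null.  See `docs/methods.md` for the full account.

A synthetic landscape generator (`traitscape.synthetic_data`) produces
every input — phylogeny, trait table with missing values, spatially
autocorrelated environment/cost/carbon/deforestation layers, and point
occurrence records — with known generating parameters, so the entire
pipeline is tested end to end without external data.  Real tables in the
same formats (Newick, flat CSV) drop in stage by stage.

## Worked example

```python
import numpy as np
from traitscape import synthetic_data as synth, phylogeny as phy, jsdm, traits as tr
from traitscape import diversity as dv, prioritization as pr

cfg = synth.SimConfig(n_species=25, n_x=6, n_y=6, seed=42, missing_rate=0.0)
tree = synth.gen_phylogeny(cfg.n_species, seed=cfg.seed)
traits = synth.gen_traits(tree, cfg)
land = synth.gen_landscape(cfg)
sim = synth.gen_occurrences(tree, traits, land, cfg)

Sigma_spp, _ = phy.phylo_covariance(tree)
Sigma_m = jsdm.spatial_covariance(land.grid)

spec = jsdm.ModelSpec(trait="leaf_length")
design = jsdm.build_design(spec, traits, land.env)
fit = jsdm.fit(sim.presence, design, Sigma_spp, Sigma_m, spec=spec)
print("trait x temperature estimate:",
      round(fit.beta[design.columns.index("leaf_length:annual_mean_temp")], 3))

probs = jsdm.predict(fit)                      # relative occurrence probability
gower = tr.gower_matrix(traits)                # block-weighted trait distances
layers = dv.build_layers(probs, gower, K=20, seed=0)
problem = pr.Problem(features=layers.to_dict(), cost=pr.build_cost(land),
                     grid=land.grid, budget_fraction=0.20, target_fraction=0.30)
sol = pr.solve_milp(problem)
print(f"selected {sol.n_selected}/36 units; objective {sol.objective:.4f}; "
      f"targets achieved: {sol.achieved_target}")
```

Output:

```
trait x temperature estimate: 0.037
selected 11/36 units; objective 0.0330; targets achieved: True
```

The interaction estimate is close to its generating value (0.04 by default
for `leaf_length` × temperature): species with long leaves occur
preferentially where it is warm, and the model recovers that from 0/1
presences.  The selection achieves 30% representation of all four
diversity layers with 20% of total land cost (objective ≈ the boundary
penalty term only, since all shortfalls are zero).  Adding the
cross-validation step shows the trait model beating the null
(`delta RMSE = -0.002` on this single small run; the effect is much larger
when the trait × environment signal is strong — see the acceptance
numbers).

The full pipeline — simulate → impute missing traits (15-iteration
random-forest + phylogenetic-ML ensemble) → five presence-background
variants → per-trait and null models → δRMSE/CPO evaluation → diversity
layers → prioritization at the 30%/70% targets → importance and
trait-impact classification → report — runs from one config:

```
traitscape run --out runs/demo --seed 11
traitscape validate --config my_config.yaml
```

Every stage writes flat CSV/JSON artifacts and the run is bit-identical
for a fixed master seed.

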