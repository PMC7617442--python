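# sesindex

Hierarchical Bayesian spatial factor analysis for **mixed dichotomous and
continuous household data** — small-area estimation of a latent
socio-economic status (SES) index.

Census-style surveys record household indicators of two kinds: continuous
(people per room, proportion illiterate, …) and 0/1 (no flush toilet, no
piped water, …), with households nested in small areas whose conditions
are spatially correlated. Classical factor analysis or PCA requires
aggregating to area level (losing the varying number of households per
area and all uncertainty) and mishandles dichotomous variables. `sesindex`
instead fits a latent-variable model at the household level: for household
*j* in area *i* and variable *k*,

    y*_ijk = α_ik + β_k θ_i + ε_ijk,   ε_ijk ~ N(0, σ_k²),

where continuous variables observe y* directly (α ≡ 0, columns centered)
and dichotomous ones observe the sign, y = 1{y* ≥ 0} with σ = 1 — a probit
item-response model with area-level "difficulties" α_ik and
"discriminations" (factor loadings) β_k. The area index θ carries a proper
conditional autoregressive (CAR) prior θ ~ N(0, (D − ιW)⁻¹) over the
adjacency graph, ι ~ U(0,1), so the data decide how spatially smooth the
index is. Four variants (hierarchical vs shared α × spatial vs independent
θ: HS, H, S, M0, plus an intrinsic-CAR option) are fitted by a
data-augmentation Gibbs sampler and compared by WAIC. See
`docs/methods.md` for the full model, priors and algorithm.

## Worked example

Simulate a survey from the model itself, fit the
hierarchical-spatial variant, and summarize:

```python
import numpy as np
import sesindex as si

adj = si.make_lattice_adjacency(5, 10)            # 50 areas, rook adjacency
spec = si.ModelSpec(variant="HS",
                    is_dichotomous=(True,) * 5 + (False,) * 2)
truth = si.draw_true_parameters(spec, iota=0.9, rng=1)
data, realized = si.generate_dataset(adj, spec, truth,
                                     households_per_area=(15, 25), rng=2)
print(data.n_households, data.n_areas)            # 1015 50

draws = si.fit(data, adj, spec,
               si.McmcConfig(n_chains=1, n_iter=10_000, seed=3))
print(np.round(np.median(draws.beta.reshape(-1, 7), axis=0), 3))
# [0.472 1.072 0.582 1.775 1.016 0.529 0.613]   posterior median loadings
print(np.round(realized.beta, 3))
# [0.346 0.822 0.33  1.303 0.905 0.446 0.537]   generating values
theta_med = np.median(draws.theta.reshape(-1, 50), axis=0)
print(round(float(np.corrcoef(theta_med, realized.theta)[0, 1]), 3))
# 0.973                                          index recovery
```

The fitted index tracks the generating field closely (correlation 0.97);
loadings are recovered up to the posterior's split of scale between β and
θ (see `docs/methods.md` on identifiability and small-sample behaviour of
the spatial intensity ι). Classification and model comparison:

```python
table = si.classify_areas(draws, level=0.90)      # low / high / undetermined
ll = si.loglik_matrix(draws, data)
print(si.waic(ll).as_dict())                      # lppd, p_waic, waic
```

A `sesindex` command-line tool mirrors the library
(`simulate`, `fit`, `diagnose`, `compare`, `summarize`, `classify`,
`simstudy`); every artifact is CSV/JSON with a run manifest:

```sh
sesindex simulate --seed 3 --out data/ --rows 5 --cols 10
sesindex fit --data-dir data/ --out run_hs/ --variant HS --iters 10000
sesindex fit --data-dir data/ --out run_m0/ --variant M0 --iters 10000
sesindex compare run_hs/ run_m0/       # WAIC table, best model first
```

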