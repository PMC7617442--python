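# Methods

## The model

`sesindex` estimates a one-dimensional latent index θ_i per small area
(census tract / enumeration area) from household-level mixed indicators.
For household *j* in area *i* and manifest variable *k* (of *p*), a latent
continuum is assumed:

    y*_ijk = α_ik + β_k θ_i + ε_ijk,     ε_ijk ~ N(0, σ_k²).

Continuous variables are observed directly (y = y*), with their α fixed at
zero and the column centered by its global mean (an optional log transform
precedes centering). Dichotomous variables observe only the sign,
y = 1{y* ≥ 0}, with σ_k ≡ 1, which gives the marginal probit model
y ~ Bernoulli(Φ(α_ik + β_k θ_i)). In item-response terms α_ik is a
(negative) item difficulty — how easy it is for variable *k* to fire in
area *i* — and β_k an item discrimination / factor loading — how sharply
variable *k* separates areas along the index. Indicators are assumed coded
so that a *higher* index means *lower* socio-economic status.

Priors (every scale deliberately fixed at 1):

* **Index**: θ ~ N(0, (D − ιW)⁻¹), a proper conditional autoregressive
  (CAR) prior over the areal adjacency graph (W the 0–1 adjacency, D the
  degree matrix), with conditional precision 1 and spatial intensity
  ι ~ U(0,1). Equivalently θ_i | θ_{−i} ~ N((ι/d_i) Σ_{j~i} θ_j, 1/d_i).
  Variant switches replace this with iid N(0,1) or with the intrinsic CAR
  (pairwise-difference) prior plus a soft sum-to-zero constraint
  Σθ_i ~ N(0, εN), ε = 0.001.
* **Difficulties**: hierarchical α_ik ~ N(α*_k, 1) with α*_k ~ N(0,1)
  (variants HS, H), or a single shared α_k ~ N(0,1) (variants S, M0).
* **Loadings**: β_k ~ half-Normal(0,1), all constrained positive.
* **Noise**: σ_k ~ Half-Cauchy(0,1) for continuous k, fixed at 1 for
  dichotomous k.

The four stock variants cross {hierarchical, shared} difficulties with
{spatial, independent} index: HS, H, S, M0, plus HS_icar.

### Identifiability

The likelihood only constrains the products β_k θ_i: (β, θ) → (cβ, θ/c)
leaves it unchanged, as does a joint sign flip. Three conventions resolve
this: the prior variance of θ is hard-coded to 1 (no knob exists), every
β_k is restricted positive, and the α of continuous variables are fixed at
zero with the columns centered. A sensitivity switch
(`beta_constraint="first_positive"`) restricts only β_1 and gives β_2..β_p
standard normal priors.

## Inference

The reference sampler is data-augmentation Gibbs with two Metropolis
steps; it was chosen over gradient-based samplers because in the augmented
model every remaining full conditional is conjugate and can be verified in
isolation. Per sweep:

1. **y*** (dichotomous cells): truncated N(α_ik + β_k θ_i, 1) on the
   half-line fixed by the observed 0/1 value. Draws use a tail-safe
   inverse-CDF transform (quantile of the smaller tail; exponential-tail
   approximation beyond the double-precision range of Φ).
2. **α_ik**: conjugate normal, precision 1 + n_i (hierarchical), or
   1 + Σn_i for the shared variant.
3. **α\*_k**: conjugate normal, precision 1 + N.
4. **β_k**: conjugate normal truncated to (0, ∞).
5. **θ**: conjugate normal full conditionals, updated in graph-coloring
   blocks — areas of one color are mutually non-adjacent, hence
   conditionally independent given the rest, so each block is one
   vectorized draw and a full sweep costs O(N + |E|). Under the ICAR
   variant the sum-to-zero constraint couples *all* areas, so θ is updated
   one area at a time there.
6. **ι**: random-walk Metropolis on the logit scale against the joint CAR
   density; the log-determinant term uses the precomputed eigenvalues λ of
   D^{−1/2} W D^{−1/2}: log|D − ιW| = Σ log d_i + Σ log(1 − ιλ_m).
7. **σ_k** (continuous only): random-walk Metropolis on the log scale with
   the Half-Cauchy prior.

Metropolis step sizes adapt every 50 iterations *during warmup only*
(target acceptance 0.3–0.5; the ι posterior can concentrate near 1, which
the logit parameterization accommodates) and are frozen afterwards, so
retained draws target the exact posterior. Defaults follow common
practice: 2 chains, 10,000 iterations each, first half discarded.

Correctness is enforced by two families of tests: a grid oracle asserting
that each closed-form conditional is proportional to the joint log-density
restricted to its block (max deviation < 1e-8), and a Geweke-style
successive-conditional run — one posterior sweep alternated with
regeneration of the data from the current parameters — whose stationary
marginals must reproduce the priors (Kolmogorov–Smirnov on β, ι, α*, σ).

## Model comparison and diagnostics

WAIC is computed from the y*-marginalized per-cell log-likelihood — one
"observation" is one (household, variable) cell — as
lppd = Σ log(mean_s exp ll), p_WAIC = Σ var_s(ll) (sample variance, S−1
denominator), WAIC = −2(lppd − p_WAIC); lower ranks first. The pointwise
unit and the marginal (not augmented) likelihood make p_WAIC comparable
across variants. R-hat is the rank-normalized split version (max of bulk
and folded statistics; the classic statistic is available behind a flag);
ESS uses Geyer's initial-monotone-positive-pair truncation per chain,
summed over chains. Moran's I uses binary (not row-standardized) weights,
matching the binary W of the CAR prior, with a one-sided permutation null
(999 permutations by default) rather than the normal approximation, for
exactness at small N.

Posterior summaries report medians and equal-tailed intervals computed
with numpy's linear-interpolation quantiles (so 100 draws 1..100 give an
80% interval of (10.9, 90.1)). Area classification at level L (default
0.90): θ interval entirely above 0 → *low* SES, entirely below → *high*,
otherwise *undetermined*; within the low and high categories posterior
medians are min–max rescaled to [0,1] (a single-area category gets 0).
Difficulty-deviation maps compare each α_ik interval (default level 0.80)
with the posterior median of α*_k.

## Synthetic data and the recovery study

The generator draws data from the model itself on a rook-adjacency
lattice: θ from the proper CAR, fresh α_ik per dataset, then household
outcomes; continuous columns are re-centered after generation so the
fitted model's α = 0 convention holds exactly. Stock study
configurations:

* **full**: 200 areas (10×20), ≈5,195 households (21–31 per area), 15
  dichotomous + 5 continuous variables, ι = 0.9, 100 replicates;
* **desk**: 50 areas (5×10), 15–25 households per area, 5 dichotomous + 2
  continuous variables, ι = 0.9, 20 replicates — sized so that the whole
  study (one chain of 4,000 iterations per replicate, half warmup) runs in
  about a minute per 20 replicates on one core.

True (β, α*, σ) are drawn once from the priors under the master seed and
recorded; θ and α_ik are redrawn per replicate. Scoring tallies
equal-tailed interval coverage at 90%/95%, bias and RMSE of posterior
medians, per block (β, α*, σ, θ, ι), with exact integer bookkeeping.

### What the generator does and does not emulate

It reproduces the model's hierarchical, spatial and mixed-type structure
and the varying number of households per area. It does **not** emulate
real-census features: marginal distributions of actual indicators,
dichotomization artifacts, within-area clustering beyond the single latent
factor, or irregular adjacency graphs (a lattice stands in for real tract
geometry). Passing recovery tests therefore demonstrates internal
consistency of model + sampler, not robustness to model misspecification.

### Known small-sample behaviour at desk scale

Two effects, both properties of the exact posterior rather than of the
sampler, are visible at 50 areas and documented here deliberately:

* **ι is weakly identified.** The spatial intensity is informed only by
  the latent field. A grid computation of p(ι | θ) with the *true* θ
  plugged in gives a mean posterior median of ≈0.79 across CAR(0.9) draws
  on the 50-area lattice (≈0.87 at 200 areas); full inference, which sees
  θ only through ≈20 households per area, lands lower still (≈0.68),
  because posterior θ-noise attenuates the apparent spatial correlation
  and the β–θ scale coupling pushes the same way. Recovery of ι to within
  ±0.1 should only be expected at a few hundred areas.
* **Centering aliases the location of θ.** Re-centering the generated
  continuous columns removes β_k·mean(θ) from the data; the intercept-free
  continuous likelihood then pins the fitted θ around zero mean, i.e.
  shifted by −mean(θ) relative to the generating field (sd of mean(θ) ≈
  0.24 at ι = 0.9, N = 50). This depresses θ and α* interval coverage at
  desk scale; β, being scale- not location-coupled, keeps near-nominal
  coverage (≈0.92 pooled at the 95% level).

## Numerical choices

* CAR draws: dense Cholesky of Q (areal problems are small); the sparse
  precision is kept for matvecs in the sampler.
* Truncated-normal sampling: inverse CDF through the smaller tail
  (`ndtri` of p or of u·q), with Robert-style exponential tail
  approximation once the tail mass underflows.
* log Φ via `scipy.special.log_ndtr`; WAIC's log-mean-exp via
  `scipy.special.logsumexp`.
* Degenerate inputs: constant MCMC chains yield NaN R-hat/ESS with a flag
  rather than an exception; a single draw is rejected by WAIC (its
  variance is undefined); islands are rejected by the proper CAR (use the
  independent-θ variant), disconnected graphs by the ICAR variant.
* Initialization: θ = 0, β = |N(0,1)|, α*_k = Φ⁻¹(observed frequency)
  clipped to [−3,3], σ_k = sample SD, ι = 0.5, y* drawn consistent with
  the observed signs.
* Replicate seeds in the simulation study are spawned from the master
  seed via `numpy.random.SeedSequence`; everything is bit-reproducible
  given the seed.

## Limitations

Single latent factor; no household- or area-level covariates; no missing
data (rows with any missing cell are rejected); probit link only (a logit
variant would require replacing the augmentation step); ICAR runs mix
slowly — expect to run several times more iterations than with the proper
CAR, and the area-by-area θ update makes each sweep costlier.
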