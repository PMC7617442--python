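"""Data-augmentation Gibbs sampler (with Metropolis steps) for all variants.

Each sweep updates, in order:

(a) the latent continua y* of the dichotomous cells — truncated
    N(α_ik + β_kθ_i, 1) on the half-line fixed by the observed 0/1 value
    (the classic probit data-augmentation step);
(b) the area-level difficulties α_ik (dichotomous variables) — conjugate
    normal combining the N(α*_k, 1) prior with the area's pseudo-
    observations (or a single shared α_k for the non-hierarchical variants);
(c) the overall difficulties α*_k — conjugate normal;
(d) the loadings/discriminations β_k — conjugate normal truncated to
    (0, ∞);
(e) the latent index θ — conjugate normal full conditionals, updated in
    graph-coloring blocks (areas of one color are conditionally independent
    given the rest, so each block is a single vectorized draw; identical
    target as an area-by-area sweep);
(f) the spatial intensity ι — random-walk Metropolis on the logit scale
    against the joint CAR density including its log-determinant (computed
    from the precomputed eigenvalues of D^{-1/2} W D^{-1/2});
(g) the continuous error SDs σ_k — random-walk Metropolis on the log scale
    with the Half-Cauchy(0,1) prior.

Metropolis step sizes are tuned during warmup toward acceptance rates in
[0.3, 0.5] and frozen afterwards, so the retained draws target the exact
posterior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit, ndtr, ndtri

from .data_model import AdjacencyStructure, MixedDataset
from .model_core import ModelSpec, ParameterState, log_joint

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "GibbsKernel",
    "fit",
    "fit_icar",
    "initialize",
    "sample_truncnorm_positive",
    "conditional_ystar",
    "conditional_alpha",
    "conditional_alpha_star",
    "conditional_beta",
    "conditional_theta",
]


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run settings.

    ``n_iter`` counts total iterations per chain; the first ``n_warmup``
    (default: half) are discarded, the remainder retained every ``thin``-th.
    """

    n_chains: int = 2
    n_iter: int = 10_000
    n_warmup: int | None = None
    thin: int = 1
    seed: int = 0
    iota_step: float = 0.5
    sigma_step: float = 0.2
    store_ystar: bool = False

    def __post_init__(self) -> None:
        if self.n_warmup is None:
            object.__setattr__(self, "n_warmup", self.n_iter // 2)
        if not 0 <= self.n_warmup < self.n_iter:
            raise ValueError("need 0 <= n_warmup < n_iter")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_warmup) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for every parameter block.

    Array shapes (C chains, S retained draws per chain, N areas, p
    variables, p_d dichotomous variables):

    * ``beta``: (C, S, p); ``sigma``: (C, S, p) (exactly 1 at dichotomous
      positions); ``theta``: (C, S, N);
    * ``alpha_star``: (C, S, p) with NaN at continuous positions
      (hierarchical variants only, else None);
    * ``alpha``: (C, S, N, p_d) for hierarchical variants, (C, S, p_d) for
      shared-difficulty variants;
    * ``iota``: (C, S) for proper-CAR variants, else None;
    * ``ystar``: (C, S, H, p_d) only when requested.
    """

    spec: ModelSpec
    config: McmcConfig
    beta: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray
    alpha: np.ndarray
    alpha_star: np.ndarray | None
    iota: np.ndarray | None
    acceptance: dict = field(default_factory=dict)
    ystar: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_retained(self) -> int:
        return self.beta.shape[1]

    @property
    def n_areas(self) -> int:
        return self.theta.shape[2]

    @property
    def dich_idx(self) -> np.ndarray:
        return np.nonzero(np.asarray(self.spec.is_dichotomous))[0]

    def _full_alpha(self, c: int, s: int) -> np.ndarray:
        out = np.zeros((self.n_areas, self.spec.p))
        if self.dich_idx.size:
            if self.spec.hierarchical_alpha:
                out[:, self.dich_idx] = self.alpha[c, s]
            else:
                out[:, self.dich_idx] = self.alpha[c, s][None, :]
        return out

    def iter_states(self, thin: int = 1):
        """Yield each retained draw as a ParameterState (chains concatenated)."""
        for c in range(self.n_chains):
            for s in range(0, self.n_retained, thin):
                astar = (self.alpha_star[c, s] if self.alpha_star is not None
                         else np.full(self.spec.p, np.nan))
                yield ParameterState(
                    alpha=self._full_alpha(c, s), alpha_star=astar,
                    beta=self.beta[c, s], theta=self.theta[c, s],
                    sigma=self.sigma[c, s],
                    iota=(float(self.iota[c, s]) if self.iota is not None
                          else np.nan))

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Flat map name -> (C, S) array for every scalar parameter."""
        out: dict[str, np.ndarray] = {}
        for k in range(self.spec.p):
            out[f"beta[{k}]"] = self.beta[:, :, k]
        for i in range(self.n_areas):
            out[f"theta[{i}]"] = self.theta[:, :, i]
        for k in np.nonzero(~np.asarray(self.spec.is_dichotomous))[0]:
            out[f"sigma[{k}]"] = self.sigma[:, :, k]
        if self.alpha_star is not None:
            for k in self.dich_idx:
                out[f"alpha_star[{k}]"] = self.alpha_star[:, :, k]
        elif self.dich_idx.size:
            for pos, k in enumerate(self.dich_idx):
                out[f"alpha[{k}]"] = self.alpha[:, :, pos]
        if self.iota is not None:
            out["iota"] = self.iota
        return out

    # -- persistence -------------------------------------------------------
    def save(self, outdir, include_alpha: bool = False) -> None:
        """Write one long-format CSV per parameter block plus a manifest."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        C, S = self.n_chains, self.n_retained
        chain = np.repeat(np.arange(C), S)
        it = np.tile(np.arange(S), C)

        def long(arr3, index_name):  # (C, S, K) -> rows chain,iter,k,value
            K = arr3.shape[2]
            return pd.DataFrame({
                "chain": np.repeat(chain, K), "iter": np.repeat(it, K),
                index_name: np.tile(np.arange(K), C * S),
                "value": arr3.reshape(-1)})

        long(self.beta, "k").to_csv(outdir / "beta.csv", index=False)
        long(self.theta, "area").to_csv(outdir / "theta.csv", index=False)
        long(self.sigma, "k").to_csv(outdir / "sigma.csv", index=False)
        if self.alpha_star is not None:
            long(self.alpha_star, "k").to_csv(outdir / "alpha_star.csv",
                                              index=False)
        if self.iota is not None:
            pd.DataFrame({"chain": chain, "iter": it,
                          "value": self.iota.reshape(-1)}
                         ).to_csv(outdir / "iota.csv", index=False)
        if include_alpha and self.spec.hierarchical_alpha:
            C_, S_, N, pd_ = self.alpha.shape
            rows = pd.DataFrame({
                "chain": np.repeat(chain, N * pd_),
                "iter": np.repeat(it, N * pd_),
                "area": np.tile(np.repeat(np.arange(N), pd_), C_ * S_),
                "k": np.tile(self.dich_idx, C_ * S_ * N),
                "value": self.alpha.reshape(-1)})
            rows.to_csv(outdir / "alpha.csv", index=False)
        manifest = {
            "spec": self.spec.to_json_dict(),
            "config": {"n_chains": self.config.n_chains,
                       "n_iter": self.config.n_iter,
                       "n_warmup": self.config.n_warmup,
                       "thin": self.config.thin, "seed": self.config.seed},
            "acceptance": {k: float(v) for k, v in self.acceptance.items()},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# truncated-normal draws (vectorized, tail-safe inverse CDF)
# ---------------------------------------------------------------------------

def _std_lower_tail(t: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Draw Z ~ N(0,1) | Z > t, elementwise, t of any sign."""
    t = np.asarray(t, dtype=np.float64)
    out = np.empty_like(t)
    easy = t <= 0
    if easy.any():
        p = ndtr(t[easy])  # <= 0.5, full relative accuracy
        out[easy] = ndtri(p + u[easy] * (1.0 - p))
    hard = ~easy
    if hard.any():
        th = t[hard]
        q = ndtr(-th)  # upper-tail mass, small
        with np.errstate(divide="ignore"):
            z = -ndtri(u[hard] * q)  # exact while u*q > tiny
        # far tail (q underflows): exponential tail approximation
        bad = ~np.isfinite(z)
        if bad.any():
            tb = th[bad]
            z[bad] = tb - np.log(u[hard][bad]) / tb
        out[hard] = z
    return out


def sample_truncnorm_positive(mean: np.ndarray, sd: np.ndarray | float,
                              rng: np.random.Generator) -> np.ndarray:
    """Vectorized draw from N(mean, sd²) truncated to (0, ∞)."""
    mean = np.asarray(mean, dtype=np.float64)
    u = rng.random(mean.shape)
    t = -mean / sd
    return mean + sd * _std_lower_tail(t, u)


def _sample_ystar(eta: np.ndarray, positive: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw y* ~ N(eta, 1) restricted to [0,∞) where positive else (−∞,0)."""
    u = rng.random(eta.shape)
    sgn = np.where(positive, 1.0, -1.0)
    # For the negative side sample −y* ~ N(−eta,1) | > 0, then flip.
    z = _std_lower_tail(-(sgn * eta), u)
    return sgn * (sgn * eta + z)


# ---------------------------------------------------------------------------
# closed-form full conditionals (pure functions; also exercised by tests)
# ---------------------------------------------------------------------------

def conditional_ystar(state: ParameterState, data: MixedDataset,
                      spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Mean (H, p_d) and required sign (+1/−1) of the y* full conditionals
    (unit variance)."""
    dich = np.asarray(spec.is_dichotomous)
    a = data.area_ids
    eta = state.alpha[a][:, dich] + state.beta[dich] * state.theta[a, None]
    positive = data.y[:, dich] >= 0.5
    return eta, np.where(positive, 1.0, -1.0)


def conditional_alpha(state: ParameterState, data: MixedDataset,
                      spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Normal full-conditional (mean, var) for the difficulty block.

    Hierarchical: shapes (N, p_d); shared: shapes (p_d,). σ = 1 for
    dichotomous variables throughout.
    """
    dich = np.asarray(spec.is_dichotomous)
    a = data.area_ids
    N = state.theta.size
    r = state.ystar[:, dich] - state.beta[dich] * state.theta[a, None]
    if spec.hierarchical_alpha:
        n_i = np.bincount(a, minlength=N).astype(float)
        sums = np.vstack([np.bincount(a, weights=r[:, j], minlength=N)
                          for j in range(r.shape[1])]).T  # (N, p_d)
        prec = 1.0 + n_i
        mean = (state.alpha_star[dich][None, :] + sums) / prec[:, None]
        return mean, np.broadcast_to((1.0 / prec)[:, None], mean.shape).copy()
    H = float(a.size)
    mean = r.sum(axis=0) / (1.0 + H)
    return mean, np.full(mean.shape, 1.0 / (1.0 + H))


def conditional_alpha_star(state: ParameterState, data: MixedDataset,
                           spec: ModelSpec) -> tuple[np.ndarray, float]:
    """Normal full-conditional (mean (p_d,), var) for the overall
    difficulties α*_k (hierarchical variants)."""
    if not spec.hierarchical_alpha:
        raise ValueError("alpha_star exists only in hierarchical variants")
    dich = np.asarray(spec.is_dichotomous)
    N = state.theta.size
    mean = state.alpha[:, dich].sum(axis=0) / (1.0 + N)
    return mean, 1.0 / (1.0 + N)


def conditional_beta(state: ParameterState, data: MixedDataset,
                     spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Normal (mean, var) of the β full conditionals *before* truncation
    to (0, ∞); shapes (p,)."""
    a = data.area_ids
    x = state.theta[a]
    s2 = float(x @ x)
    R = state.ystar - state.alpha[a]  # continuous columns: y (alpha = 0)
    xr = x @ R
    prec = 1.0 + s2 / state.sigma**2
    mean = (xr / state.sigma**2) / prec
    return mean, 1.0 / prec


def conditional_theta(state: ParameterState, data: MixedDataset,
                      spec: ModelSpec,
                      adjacency: AdjacencyStructure | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Normal (mean, var) of each θ_i full conditional, shapes (N,).

    Valid jointly only for sets of areas that are mutually non-adjacent
    (the sampler updates one color class at a time).
    """
    a = data.area_ids
    N = state.theta.size
    n_i = np.bincount(a, minlength=N).astype(float)
    w = state.beta / state.sigma**2
    R = state.ystar - state.alpha[a]
    lin_lik = np.bincount(a, weights=R @ w, minlength=N)
    prec_lik = n_i * float(state.beta @ w)
    if spec.spatial_theta:
        d = adjacency.degrees.astype(float)
        Wt = adjacency.W @ state.theta
        prec0 = d
        lin0 = state.iota * Wt
    elif spec.icar_theta:
        d = adjacency.degrees.astype(float)
        Wt = adjacency.W @ state.theta
        eps_n = spec.icar_constraint_scale * N
        prec0 = d + 1.0 / eps_n
        lin0 = Wt - (state.theta.sum() - state.theta) / eps_n
    else:
        prec0 = np.ones(N)
        lin0 = np.zeros(N)
    prec = prec0 + prec_lik
    return (lin0 + lin_lik) / prec, 1.0 / prec


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(data: MixedDataset, spec: ModelSpec,
               seed: int | np.random.Generator = 0) -> ParameterState:
    """Deterministic-given-seed starting state.

    θ = 0; β = |N(0,1)| draws; α*_k = Φ⁻¹(observed proportion of ones)
    clipped to [−3, 3] with α_ik = α*_k; σ_k = sample SD of the continuous
    column; ι = 0.5; y* drawn consistent with the observed signs.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    dich = data.is_dichotomous
    p = data.n_variables
    N = data.n_areas
    beta = np.abs(rng.standard_normal(p))
    beta[beta < 1e-3] = 1e-3
    theta = np.zeros(N)
    alpha_star = np.full(p, np.nan)
    alpha = np.zeros((N, p))
    sigma = np.ones(p)
    for k in range(p):
        if dich[k]:
            prop = float(data.y[:, k].mean())
            alpha_star[k] = float(np.clip(ndtri(prop) if 0 < prop < 1
                                          else (3.0 if prop >= 1 else -3.0),
                                          -3.0, 3.0))
            alpha[:, k] = alpha_star[k]
        else:
            sigma[k] = float(data.y[:, k].std(ddof=1)) or 1.0
    iota = 0.5 if spec.spatial_theta else np.nan
    state = ParameterState(alpha=alpha, alpha_star=alpha_star, beta=beta,
                           theta=theta, sigma=sigma, iota=iota)
    # y* consistent with observed signs
    ystar = data.y.copy()
    if dich.any():
        eta, _ = conditional_ystar(state, data, spec)
        ystar[:, dich] = _sample_ystar(eta, data.y[:, dich] >= 0.5, rng)
    state.ystar = ystar
    return state


# ---------------------------------------------------------------------------
# graph coloring for blocked theta updates
# ---------------------------------------------------------------------------

def _greedy_coloring(neighbours: list[list[int]]) -> list[np.ndarray]:
    n = len(neighbours)
    order = sorted(range(n), key=lambda i: -len(neighbours[i]))
    color = np.full(n, -1)
    for i in order:
        used = {color[j] for j in neighbours[i] if color[j] >= 0}
        c = 0
        while c in used:
            c += 1
        color[i] = c
    return [np.nonzero(color == c)[0] for c in range(color.max() + 1)]


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _MhStep:
    """Random-walk step size with warmup-only Robbins-Monro-style tuning."""

    def __init__(self, step: float, lo: float = 0.3, hi: float = 0.5):
        self.step = step
        self.lo, self.hi = lo, hi
        self.accepted = 0
        self.proposed = 0
        self.post_accepted = 0
        self.post_proposed = 0

    def record(self, accepted: bool, warmup: bool) -> None:
        if warmup:
            self.accepted += int(accepted)
            self.proposed += 1
            if self.proposed % 50 == 0:
                rate = self.accepted / 50
                if rate < self.lo:
                    self.step *= 0.7
                elif rate > self.hi:
                    self.step *= 1.4
                self.accepted = 0
        else:
            self.post_accepted += int(accepted)
            self.post_proposed += 1

    @property
    def rate(self) -> float:
        return (self.post_accepted / self.post_proposed
                if self.post_proposed else np.nan)


class GibbsKernel:
    """One full update sweep over all blocks, with its precomputed structure.

    Exposed so that exactness tests (e.g. prior-reproduction runs that
    alternate a posterior sweep with regeneration of the data) can drive
    the very same code path as :func:`fit`.
    """

    def __init__(self, data: MixedDataset,
                 adjacency: AdjacencyStructure | None, spec: ModelSpec,
                 iota_step: float = 0.5, sigma_step: float = 0.2):
        self.data, self.adjacency, self.spec = data, adjacency, spec
        self.dich = data.is_dichotomous
        self.cont_idx = np.nonzero(~self.dich)[0]
        self.dich_idx = np.nonzero(self.dich)[0]
        self.a = data.area_ids
        self.N, self.p, self.H = (data.n_areas, data.n_variables,
                                  data.n_households)
        self.n_i = data.households_per_area.astype(float)
        spatial = spec.spatial_theta or spec.icar_theta
        if spatial:
            self.d = adjacency.degrees.astype(float)
            self.W = adjacency.W
            if spec.icar_theta:
                # the soft sum-to-zero constraint couples *all* areas, so
                # color blocks are not conditionally independent: update
                # one area at a time
                self.colors = [np.array([i]) for i in range(self.N)]
            else:
                self.colors = _greedy_coloring(adjacency.neighbours)
            if spec.spatial_theta:
                # eigenvalues of D^{-1/2} W D^{-1/2} for the CAR logdet
                sqinv = 1.0 / np.sqrt(self.d)
                M = (self.W.toarray() * sqinv[:, None]) * sqinv[None, :]
                self.lam = np.linalg.eigvalsh(M)
                self.sum_log_d = float(np.log(self.d).sum())
        else:
            self.colors = [np.arange(self.N)]
        self.mh_iota = _MhStep(iota_step)
        self.mh_sigma = {int(k): _MhStep(sigma_step) for k in self.cont_idx}

    def car_logdensity(self, iota: float, thD: float, thW: float) -> float:
        """log N(θ | 0, (D − ιW)⁻¹) up to the constant, via precomputed
        eigenvalues; thD = θ'Dθ, thW = θ'Wθ."""
        return 0.5 * (self.sum_log_d + float(np.log1p(-iota * self.lam).sum())
                      - thD + iota * thW)

    def sweep(self, st: ParameterState, rng: np.random.Generator,
              warm: bool) -> None:
        data, spec = self.data, self.spec
        a, N, H = self.a, self.N, self.H
        dich, dich_idx, cont_idx = self.dich, self.dich_idx, self.cont_idx
        n_i = self.n_i
        theta_a = st.theta[a]

        # (a) latent continua
        if dich_idx.size:
            eta = st.alpha[a][:, dich] + st.beta[dich] * theta_a[:, None]
            st.ystar[:, dich] = _sample_ystar(
                eta, data.y[:, dich] >= 0.5, rng)

        # (b) difficulties
        if dich_idx.size:
            if spec.hierarchical_alpha:
                prec = 1.0 + n_i
                sd_a = np.sqrt(1.0 / prec)
                for k in dich_idx:
                    s_k = np.bincount(
                        a, weights=st.ystar[:, k] - st.beta[k] * theta_a,
                        minlength=N)
                    m = (st.alpha_star[k] + s_k) / prec
                    st.alpha[:, k] = m + sd_a * rng.standard_normal(N)
                # (c) overall difficulties
                prec_s = 1.0 + N
                m_s = st.alpha[:, dich].sum(axis=0) / prec_s
                st.alpha_star[dich_idx] = (
                    m_s + rng.standard_normal(dich_idx.size)
                    / np.sqrt(prec_s))
            else:
                prec = 1.0 + H
                for k in dich_idx:
                    s_k = float(
                        (st.ystar[:, k] - st.beta[k] * theta_a).sum())
                    st.alpha[:, k] = (s_k / prec + rng.standard_normal()
                                      / np.sqrt(prec))

        # (d) loadings
        m_b, v_b = conditional_beta(st, data, spec)
        sd_b = np.sqrt(v_b)
        if spec.beta_constraint == "all_positive":
            st.beta = sample_truncnorm_positive(m_b, sd_b, rng)
        else:
            st.beta = m_b + sd_b * rng.standard_normal(self.p)
            st.beta[0] = sample_truncnorm_positive(
                m_b[:1], sd_b[:1], rng)[0]

        # (e) latent index, by color blocks
        w = st.beta / st.sigma**2
        prec_lik = n_i * float(st.beta @ w)
        R = st.ystar - st.alpha[a]
        lin_lik = np.bincount(a, weights=R @ w, minlength=N)
        for block in self.colors:
            if spec.spatial_theta:
                Wt = self.W @ st.theta
                prec0 = self.d[block]
                lin0 = st.iota * Wt[block]
            elif spec.icar_theta:
                Wt = self.W @ st.theta
                eps_n = spec.icar_constraint_scale * N
                prec0 = self.d[block] + 1.0 / eps_n
                lin0 = (Wt[block]
                        - (st.theta.sum() - st.theta[block]) / eps_n)
            else:
                prec0 = 1.0
                lin0 = 0.0
            prec_t = prec0 + prec_lik[block]
            mean_t = (lin0 + lin_lik[block]) / prec_t
            st.theta[block] = mean_t + rng.standard_normal(
                block.size) / np.sqrt(prec_t)

        # (f) spatial intensity: logit-scale random walk
        if spec.spatial_theta:
            thD = float(self.d @ st.theta**2)
            thW = float(st.theta @ (self.W @ st.theta))
            prop = float(expit(logit(st.iota)
                               + self.mh_iota.step * rng.standard_normal()))
            # include the Jacobian dι/dlogit = ι(1−ι)
            log_r = (self.car_logdensity(prop, thD, thW)
                     - self.car_logdensity(st.iota, thD, thW)
                     + np.log(prop * (1 - prop))
                     - np.log(st.iota * (1 - st.iota)))
            acc = np.log(rng.random()) < log_r
            if acc:
                st.iota = prop
            self.mh_iota.record(bool(acc), warm)

        # (g) error SDs of continuous variables: log-scale random walk
        theta_a = st.theta[a]  # refresh after the theta update
        for k in cont_idx:
            k = int(k)
            resid = data.y[:, k] - st.beta[k] * theta_a
            ssr = float(resid @ resid)

            def lpost_sig(s: float) -> float:
                # Half-Cauchy(0,1) prior + log-scale Jacobian (+log s)
                return (-H * np.log(s) - 0.5 * ssr / s**2
                        - np.log1p(s * s) + np.log(s))

            prop_s = float(np.exp(np.log(st.sigma[k])
                                  + self.mh_sigma[k].step
                                  * rng.standard_normal()))
            acc = (np.log(rng.random())
                   < lpost_sig(prop_s) - lpost_sig(st.sigma[k]))
            if acc:
                st.sigma[k] = prop_s
            self.mh_sigma[k].record(bool(acc), warm)

    def acceptance_rates(self, chain: int) -> dict[str, float]:
        out = {}
        if self.spec.spatial_theta:
            out[f"iota_chain{chain}"] = self.mh_iota.rate
        for k in self.cont_idx:
            out[f"sigma[{int(k)}]_chain{chain}"] = self.mh_sigma[int(k)].rate
        return out


def fit(data: MixedDataset, adjacency: AdjacencyStructure | None,
        spec: ModelSpec, mcmc: McmcConfig) -> PosteriorDraws:
    """Run the Gibbs sampler; returns retained posterior draws.

    ``data`` must be preprocessed (continuous columns centered).
    ``adjacency`` is required exactly for the spatial variants; islands are
    rejected for the proper CAR, disconnected graphs for the ICAR.
    """
    if not data.preprocessed:
        raise ValueError("preprocess(data) before fitting (centering is part "
                         "of the model's identification)")
    if spec.p != data.n_variables or tuple(spec.is_dichotomous) != tuple(
            data.is_dichotomous):
        raise ValueError("spec.is_dichotomous does not match the dataset")
    spatial = spec.spatial_theta or spec.icar_theta
    if spatial:
        if adjacency is None:
            raise ValueError("spatial variant needs an adjacency structure")
        if adjacency.n_areas != data.n_areas:
            raise ValueError("adjacency area count does not match the data")
        if spec.spatial_theta and adjacency.has_islands():
            raise ValueError("island areas: the proper CAR is undefined — "
                             "use the independent-theta variant")
        if spec.icar_theta and not adjacency.is_connected():
            raise ValueError("ICAR variant requires a connected graph")

    dich = data.is_dichotomous
    dich_idx = np.nonzero(dich)[0]
    N, p, H = data.n_areas, data.n_variables, data.n_households

    C, S = mcmc.n_chains, mcmc.n_retained
    beta_d = np.empty((C, S, p))
    theta_d = np.empty((C, S, N))
    sigma_d = np.empty((C, S, p))
    alpha_d = (np.empty((C, S, N, dich_idx.size)) if spec.hierarchical_alpha
               else np.empty((C, S, dich_idx.size)))
    astar_d = np.empty((C, S, p)) if spec.hierarchical_alpha else None
    iota_d = np.empty((C, S)) if spec.spatial_theta else None
    ystar_d = (np.empty((C, S, H, dich_idx.size), dtype=np.float32)
               if mcmc.store_ystar else None)
    acceptance: dict[str, float] = {}

    chain_seeds = np.random.SeedSequence(mcmc.seed).spawn(C)
    for c in range(C):
        rng = np.random.default_rng(chain_seeds[c])
        st = initialize(data, spec, rng)
        lj0 = log_joint(st, data, spec, adjacency if spatial else None)
        if not np.isfinite(lj0):
            raise RuntimeError(
                f"non-finite log-joint at initialization ({lj0}); check for "
                "degenerate columns (all-constant) or unpreprocessed data")
        kernel = GibbsKernel(data, adjacency, spec,
                             iota_step=mcmc.iota_step,
                             sigma_step=mcmc.sigma_step)
        kept = 0
        for t in range(1, mcmc.n_iter + 1):
            warm = t <= mcmc.n_warmup
            kernel.sweep(st, rng, warm)
            if not warm and (t - mcmc.n_warmup) % mcmc.thin == 0:
                beta_d[c, kept] = st.beta
                theta_d[c, kept] = st.theta
                sigma_d[c, kept] = st.sigma
                if spec.hierarchical_alpha:
                    alpha_d[c, kept] = st.alpha[:, dich]
                    astar_d[c, kept] = st.alpha_star
                elif dich_idx.size:
                    alpha_d[c, kept] = st.alpha[0, dich]
                if iota_d is not None:
                    iota_d[c, kept] = st.iota
                if ystar_d is not None:
                    ystar_d[c, kept] = st.ystar[:, dich]
                kept += 1
        acceptance.update(kernel.acceptance_rates(c))

    return PosteriorDraws(spec=spec, config=mcmc, beta=beta_d, theta=theta_d,
                          sigma=sigma_d, alpha=alpha_d, alpha_star=astar_d,
                          iota=iota_d, acceptance=acceptance, ystar=ystar_d)


def fit_icar(data: MixedDataset, adjacency: AdjacencyStructure,
             spec: ModelSpec, mcmc: McmcConfig) -> PosteriorDraws:
    """Fit the intrinsic-CAR variant (pairwise-difference prior for θ with a
    soft sum-to-zero constraint Σθ_i ~ N(0, εN); ι is absent).

    Long runs are expected: ICAR factor models are known to mix slowly,
    especially with mixed outcome types.
    """
    if spec.variant != "HS_icar":
        spec = ModelSpec(variant="HS_icar",
                         is_dichotomous=spec.is_dichotomous,
                         beta_constraint=spec.beta_constraint,
                         icar_constraint_scale=spec.icar_constraint_scale)
    return fit(data, adjacency, spec, mcmc)
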