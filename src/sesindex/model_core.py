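"""Generative model: measurement equations, priors, and log-densities.

The latent-variable measurement model is

    y*_ijk = α_ik + β_k θ_i + ε_ijk,      ε_ijk ~ N(0, σ_k²),

for household j in area i and manifest variable k. Continuous variables are
observed directly (y = y*, with α_ik ≡ 0 and the column centered);
dichotomous variables observe only the sign, y = 1{y* ≥ 0}, with σ_k ≡ 1,
so marginally  y_ijk ~ Bernoulli(Φ(α_ik + β_k θ_i))  — a two-parameter
probit item-response model where α is a negative item difficulty and β an
item discrimination / factor loading.

Priors (all scales fixed at 1 for identifiability):

* θ ~ N(0, (D − ιW)⁻¹) proper CAR with ι ~ U(0,1), or θ_i ~ N(0,1) iid,
  or intrinsic CAR with a soft sum-to-zero constraint (variant switch);
* α_ik ~ N(α*_k, 1), α*_k ~ N(0,1) hierarchical — or α_ik = α_k ~ N(0,1)
  shared across areas (variant switch);
* β_k ~ half-Normal(0,1), all loadings constrained positive (resolves the
  (β,θ) → (−β,−θ) sign flip; the scale flip (cβ, θ/c) is resolved by fixing
  the prior variance of θ at 1);
* σ_k ~ Half-Cauchy(0,1) for continuous k, fixed at 1 for dichotomous k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

from .data_model import AdjacencyStructure, MixedDataset
from .spatial import build_car_precision, car_logpdf

__all__ = ["ModelSpec", "ParameterState", "loglik_observation", "log_joint",
           "loglik_matrix", "VARIANTS"]

VARIANTS = ("HS", "H", "S", "M0", "HS_icar")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Model-variant switches and fixed hyperparameters.

    Variants (hierarchical difficulty × spatial index):

    ========  =====================  =============================
    variant   prior for α (dich.)    prior for θ
    ========  =====================  =============================
    HS        α_ik ~ N(α*_k, 1)      proper CAR N(0, (D − ιW)⁻¹)
    H         α_ik ~ N(α*_k, 1)      iid N(0, 1)
    S         α_k ~ N(0, 1) shared   proper CAR
    M0        α_k ~ N(0, 1) shared   iid N(0, 1)
    HS_icar   α_ik ~ N(α*_k, 1)      intrinsic CAR + sum-to-zero
    ========  =====================  =============================

    All prior scales are fixed at 1; the prior variance of θ in particular
    is not configurable (identifiability).

    ``beta_constraint`` is ``"all_positive"`` (default) or ``"first_positive"``
    (sensitivity variant: only β_1 restricted, β_2.. ~ N(0,1)).
    """

    variant: str = "HS"
    is_dichotomous: tuple[bool, ...] = ()
    beta_constraint: str = "all_positive"
    icar_constraint_scale: float = 0.001  # ε in Σθ_i ~ N(0, εN)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.beta_constraint not in ("all_positive", "first_positive"):
            raise ValueError(f"unknown beta_constraint {self.beta_constraint!r}")
        object.__setattr__(self, "is_dichotomous", tuple(self.is_dichotomous))

    @property
    def p(self) -> int:
        return len(self.is_dichotomous)

    @property
    def hierarchical_alpha(self) -> bool:
        return self.variant in ("HS", "H", "HS_icar")

    @property
    def spatial_theta(self) -> bool:
        return self.variant in ("HS", "S")

    @property
    def icar_theta(self) -> bool:
        return self.variant == "HS_icar"

    @classmethod
    def for_data(cls, data: MixedDataset, variant: str = "HS", **kw) -> "ModelSpec":
        return cls(variant=variant,
                   is_dichotomous=tuple(bool(b) for b in data.is_dichotomous), **kw)

    def to_json_dict(self) -> dict:
        return {"variant": self.variant, "beta_constraint": self.beta_constraint,
                "is_dichotomous": list(self.is_dichotomous)}

    @classmethod
    def from_json_dict(cls, obj: dict) -> "ModelSpec":
        return cls(variant=obj["variant"],
                   is_dichotomous=tuple(obj.get("is_dichotomous", ())),
                   beta_constraint=obj.get("beta_constraint", "all_positive"))


@dataclass
class ParameterState:
    """One point in parameter space (plus the augmented latents y*).

    Shapes: ``alpha`` (N, p) with zero columns for continuous variables and
    identical rows for non-hierarchical variants; ``alpha_star`` (p,) (NaN
    for continuous k); ``beta``, ``sigma`` (p,) with σ_k = 1 for dichotomous
    k; ``theta`` (N,); ``iota`` scalar in [0,1) (NaN for non-CAR variants);
    ``ystar`` (H, p) holding the latent continua for dichotomous entries and
    the observed values for continuous entries (may be None when not
    augmented).
    """

    alpha: np.ndarray
    alpha_star: np.ndarray
    beta: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray
    iota: float = np.nan
    ystar: np.ndarray | None = None

    def copy(self) -> "ParameterState":
        return ParameterState(
            alpha=self.alpha.copy(), alpha_star=self.alpha_star.copy(),
            beta=self.beta.copy(), theta=self.theta.copy(),
            sigma=self.sigma.copy(), iota=self.iota,
            ystar=None if self.ystar is None else self.ystar.copy())

    def validate(self, spec: ModelSpec) -> None:
        dich = np.asarray(spec.is_dichotomous)
        if spec.beta_constraint == "all_positive":
            if (self.beta <= 0).any():
                raise ValueError("all beta must be positive")
        elif self.beta[0] <= 0:
            raise ValueError("beta[0] must be positive")
        if (self.sigma[dich] != 1.0).any():
            raise ValueError("sigma must be fixed at 1 for dichotomous variables")
        if (np.abs(self.alpha[:, ~dich]) > 0).any():
            raise ValueError("alpha must be 0 for continuous variables")
        if spec.spatial_theta and not (0.0 <= self.iota < 1.0):
            raise ValueError("iota must lie in [0, 1) for proper-CAR variants")


# ---------------------------------------------------------------------------
# marginal (y*-integrated) log-likelihood — feeds WAIC
# ---------------------------------------------------------------------------

def loglik_observation(state: ParameterState, spec: ModelSpec,
                       i: int, k: int, y: float) -> float:
    """Marginal log-likelihood of one observation y_ijk.

    Continuous: log N(y | β_k θ_i, σ_k²) (α ≡ 0, column centered).
    Dichotomous: log Φ(η) if y = 1 else log Φ(−η), η = α_ik + β_k θ_i —
    the latent y* integrated out at σ = 1.
    """
    eta = state.alpha[i, k] + state.beta[k] * state.theta[i]
    if spec.is_dichotomous[k]:
        return float(log_ndtr(eta if y >= 0.5 else -eta))
    z = (y - eta) / state.sigma[k]
    return float(-0.5 * z * z - np.log(state.sigma[k]) - _LOG_SQRT_2PI)


def pointwise_loglik(state: ParameterState, data: MixedDataset,
                     spec: ModelSpec) -> np.ndarray:
    """Marginal log-likelihood of every cell, shape (H, p), for one state."""
    eta = state.alpha[data.area_ids] + state.beta * state.theta[data.area_ids, None]
    out = np.empty_like(data.y)
    dich = data.is_dichotomous
    if dich.any():
        e = eta[:, dich]
        yd = data.y[:, dich]
        out[:, dich] = np.where(yd >= 0.5, log_ndtr(e), log_ndtr(-e))
    cont = ~dich
    if cont.any():
        z = (data.y[:, cont] - eta[:, cont]) / state.sigma[cont]
        out[:, cont] = -0.5 * z * z - np.log(state.sigma[cont]) - _LOG_SQRT_2PI
    return out


def loglik_matrix(draws, data: MixedDataset, thin: int = 1) -> np.ndarray:
    """Per-draw, per-observation marginal log-likelihood table for WAIC.

    One "observation" is one (household, variable) cell y_ijk; rows are the
    retained posterior draws (all chains concatenated, optionally thinned),
    columns the H·p cells in row-major (household, variable) order.
    """
    from .sampler import PosteriorDraws  # local import to avoid a cycle

    if not isinstance(draws, PosteriorDraws):
        raise TypeError("draws must be a PosteriorDraws")
    states = list(draws.iter_states(thin=thin))
    H, p = data.y.shape
    out = np.empty((len(states), H * p))
    for r, st in enumerate(states):
        out[r] = pointwise_loglik(st, data, draws.spec).ravel()
    return out


# ---------------------------------------------------------------------------
# joint log-density of the augmented model
# ---------------------------------------------------------------------------

def _halfcauchy_logpdf(x: np.ndarray) -> np.ndarray:
    # scale 1: log 2/π − log(1 + x²) on x > 0
    return np.where(x > 0, np.log(2.0 / np.pi) - np.log1p(x * x), -np.inf)


def log_joint(state: ParameterState, data: MixedDataset, spec: ModelSpec,
              adjacency: AdjacencyStructure | None = None) -> float:
    """Log of the augmented posterior kernel: likelihood of (y, y*) + priors.

    The augmented likelihood uses the truncated-normal representation for
    dichotomous cells: density N(y* | α + βθ, 1) times the sign indicator
    1{y = 1, y* ≥ 0} + 1{y = 0, y* < 0}; any violated indicator gives −inf.
    Continuous cells contribute N(y | βθ, σ_k²). Priors as per ``spec``.
    Requires ``state.ystar`` for dichotomous variables.
    """
    dich = np.asarray(spec.is_dichotomous)
    if dich.any() and state.ystar is None:
        raise ValueError("log_joint of the augmented model needs state.ystar")
    if spec.spatial_theta or spec.icar_theta:
        if adjacency is None:
            raise ValueError("spatial variants need an adjacency structure")
        if adjacency.n_areas != state.theta.size:
            raise ValueError("adjacency / theta dimension mismatch")

    a = data.area_ids
    eta = state.alpha[a] + state.beta * state.theta[a, None]
    total = 0.0

    # augmented likelihood, dichotomous (sigma = 1)
    if dich.any():
        ys = state.ystar[:, dich]
        yd = data.y[:, dich]
        sign_ok = np.where(yd >= 0.5, ys >= 0.0, ys < 0.0)
        if not sign_ok.all():
            return -np.inf
        r = ys - eta[:, dich]
        total += float(np.sum(-0.5 * r * r - _LOG_SQRT_2PI))

    # Gaussian likelihood, continuous
    cont = ~dich
    if cont.any():
        z = (data.y[:, cont] - eta[:, cont]) / state.sigma[cont]
        total += float(np.sum(-0.5 * z * z - np.log(state.sigma[cont])
                              - _LOG_SQRT_2PI))

    # --- priors -----------------------------------------------------------
    # theta
    if spec.spatial_theta:
        if not (0.0 <= state.iota < 1.0):
            return -np.inf
        prec = build_car_precision(adjacency, state.iota)
        total += car_logpdf(state.theta, prec)
        # iota ~ U(0,1): contributes 0 on its support
    elif spec.icar_theta:
        W = adjacency.W
        d = adjacency.degrees.astype(float)
        quad = float(state.theta @ (d * state.theta) - state.theta @ (W @ state.theta))
        total += -0.5 * quad  # pairwise-difference kernel (improper, no logdet)
        s = float(state.theta.sum())
        var = spec.icar_constraint_scale * state.theta.size
        total += -0.5 * s * s / var - 0.5 * np.log(2 * np.pi * var)
    else:
        total += float(np.sum(-0.5 * state.theta**2 - _LOG_SQRT_2PI))

    # alpha hierarchy (dichotomous columns only)
    if dich.any():
        if spec.hierarchical_alpha:
            da = state.alpha[:, dich] - state.alpha_star[dich]
            total += float(np.sum(-0.5 * da * da - _LOG_SQRT_2PI))
            astar = state.alpha_star[dich]
            total += float(np.sum(-0.5 * astar**2 - _LOG_SQRT_2PI))
        else:
            # shared alpha_k = first row; one N(0,1) prior per variable
            ak = state.alpha[0, dich]
            total += float(np.sum(-0.5 * ak**2 - _LOG_SQRT_2PI))

    # beta
    if spec.beta_constraint == "all_positive":
        if (state.beta <= 0).any():
            return -np.inf
        total += float(np.sum(-0.5 * state.beta**2 - _LOG_SQRT_2PI
                              + np.log(2.0)))
    else:
        if state.beta[0] <= 0:
            return -np.inf
        total += float(-0.5 * state.beta[0] ** 2 - _LOG_SQRT_2PI + np.log(2.0))
        total += float(np.sum(-0.5 * state.beta[1:] ** 2 - _LOG_SQRT_2PI))

    # sigma, continuous only
    if cont.any():
        lp = _halfcauchy_logpdf(state.sigma[cont])
        if np.isneginf(lp).any():
            return -np.inf
        total += float(lp.sum())

    return total
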