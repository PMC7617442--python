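"""Generate datasets from the generative model itself.

Used both as the fixture generator for tests and as the engine of the
parameter-recovery simulation study: draw a spatially correlated latent
index θ over a lattice of areas, then household-level mixed outcomes

    y*_ijk = α_ik + β_k θ_i + ε_ijk,
    y_ijk  = y*  (continuous, then re-centered)  or  1{y* ≥ 0} (dichotomous).

True parameter values default to draws from the model's own priors
(recorded alongside the data so recovery can be scored), since the index
and loadings of any real population are never observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AdjacencyStructure, MixedDataset, VariableMeta, preprocess
from .model_core import ModelSpec
from .spatial import build_car_precision, sample_car

__all__ = [
    "TrueParameters",
    "make_lattice_adjacency",
    "draw_true_parameters",
    "generate_dataset",
    "simulation_study_config",
    "StudyConfig",
]


@dataclass
class TrueParameters:
    """Generating parameter values (same components as a ParameterState,
    minus the augmented y*), with a provenance note."""

    alpha_star: np.ndarray   # (p,), NaN at continuous positions
    beta: np.ndarray         # (p,), positive
    sigma: np.ndarray        # (p,), 1 at dichotomous positions
    iota: float              # spatial intensity (NaN for non-spatial)
    theta: np.ndarray | None = None   # realized per dataset
    alpha: np.ndarray | None = None   # realized (N, p) per dataset
    provenance: str = "prior-draw"

    def validate(self, spec: ModelSpec) -> None:
        dich = np.asarray(spec.is_dichotomous)
        if len(dich) != self.beta.size:
            raise ValueError("truth/spec dimension mismatch")
        if (self.beta <= 0).any():
            raise ValueError("true beta must be positive")
        if (self.sigma[dich] != 1.0).any():
            raise ValueError("true sigma must be 1 for dichotomous variables")
        if spec.spatial_theta and not (0.0 <= self.iota < 1.0):
            raise ValueError("true iota must be in [0,1) for spatial variants")


def make_lattice_adjacency(rows: int, cols: int) -> AdjacencyStructure:
    """Rook-adjacency grid of ``rows × cols`` areas (connected, no islands)."""
    if rows * cols < 4:
        raise ValueError("lattice needs at least 4 areas")
    idx = lambda r, c: r * cols + c
    neighbours: list[list[int]] = []
    for r in range(rows):
        for c in range(cols):
            nbrs = []
            if r > 0:
                nbrs.append(idx(r - 1, c))
            if r < rows - 1:
                nbrs.append(idx(r + 1, c))
            if c > 0:
                nbrs.append(idx(r, c - 1))
            if c < cols - 1:
                nbrs.append(idx(r, c + 1))
            neighbours.append(nbrs)
    return AdjacencyStructure(neighbours=neighbours)


def draw_true_parameters(spec: ModelSpec, iota: float = 0.9,
                         rng: np.random.Generator | int | None = None
                         ) -> TrueParameters:
    """Draw (β, α*, σ) from the model priors; ι is fixed by the caller.

    β_k ~ half-Normal(0,1); α*_k ~ N(0,1) (dichotomous only);
    σ_k ~ Half-Cauchy(0,1) (continuous only, 1 otherwise).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dich = np.asarray(spec.is_dichotomous)
    p = spec.p
    beta = np.abs(rng.standard_normal(p))
    alpha_star = np.where(dich, rng.standard_normal(p), np.nan)
    sigma = np.where(dich, 1.0, np.abs(rng.standard_cauchy(p)))
    return TrueParameters(alpha_star=alpha_star, beta=beta, sigma=sigma,
                          iota=float(iota) if spec.spatial_theta else np.nan,
                          provenance="prior-draw")


def generate_dataset(adjacency: AdjacencyStructure, spec: ModelSpec,
                     truth: TrueParameters,
                     households_per_area: np.ndarray | tuple[int, int] | int,
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[MixedDataset, TrueParameters]:
    """Generate one dataset from the model; returns (data, realized truth).

    θ is drawn from the proper CAR N(0, (D − ιW)⁻¹) (spatial variants) or
    iid N(0,1); the area-level difficulties α_ik are drawn fresh around α*_k
    for hierarchical variants (or set to α*_k for shared-α variants); then
    y* = α + βθ + ε with ε ~ N(0, σ_k²); dichotomous y = 1{y* ≥ 0};
    continuous y = y*, re-centered so the fitted model's α = 0 convention
    holds exactly. The returned TrueParameters carries the realized θ and α
    for recovery scoring.

    ``households_per_area`` may be an explicit length-N integer array, a
    ``(lo, hi)`` tuple (n_i ~ Uniform{lo..hi}), or a single integer.
    """
    truth.validate(spec)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    N = adjacency.n_areas
    p = spec.p
    dich = np.asarray(spec.is_dichotomous)

    if isinstance(households_per_area, tuple):
        lo, hi = households_per_area
        n_i = rng.integers(lo, hi + 1, size=N)
    elif np.isscalar(households_per_area):
        n_i = np.full(N, int(households_per_area))
    else:
        n_i = np.asarray(households_per_area, dtype=np.int64)
        if n_i.shape != (N,):
            raise ValueError("households_per_area must be length N")
    if (n_i < 1).any():
        raise ValueError("every area needs at least one household")

    # latent index
    if spec.spatial_theta:
        theta = sample_car(build_car_precision(adjacency, truth.iota), rng)
    elif spec.icar_theta:
        raise ValueError("generate under the proper-CAR spec; the ICAR variant "
                         "is a fitting prior, not a generative truth")
    else:
        theta = rng.standard_normal(N)

    # area-level difficulties
    alpha = np.zeros((N, p))
    if dich.any():
        if spec.hierarchical_alpha:
            alpha[:, dich] = truth.alpha_star[dich] + rng.standard_normal(
                (N, int(dich.sum())))
        else:
            alpha[:, dich] = truth.alpha_star[dich]

    area_ids = np.repeat(np.arange(N), n_i)
    H = int(n_i.sum())
    eps = rng.standard_normal((H, p)) * truth.sigma
    ystar = alpha[area_ids] + truth.beta * theta[area_ids, None] + eps
    y = np.where(dich, (ystar >= 0).astype(float), ystar)

    meta = [VariableMeta(name=(f"d{k+1}" if dich[k] else f"c{k+1}"),
                         kind=("dichotomous" if dich[k] else "continuous"))
            for k in range(p)]
    data = preprocess(MixedDataset(area_ids=area_ids, y=y, meta=meta,
                                   area_labels=list(adjacency.area_labels)))
    realized = TrueParameters(alpha_star=truth.alpha_star.copy(),
                              beta=truth.beta.copy(), sigma=truth.sigma.copy(),
                              iota=truth.iota, theta=theta, alpha=alpha,
                              provenance=truth.provenance)
    return data, realized


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a parameter-recovery simulation study."""

    rows: int
    cols: int
    households_range: tuple[int, int]
    n_dichotomous: int
    n_continuous: int
    iota: float
    n_replicates: int
    variant: str = "HS"

    @property
    def n_areas(self) -> int:
        return self.rows * self.cols

    def adjacency(self) -> AdjacencyStructure:
        return make_lattice_adjacency(self.rows, self.cols)

    def model_spec(self) -> ModelSpec:
        kinds = (True,) * self.n_dichotomous + (False,) * self.n_continuous
        return ModelSpec(variant=self.variant, is_dichotomous=kinds)


def simulation_study_config(scale: str = "desk") -> StudyConfig:
    """Stock study configurations.

    ``"full"``: 200 areas (10×20 lattice), ~5,195 households in total
    (expected 26 per area, drawn 21–31), 15 dichotomous + 5 continuous
    variables, spatial intensity 0.9, 100 replicates.

    ``"desk"``: 50 areas (5×10), 15–25 households per area, 5 dichotomous +
    2 continuous variables, spatial intensity 0.9, 20 replicates — sized so
    a full study runs in minutes on one core.
    """
    if scale == "full":
        return StudyConfig(rows=10, cols=20, households_range=(21, 31),
                           n_dichotomous=15, n_continuous=5, iota=0.9,
                           n_replicates=100)
    if scale == "desk":
        return StudyConfig(rows=5, cols=10, households_range=(15, 25),
                           n_dichotomous=5, n_continuous=2, iota=0.9,
                           n_replicates=20)
    raise ValueError(f"unknown scale {scale!r}; use 'full' or 'desk'")
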