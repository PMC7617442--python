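"""Proper-CAR precision algebra, CAR sampling, and Moran's I diagnostics.

The latent area index θ carries a proper conditional autoregressive (CAR)
prior θ ~ N(0, (D − ιW)⁻¹) with conditional precision fixed at 1:

    θ_i | θ_{-i} ~ N( (ι/d_i) Σ_{j~i} θ_j , 1/d_i ),

where W is the 0-1 adjacency, D = diag(d_i) the degrees, and ι ∈ [0,1)
the spatial-intensity parameter. For a connected graph and ι < 1 the
precision Q = D − ιW is positive definite (diagonally dominant with strict
dominance wherever ι < 1, irreducible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.sparse import csr_matrix, diags

from .data_model import AdjacencyStructure

__all__ = [
    "CarPrecision",
    "build_car_precision",
    "sample_car",
    "car_logpdf",
    "morans_i",
]


@dataclass
class CarPrecision:
    """Precision matrix Q = D − ιW of the proper CAR prior."""

    Q: csr_matrix
    iota: float
    adjacency: AdjacencyStructure

    @property
    def n_areas(self) -> int:
        return self.Q.shape[0]

    def dense(self) -> np.ndarray:
        return self.Q.toarray()


def build_car_precision(adjacency: AdjacencyStructure, iota: float) -> CarPrecision:
    """Build Q = D − ιW for 0 ≤ ι < 1.

    Raises
    ------
    ValueError
        If ι is outside [0, 1) (the ι → 1 intrinsic limit is handled by the
        ICAR variant, not here) or if any area has no neighbours — with an
        island the CAR conditional is undefined, use the independent-θ
        variant instead.
    """
    if not 0.0 <= iota < 1.0:
        raise ValueError(
            f"iota must be in [0, 1), got {iota}; the improper iota=1 limit "
            "is the ICAR variant"
        )
    if adjacency.has_islands():
        raise ValueError(
            "adjacency has island areas (degree 0); the CAR prior is "
            "undefined there — use the independent-theta model variant"
        )
    d = adjacency.degrees.astype(np.float64)
    Q = (diags(d) - iota * adjacency.W).tocsr()
    return CarPrecision(Q=Q, iota=float(iota), adjacency=adjacency)


def sample_car(
    precision: CarPrecision, rng: np.random.Generator | int, size: int | None = None
) -> np.ndarray:
    """Draw from N(0, Q⁻¹) by solving Lᵀ x = z with Q = L Lᵀ.

    Parameters
    ----------
    precision
        Positive-definite CAR precision.
    rng
        `numpy.random.Generator` or integer seed; fixed seed reproduces the
        draw bit-exactly.
    size
        Number of draws; ``None`` returns a single length-N vector.

    Notes
    -----
    Factorizes Q = UᵀU (dense Cholesky — areal problems have at most a few
    thousand areas) and solves U x = z for z ~ N(0, I), giving
    cov(x) = U⁻¹ U⁻ᵀ = Q⁻¹. The contract is only distributional correctness
    and seed-reproducibility.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = precision.n_areas
    m = 1 if size is None else size
    z = rng.standard_normal((n, m))
    try:
        U = cholesky(precision.dense(), lower=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Cholesky of the CAR precision failed; check that the adjacency "
            "graph is connected and iota < 1"
        ) from exc
    x = solve_triangular(U, z, lower=False)
    return x[:, 0] if size is None else x.T


def car_logpdf(theta: np.ndarray, precision: CarPrecision) -> float:
    """Log-density of N(0, Q⁻¹) at θ, including the ½ log|Q| term."""
    n = precision.n_areas
    U = cholesky(precision.dense(), lower=False)
    logdet = 2.0 * np.log(np.diag(U)).sum()
    quad = float(theta @ (precision.Q @ theta))
    return 0.5 * (logdet - quad - n * np.log(2.0 * np.pi))


def morans_i(
    values: np.ndarray,
    adjacency: AdjacencyStructure,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float | None]:
    """Classical Moran's I with binary weights and a permutation p-value.

        I = (N / S0) · Σ_ij w_ij z_i z_j / Σ_i z_i²,   z = values − mean,

    with S0 = Σ_ij w_ij. The p-value is one-sided (greater): the proportion
    of random relabelings of areas with I at least as large, including the
    observed arrangement, (#{I_perm ≥ I_obs} + 1)/(B + 1).

    W is used as-is (binary, not row-standardized), matching the 0-1
    adjacency of the CAR formulation; row-standardized conventions give
    different values on irregular graphs.

    Returns ``(I, p_value)``; p_value is None when ``n_permutations == 0``.
    """
    values = np.asarray(values, dtype=np.float64)
    n = adjacency.n_areas
    if values.shape != (n,):
        raise ValueError("values must be a length-N area vector")
    if n < 3:
        raise ValueError("Moran's I needs at least 3 areas")
    z = values - values.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for constant values")
    W = adjacency.W
    s0 = float(W.sum())
    scale = n / s0

    def stat(zv: np.ndarray) -> float:
        return scale * float(zv @ (W @ zv)) / float(zv @ zv)

    i_obs = stat(z)
    if n_permutations <= 0:
        return i_obs, None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    count = 0
    for _ in range(n_permutations):
        if stat(rng.permutation(z)) >= i_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return i_obs, p
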