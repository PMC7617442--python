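"""Convergence diagnostics (ESS, split R-hat) and WAIC model comparison.

WAIC follows the standard decomposition

    lppd    = Σ_obs log( mean_draws exp(loglik) )
    p_WAIC  = Σ_obs var_draws(loglik)          (sample variance, n−1)
    WAIC    = −2 (lppd − p_WAIC)

with the pointwise unit being one (household, variable) cell y_ijk, using
the y*-marginalized probit likelihood. Lower WAIC ranks first.

R-hat is the rank-normalized split version (each chain halved, draws
replaced by normal scores of their pooled ranks, classic potential scale
reduction taken as the max of the bulk and folded statistics); ESS uses
Geyer's initial-monotone-positive-pair truncation of the autocorrelation
series, computed per chain and summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtri

__all__ = ["WAICResult", "waic", "compare_waic", "rhat", "ess",
           "convergence_report", "pearson_residuals"]


@dataclass
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray

    def as_dict(self) -> dict:
        return {"lppd": self.lppd, "p_waic": self.p_waic, "waic": self.waic}


def waic(loglik: np.ndarray) -> WAICResult:
    """WAIC from a (draws × observations) pointwise log-likelihood table."""
    loglik = np.asarray(loglik, dtype=np.float64)
    if loglik.ndim != 2:
        raise ValueError("loglik must be 2-D (draws, observations)")
    S = loglik.shape[0]
    if S < 2:
        raise ValueError("WAIC needs at least 2 draws (p_waic is a variance)")
    pointwise_lppd = logsumexp(loglik, axis=0) - np.log(S)
    # exactly-identical draws carry exactly zero complexity (guard against
    # the float noise of the mean subtraction)
    pointwise_p = np.where(np.ptp(loglik, axis=0) == 0.0, 0.0,
                           loglik.var(axis=0, ddof=1))
    lppd = float(pointwise_lppd.sum())
    p_w = float(pointwise_p.sum())
    return WAICResult(lppd=lppd, p_waic=p_w, waic=-2.0 * (lppd - p_w),
                      pointwise_lppd=pointwise_lppd, pointwise_p=pointwise_p)


def compare_waic(results: dict[str, WAICResult]) -> pd.DataFrame:
    """Comparison table (model, p_waic, lppd, waic) sorted ascending by WAIC
    — the first row is the preferred model."""
    rows = [{"model": name, "p_waic": r.p_waic, "lppd": r.lppd,
             "waic": r.waic} for name, r in results.items()]
    return (pd.DataFrame(rows).sort_values("waic", kind="stable")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# R-hat / ESS
# ---------------------------------------------------------------------------

def _split_chains(draws: np.ndarray) -> np.ndarray:
    draws = np.atleast_2d(np.asarray(draws, dtype=np.float64))
    n = draws.shape[1] // 2
    return np.vstack([draws[:, :n], draws[:, n:2 * n]])


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    r = rankdata(x, axis=None).reshape(x.shape)
    return ndtri((r - 3.0 / 8.0) / (x.size + 1.0 / 4.0))


def _psrf(chains: np.ndarray) -> float:
    """Classic potential scale reduction on pre-split chains (m, n)."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    B = n * means.var(ddof=1)
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0:
        return np.nan
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def rhat(draws: np.ndarray, rank_normalized: bool = True) -> float:
    """Split R-hat of one scalar parameter.

    ``draws`` is (chains, iterations) or a single 1-D chain (split into
    halves either way). Rank-normalized by default: the max of the bulk
    statistic (on normal scores of pooled ranks) and the tail-sensitive
    folded statistic (same transform of |x − median|). Constant draws give
    NaN rather than raising.
    """
    chains = _split_chains(draws)
    if chains.shape[1] < 4:
        raise ValueError("need at least 4 draws per split half")
    if np.ptp(chains) == 0:
        return np.nan
    if not rank_normalized:
        return _psrf(chains)
    bulk = _psrf(_rank_normalize(chains))
    folded = _psrf(_rank_normalize(np.abs(chains - np.median(chains))))
    return float(np.nanmax([bulk, folded]))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance function via FFT, lags 0..n-1."""
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    return acov / n


def _ess_one_chain(x: np.ndarray) -> float:
    n = x.size
    acov = _autocov(x)
    if acov[0] == 0:
        return np.nan
    rho = acov / acov[0]
    # Geyer: τ = −1 + 2 Σ_t Γ_t with Γ_t = ρ_{2t} + ρ_{2t+1}; truncate at
    # the first negative pair, enforce monotone non-increase
    tau = -1.0
    prev = np.inf
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        tau += 2.0 * pair
        prev = pair
        t += 2
    # antithetic chains give τ ≤ 0 (super-efficient); clamp as Stan does so
    # ESS stays finite (capped near n·log10(n))
    tau = max(tau, 1.0 / np.log10(max(n, 10)))
    return n / tau


def ess(draws: np.ndarray) -> float:
    """Effective sample size: Geyer-truncated autocorrelation ESS per chain,
    summed across chains. Accepts (chains, iterations) or 1-D."""
    draws = np.atleast_2d(np.asarray(draws, dtype=np.float64))
    if np.ptp(draws) == 0:
        return np.nan
    return float(sum(_ess_one_chain(row) for row in draws))


def convergence_report(draws, rhat_threshold: float = 1.01,
                       ess_threshold: float = 400.0) -> pd.DataFrame:
    """Per-parameter ESS / R-hat table with pass/fail flags.

    Covers every retained scalar in the PosteriorDraws (β, θ, σ, α or α*,
    ι). With a single chain, R-hat is computed on its split halves.
    """
    rows = []
    for name, arr in draws.scalar_draws().items():
        r = rhat(arr)
        e = ess(arr)
        rows.append({"parameter": name, "rhat": r, "ess": e,
                     "rhat_ok": bool(r < rhat_threshold) if np.isfinite(r)
                     else False,
                     "ess_ok": bool(e >= ess_threshold) if np.isfinite(e)
                     else False})
    return pd.DataFrame(rows)


def trace_long(draws) -> pd.DataFrame:
    """Long-format (parameter, chain, iter, value) export for trace plots."""
    frames = []
    for name, arr in draws.scalar_draws().items():
        C, S = arr.shape
        frames.append(pd.DataFrame({
            "parameter": name,
            "chain": np.repeat(np.arange(C), S),
            "iter": np.tile(np.arange(S), C),
            "value": arr.reshape(-1)}))
    return pd.concat(frames, ignore_index=True)


def pearson_residuals(draws, data) -> np.ndarray:
    """Posterior-mean standardized residuals (y − E[y]) / SD[y] per cell.

    For continuous cells E[y] = β θ (α ≡ 0), SD = σ; for dichotomous cells
    E[y] = Φ(α + βθ), SD = sqrt(p(1−p)); parameters are posterior means of
    the per-draw cell means. Exported for plotting; no formal test attached.
    """
    from scipy.special import ndtr

    a = data.area_ids
    dich = data.is_dichotomous
    mean_eta = 0.0
    n = 0
    for st in draws.iter_states():
        eta = st.alpha[a] + st.beta * st.theta[a, None]
        mean_eta = mean_eta + eta
        n += 1
    eta = mean_eta / n
    sigma = np.vstack([st.sigma for st in draws.iter_states()]).mean(axis=0)
    out = np.empty_like(data.y)
    if dich.any():
        pr = ndtr(eta[:, dich])
        out[:, dich] = (data.y[:, dich] - pr) / np.sqrt(pr * (1 - pr))
    cont = ~dich
    if cont.any():
        out[:, cont] = (data.y[:, cont] - eta[:, cont]) / sigma[cont]
    return out
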