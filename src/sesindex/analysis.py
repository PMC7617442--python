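"""Posterior summaries, SES classification tables, and the parameter-
recovery simulation study.

Area classification follows the credible-interval convention: an area whose
θ interval lies entirely above zero is *low* SES (variables are coded so
that a higher latent score means lower status), entirely below zero is
*high* SES, and an interval containing zero is *undetermined*; within each
labelled category the posterior medians are min-max rescaled to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sampler import McmcConfig, PosteriorDraws, fit
from .synthetic import StudyConfig, draw_true_parameters, generate_dataset

__all__ = ["summarize", "classify_areas", "alpha_deviation_map",
           "SimulationResult", "run_simulation_study"]


def _quantiles(x: np.ndarray, probs: list[float]) -> np.ndarray:
    # linear-interpolation quantiles (numpy default); documented rule
    return np.quantile(x, probs)


def summarize(draws: PosteriorDraws, levels: tuple[float, ...] = (0.8, 0.95)
              ) -> pd.DataFrame:
    """Posterior medians and equal-tailed credible intervals per parameter.

    One row per scalar parameter; for each level L, columns
    ``lo{100L}`` / ``hi{100L}`` hold the (1−L)/2 and (1+L)/2 quantiles.
    For display conventions, difficulties are usually reported as −α*; this
    table keeps the model's parameterization and leaves negation to the
    caller.
    """
    for lv in levels:
        if not 0.0 < lv < 1.0:
            raise ValueError(f"credible level must be in (0,1), got {lv}")
    rows = []
    for name, arr in draws.scalar_draws().items():
        x = arr.reshape(-1)
        row = {"parameter": name, "median": float(np.median(x))}
        for lv in levels:
            lo, hi = _quantiles(x, [(1 - lv) / 2, (1 + lv) / 2])
            row[f"lo{int(round(100 * lv))}"] = float(lo)
            row[f"hi{int(round(100 * lv))}"] = float(hi)
        rows.append(row)
    return pd.DataFrame(rows)


def classify_areas(draws: PosteriorDraws, level: float = 0.90) -> pd.DataFrame:
    """Label each area {low, high, undetermined} from its θ interval.

    Interval entirely > 0 → ``low`` SES; entirely < 0 → ``high``; else
    ``undetermined``. Within the low and high categories the posterior
    medians are min-max rescaled to [0, 1] (``score``; a single-area
    category gets score 0 by convention, undetermined areas get NaN).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0,1)")
    th = draws.theta.reshape(-1, draws.n_areas)
    lo, med, hi = np.quantile(
        th, [(1 - level) / 2, 0.5, (1 + level) / 2], axis=0)
    label = np.where(lo > 0, "low", np.where(hi < 0, "high", "undetermined"))
    score = np.full(draws.n_areas, np.nan)
    meta = {}
    for lab in ("low", "high"):
        m = label == lab
        if not m.any():
            continue
        mn, mx = med[m].min(), med[m].max()
        score[m] = 0.0 if mx == mn else (med[m] - mn) / (mx - mn)
        meta[lab] = {"min": float(mn), "max": float(mx)}
    out = pd.DataFrame({"area": np.arange(draws.n_areas), "median": med,
                        "lo": lo, "hi": hi, "label": label, "score": score})
    out.attrs["rescaling"] = meta
    out.attrs["level"] = level
    return out


def alpha_deviation_map(draws: PosteriorDraws, level: float = 0.80
                        ) -> pd.DataFrame:
    """Compare each area-level difficulty interval with the overall one.

    For every (area i, dichotomous variable k), labels whether the
    equal-tailed ``level`` interval for α_ik lies strictly above / below the
    posterior median of α*_k, or contains it. Requires a hierarchical-α
    variant.
    """
    if not draws.spec.hierarchical_alpha:
        raise ValueError("alpha deviation map needs a hierarchical-alpha "
                         "variant (HS, H or HS_icar)")
    pd_idx = draws.dich_idx
    A = draws.alpha.reshape(-1, draws.n_areas, pd_idx.size)
    lo, hi = np.quantile(A, [(1 - level) / 2, (1 + level) / 2], axis=0)
    astar_med = np.median(
        draws.alpha_star[:, :, pd_idx].reshape(-1, pd_idx.size), axis=0)
    label = np.where(lo > astar_med, "above",
                     np.where(hi < astar_med, "below", "contains"))
    rows = []
    for j, k in enumerate(pd_idx):
        for i in range(draws.n_areas):
            rows.append({"area": i, "k": int(k), "lo": lo[i, j],
                         "hi": hi[i, j], "alpha_star_median": astar_med[j],
                         "label": label[i, j]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------

_BLOCKS = ("beta", "alpha_star", "sigma", "theta", "iota")


@dataclass
class SimulationResult:
    """Coverage / bias / RMSE bookkeeping across replicates.

    ``inside[level][block]`` and ``total[level][block]`` are exact integer
    tallies of true values inside their nominal equal-tailed intervals,
    pooled over replicates; ``records`` holds the per-replicate summaries.
    """

    config: StudyConfig
    levels: tuple[float, ...]
    inside: dict = field(default_factory=dict)
    total: dict = field(default_factory=dict)
    records: list = field(default_factory=list)
    failures: list = field(default_factory=list)

    def coverage(self, level: float, block: str) -> float:
        tot = self.total[level][block]
        return self.inside[level][block] / tot if tot else np.nan

    def coverage_table(self) -> pd.DataFrame:
        rows = []
        for lv in self.levels:
            for b in _BLOCKS:
                if self.total[lv][b]:
                    rows.append({"level": lv, "block": b,
                                 "inside": self.inside[lv][b],
                                 "total": self.total[lv][b],
                                 "coverage": self.coverage(lv, b)})
        return pd.DataFrame(rows)

    def bias_rmse(self) -> pd.DataFrame:
        rows = []
        for b in _BLOCKS:
            errs = np.concatenate([r["errors"][b] for r in self.records
                                   if b in r["errors"]]) if any(
                b in r["errors"] for r in self.records) else np.array([])
            if errs.size:
                rows.append({"block": b, "bias": float(errs.mean()),
                             "rmse": float(np.sqrt((errs**2).mean()))})
        return pd.DataFrame(rows)

    @property
    def mean_iota_median(self) -> float:
        vals = [r["iota_median"] for r in self.records
                if r.get("iota_median") is not None]
        return float(np.mean(vals)) if vals else np.nan

    def to_json_dict(self) -> dict:
        return {
            "n_replicates_done": len(self.records),
            "failures": self.failures,
            "coverage": {str(lv): {b: [self.inside[lv][b], self.total[lv][b]]
                                   for b in _BLOCKS}
                         for lv in self.levels},
            "mean_iota_median": self.mean_iota_median,
        }


def _score_replicate(truth, draws: PosteriorDraws, levels) -> dict:
    """Interval-coverage and median-error bookkeeping for one replicate."""
    spec = draws.spec
    dich = np.asarray(spec.is_dichotomous)
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    # (true values, draw matrix with matching column order)
    blocks["beta"] = (truth.beta,
                      draws.beta.reshape(-1, spec.p))
    if spec.hierarchical_alpha and dich.any():
        blocks["alpha_star"] = (
            truth.alpha_star[dich],
            draws.alpha_star.reshape(-1, spec.p)[:, dich])
    cont = ~dich
    if cont.any():
        blocks["sigma"] = (truth.sigma[cont],
                           draws.sigma.reshape(-1, spec.p)[:, cont])
    blocks["theta"] = (truth.theta, draws.theta.reshape(-1, draws.n_areas))
    if draws.iota is not None:
        blocks["iota"] = (np.array([truth.iota]),
                          draws.iota.reshape(-1, 1))
    rec = {"errors": {}, "inside": {lv: {} for lv in levels},
           "total": {lv: {} for lv in levels}}
    for b, (tv, mat) in blocks.items():
        med = np.median(mat, axis=0)
        rec["errors"][b] = med - tv
        for lv in levels:
            lo, hi = np.quantile(mat, [(1 - lv) / 2, (1 + lv) / 2], axis=0)
            rec["inside"][lv][b] = int(((tv >= lo) & (tv <= hi)).sum())
            rec["total"][lv][b] = int(tv.size)
    if draws.iota is not None:
        rec["iota_median"] = float(np.median(draws.iota))
    else:
        rec["iota_median"] = None
    return rec


def run_simulation_study(config: StudyConfig, seed: int = 0,
                         n_iter: int = 4000, n_warmup: int | None = None,
                         levels: tuple[float, ...] = (0.90, 0.95),
                         checkpoint_dir=None,
                         progress: bool = False) -> SimulationResult:
    """Generate → fit → score, ``config.n_replicates`` times.

    True (β, α*, σ) are drawn once from the priors under the master seed
    and reused for every replicate (ι fixed by the config); θ, the
    area-level difficulties α_ik, and the observations are regenerated per
    replicate. Each replicate is fitted with one chain and scored for
    equal-tailed interval coverage at the nominal ``levels``, and for bias /
    RMSE of posterior medians. Replicate seeds are spawned deterministically
    from the master seed; a failing replicate is recorded and skipped, but
    more than 20% failures abort the study.
    """
    adjacency = config.adjacency()
    spec = config.model_spec()
    root = np.random.SeedSequence(seed)
    truth_ss, *rep_ss = root.spawn(config.n_replicates + 1)
    truth = draw_true_parameters(spec, iota=config.iota,
                                 rng=np.random.default_rng(truth_ss))

    result = SimulationResult(config=config, levels=tuple(levels))
    for lv in levels:
        result.inside[lv] = {b: 0 for b in _BLOCKS}
        result.total[lv] = {b: 0 for b in _BLOCKS}

    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)

    for r in range(config.n_replicates):
        rep_rng = np.random.default_rng(rep_ss[r])
        rep_seed = int(rep_ss[r].generate_state(1)[0] % (2**31))
        try:
            data, realized = generate_dataset(
                adjacency, spec, truth, config.households_range, rep_rng)
            draws = fit(data, adjacency, spec,
                        McmcConfig(n_chains=1, n_iter=n_iter,
                                   n_warmup=n_warmup, seed=rep_seed))
            rec = _score_replicate(realized, draws, levels)
        except Exception as exc:  # sampler failure: record and move on
            result.failures.append({"replicate": r, "error": repr(exc)})
            if len(result.failures) > 0.2 * config.n_replicates:
                raise RuntimeError(
                    f"{len(result.failures)} of {config.n_replicates} "
                    "replicates failed; study aborted") from exc
            continue
        result.records.append(rec)
        for lv in levels:
            for b, v in rec["inside"][lv].items():
                result.inside[lv][b] += v
                result.total[lv][b] += rec["total"][lv][b]
        if ckpt:
            with open(ckpt / f"replicate_{r:03d}.json", "w") as fh:
                json.dump({"replicate": r, "iota_median": rec["iota_median"],
                           "inside": {str(lv): rec["inside"][lv]
                                      for lv in levels},
                           "total": {str(lv): rec["total"][lv]
                                     for lv in levels}}, fh)
        if progress:
            print(f"replicate {r + 1}/{config.n_replicates} done", flush=True)
    return result
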