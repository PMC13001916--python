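"""Simulation-study layer: multi-seed aggregation, fixed-alpha sweeps, and
the bias-noise grid of learned alphas."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import syngen, trainer
from .errors import ConfigError

DEFAULT_SIGMA_GRID = (0.0, 0.1, 0.2, 0.3, 0.4)
DEFAULT_BETA_GRID = (0.0, 0.1, 0.2, 0.3, 0.4)
DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 2))


@dataclass
class MultiSeedResult:
    """Per-seed runs plus per-epoch order statistics over seeds."""

    runs: list[trainer.RunResult]
    seeds: list[int]
    summary: pd.DataFrame  # per epoch/metric: median, q25, q75, mean, std


@dataclass
class SweepResult:
    """Plateau MSE against the true outcome for each fixed alpha."""

    alpha_grid: np.ndarray
    mse_per_alpha: np.ndarray
    condition: syngen.FeedbackParams
    optimal_alpha: float


@dataclass
class GridResult:
    """Median terminal learned alpha per (community-noise, physician-bias) cell."""

    sigma_grid: np.ndarray
    beta_grid: np.ndarray
    alpha_matrix: np.ndarray  # shape (len(sigma_grid), len(beta_grid))


def _with(cfg: trainer.RunConfig, **kw) -> trainer.RunConfig:
    return dataclasses.replace(cfg, **kw)


def aggregate_metrics(frames: list[pd.DataFrame],
                      metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-epoch order statistics over runs: median, quartiles, mean, std.

    Quartiles are taken as the closest order statistic (so two runs at 0.4
    and 0.6 give an interquartile range of 0.2, not an interpolated 0.1).
    All frames must share an epoch count.
    """
    if len({len(f) for f in frames}) != 1:
        raise ConfigError(
            f"runs have mismatched epoch counts: {sorted({len(f) for f in frames})}"
        )
    if metrics is None:
        metrics = [c for c in trainer.METRIC_COLUMNS if c != "epoch"]
    out = []
    for m in metrics:
        x = np.column_stack([f[m].to_numpy() for f in frames])
        out.append(pd.DataFrame({
            "epoch": frames[0]["epoch"],
            "metric": m,
            "median": np.nanmedian(x, axis=1),
            "q25": np.nanpercentile(x, 25, axis=1, method="closest_observation"),
            "q75": np.nanpercentile(x, 75, axis=1, method="closest_observation"),
            "mean": np.nanmean(x, axis=1),
            "std": np.nanstd(x, axis=1),
        }))
    return pd.concat(out, ignore_index=True)


def multi_seed(cfg: trainer.RunConfig, seeds: list[int],
               scenarios: syngen.ScenarioSet | None = None) -> MultiSeedResult:
    """Repeat a run over training seeds on a fixed dataset and aggregate.

    Per epoch and metric the summary holds the across-seed median,
    interquartile bounds, mean, and standard deviation.
    """
    if len(seeds) < 2:
        raise ConfigError("multi_seed requires at least 2 seeds")
    if scenarios is None:
        scenarios = syngen.generate_scenarios(cfg.generator)
    runs = [trainer.train_run(_with(cfg, seed=s), scenarios=scenarios) for s in seeds]
    summary = aggregate_metrics([r.metrics for r in runs])
    return MultiSeedResult(runs=runs, seeds=list(seeds), summary=summary)


def alpha_sweep(cfg: trainer.RunConfig, alpha_grid,
                condition: syngen.FeedbackParams,
                seeds: list[int] | None = None,
                scenarios: syngen.ScenarioSet | None = None) -> SweepResult:
    """Offline sweep: supervised-only training at each fixed alpha.

    Records the plateau held-out MSE against the true outcome (mean over
    the trailing eval window, averaged over seeds when several are given)
    and the grid argmin.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=np.float64)
    if alpha_grid.size == 0:
        raise ConfigError("alpha_grid must be nonempty")
    if alpha_grid.min() < 0 or alpha_grid.max() > 1:
        raise ConfigError("alpha_grid values must lie in [0, 1]")
    seeds = seeds if seeds is not None else [cfg.seed]
    base = _with(cfg, feedback=condition)
    if scenarios is None:
        scenarios = syngen.generate_scenarios(base.generator)

    mse = np.empty(len(alpha_grid))
    for i, alpha in enumerate(alpha_grid):
        vals = [trainer.train_run(_with(base, seed=s), scenarios=scenarios,
                                  fixed_alpha=float(alpha)).plateau("mse")
                for s in seeds]
        mse[i] = np.mean(vals)
    return SweepResult(alpha_grid=alpha_grid, mse_per_alpha=mse,
                       condition=condition,
                       optimal_alpha=float(alpha_grid[int(np.argmin(mse))]))


def terminal_alpha(result: trainer.RunResult) -> float:
    """Learned mixing weight at the last epoch of a run."""
    return float(result.metrics["alpha_hat"].iloc[-1])


def bias_noise_grid(cfg: trainer.RunConfig, sigma_grid, beta_grid,
                    seeds: list[int],
                    scenarios: syngen.ScenarioSet | None = None
                    ) -> tuple[GridResult, pd.DataFrame]:
    """Median terminal alpha from full policy runs for every (sigma, beta) cell.

    Returns the grid plus a tidy frame with one row per (cell, seed).
    """
    sigma_grid = np.asarray(sigma_grid, dtype=np.float64)
    beta_grid = np.asarray(beta_grid, dtype=np.float64)
    for g, name in ((sigma_grid, "sigma_grid"), (beta_grid, "beta_grid")):
        if g.size == 0 or g.min() < 0 or g.max() > 1:
            raise ConfigError(f"{name} must be nonempty with values in [0, 1]")
    if scenarios is None:
        scenarios = syngen.generate_scenarios(cfg.generator)

    mat = np.empty((len(sigma_grid), len(beta_grid)))
    rows = []
    for i, sigma in enumerate(sigma_grid):
        for j, beta in enumerate(beta_grid):
            fb = syngen.FeedbackParams(sigma_comm=float(sigma),
                                       beta_phys=float(beta),
                                       k_queries=cfg.feedback.k_queries)
            terms = []
            for s in seeds:
                res = trainer.train_run(_with(cfg, seed=s, feedback=fb),
                                        scenarios=scenarios)
                t = terminal_alpha(res)
                terms.append(t)
                rows.append({"sigma_comm": sigma, "beta_phys": beta,
                             "seed": s, "terminal_alpha": t,
                             "plateau_mse": res.plateau("mse"),
                             "plateau_reward": res.plateau("reward")})
            mat[i, j] = float(np.median(terms))
    tidy = pd.DataFrame(rows)
    return GridResult(sigma_grid=sigma_grid, beta_grid=beta_grid,
                      alpha_matrix=mat), tidy
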