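"""Computational experiments over the model's parameter space.

The central experiment is a grid over topoisomerase activities expressed
as fractions of the steady-state rates ``k_T*`` and ``k_G*`` (the rates
that exactly cancel elongation-generated supercoiling), crossed with
promoter strengths and barrier distances.  On top of the grid sit the
derived analyses: log2 fold-change maps between paired grids, the
strong-vs-weak response statistic under simulated topoisomerase
inhibition, the Far/Close expression ratio for asymmetric barrier
distances, and a generic expression-quartile analysis of per-gene
fold-change tables (with a synthetic table generator for testing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import run
from .kinetics import steady_state_rates
from .observables import burn_in_for, summarize
from .state import make_config


__all__ = [
    "GridSpec",
    "SweepResult",
    "run_grid",
    "log2_fold_change",
    "inhibition_ratio",
    "far_close_ratio",
    "QuartileResult",
    "quartile_response",
    "synth_expression_table",
]

_CONDITION_KEYS = ["topoI_fraction", "gyrase_fraction", "k_i", "D"]


def _summarize_run(cfg, seed):
    """Run + summarize with the burn-in clamped for smoke-scale runs."""
    burn_in = burn_in_for(cfg)
    if burn_in >= cfg.n_steps:
        burn_in = cfg.n_steps // 10
    return summarize(run(cfg, seed=seed), burn_in=burn_in)


def _run_seed(base_seed: int, *key: int) -> int:
    """Deterministic per-condition RNG seed derived from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class GridSpec:
    """Grid of conditions: topoisomerase fractions x promoters x distances."""

    topoI_fractions: tuple = tuple(np.round(np.arange(0.0, 2.01, 0.1), 10))
    gyrase_fractions: tuple = tuple(np.round(np.arange(0.0, 2.01, 0.1), 10))
    promoter_strengths: tuple = (0.008, 0.05, 0.2)
    barrier_distances: tuple = (10_000.0,)
    seeds: tuple = (0,)
    n_steps: int = 2_000_000
    burn_in_steps: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.topoI_fractions and self.gyrase_fractions and self.promoter_strengths):
            raise ValueError("grid axes must be non-empty")
        if any(f < 0 for f in self.topoI_fractions + self.gyrase_fractions):
            raise ValueError("topoisomerase fractions must be non-negative")


@dataclass
class SweepResult:
    """Long-format table: one row per (condition, seed) with all summary stats."""

    table: pd.DataFrame
    spec: Optional[GridSpec] = None

    def mean_over_seeds(self, value: str = "k_obs") -> pd.DataFrame:
        return (
            self.table.groupby(_CONDITION_KEYS, as_index=False)[value].mean()
        )


def run_grid(spec: GridSpec, *, L: float = 1000.0, **config_kwargs) -> SweepResult:
    """Run and summarize the engine at every grid point and seed.

    Fully deterministic: the RNG stream of each cell is derived from the
    replicate seed and the cell's grid indices.  A failed cell is recorded
    with missing statistics rather than aborting the sweep.
    """
    rows = []
    for iD, D in enumerate(spec.barrier_distances):
        star = steady_state_rates(D)
        for ip, k_i in enumerate(spec.promoter_strengths):
            for iT, fT in enumerate(spec.topoI_fractions):
                for iG, fG in enumerate(spec.gyrase_fractions):
                    for seed in spec.seeds:
                        cond = {
                            "topoI_fraction": fT,
                            "gyrase_fraction": fG,
                            "k_i": k_i,
                            "D": D,
                            "seed": seed,
                        }
                        cfg = make_config(
                            D=D,
                            L=L,
                            k_i=k_i,
                            k_T=fT * star.k_T_star,
                            k_G=fG * star.k_G_star,
                            n_steps=spec.n_steps,
                            burn_in_steps=spec.burn_in_steps,
                            **config_kwargs,
                        )
                        run_seed = _run_seed(seed, iD, ip, iT, iG)
                        try:
                            stats = _summarize_run(cfg, run_seed).to_dict()
                        except Exception:  # failed cell -> missing stats
                            stats = {}
                        rows.append({**cond, **stats})
    return SweepResult(table=pd.DataFrame(rows), spec=spec)


def log2_fold_change(
    resultA: SweepResult,
    resultB: SweepResult,
    on: Sequence[str] = ("topoI_fraction", "gyrase_fraction", "k_i"),
) -> pd.DataFrame:
    """Per-condition log2(rateB / rateA) of seed-averaged transcription rates.

    Cells with a zero rate on either side are reported as missing (NaN).
    Raises if the two results do not cover the same conditions.
    """
    on = list(on)
    a = resultA.table.groupby(on, as_index=False)["k_obs"].mean()
    b = resultB.table.groupby(on, as_index=False)["k_obs"].mean()
    merged = a.merge(b, on=on, how="outer", suffixes=("_A", "_B"), indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("condition keys of the two sweeps do not match")
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(merged["k_obs_B"] / merged["k_obs_A"])
    merged["log2fc"] = np.where(
        (merged["k_obs_A"] > 0) & (merged["k_obs_B"] > 0), lfc, np.nan
    )
    return merged.drop(columns=["_merge"])


def strong_weak_statistic(
    rate_strong_base: float,
    rate_strong_inhibited: float,
    rate_weak_base: float,
    rate_weak_inhibited: float,
) -> float:
    """log2FC(strong) - log2FC(weak) under an inhibition; NaN for zero baselines."""
    if min(rate_strong_base, rate_weak_base, rate_strong_inhibited, rate_weak_inhibited) <= 0:
        return math.nan
    return math.log2(rate_strong_inhibited / rate_strong_base) - math.log2(
        rate_weak_inhibited / rate_weak_base
    )


def inhibition_ratio(
    grid: GridSpec,
    promoter_strong: float = 0.2,
    promoter_weak: float = 0.008,
    factor: float = 5.0,
    *,
    enzyme: str = "topoI",
    L: float = 1000.0,
    **config_kwargs,
) -> pd.DataFrame:
    """Strong-vs-weak transcriptional response to topoisomerase inhibition.

    For every (k_T fraction, k_G fraction) cell of the grid, the chosen
    enzyme's rate is divided by ``factor`` and the statistic
    ``log2FC(strong gene) - log2FC(weak gene)`` is computed from
    seed-averaged rates.  Negative values mean the strong gene is
    preferentially repressed by the inhibition.
    """
    if factor <= 1:
        raise ValueError("inhibition factor must exceed 1")
    if enzyme not in ("topoI", "gyrase"):
        raise ValueError("enzyme must be 'topoI' or 'gyrase'")
    rows = []
    for iD, D in enumerate(grid.barrier_distances):
        star = steady_state_rates(D)
        for iT, fT in enumerate(grid.topoI_fractions):
            for iG, fG in enumerate(grid.gyrase_fractions):
                rates = {}
                for ip, k_i in enumerate((promoter_strong, promoter_weak)):
                    for inhibited in (False, True):
                        k_T = fT * star.k_T_star
                        k_G = fG * star.k_G_star
                        if inhibited:
                            if enzyme == "topoI":
                                k_T /= factor
                            else:
                                k_G /= factor
                        vals = []
                        for seed in grid.seeds:
                            cfg = make_config(
                                D=D,
                                L=L,
                                k_i=k_i,
                                k_T=k_T,
                                k_G=k_G,
                                n_steps=grid.n_steps,
                                burn_in_steps=grid.burn_in_steps,
                                **config_kwargs,
                            )
                            run_seed = _run_seed(seed, iD, ip, iT, iG, int(inhibited))
                            vals.append(_summarize_run(cfg, run_seed).k_obs)
                        rates[(ip, inhibited)] = float(np.mean(vals))
                stat = strong_weak_statistic(
                    rates[(0, False)], rates[(0, True)], rates[(1, False)], rates[(1, True)]
                )
                rows.append(
                    {
                        "topoI_fraction": fT,
                        "gyrase_fraction": fG,
                        "D": D,
                        "rate_strong_base": rates[(0, False)],
                        "rate_strong_inhibited": rates[(0, True)],
                        "rate_weak_base": rates[(1, False)],
                        "rate_weak_inhibited": rates[(1, True)],
                        "log2_ratio": stat,
                    }
                )
    return pd.DataFrame(rows)


def far_close_ratio(
    side: str,
    far_distance: float,
    *,
    k_i: float = 0.05,
    topoI_fraction: float = 0.2,
    gyrase_fraction: float = 2.0,
    base_up: float = 250.0,
    base_down: float = 320.0,
    L: float = 1000.0,
    seeds: Sequence[int] = (0,),
    n_steps: int = 2_000_000,
    burn_in_steps: Optional[int] = None,
    **config_kwargs,
) -> float:
    """Ratio of expression with one barrier moved far away vs the close baseline.

    The baseline places the upstream barrier 250 bp from the TSS and the
    downstream barrier 320 bp from the terminator.  Topoisomerase per-bp
    rates are held fixed at fractions of the steady-state rates computed
    for the close geometry (TopoI against the upstream distance, gyrase
    against the downstream distance), so moving a barrier changes the
    number of available binding sites, not the per-bp rates.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    base = (base_up, base_down)
    if side == "upstream":
        if far_distance < base_up:
            raise ValueError("far_distance must be at least the close upstream distance")
        far = (far_distance, base_down)
    else:
        if far_distance < base_down:
            raise ValueError("far_distance must be at least the close downstream distance")
        far = (base_up, far_distance)
    k_T = topoI_fraction * steady_state_rates(base_up).k_T_star
    k_G = gyrase_fraction * steady_state_rates(base_down).k_G_star

    def _mean_rate(D_up: float, D_down: float, tag: int) -> float:
        vals = []
        for seed in seeds:
            cfg = make_config(
                D_up=D_up,
                D_down=D_down,
                L=L,
                k_i=k_i,
                k_T=k_T,
                k_G=k_G,
                n_steps=n_steps,
                burn_in_steps=burn_in_steps,
                **config_kwargs,
            )
            vals.append(_summarize_run(cfg, _run_seed(seed, tag)).k_obs)
        return float(np.mean(vals))

    if far == base:
        return 1.0
    rate_close = _mean_rate(*base, 0)
    rate_far = _mean_rate(*far, 1)
    return rate_far / rate_close if rate_close > 0 else math.nan


@dataclass(frozen=True)
class QuartileResult:
    quartile_mean_fc: tuple  # mean linear fold-change per expression quartile
    log2_ratio: float  # log2(mean FC Q4 / mean FC Q1)
    p_value: float  # Welch t-test, Q1 vs Q4 log2 fold-changes
    n_genes: int


def quartile_response(table: pd.DataFrame) -> QuartileResult:
    """Group genes into expression quartiles and compare fold-change responses.

    ``table`` needs an ``expression`` column (positive) and either a
    ``log2fc`` or a ``fold_change`` column.  Genes are ranked by expression
    (ties broken by stable order) into four equal-count bins; the statistic
    is the log2 ratio of the mean linear fold-change of the top quartile to
    the bottom quartile, with a two-sample unequal-variance t-test between
    the two quartiles' log2 fold-changes.
    """
    n = len(table)
    if n < 8:
        raise ValueError(f"need at least 8 genes, got {n}")
    expr = np.asarray(table["expression"], dtype=float)
    if np.any(expr <= 0) or not np.all(np.isfinite(expr)):
        raise ValueError("expression strengths must be positive and finite")
    if "log2fc" in table.columns:
        lfc = np.asarray(table["log2fc"], dtype=float)
    elif "fold_change" in table.columns:
        lfc = np.log2(np.asarray(table["fold_change"], dtype=float))
    else:
        raise ValueError("table needs a 'log2fc' or 'fold_change' column")
    order = np.argsort(expr, kind="stable")
    quartile = np.empty(n, dtype=int)
    quartile[order] = (4 * np.arange(n)) // n
    fc = 2.0**lfc
    means = tuple(float(fc[quartile == q].mean()) for q in range(4))
    log2_ratio = float(np.log2(means[3] / means[0]))
    q1, q4 = lfc[quartile == 0], lfc[quartile == 3]
    if np.ptp(q1) == 0 and np.ptp(q4) == 0:
        p = 1.0 if q1[0] == q4[0] else 0.0
    else:
        p = float(sps.ttest_ind(q1, q4, equal_var=False).pvalue)
    return QuartileResult(quartile_mean_fc=means, log2_ratio=log2_ratio, p_value=p, n_genes=n)


def synth_expression_table(
    rng,
    n_genes: int = 2000,
    effect: float = -1.0,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Synthetic per-gene (expression, fold-change) table for testing.

    Expression strengths are log-normal (a typical transcriptome-wide
    distribution); log2 fold-changes follow a linear trend in the
    expression rank percentile scaled so that the expected difference in
    mean log2 fold-change between the top and bottom quartiles equals
    ``effect``, plus Gaussian noise.  :func:`quartile_response` therefore
    recovers ``effect`` (as its log2 ratio) up to noise.
    """
    if n_genes < 8:
        raise ValueError("n_genes must be at least 8")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    expression = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    rank = np.empty(n_genes, dtype=float)
    rank[np.argsort(expression, kind="stable")] = np.arange(n_genes)
    pct = (rank + 0.5) / n_genes
    # Q4 mean pct - Q1 mean pct = 0.75, hence the 0.75 normalisation.
    mu = effect * (pct - 0.5) / 0.75
    log2fc = mu + rng.normal(0.0, noise_sd, size=n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "expression": expression,
            "log2fc": log2fc,
        }
    )
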