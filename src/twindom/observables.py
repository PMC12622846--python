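"""Derived statistics of a simulated trajectory.

The observables mirror the quantities used to characterise supercoiling-
coupled transcription: the transcription rate (terminations per second of
retained time), the rate normalised by the maximal promoter strength, the
free promoter fraction (observed rate over the time-averaged SC-dependent
initiation rate -- a measure of steric promoter availability), the mean
elongation speed of completed transits, and the noise statistics of the
RNA copy-number time series (Fano factor = variance/mean; normalised
variance = variance/mean^2).  A Fano factor of one indicates Poissonian
expression; values above one indicate transcriptional bursting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from typing import Optional

from .state import SimulationConfig, Trajectory

__all__ = ["SummaryStats", "summarize", "burn_in_for"]


@dataclass(frozen=True)
class SummaryStats:
    k_obs: float
    normalized_rate: float
    free_promoter_fraction: float
    mean_elongation_speed: float
    mean_rna: float
    fano: float
    normalized_variance: float
    mean_sigma_up: float
    mean_sigma_down: float
    mean_sigma_domain: float
    n_terminations: int
    retained_time: float

    def to_dict(self) -> dict:
        return asdict(self)


def burn_in_for(cfg: SimulationConfig) -> int:
    """Timesteps discarded before statistics are computed.

    30 simulated minutes by default; 60 minutes for domains with a barrier
    distance of 100 kb or more, which equilibrate more slowly.  A value set
    explicitly on the config wins.
    """
    if cfg.burn_in_steps is not None:
        return cfg.burn_in_steps
    minutes = 60.0 if max(cfg.D_up, cfg.D_down) >= 100_000.0 else 30.0
    return int(round(minutes * 60.0 / cfg.dt))


def summarize(traj: Trajectory, burn_in: Optional[int] = None) -> SummaryStats:
    """Compute all summary statistics on the post-burn-in samples."""
    cfg = traj.cfg
    if burn_in is None:
        burn_in = burn_in_for(cfg)
    if traj.n_steps <= burn_in:
        raise ValueError(
            f"trajectory of {traj.n_steps} steps is not longer than burn-in {burn_in}"
        )
    t_burn = burn_in * cfg.dt
    total_time = traj.n_steps * cfg.dt
    retained_time = total_time - t_burn

    term_mask = traj.termination_times > t_burn
    n_term = int(term_mask.sum())
    k_obs = n_term / retained_time
    k_i = cfg.promoter.max_rate
    normalized_rate = k_obs / k_i if k_i > 0 else math.nan

    k_eff = traj.k_i_eff[burn_in:]
    mean_k_eff = float(k_eff.mean())
    free_promoter = k_obs / mean_k_eff if mean_k_eff > 0 else math.nan

    transits = traj.transit_times[term_mask]
    speed = float((cfg.L / transits).mean()) if transits.size else math.nan

    rna = traj.rna[burn_in:]
    mean_rna = float(rna.mean())
    var_rna = float(rna.var())
    if mean_rna > 0:
        fano = var_rna / mean_rna
        norm_var = var_rna / mean_rna**2
    else:
        warnings.warn("zero mean RNA count: Fano factor undefined", stacklevel=2)
        fano = math.nan
        norm_var = math.nan

    return SummaryStats(
        k_obs=k_obs,
        normalized_rate=normalized_rate,
        free_promoter_fraction=free_promoter,
        mean_elongation_speed=speed,
        mean_rna=mean_rna,
        fano=fano,
        normalized_variance=norm_var,
        mean_sigma_up=float(traj.sigma_up[burn_in:].mean()),
        mean_sigma_down=float(traj.sigma_down[burn_in:].mean()),
        mean_sigma_domain=float(traj.sigma_domain[burn_in:].mean()),
        n_terminations=n_term,
        retained_time=retained_time,
    )
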