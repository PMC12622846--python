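"""The timestep loop: stochastic events, then deterministic elongation.

Each timestep spans ``dt = 1/v`` seconds (0.04 s at the default RNAP
velocity of 25 bp/s).  Within the window, stochastic channels -- promoter
initiation, TopoI and gyrase binding on each flank, and scheduled RNA
decays -- are resolved in chronological order: every channel's waiting
time is exponential at its *current* rate, the earliest in-window event
fires, the state (and hence all rates) is updated, and waiting times are
redrawn, until no further event falls inside the window.  By memorylessness
this is realised exactly by drawing one exponential at the total rate and
picking the firing channel in proportion to the individual rates.  After
the stochastic sweep every non-stalled, non-blocked RNAP advances one bp
(holding the flanking linking numbers fixed: the DNA, not the polymerase,
rotates), and any RNAP at the terminator is removed, producing an RNA.
"""

from __future__ import annotations

import heapq
import logging
from math import inf, log

import numpy as np

from .kinetics import sigmoid_rate
from .state import DomainState, SimulationConfig, Trajectory, init_state, sigma_of

__all__ = [
    "EventDraws",
    "effective_initiation_rate",
    "bind_rnap",
    "is_stalled",
    "elongate_all",
    "terminate_if_due",
    "topo_channel_rates",
    "apply_topoI",
    "apply_gyrase",
    "step",
    "run",
]

logger = logging.getLogger(__name__)


class EventDraws:
    """Buffered deterministic stream of random variates.

    Wraps a :class:`numpy.random.Generator`, consuming pre-drawn blocks of
    standard exponentials and uniforms so that scalar draws in the inner
    loop are cheap while remaining fully reproducible from the seed.
    """

    __slots__ = ("rng", "_block", "_exp", "_ie", "_uni", "_iu")

    def __init__(self, rng, block: int = 1 << 15):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.rng = rng
        self._block = block
        self._exp = rng.standard_exponential(block)
        self._ie = 0
        self._uni = rng.random(block)
        self._iu = 0

    def exponential(self) -> float:
        i = self._ie
        if i == self._block:
            self._exp = self.rng.standard_exponential(self._block)
            i = 0
        self._ie = i + 1
        return self._exp[i]

    def uniform(self) -> float:
        i = self._iu
        if i == self._block:
            self._uni = self.rng.random(self._block)
            i = 0
        self._iu = i + 1
        return self._uni[i]

    def geometric(self, mean: float) -> int:
        """Geometric variate on {1, 2, ...} with the given mean (>= 1)."""
        if mean <= 1.0:
            return 1
        p = 1.0 / mean
        return 1 + int(log(1.0 - self.uniform()) / log(1.0 - p))


def _as_draws(rng) -> EventDraws:
    return rng if isinstance(rng, EventDraws) else EventDraws(rng)


def promoter_sigma(state: DomainState, cfg: SimulationConfig) -> float:
    """Supercoiling density of the segment containing the promoter (at D_up)."""
    x = state.x
    if not x or x[0] > cfg.D_up:
        length = x[0] if x else cfg.total_length
        return sigma_of(state.Lk[0], length, cfg.h)
    right = x[1] if len(x) > 1 else cfg.total_length
    return sigma_of(state.Lk[1], right - x[0], cfg.h)


def promoter_occluded(state: DomainState, cfg: SimulationConfig) -> bool:
    return bool(state.x) and state.x[0] < cfg.D_up + cfg.w / 2.0


def effective_initiation_rate(state: DomainState, cfg: SimulationConfig) -> float:
    """Instantaneous initiation rate: 0 when occluded, else the promoter rate law."""
    if promoter_occluded(state, cfg):
        return 0.0
    if not cfg.sc_dependent_initiation:
        return cfg.promoter.max_rate
    return sigmoid_rate(cfg.promoter, promoter_sigma(state, cfg))


def bind_rnap(state: DomainState, cfg: SimulationConfig, birth_time: float | None = None) -> DomainState:
    """Place a new RNAP with its center at ``D_up - w/2`` (downstream edge at the TSS).

    The segment containing that position is split there, both halves
    inheriting its supercoiling density; existing RNAPs shift one index.
    """
    if promoter_occluded(state, cfg):
        logger.warning("bind_rnap called with occluded promoter at t=%.3f; ignored", state.time)
        return state
    x_new = cfg.D_up - cfg.w / 2.0
    seg_len = state.x[0] if state.x else cfg.total_length
    lk = state.Lk[0]
    lk_left = lk * (x_new / seg_len)
    state.Lk[0] = lk_left
    state.Lk.insert(1, lk - lk_left)
    state.x.insert(0, x_new)
    t = state.time if birth_time is None else birth_time
    state.birth.insert(0, t)
    state.initiations += 1
    state.initiation_times.append(t)
    if state.events is not None:
        state.events.append((t, "initiation", ""))
    return state


def is_stalled(state: DomainState, i: int, cfg: SimulationConfig) -> bool:
    """Torque stalling: upstream sigma below -sigma_s or downstream above +sigma_s."""
    x = state.x
    left = x[i - 1] if i > 0 else 0.0
    right = x[i + 1] if i < len(x) - 1 else cfg.total_length
    s_up = sigma_of(state.Lk[i], x[i] - left, cfg.h)
    s_down = sigma_of(state.Lk[i + 1], right - x[i], cfg.h)
    return s_up < -cfg.sigma_s or s_down > cfg.sigma_s


def elongate_all(state: DomainState, cfg: SimulationConfig) -> DomainState:
    """Advance every non-stalled RNAP one bp, holding its flanking Lk fixed.

    RNAPs are processed downstream-first; a trailing RNAP whose advance
    would bring its center closer than ``w`` to the RNAP ahead stays put
    this step (steric blocking).
    """
    x = state.x
    k = len(x)
    if k == 0:
        return state
    Lk = state.Lk
    h = cfg.h
    s_s = cfg.sigma_s
    w = cfg.w
    right = cfg.total_length
    for i in range(k - 1, -1, -1):
        xi = x[i]
        left = x[i - 1] if i else 0.0
        s_up = Lk[i] * h / (xi - left) - 1.0
        s_down = Lk[i + 1] * h / (right - xi) - 1.0
        if s_up < -s_s or s_down > s_s:
            right = xi
            continue
        if i < k - 1 and x[i + 1] - xi < w + 1.0:
            right = xi
            continue
        x[i] = xi + 1.0
        right = xi + 1.0
    return state


def terminate_if_due(state: DomainState, cfg: SimulationConfig, draws: EventDraws) -> DomainState:
    """Remove RNAPs that reached the terminator; merge flanks; queue RNA decay."""
    term_pos = cfg.D_up + cfg.L
    while state.x and state.x[-1] >= term_pos:
        state.x.pop()
        birth = state.birth.pop()
        lk = state.Lk.pop()
        state.Lk[-1] += lk
        state.terminations += 1
        t = state.time
        state.termination_times.append(t)
        state.transit_times.append(t - birth)
        heapq.heappush(state.decay_heap, t + cfg.t_RNA * draws.exponential())
        if state.events is not None:
            state.events.append((t, "termination", ""))
    return state


def topo_channel_rates(
    state: DomainState, cfg: SimulationConfig
) -> tuple[float, float, float, float]:
    """Total event rates (topoI_up, topoI_down, gyrase_up, gyrase_down).

    Topoisomerases bind non-specifically over the gene-flanking regions of
    lengths ``D_up`` and ``D_down``; each channel's rate is the per-bp rate
    law evaluated at the sigma of the segment containing that flank, times
    the flank length.  A gyrase channel is closed when its flank sigma is
    at or below the binding threshold ``sigma_rho``.
    """
    x = state.x
    total = cfg.total_length
    if x:
        s_up = sigma_of(state.Lk[0], x[0], cfg.h)
        s_down = sigma_of(state.Lk[-1], total - x[-1], cfg.h)
    else:
        s_up = s_down = sigma_of(state.Lk[0], total, cfg.h)
    tI_up = sigmoid_rate(cfg.topoI, s_up) * cfg.D_up
    tI_down = sigmoid_rate(cfg.topoI, s_down) * cfg.D_down
    g_up = 0.0 if s_up <= cfg.sigma_rho else sigmoid_rate(cfg.gyrase, s_up) * cfg.D_up
    g_down = 0.0 if s_down <= cfg.sigma_rho else sigmoid_rate(cfg.gyrase, s_down) * cfg.D_down
    return tI_up, tI_down, g_up, g_down


def _flank_index_length(state: DomainState, cfg: SimulationConfig, side: str) -> tuple[int, float]:
    if side == "up":
        return 0, (state.x[0] if state.x else cfg.total_length)
    if side == "down":
        return len(state.Lk) - 1, (
            cfg.total_length - state.x[-1] if state.x else cfg.total_length
        )
    raise ValueError(f"side must be 'up' or 'down', got {side!r}")


def apply_topoI(state: DomainState, side: str) -> DomainState:
    """One TopoI event on the given flank: +1 Lk, instantaneous unbinding."""
    if side == "up":
        idx = 0
    elif side == "down":
        idx = len(state.Lk) - 1
    else:
        raise ValueError(f"side must be 'up' or 'down', got {side!r}")
    state.Lk[idx] += 1.0
    state.topoI_events += 1
    if state.events is not None:
        state.events.append((state.time, "topoI", side))
    return state


def apply_gyrase(
    state: DomainState, side: str, rng, cfg: SimulationConfig
) -> DomainState:
    """One gyrase binding: a geometric number of -2 Lk cycles, capped at sigma_rho.

    The cycle count is geometric on {1, 2, ...} with mean ``rho_G``; cycles
    are applied sequentially and abandoned as soon as the segment's sigma
    has reached ``sigma_rho``, so gyrase never acts on DNA supercoiled
    below its binding threshold.
    """
    draws = _as_draws(rng)
    idx, length = _flank_index_length(state, cfg, side)
    Lk0 = length / cfg.h
    if (state.Lk[idx] - Lk0) / Lk0 <= cfg.sigma_rho:
        raise RuntimeError("apply_gyrase scheduled on a flank at or below sigma_rho")
    n = draws.geometric(cfg.rho_G)
    applied = 0
    for _ in range(n):
        if (state.Lk[idx] - Lk0) / Lk0 <= cfg.sigma_rho:
            break
        state.Lk[idx] -= 2.0
        applied += 1
    state.gyrase_bindings += 1
    state.gyrase_cycles += applied
    if state.events is not None:
        state.events.append((state.time, "gyrase", f"{side}:{applied}"))
    return state


def _sample(state: DomainState, cfg: SimulationConfig):
    x = state.x
    Lk = state.Lk
    h = cfg.h
    total = cfg.total_length
    if x:
        s_up = Lk[0] * h / x[0] - 1.0
        s_down = Lk[-1] * h / (total - x[-1]) - 1.0
    else:
        s_up = s_down = Lk[0] * h / total - 1.0
    s_dom = sum(Lk) * h / total - 1.0
    occ = bool(x) and x[0] < cfg.D_up + cfg.w / 2.0
    if not cfg.sc_dependent_initiation:
        k_eff = cfg.promoter.max_rate
    else:
        if not x or x[0] > cfg.D_up:
            s_prom = s_up
        else:
            right = x[1] if len(x) > 1 else total
            s_prom = Lk[1] * h / (right - x[0]) - 1.0
        k_eff = sigmoid_rate(cfg.promoter, s_prom)
    if cfg.track_drift:
        start = cfg.sigma_start
        drift = state.max_drift
        left = 0.0
        for i, lk in enumerate(Lk):
            r = x[i] if i < len(x) else total
            d = abs(lk * h / (r - left) - 1.0 - start)
            if d > drift:
                drift = d
            left = r
        state.max_drift = drift
    return len(state.decay_heap), len(x), s_up, s_down, s_dom, k_eff, occ


def step(state: DomainState, cfg: SimulationConfig, rng):
    """Advance the state by one timestep; returns the end-of-step sample.

    Stochastic channels are resolved in time order within the window, then
    elongation and termination run deterministically and the clock advances
    by ``dt``.
    """
    draws = _as_draws(rng)
    t_end = state.time + cfg.dt
    t_cur = state.time
    heap = state.decay_heap
    while True:
        r_init = effective_initiation_rate(state, cfg)
        tI_up, tI_down, g_up, g_down = topo_channel_rates(state, cfg)
        R = r_init + tI_up + tI_down + g_up + g_down
        t_decay = heap[0] if heap else inf
        t_event = t_cur + draws.exponential() / R if R > 0.0 else inf
        if t_decay <= t_event:
            if t_decay >= t_end:
                break
            heapq.heappop(heap)
            state.decays += 1
            if state.events is not None:
                state.events.append((t_decay, "decay", ""))
            t_cur = t_decay
            continue
        if t_event >= t_end:
            break
        u = draws.uniform() * R
        if u < r_init:
            bind_rnap(state, cfg, birth_time=t_event)
        elif u < r_init + tI_up:
            state.time = t_event
            apply_topoI(state, "up")
        elif u < r_init + tI_up + tI_down:
            state.time = t_event
            apply_topoI(state, "down")
        elif u < r_init + tI_up + tI_down + g_up:
            state.time = t_event
            apply_gyrase(state, "up", draws, cfg)
        else:
            state.time = t_event
            apply_gyrase(state, "down", draws, cfg)
        t_cur = t_event
    elongate_all(state, cfg)
    state.time = t_end
    terminate_if_due(state, cfg, draws)
    return _sample(state, cfg)


def check_lk_ledger(state: DomainState, tol: float = 1e-6) -> None:
    """Assert the global linking-number ledger; raises on violation."""
    expected = state.expected_total_Lk()
    actual = state.total_Lk()
    scale = max(1.0, abs(expected))
    if abs(actual - expected) > tol * scale:
        raise RuntimeError(
            f"Lk ledger violated: total {actual!r} vs expected {expected!r}"
        )


def run(cfg: SimulationConfig, seed: int | None = None) -> Trajectory:
    """Execute ``cfg.n_steps`` timesteps from a fresh state with a seeded RNG."""
    if seed is None:
        seed = cfg.seed
    draws = EventDraws(np.random.default_rng(seed))
    state = init_state(cfg)
    n = cfg.n_steps
    traj = Trajectory(cfg, n)
    rna = traj.rna
    rnaps = traj.rnaps
    sig_up = traj.sigma_up
    sig_dn = traj.sigma_down
    sig_dom = traj.sigma_domain
    k_eff_arr = traj.k_i_eff
    occl = traj.occluded
    log_every = max(1, int(round(600.0 / cfg.dt)))  # every 10 simulated minutes
    for j in range(n):
        r, p, su, sd, sm, ke, oc = step(state, cfg, draws)
        rna[j] = r
        rnaps[j] = p
        sig_up[j] = su
        sig_dn[j] = sd
        sig_dom[j] = sm
        k_eff_arr[j] = ke
        occl[j] = oc
        if (j + 1) % log_every == 0 and logger.isEnabledFor(logging.INFO):
            logger.info(
                "t=%.0fs rna=%d rnaps=%d init=%d term=%d topoI=%d gyr=%d",
                state.time, r, p, state.initiations, state.terminations,
                state.topoI_events, state.gyrase_bindings,
            )
    check_lk_ledger(state)
    traj.termination_times = np.asarray(state.termination_times)
    traj.transit_times = np.asarray(state.transit_times)
    traj.initiation_times = np.asarray(state.initiation_times)
    traj.events = state.events
    traj.counters = {
        "initiations": state.initiations,
        "terminations": state.terminations,
        "decays": state.decays,
        "topoI_events": state.topoI_events,
        "gyrase_bindings": state.gyrase_bindings,
        "gyrase_cycles": state.gyrase_cycles,
    }
    traj.max_sigma_drift = state.max_drift if cfg.track_drift else None
    return traj
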