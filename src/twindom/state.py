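"""Domain data model and linking-number bookkeeping.

A simulation tracks a linear topological domain ``[0, D_up + L + D_down]``:
a gene of length ``L`` whose transcription start site sits at ``D_up`` and
terminator at ``D_up + L``, flanked by rotation barriers at both domain
ends.  Bound RNA polymerases act as additional rotation barriers, so for
``k`` bound RNAPs the domain is tiled by ``k + 1`` DNA segments, each with
a real-valued linking number ``Lk``.  Supercoiling diffuses instantaneously
within a segment, so each segment has a single supercoiling density

    sigma = (Lk - Lk0) / Lk0,      Lk0 = length / h,

with ``h = 10.5`` bp per turn for relaxed B-form DNA.  The total linking
number over all segments changes only through topoisomerase action (+1 per
TopoI event, -2 per gyrase cycle), never through RNAP binding, elongation
or termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Optional

import numpy as np

from .kinetics import BP_PER_TURN, SigmoidParams, steady_state_rates

__all__ = [
    "SimulationConfig",
    "make_config",
    "Segment",
    "DomainState",
    "Trajectory",
    "sigma_of",
    "init_state",
    "split_segment",
    "merge_segments",
]


def sigma_of(Lk: float, length: float, h: float = BP_PER_TURN) -> float:
    """Supercoiling density of a stretch of ``length`` bp with linking number ``Lk``."""
    if not length > 0:
        raise ValueError(f"segment length must be positive, got {length}")
    Lk0 = length / h
    return (Lk - Lk0) / Lk0


@dataclass(frozen=True)
class SimulationConfig:
    """All model parameters plus run controls.

    Rate laws are carried as :class:`~twindom.kinetics.SigmoidParams`:
    ``promoter`` holds (k_i, sigma_i, beta_i), ``topoI`` (k_T, sigma_T,
    beta_T) and ``gyrase`` (k_G, sigma_G, beta_G).  The timestep is tied to
    the RNAP velocity, ``dt = 1/v``, so that elongation advances exactly
    one bp per step.
    """

    L: float = 1000.0
    D_up: float = 10_000.0
    D_down: float = 10_000.0
    sigma_start: float = -0.055
    promoter: SigmoidParams = field(
        default_factory=lambda: SigmoidParams(0.05, -0.04, 0.005, decreasing=True)
    )
    topoI: SigmoidParams = field(
        default_factory=lambda: SigmoidParams(25.0 / BP_PER_TURN / 10_000.0, -0.04, 0.005, decreasing=True)
    )
    gyrase: SigmoidParams = field(
        default_factory=lambda: SigmoidParams(25.0 / BP_PER_TURN / 80_000.0, 0.0, 0.015, decreasing=False)
    )
    rho_G: float = 4.0
    sigma_rho: float = -0.11
    v: float = 25.0
    sigma_s: float = 0.062
    t_RNA: float = 120.0
    w: float = 30.0
    h: float = BP_PER_TURN
    n_steps: int = 2_000_000
    burn_in_steps: Optional[int] = None
    seed: int = 0
    sc_dependent_initiation: bool = True
    record_events: bool = False
    track_drift: bool = False

    def __post_init__(self) -> None:
        if not self.w < self.L:
            raise ValueError("RNAP footprint w must be smaller than the gene length L")
        if self.D_up < self.w or self.D_down < self.w:
            raise ValueError("barrier distances must be at least the RNAP footprint w")
        if not self.sigma_s > 0:
            raise ValueError("stalling threshold sigma_s must be positive")
        if not (self.v > 0 and self.h > 0 and self.t_RNA > 0 and self.rho_G >= 1):
            raise ValueError("v, h, t_RNA must be positive and rho_G >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")

    @cached_property
    def dt(self) -> float:
        return 1.0 / self.v

    @cached_property
    def total_length(self) -> float:
        return self.D_up + self.L + self.D_down

    @cached_property
    def k_i(self) -> float:
        return self.promoter.max_rate

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


def make_config(
    *,
    D: float = 10_000.0,
    D_up: Optional[float] = None,
    D_down: Optional[float] = None,
    L: float = 1000.0,
    k_i: float = 0.05,
    sigma_i: float = -0.04,
    beta_i: float = 0.005,
    k_T: Optional[float] = None,
    sigma_T: float = -0.04,
    beta_T: float = 0.005,
    k_G: Optional[float] = None,
    sigma_G: float = 0.0,
    beta_G: float = 0.015,
    topoI_fraction: float = 1.0,
    gyrase_fraction: float = 1.0,
    **kwargs,
) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from flat, Table-style parameters.

    When ``k_T``/``k_G`` are not given they default to the steady-state
    values ``k_T*``/``k_G*`` (scaled by ``topoI_fraction`` and
    ``gyrase_fraction``) computed for the barrier distances: TopoI against
    the upstream distance (it removes the upstream negative supercoiling)
    and gyrase against the downstream distance.
    """
    D_up = D if D_up is None else D_up
    D_down = D if D_down is None else D_down
    v = kwargs.get("v", 25.0)
    h = kwargs.get("h", BP_PER_TURN)
    rho_G = kwargs.get("rho_G", 4.0)
    if k_T is None:
        k_T = topoI_fraction * steady_state_rates(D_up, v=v, h=h, rho_G=rho_G).k_T_star
    if k_G is None:
        k_G = gyrase_fraction * steady_state_rates(D_down, v=v, h=h, rho_G=rho_G).k_G_star
    return SimulationConfig(
        L=L,
        D_up=D_up,
        D_down=D_down,
        promoter=SigmoidParams(k_i, sigma_i, beta_i, decreasing=True),
        topoI=SigmoidParams(k_T, sigma_T, beta_T, decreasing=True),
        gyrase=SigmoidParams(k_G, sigma_G, beta_G, decreasing=False),
        **kwargs,
    )


@dataclass(frozen=True)
class Segment:
    """A stretch of DNA between adjacent rotation barriers."""

    start: float
    end: float
    Lk: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> float:
        return self.end - self.start

    def sigma(self, h: float = BP_PER_TURN) -> float:
        return sigma_of(self.Lk, self.length, h)


def split_segment(seg: Segment, at: float) -> tuple[Segment, Segment]:
    """Split a segment at an interior point, partitioning Lk proportionally.

    Both children inherit the parent's supercoiling density, and their
    lengths and linking numbers sum to the parent's.
    """
    if not (seg.start < at < seg.end):
        raise ValueError(f"split point {at} outside ({seg.start}, {seg.end})")
    frac = (at - seg.start) / seg.length
    lk_left = seg.Lk * frac
    return Segment(seg.start, at, lk_left), Segment(at, seg.end, seg.Lk - lk_left)


def merge_segments(a: Segment, b: Segment) -> Segment:
    """Merge two adjacent segments; Lk adds, sigma becomes the length-weighted mix."""
    if a.end != b.start:
        raise ValueError("segments are not adjacent")
    return Segment(a.start, b.end, a.Lk + b.Lk)


class DomainState:
    """Mutable state of the domain during a simulation.

    ``x`` holds RNAP center positions in ascending coordinate order, so
    ``x[0]`` is the most upstream (newest) RNAP; ``Lk[i]`` is the linking
    number of the segment between boundary ``i-1`` and ``i`` of the tiling
    ``[0, x[0], ..., x[-1], total]``.  ``decay_heap`` holds the scheduled
    absolute decay times of surviving transcripts (the RNA copy number is
    its length).
    """

    __slots__ = (
        "time",
        "x",
        "birth",
        "Lk",
        "decay_heap",
        "Lk_initial",
        "initiations",
        "terminations",
        "decays",
        "topoI_events",
        "gyrase_bindings",
        "gyrase_cycles",
        "termination_times",
        "transit_times",
        "initiation_times",
        "events",
        "max_drift",
    )

    def __init__(self, Lk_dom: float):
        self.time = 0.0
        self.x: list[float] = []
        self.birth: list[float] = []
        self.Lk: list[float] = [Lk_dom]
        self.decay_heap: list[float] = []
        self.Lk_initial = Lk_dom
        self.initiations = 0
        self.terminations = 0
        self.decays = 0
        self.topoI_events = 0
        self.gyrase_bindings = 0
        self.gyrase_cycles = 0
        self.termination_times: list[float] = []
        self.transit_times: list[float] = []
        self.initiation_times: list[float] = []
        self.events: Optional[list[tuple[float, str, str]]] = None
        self.max_drift = 0.0

    @property
    def n_rnaps(self) -> int:
        return len(self.x)

    @property
    def rna_count(self) -> int:
        return len(self.decay_heap)

    def total_Lk(self) -> float:
        return sum(self.Lk)

    def expected_total_Lk(self) -> float:
        """Ledger prediction: initial Lk plus TopoI events minus two per gyrase cycle."""
        return self.Lk_initial + self.topoI_events - 2.0 * self.gyrase_cycles

    def segments(self, cfg: SimulationConfig) -> list[Segment]:
        bounds = [0.0, *self.x, cfg.total_length]
        return [Segment(bounds[i], bounds[i + 1], self.Lk[i]) for i in range(len(self.Lk))]


def init_state(cfg: SimulationConfig) -> DomainState:
    """Fresh state: no RNAPs, one domain-spanning segment at ``sigma_start``."""
    Lk_dom = (1.0 + cfg.sigma_start) * cfg.total_length / cfg.h
    state = DomainState(Lk_dom)
    if cfg.record_events:
        state.events = []
    return state


class Trajectory:
    """Per-timestep samples of a run plus sparse event records.

    Samples are taken at the end of each timestep: RNA copy number, bound
    RNAP count, sigma of the upstream and downstream flank segments, the
    domain-average sigma, the instantaneous SC-dependent initiation rate at
    the promoter (evaluated whether or not the promoter is occluded), and
    the occlusion flag.
    """

    def __init__(self, cfg: SimulationConfig, n_steps: int):
        self.cfg = cfg
        self.n_steps = n_steps
        self.rna = np.zeros(n_steps, dtype=np.int32)
        self.rnaps = np.zeros(n_steps, dtype=np.int16)
        self.sigma_up = np.zeros(n_steps)
        self.sigma_down = np.zeros(n_steps)
        self.sigma_domain = np.zeros(n_steps)
        self.k_i_eff = np.zeros(n_steps)
        self.occluded = np.zeros(n_steps, dtype=bool)
        self.termination_times = np.empty(0)
        self.transit_times = np.empty(0)
        self.initiation_times = np.empty(0)
        self.events: Optional[list[tuple[float, str, str]]] = None
        self.counters: dict[str, int] = {}
        self.max_sigma_drift: Optional[float] = None

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_steps, dtype=float) + 1.0) * self.cfg.dt

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "rna": self.rna,
                "rnaps": self.rnaps,
                "sigma_up": self.sigma_up,
                "sigma_down": self.sigma_down,
                "sigma_domain": self.sigma_domain,
                "k_i_eff": self.k_i_eff,
                "occluded": self.occluded.astype(int),
            }
        )
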