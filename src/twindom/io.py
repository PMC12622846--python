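"""Configuration parsing, seeding policy, and file writers/readers.

Config files are TOML with flat keys named after the model symbols
(``k_i``, ``sigma_i``, ``beta_i``, ``k_T``, ``sigma_T``, ``beta_T``,
``k_G``, ``sigma_G``, ``beta_G``, ``rho_G``, ``sigma_rho``, ``L``, ``D`` /
``D_up`` / ``D_down``, ``sigma_start``, ``v``, ``sigma_s``, ``t_RNA``,
``w``, ``h``) plus run controls (``n_steps``, ``burn_in_steps``, ``seed``).
Unspecified keys take the model defaults.  Trajectories and event logs are
written as TSV, summaries and run manifests as JSON.
"""

from __future__ import annotations

import datetime
import json
import tomllib
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import pandas as pd

from .observables import SummaryStats
from .state import SimulationConfig, Trajectory, make_config

__all__ = [
    "CONFIG_KEYS",
    "load_config",
    "config_to_dict",
    "RunManifest",
    "write_outputs",
    "write_trajectory",
    "read_trajectory",
    "write_events",
    "write_summary",
    "read_summary",
]

CONFIG_KEYS = frozenset(
    {
        "L", "D", "D_up", "D_down", "sigma_start",
        "k_i", "sigma_i", "beta_i",
        "k_T", "sigma_T", "beta_T",
        "k_G", "sigma_G", "beta_G",
        "topoI_fraction", "gyrase_fraction",
        "rho_G", "sigma_rho", "v", "sigma_s", "t_RNA", "w", "h",
        "n_steps", "burn_in_steps", "seed",
        "sc_dependent_initiation", "record_events", "track_drift",
    }
)


def load_config(path) -> SimulationConfig:
    """Parse a TOML config; unspecified keys take the model defaults."""
    raw = Path(path).read_bytes()
    data = tomllib.loads(raw.decode())
    unknown = set(data) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return make_config(**data)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Flatten a config back to symbol-named keys (round-trips via make_config)."""
    return {
        "L": cfg.L,
        "D_up": cfg.D_up,
        "D_down": cfg.D_down,
        "sigma_start": cfg.sigma_start,
        "k_i": cfg.promoter.max_rate,
        "sigma_i": cfg.promoter.midpoint,
        "beta_i": cfg.promoter.width,
        "k_T": cfg.topoI.max_rate,
        "sigma_T": cfg.topoI.midpoint,
        "beta_T": cfg.topoI.width,
        "k_G": cfg.gyrase.max_rate,
        "sigma_G": cfg.gyrase.midpoint,
        "beta_G": cfg.gyrase.width,
        "rho_G": cfg.rho_G,
        "sigma_rho": cfg.sigma_rho,
        "v": cfg.v,
        "sigma_s": cfg.sigma_s,
        "t_RNA": cfg.t_RNA,
        "w": cfg.w,
        "h": cfg.h,
        "n_steps": cfg.n_steps,
        "burn_in_steps": cfg.burn_in_steps,
        "seed": cfg.seed,
        "sc_dependent_initiation": cfg.sc_dependent_initiation,
        "record_events": cfg.record_events,
        "track_drift": cfg.track_drift,
    }


def _package_version() -> str:
    try:
        return version("twindom")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunManifest:
    """Provenance record tying outputs to the config and seed that made them."""

    config: dict
    seed: int
    outputs: list = field(default_factory=list)
    code_version: str = field(default_factory=_package_version)
    start_time: Optional[str] = None
    end_time: Optional[str] = None
    checks: dict = field(default_factory=dict)

    @staticmethod
    def now() -> str:
        return datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_events(traj: Trajectory, path) -> None:
    """Event log TSV: always includes initiations/terminations; full log when recorded."""
    if traj.events is not None:
        df = pd.DataFrame(traj.events, columns=["time_s", "event_type", "detail"])
    else:
        rows = [(t, "initiation", "") for t in traj.initiation_times]
        rows += [(t, "termination", "") for t in traj.termination_times]
        rows.sort()
        df = pd.DataFrame(rows, columns=["time_s", "event_type", "detail"])
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_summary(stats: SummaryStats, path, extra: Optional[dict] = None) -> None:
    payload = stats.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def read_summary(path) -> dict:
    return json.loads(Path(path).read_text())


def write_outputs(traj: Trajectory, stats: SummaryStats, manifest: RunManifest, prefix) -> dict:
    """Write the trajectory TSV, event TSV, summary JSON and manifest JSON.

    Returns a mapping of artifact kind to path; every output file is
    referenced by the manifest.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": f"{prefix}.trajectory.tsv",
        "events": f"{prefix}.events.tsv",
        "summary": f"{prefix}.summary.json",
        "manifest": f"{prefix}.manifest.json",
    }
    write_trajectory(traj, paths["trajectory"])
    write_events(traj, paths["events"])
    write_summary(stats, paths["summary"])
    manifest.outputs = [str(p) for p in paths.values()]
    manifest.end_time = RunManifest.now()
    if traj.max_sigma_drift is not None:
        manifest.checks["max_sigma_drift"] = traj.max_sigma_drift
    manifest.checks.setdefault("lk_ledger", True)  # run() raises on violation
    manifest.write(paths["manifest"])
    return paths
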