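"""Phenotype scoring and fitness-proportional selection.

A cell's fitness contribution rewards expression of the zone-correct
fitness protein (CZ protein = TF type 13, OC protein = TF type 12) and
penalizes misexpression:

    CZ cell:     +100 Pcz/(Pcz+100) - 50 Poc/(Poc+200)
    CZ&OC cell:  + 50 Pcz/(Pcz+100) + 50 Poc/(Poc+100)
    OC cell:     +100 Poc/(Poc+100) - 50 Pcz/(Pcz+200)
    other cell:  - 50 Poc/(Poc+200) - 50 Pcz/(Pcz+200)

with a saturation cap: when the zone-correct protein exceeds 400 the cell
contribution is set to exactly 100.  The total fitness averages the
contributions over all cells and all fitness sample times, floored at 0,
which bounds F to [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import FitnessConfig, FITNESS_TYPES
from .develop import Trajectory
from .tissue import Tissue

log = logging.getLogger(__name__)

OC_TYPE, CZ_TYPE = FITNESS_TYPES  # protein 12 = OC target, 13 = CZ target


@dataclass
class FitnessReport:
    F: float
    #: per-sample-time, per-cell contributions (n_samples, n_cells)
    contributions: np.ndarray
    sample_times: np.ndarray
    zones: list[str] = field(default_factory=list)

    @property
    def raw_sum(self) -> float:
        return float(self.contributions.sum())


def cell_fitness(zone: str, p_cz: float, p_oc: float,
                 config: FitnessConfig | None = None) -> float:
    """Fitness contribution of one cell at one time point."""
    cfg = config or FitnessConfig()
    if zone == "CZ":
        f = 100.0 * p_cz / (p_cz + 100.0) - 50.0 * p_oc / (p_oc + 200.0)
        capped = p_cz > cfg.cap
    elif zone == "CZ_OC":
        f = 50.0 * p_cz / (p_cz + 100.0) + 50.0 * p_oc / (p_oc + 100.0)
        capped = p_cz > cfg.cap or p_oc > cfg.cap
    elif zone == "OC":
        f = 100.0 * p_oc / (p_oc + 100.0) - 50.0 * p_cz / (p_cz + 200.0)
        capped = p_oc > cfg.cap
    elif zone == "other":
        f = -50.0 * p_oc / (p_oc + 200.0) - 50.0 * p_cz / (p_cz + 200.0)
        capped = False
    else:
        raise ValueError(f"unknown zone {zone!r}")
    if capped and cfg.cap_overrides_negative:
        return 100.0
    if capped:  # alternative reading: saturate only the positive term
        if zone == "CZ":
            return 100.0 - 50.0 * p_oc / (p_oc + 200.0)
        if zone == "OC":
            return 100.0 - 50.0 * p_cz / (p_cz + 200.0)
        return 100.0
    return f


def _contributions(p_cz: np.ndarray, p_oc: np.ndarray, zones: list[str],
                   cfg: FitnessConfig) -> np.ndarray:
    """Vectorized per-cell contributions; rows = sample times."""
    zones = np.asarray(zones)
    f = np.zeros_like(p_cz)
    m = zones == "CZ"
    f[:, m] = (100.0 * p_cz[:, m] / (p_cz[:, m] + 100.0)
               - 50.0 * p_oc[:, m] / (p_oc[:, m] + 200.0))
    cap = p_cz[:, m] > cfg.cap
    if cfg.cap_overrides_negative:
        f[:, m] = np.where(cap, 100.0, f[:, m])
    else:
        f[:, m] = np.where(cap, 100.0 - 50.0 * p_oc[:, m] / (p_oc[:, m] + 200.0),
                           f[:, m])
    m = zones == "CZ_OC"
    f[:, m] = (50.0 * p_cz[:, m] / (p_cz[:, m] + 100.0)
               + 50.0 * p_oc[:, m] / (p_oc[:, m] + 100.0))
    cap = (p_cz[:, m] > cfg.cap) | (p_oc[:, m] > cfg.cap)
    f[:, m] = np.where(cap, 100.0, f[:, m])
    m = zones == "OC"
    f[:, m] = (100.0 * p_oc[:, m] / (p_oc[:, m] + 100.0)
               - 50.0 * p_cz[:, m] / (p_cz[:, m] + 200.0))
    cap = p_oc[:, m] > cfg.cap
    if cfg.cap_overrides_negative:
        f[:, m] = np.where(cap, 100.0, f[:, m])
    else:
        f[:, m] = np.where(cap, 100.0 - 50.0 * p_cz[:, m] / (p_cz[:, m] + 200.0),
                           f[:, m])
    m = zones == "other"
    f[:, m] = (-50.0 * p_oc[:, m] / (p_oc[:, m] + 200.0)
               - 50.0 * p_cz[:, m] / (p_cz[:, m] + 200.0))
    return f


def total_fitness(trajectory: Trajectory, tissue: Tissue,
                  config: FitnessConfig | None = None) -> FitnessReport:
    """Total fitness F = max(0, sum of contributions / (n_cells *
    n_sample_times)), retaining the per-cell decomposition."""
    cfg = config or FitnessConfig()
    if trajectory.n_samples == 0:
        raise ValueError("trajectory contains no fitness sample times")
    p_cz = trajectory.P[:, CZ_TYPE, :]
    p_oc = trajectory.P[:, OC_TYPE, :]
    zones = tissue.zones
    f = _contributions(p_cz, p_oc, zones, cfg)
    F = max(0.0, f.sum() / (tissue.n_cells * trajectory.n_samples))
    return FitnessReport(F=F, contributions=f,
                         sample_times=trajectory.times, zones=zones)


def field_fitness(p_cz: np.ndarray, p_oc: np.ndarray, zones: list[str],
                  config: FitnessConfig | None = None) -> float:
    """Fitness of explicit concentration fields (n_samples, n_cells)."""
    cfg = config or FitnessConfig()
    p_cz = np.atleast_2d(p_cz)
    p_oc = np.atleast_2d(p_oc)
    f = _contributions(p_cz, p_oc, zones, cfg)
    return max(0.0, float(f.sum()) / (p_cz.shape[1] * p_cz.shape[0]))


def select_parents(fitnesses, n_offspring: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional parent choice: rho(i) = F_i / sum_j F_j,
    independent draws.  Falls back to uniform choice when every fitness is
    zero."""
    f = np.asarray(fitnesses, dtype=float)
    if (f < 0).any():
        raise ValueError("fitnesses must be non-negative")
    total = f.sum()
    if total <= 0.0:
        log.warning("all fitnesses zero; selecting parents uniformly")
        return rng.integers(0, f.size, size=n_offspring)
    return rng.choice(f.size, size=n_offspring, p=f / total)
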