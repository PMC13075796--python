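"""Shared fixtures.

The expensive evolutionary fixtures are session-scoped and shared between
the dynamics tests: three scaled selected runs with matched no-selection
controls, plus a clone experiment continued from the first run.
"""

from __future__ import annotations

import numpy as np
import pytest

import samdrift as sd
from samdrift.evolve import run_evolution, run_control, clone_and_continue

EVO_SEEDS = (11, 12, 13)


def scaled_config(seed: int) -> sd.RunConfig:
    """Desk-preset configuration scaled to the test budget: 50 individuals,
    40-cell tissues, 600 generations (the smallest scale at which selected
    runs reliably clear the adaptation threshold)."""
    cfg = sd.desk_config(seed)
    cfg.evo.population_size = 50
    cfg.evo.generations = 600
    cfg.evo.n_tissues = 4
    return cfg


@pytest.fixture(scope="session")
def small_tissue():
    cfg = sd.desk_config(0)
    return sd.generate_tissue(42, cfg.tissue, cfg.fitness)


@pytest.fixture(scope="session")
def tiny_pool(small_tissue):
    return [small_tissue]


@pytest.fixture(scope="session")
def desk_cfg():
    return sd.desk_config(0)


def all_cz_fitness_config() -> sd.FitnessConfig:
    """Zone configuration labelling every cell CZ (toy phenotypes where a
    single uniformly expressed fitness gene gives positive fitness)."""
    from samdrift.config import ZoneBox
    big = 1e9
    return sd.FitnessConfig(cz_box=ZoneBox(-big, big, -big, np.inf),
                            cz_oc_box=ZoneBox(0, 0, 0, 0),
                            oc_box=ZoneBox(0, 0, 0, 0))


@pytest.fixture(scope="session")
def all_cz_tissue(small_tissue):
    """The small tissue relabelled so every cell is a CZ cell."""
    t = sd.Tissue.from_dict(small_tissue.to_dict(), small_tissue.config)
    sd.assign_zones(t, all_cz_fitness_config())
    sd.mark_l1(t)
    return t


@pytest.fixture(scope="session")
def evolved_runs():
    """Three scaled selected runs plus matched no-selection controls."""
    runs = {}
    for seed in EVO_SEEDS:
        cfg = scaled_config(seed)
        logd, state = run_evolution(cfg)
        ccfg = scaled_config(seed + 1000)
        ccfg.evo.selection = "uniform"
        ccfg.evo.skip_development = True
        clog, _ = run_control(ccfg)
        runs[seed] = {"config": cfg, "log": logd, "state": state,
                      "control": clog}
    return runs


@pytest.fixture(scope="session")
def clone_runs(evolved_runs):
    """Two clone lineages continued from the first selected run."""
    state = evolved_runs[EVO_SEEDS[0]]["state"]
    return clone_and_continue(state, 2, 250, seeds=[21, 22])
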